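import numpy as np
import pytest

from kelpscan.variant_io import GenotypeMatrix


def make_matrix(genotypes, positions=None, chrom="chr1", sample_ids=None,
                contig_length=None, chroms=None):
    """Build a GenotypeMatrix from a (samples x sites) array of codes."""
    g = np.asarray(genotypes, dtype=np.int8)
    n_samples, n_sites = g.shape
    if positions is None:
        positions = np.arange(1, n_sites + 1) * 10
    positions = np.asarray(positions, dtype=np.int64)
    if chroms is None:
        chroms = np.full(n_sites, chrom, dtype=object)
    else:
        chroms = np.asarray(chroms, dtype=object)
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(n_samples)]
    lengths = None
    if contig_length is not None:
        lengths = {c: contig_length for c in dict.fromkeys(chroms)}
    return GenotypeMatrix(
        sample_ids=list(sample_ids),
        chrom=chroms,
        pos=positions,
        ref=np.full(n_sites, "A", dtype=object),
        alt=np.full(n_sites, "T", dtype=object),
        genotypes=g,
        contig_lengths=lengths,
    )


def random_matrix(rng, n_samples=None, n_sites=None, missing_rate=0.0,
                  length=10_000):
    """Random small genotype matrix for oracle-equivalence checks."""
    n_samples = n_samples or int(rng.integers(2, 11))
    n_sites = n_sites or int(rng.integers(1, 51))
    g = rng.integers(0, 3, size=(n_samples, n_sites)).astype(np.int8)
    if missing_rate > 0:
        g[rng.random(g.shape) < missing_rate] = -1
    positions = np.sort(rng.choice(length, size=n_sites, replace=False)) + 1
    return make_matrix(g, positions=positions, contig_length=length)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
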