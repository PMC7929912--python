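import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kelpscan import variant_io as vio
from kelpscan.variant_io import (
    MISSING,
    FilterReport,
    GenotypeMatrix,
    PopulationMap,
    VcfParseError,
    Window,
    filter_variants,
    make_windows,
    read_vcf,
    write_vcf,
)

from conftest import make_matrix, random_matrix


def write_text_vcf(path, body, samples=("s1",)):
    header = (
        "##fileformat=VCFv4.2\n"
        "##contig=<ID=chr1,length=100000>\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples) + "\n"
    )
    path.write_text(header + body)


class TestReadVcf:
    def test_single_het_record(self, tmp_path):
        p = tmp_path / "a.vcf"
        write_text_vcf(p, "chr1\t100\t.\tA\tT\t.\t.\t.\tGT\t0/1\n")
        m = read_vcf(p)
        assert m.n_samples == 1 and m.n_sites == 1
        assert m.genotypes[0, 0] == 1
        assert m.pos[0] == 100 and m.ref[0] == "A" and m.alt[0] == "T"

    def test_missing_and_half_missing(self, tmp_path):
        p = tmp_path / "a.vcf"
        write_text_vcf(p, "chr1\t100\t.\tA\tT\t.\t.\t.\tGT\t./.\t./1\n",
                       samples=("s1", "s2"))
        m = read_vcf(p)
        assert m.genotypes[0, 0] == MISSING
        assert m.genotypes[1, 0] == MISSING

    def test_phased_separator_ignored(self, tmp_path):
        p = tmp_path / "a.vcf"
        write_text_vcf(p, "chr1\t100\t.\tA\tT\t.\t.\t.\tGT\t1|1\n")
        assert read_vcf(p).genotypes[0, 0] == 2

    def test_non_diploid_call_rejected(self, tmp_path):
        p = tmp_path / "a.vcf"
        write_text_vcf(p, "chr1\t100\t.\tA\tT\t.\t.\t.\tGT\t0\n")
        with pytest.raises(VcfParseError, match="chr1:100"):
            read_vcf(p)

    def test_no_gt_rejected(self, tmp_path):
        p = tmp_path / "a.vcf"
        p.write_text(
            "##fileformat=VCFv4.2\n##contig=<ID=chr1,length=1000>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "chr1\t100\t.\tA\tT\t.\t.\t.\n")
        with pytest.raises(VcfParseError):
            read_vcf(p)

    def test_unsorted_rejected(self, tmp_path):
        p = tmp_path / "a.vcf"
        write_text_vcf(p, "chr1\t200\t.\tA\tT\t.\t.\t.\tGT\t0/0\n"
                          "chr1\t100\t.\tA\tT\t.\t.\t.\tGT\t0/0\n")
        with pytest.raises(VcfParseError):
            read_vcf(p)


class TestWriteVcf:
    def test_header_only_for_empty_sites(self, tmp_path):
        m = make_matrix(np.empty((2, 0), dtype=np.int8), positions=[],
                        contig_length=1000)
        path = tmp_path / "empty.vcf"
        write_vcf(m, path)
        lines = path.read_text().splitlines()
        assert all(l.startswith("#") for l in lines)
        back = read_vcf(path)
        assert back.n_sites == 0 and back.sample_ids == m.sample_ids

    def test_shape(self, tmp_path):
        m = make_matrix([[0, 1, 2], [2, 1, 0]])
        path = tmp_path / "m.vcf"
        write_vcf(m, path)
        body = [l for l in path.read_text().splitlines() if not l.startswith("#")]
        assert len(body) == 3
        assert all(len(l.split("\t")) == 11 for l in body)  # 9 fixed + 2 samples

    def test_round_trip_identity(self, tmp_path, rng):
        for k in range(5):
            m = random_matrix(rng, missing_rate=0.1 if k % 2 else 0.0)
            path = tmp_path / f"rt{k}.vcf"
            write_vcf(m, path)
            assert read_vcf(path).equal(m)


class TestFilterVariants:
    @pytest.fixture
    def toy(self):
        # 25 samples x 5 sites: indel, triallelic, MAF 0.02, and 2 passing
        n = 25
        g = np.zeros((n, 5), dtype=np.int8)
        g[:10, 0] = 1          # indel site, freq irrelevant
        g[:10, 1] = 1          # triallelic site
        g[0, 2] = 1            # singleton het -> MAF 1/50 = 0.02
        g[:10, 3] = 1          # MAF 0.2
        g[:5, 4] = 2           # MAF 0.2
        m = make_matrix(g)
        m.ref[0] = "AT"        # indel
        m.alt[1] = "T,G"       # multi-allelic SNP
        return m

    def test_derived_counts(self, toy):
        out, rep = filter_variants(toy, maf_min=0.05)
        assert out.n_sites == 2
        assert rep.removed_non_snp == 1
        assert rep.removed_multiallelic == 1
        assert rep.removed_maf == 1
        assert rep.n_retained == 2
        rep.check()

    def test_empty_matrix(self):
        m = make_matrix(np.empty((3, 0), dtype=np.int8), positions=[])
        out, rep = filter_variants(m, maf_min=0.1)
        assert out.n_sites == 0 and rep.n_input == 0
        rep.check()

    def test_noop_filter_is_identity(self, rng):
        m = random_matrix(rng, missing_rate=0.2)
        out, rep = filter_variants(m, snps_only=False, biallelic_only=False,
                                   maf_min=0.0, max_missing=1.0)
        assert out.equal(m)
        assert rep.n_retained == m.n_sites

    def test_idempotent(self, rng):
        m = random_matrix(rng, missing_rate=0.2)
        kw = dict(maf_min=0.1, max_missing=0.3)
        once, _ = filter_variants(m, **kw)
        twice, rep = filter_variants(once, **kw)
        assert twice.equal(once)
        assert rep.n_retained == once.n_sites

    def test_call_rate_rule(self):
        g = np.array([[MISSING, 1], [MISSING, 1], [0, 0], [1, 1]], dtype=np.int8)
        m = make_matrix(g)
        out, rep = filter_variants(m, max_missing=0.25)
        assert rep.removed_callrate == 1 and out.n_sites == 1


class TestMakeWindows:
    def test_truncated_tail(self):
        w = make_windows({"c": 120_000}, 50_000)
        assert [(x.start, x.end) for x in w] == [
            (0, 50_000), (50_000, 100_000), (100_000, 120_000)]

    def test_exact_fit(self):
        assert len(make_windows({"c": 50_000}, 50_000)) == 1

    def test_non_positive_size(self):
        with pytest.raises(ValueError):
            make_windows({"c": 100}, 0)

    @given(st.dictionaries(st.sampled_from(["c1", "c2", "c3"]),
                           st.integers(1, 10**6), min_size=1),
           st.integers(1, 10**5))
    @settings(max_examples=50, deadline=None)
    def test_partition(self, contigs, size):
        windows = make_windows(contigs, size)
        # conservation of length
        assert sum(w.length for w in windows) == sum(contigs.values())
        # non-overlap and sortedness per contig
        for chrom in contigs:
            ws = [w for w in windows if w.chrom == chrom]
            assert ws[0].start == 0 and ws[-1].end == contigs[chrom]
            for a, b in zip(ws, ws[1:]):
                assert a.end == b.start


class TestSideFiles:
    def test_popmap_round_trip(self, tmp_path):
        pm = PopulationMap({"a": ("p1", "natural"), "b": ("p2", "cultivated"),
                            "c": ("p1", "natural")})
        path = tmp_path / "pm.tsv"
        vio.write_popmap(pm, path)
        back = vio.read_popmap(path)
        assert back.entries == pm.entries
        assert back.populations == ["p1", "p2"]
        assert back.samples_in("p1") == ["a", "c"]
        assert back.resolve_group("cultivated") == ["b"]

    def test_popmap_rejects_bad_category(self):
        with pytest.raises(ValueError):
            PopulationMap({"a": ("p1", "wild")})

    def test_contig_lengths_round_trip(self, tmp_path):
        d = {"chr1": 1000, "chr2": 500}
        path = tmp_path / "cl.tsv"
        vio.write_contig_lengths(d, path)
        assert vio.read_contig_lengths(path) == d

    def test_bed_round_trip(self, tmp_path):
        from kelpscan.synthetic_data import synthetic_genes
        genes = synthetic_genes({"chr1": 30_000}, gene_length=2000, spacing=5000)
        path = tmp_path / "g.bed"
        vio.write_bed(genes, path)
        back = vio.read_bed(path)
        assert back.equals(genes)

    def test_validate_against(self):
        pm = PopulationMap({"s0": ("p", "natural")})
        m = make_matrix([[0, 1], [1, 0]])
        with pytest.raises(ValueError, match="s1"):
            pm.validate_against(m)


class TestGenotypeMatrix:
    def test_rejects_bad_codes(self):
        with pytest.raises(ValueError):
            make_matrix([[0, 5]])

    def test_rejects_duplicate_positions(self):
        with pytest.raises(ValueError):
            make_matrix([[0, 1]], positions=[10, 10])

    def test_sites_in_window_is_half_open(self):
        m = make_matrix([[0, 1, 2]], positions=[100, 150, 200])
        # 0-based window [99, 150) holds 1-based positions 100..150
        assert list(m.sites_in("chr1", 99, 150)) == [0, 1]
        assert list(m.sites_in("chr1", 100, 199)) == [1]

    def test_subset_by_samples_and_sites(self):
        m = make_matrix([[0, 1, 2], [2, 1, 0]])
        sub = m.subset(samples=["s1"], sites=np.array([0, 2]))
        assert sub.sample_ids == ["s1"]
        assert list(sub.genotypes[0]) == [2, 0]
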