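import math

import numpy as np
import pytest

from kelpscan import diversity as dv
from kelpscan.variant_io import MISSING, Window

import oracles
from conftest import make_matrix, random_matrix


class TestSitePi:
    def test_two_of_four(self):
        assert dv.site_pi(2, 4) == pytest.approx(0.666667, abs=1e-6)
        # oracle: 4 of the C(4,2)=6 allele pairs differ
        assert oracles.oracle_site_pi(2, 4) == pytest.approx(2 / 3)

    def test_monomorphic(self):
        assert dv.site_pi(0, 10) == 0.0
        assert dv.site_pi(10, 10) == 0.0

    def test_undefined_below_two_alleles(self):
        assert math.isnan(dv.site_pi(0, 1))


class TestWindowPi:
    def test_two_sites_in_100bp(self):
        # both sites have site_pi = 2/3 with 2 diploid samples (j=2, n=4)
        m = make_matrix([[1, 1], [1, 1]], positions=[10, 20], contig_length=100)
        pi, n_snps = dv.window_pi(m, Window("chr1", 0, 100), m.sample_ids)
        assert pi == pytest.approx(0.013333, abs=1e-6)
        assert n_snps == 2

    def test_empty_window(self):
        m = make_matrix([[1], [1]], positions=[500], contig_length=1000)
        pi, n_snps = dv.window_pi(m, Window("chr1", 0, 100), m.sample_ids)
        assert pi == 0.0 and n_snps == 0

    def test_denominator_scaling(self):
        m = make_matrix([[1, 1], [1, 1]], positions=[10, 20], contig_length=200)
        pi_100, _ = dv.window_pi(m, Window("chr1", 0, 100), m.sample_ids)
        pi_200, _ = dv.window_pi(m, Window("chr1", 0, 200), m.sample_ids)
        assert pi_200 == pytest.approx(pi_100 / 2)


class TestWatterson:
    def test_worked_example(self):
        assert dv.watterson_theta(3, 4, 100) == pytest.approx(0.016364, abs=1e-6)

    def test_no_segregating_sites(self):
        assert dv.watterson_theta(0, 8, 100) == 0.0

    def test_two_alleles(self):
        assert dv.watterson_theta(5, 2, 100) == pytest.approx(0.05)

    def test_undefined(self):
        assert math.isnan(dv.watterson_theta(3, 1, 100))


class TestTajimasD:
    def test_worked_example_n4(self):
        # alt counts {2, 2, 1} over 4 alleles (2 diploid samples)
        m = make_matrix([[1, 2, 1], [1, 0, 0]], positions=[10, 20, 30],
                        contig_length=100)
        d = dv.tajimas_d(m, Window("chr1", 0, 100), m.sample_ids)
        assert d == pytest.approx(1.090, abs=1e-3)
        assert d == pytest.approx(oracles.oracle_tajima_d([2, 2, 1], 4), abs=1e-12)

    def test_no_segregating_sites_missing(self):
        m = make_matrix([[0, 0], [0, 0]], positions=[10, 20], contig_length=100)
        assert math.isnan(dv.tajimas_d(m, Window("chr1", 0, 100), m.sample_ids))

    def test_singleton_excess_is_negative(self):
        # every site a singleton: rare-variant excess, D < 0
        n = 6
        g = np.zeros((n, n), dtype=np.int8)
        for j in range(n):
            g[j, j] = 1
        m = make_matrix(g, positions=np.arange(1, n + 1) * 10, contig_length=100)
        d = dv.tajimas_d(m, Window("chr1", 0, 100), m.sample_ids)
        assert d < 0
        assert d == pytest.approx(oracles.oracle_tajima_d([1] * n, 2 * n), abs=1e-12)


class TestHeterozygosity:
    def test_all_het_worked_example(self):
        m = make_matrix([[1], [1], [1], [1]], positions=[10], contig_length=100)
        he, ho = dv.expected_observed_het(m, Window("chr1", 0, 100), m.sample_ids)
        assert ho == 1.0
        assert he == pytest.approx(0.5714, abs=1e-4)
        assert dv.inbreeding_fis(he, ho) == pytest.approx(-0.75, abs=1e-3)

    def test_monomorphic_window_missing(self):
        m = make_matrix([[0], [0]], positions=[10], contig_length=100)
        he, ho = dv.expected_observed_het(m, Window("chr1", 0, 100), m.sample_ids)
        assert math.isnan(he) and math.isnan(ho)

    def test_fis_edge_cases(self):
        assert dv.inbreeding_fis(0.5, 0.5) == 0.0
        assert dv.inbreeding_fis(0.5, 0.0) == 1.0
        assert math.isnan(dv.inbreeding_fis(0.0, 0.0))


class TestWeirCockerhamFst:
    def test_fixed_difference_is_one(self):
        g = np.array([[0] * 1] * 10 + [[2] * 1] * 10, dtype=np.int8)
        m = make_matrix(g, positions=[10], contig_length=100)
        a = m.sample_ids[:10]
        b = m.sample_ids[10:]
        assert dv.weir_cockerham_fst(m, Window("chr1", 0, 100), a, b) == pytest.approx(1.0)

    def test_same_samples_near_zero(self, rng):
        # identical groups give theta-hat ~ -1/(2(n-1)) under HWE, so a
        # sample of 20 diploids keeps the magnitude inside 0.05
        freqs = rng.uniform(0.2, 0.8, size=60)
        g = (rng.random((20, 60, 2)) < freqs[None, :, None]).sum(axis=2)
        m = make_matrix(g.astype(np.int8), positions=np.arange(1, 61) * 100,
                        contig_length=10_000)
        w = Window("chr1", 0, 10_000)
        v = dv.weir_cockerham_fst(m, w, m.sample_ids, m.sample_ids)
        assert abs(v) < 0.05

    def test_hom_frequency_example_vs_oracle(self):
        # 2 pops x 5 diploids, one site, freqs 0.2 vs 0.8, all homozygous
        ga = np.array([[2], [0], [0], [0], [0]], dtype=np.int8)
        gb = np.array([[2], [2], [2], [2], [0]], dtype=np.int8)
        m = make_matrix(np.vstack([ga, gb]), positions=[10], contig_length=100)
        v = dv.weir_cockerham_fst(m, Window("chr1", 0, 100),
                                  m.sample_ids[:5], m.sample_ids[5:])
        assert v == pytest.approx(oracles.oracle_wc_fst(ga, gb), abs=1e-12)

    def test_symmetry(self, rng):
        for _ in range(10):
            m = random_matrix(rng, n_samples=8, n_sites=20, missing_rate=0.1)
            w = Window("chr1", 0, 10_000)
            a, b = m.sample_ids[:4], m.sample_ids[4:]
            ab = dv.weir_cockerham_fst(m, w, a, b)
            ba = dv.weir_cockerham_fst(m, w, b, a)
            assert (math.isnan(ab) and math.isnan(ba)) or ab == pytest.approx(ba, abs=1e-12)

    def test_fully_missing_population(self):
        g = np.array([[0, 1], [1, 0], [MISSING, MISSING], [MISSING, MISSING]],
                     dtype=np.int8)
        m = make_matrix(g)
        v = dv.weir_cockerham_fst(m, Window("chr1", 0, 100),
                                  m.sample_ids[:2], m.sample_ids[2:])
        assert math.isnan(v)


class TestRodAndDelta:
    def test_rod_examples(self):
        assert dv.rod(0.001, 0.004) == pytest.approx(0.75)
        assert dv.rod(0.002, 0.002) == 0.0
        assert dv.rod(0.0, 0.002) == 1.0
        assert math.isnan(dv.rod(0.001, 0.0))

    def test_delta_examples(self):
        assert dv.delta_tajima(-1.2, 0.3) == pytest.approx(-1.5)
        assert dv.delta_tajima(0.4, 0.4) == 0.0
        assert math.isnan(dv.delta_tajima(math.nan, 0.3))


class TestInvariances:
    def test_sample_reordering(self, rng):
        m = random_matrix(rng, n_samples=8, n_sites=30, missing_rate=0.1)
        w = Window("chr1", 0, 10_000)
        perm = list(rng.permutation(m.sample_ids))
        assert dv.window_pi(m, w, m.sample_ids)[0] == pytest.approx(
            dv.window_pi(m, w, perm)[0], abs=1e-12)
        he1, ho1 = dv.expected_observed_het(m, w, m.sample_ids)
        he2, ho2 = dv.expected_observed_het(m, w, perm)
        assert he1 == pytest.approx(he2, abs=1e-12)
        assert ho1 == pytest.approx(ho2, abs=1e-12)

    def test_allele_label_swap(self, rng):
        m = random_matrix(rng, n_samples=8, n_sites=30)
        swapped = make_matrix(2 - m.genotypes, positions=m.pos,
                              contig_length=10_000)
        w = Window("chr1", 0, 10_000)
        a, b = m.sample_ids[:4], m.sample_ids[4:]
        assert dv.window_pi(m, w, m.sample_ids)[0] == pytest.approx(
            dv.window_pi(swapped, w, m.sample_ids)[0], abs=1e-12)
        he1, _ = dv.expected_observed_het(m, w, m.sample_ids)
        he2, _ = dv.expected_observed_het(swapped, w, m.sample_ids)
        assert he1 == pytest.approx(he2, abs=1e-12)
        f1 = dv.weir_cockerham_fst(m, w, a, b)
        f2 = dv.weir_cockerham_fst(swapped, w, a, b)
        assert (math.isnan(f1) and math.isnan(f2)) or f1 == pytest.approx(f2, abs=1e-12)


class TestTables:
    def test_population_window_stats_columns(self, rng):
        m = random_matrix(rng, n_samples=6, n_sites=40)
        windows = [Window("chr1", 0, 5_000), Window("chr1", 5_000, 10_000)]
        df = dv.population_window_stats(m, m.sample_ids, windows)
        assert list(df["start"]) == [0, 5_000]
        assert (df["n_snps"] <= 40).all()
        assert (df["pi"] >= 0).all()
        assert df["he"].dropna().between(0, 1).all()

    def test_pair_window_stats_orientation(self, rng):
        m = random_matrix(rng, n_samples=8, n_sites=40)
        windows = [Window("chr1", 0, 10_000)]
        a, b = m.sample_ids[:4], m.sample_ids[4:]
        fwd = dv.pair_window_stats(m, a, b, windows)
        rev = dv.pair_window_stats(m, b, a, windows)
        # swapping focal/reference negates delta D and remaps ROD
        if not math.isnan(fwd["delta_d"][0]):
            assert rev["delta_d"][0] == pytest.approx(-fwd["delta_d"][0], abs=1e-12)
        assert fwd["fst"][0] == pytest.approx(rev["fst"][0], abs=1e-12)
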