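import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from migradiv import popgen_stats as ps
from migradiv.formats_io import MISSING, CallableMask, GenomeLayout, VariantTable

from _oracles import (
    nearest_feature_brute,
    site_pairwise_dxy,
    site_pairwise_pi,
    tajimas_d_direct,
    wc_components_site,
)


def toy_dosage(rng, n_sites=50, n1=5, n2=7, missing_rate=0.05):
    dos = rng.integers(0, 3, size=(n_sites, n1 + n2)).astype(np.int8)
    dos[rng.random(dos.shape) < missing_rate] = MISSING
    return dos, np.arange(n1), np.arange(n1, n1 + n2)


class TestWeirCockerhamFst:
    def test_fixed_difference_gives_one(self):
        dos = np.array([[0, 0, 0, 2, 2, 2]], dtype=np.int8)
        a, b, c = ps.wc_fst_components(dos, np.arange(3), np.arange(3, 6))
        assert a[0] / (a + b + c)[0] == pytest.approx(1.0)

    def test_identical_populations_nonpositive(self, rng):
        block = rng.integers(0, 3, size=(20, 6)).astype(np.int8)
        dos = np.concatenate([block, block], axis=1)
        a, b, c = ps.wc_fst_components(dos, np.arange(6), np.arange(6, 12))
        est = a / (a + b + c)
        assert np.all(est[np.isfinite(est)] <= 1e-12)

    def test_monomorphic_site_undefined(self):
        dos = np.zeros((1, 8), dtype=np.int8)
        a, b, c = ps.wc_fst_components(dos, np.arange(4), np.arange(4, 8))
        assert (a + b + c)[0] == 0  # estimate undefined, not 0

    def test_matches_scalar_oracle(self, rng):
        dos, g1, g2 = toy_dosage(rng)
        a, b, c = ps.wc_fst_components(dos, g1, g2)
        for i in range(len(dos)):
            oa, ob, oc = wc_components_site(dos[i, g1], dos[i, g2])
            np.testing.assert_allclose([a[i], b[i], c[i]], [oa, ob, oc],
                                       atol=1e-12, equal_nan=True)

    def test_specified_counts_against_oracle(self):
        # pop1: 4x hom-ref + 4x het; pop2: 2x het + 6x hom-alt
        d1 = np.array([0, 0, 0, 0, 1, 1, 1, 1], dtype=np.int8)
        d2 = np.array([1, 1, 2, 2, 2, 2, 2, 2], dtype=np.int8)
        dos = np.concatenate([d1, d2])[None, :]
        a, b, c = ps.wc_fst_components(dos, np.arange(8), np.arange(8, 16))
        oa, ob, oc = wc_components_site(d1, d2)
        assert a[0] / (a + b + c)[0] == pytest.approx(oa / (oa + ob + oc), abs=1e-12)

    @given(st.integers(0, 2 ** 32 - 1))
    def test_symmetric_under_population_swap(self, seed):
        dos, g1, g2 = toy_dosage(np.random.default_rng(seed), n_sites=5)
        a1, b1, c1 = ps.wc_fst_components(dos, g1, g2)
        a2, b2, c2 = ps.wc_fst_components(dos, g2, g1)
        np.testing.assert_allclose(a1, a2, atol=1e-12, equal_nan=True)
        np.testing.assert_allclose(b1 + c1, b2 + c2, atol=1e-12, equal_nan=True)

    def test_window_weighted_single_site_equals_site_estimate(self, rng):
        dos, g1, g2 = toy_dosage(rng, n_sites=1, missing_rate=0)
        a, b, c = ps.wc_fst_components(dos, g1, g2)
        if not np.isnan(a[0]) and (a + b + c)[0] != 0:
            assert ps.window_fst_weighted(a, b, c) == pytest.approx(
                (a / (a + b + c))[0])


class TestDiversityDivergence:
    def test_all_identical_zero_pi(self):
        dos = np.full((10, 4), 2, dtype=np.int8)
        terms, _ = ps.site_pi_terms(dos, np.arange(4))
        assert np.all(terms == 0)

    def test_two_haplotypes_one_diff_in_100(self):
        # one diploid sample = 2 haplotypes; het at 1 of 100 callable sites
        dos = np.zeros((1, 1), dtype=np.int8)
        dos[0, 0] = 1
        terms, _ = ps.site_pi_terms(dos, np.array([0]))
        assert terms.sum() / 100 == pytest.approx(0.01)

    def test_pi_matches_pairwise_oracle(self, rng):
        dos, g1, _ = toy_dosage(rng)
        terms, _ = ps.site_pi_terms(dos, g1)
        for i in range(len(dos)):
            np.testing.assert_allclose(np.nan_to_num(terms[i]),
                                       np.nan_to_num(site_pairwise_pi(dos[i, g1])),
                                       atol=1e-10)

    def test_dxy_matches_pairwise_oracle(self, rng):
        dos, g1, g2 = toy_dosage(rng)
        terms = ps.site_dxy_terms(dos, g1, g2)
        for i in range(len(dos)):
            np.testing.assert_allclose(np.nan_to_num(terms[i]),
                                       np.nan_to_num(site_pairwise_dxy(dos[i, g1], dos[i, g2])),
                                       atol=1e-10)

    def test_fixed_groups_dxy_equals_da(self):
        # groups fixed for haplotypes differing at 5 of 1000 callable sites
        dos = np.zeros((5, 8), dtype=np.int8)
        dos[:, 4:] = 2
        g1, g2 = np.arange(4), np.arange(4, 8)
        dxy = ps.site_dxy_terms(dos, g1, g2).sum() / 1000
        pi1, _ = ps.site_pi_terms(dos, g1)
        pi2, _ = ps.site_pi_terms(dos, g2)
        da = dxy - (pi1.sum() + pi2.sum()) / 2 / 1000
        assert dxy == pytest.approx(0.005) and da == pytest.approx(0.005)

    def test_pi_invariant_under_relabeling(self, rng):
        dos, g1, _ = toy_dosage(rng)
        t1, _ = ps.site_pi_terms(dos, g1)
        t2, _ = ps.site_pi_terms(dos, g1[::-1])
        np.testing.assert_allclose(t1, t2, equal_nan=True)


class TestTajimasD:
    def test_constants_harmonic_sum(self):
        k = ps.tajima_coefficients(10)
        assert k.a1 == pytest.approx(sum(1 / i for i in range(1, 10)))
        assert np.isfinite([k.b1, k.b2, k.c1, k.c2, k.e1, k.e2]).all()

    def test_no_segregating_sites_undefined(self):
        assert np.isnan(ps.tajimas_d(0, 0.0, 20))

    def test_all_singletons_negative(self):
        # 10 diploids (n=20 haplotypes), 3 sites each with a single het carrier
        dos = np.zeros((3, 10), dtype=np.int8)
        for i in range(3):
            dos[i, i] = 1
        terms, _ = ps.site_pi_terms(dos, np.arange(10))
        d = ps.tajimas_d(3, float(terms.sum()), 20)
        assert d < 0

    def test_matches_bruteforce_oracle(self, rng):
        dos, g1, _ = toy_dosage(rng, missing_rate=0)
        terms, _ = ps.site_pi_terms(dos, g1)
        seg = terms > 0
        d = ps.tajimas_d(int(seg.sum()), float(terms[seg].sum()), 2 * len(g1))
        assert d == pytest.approx(tajimas_d_direct(dos, g1), abs=1e-10)

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            ps.tajima_coefficients(3)


@pytest.fixture(scope="module")
def trees():
    msprime = pytest.importorskip("msprime")
    ts = msprime.sim_ancestry(samples=9, sequence_length=200_000,
                              population_size=10_000, recombination_rate=1e-8,
                              random_seed=7)
    ts = msprime.sim_mutations(ts, rate=1e-7, random_seed=8,
                               model=msprime.BinaryMutationModel())
    multi = np.flatnonzero(ts.genotype_matrix().max(axis=1) > 1)
    return ts.delete_sites(multi) if len(multi) else ts


class TestNeutralCoalescentOracle:
    """msprime/tskit as an independent route for pi, d_XY and Tajima's D."""

    def _dosage(self, trees):
        g = trees.genotype_matrix()
        return (g[:, 0::2] + g[:, 1::2]).astype(np.int8)

    def test_windowed_pi_matches_tskit(self, trees):
        windows = np.arange(0, 200_001, 10_000, dtype=float)
        expected = trees.diversity(windows=windows, mode="site")
        dos = self._dosage(trees)
        pos = trees.tables.sites.position.astype(int)
        terms, _ = ps.site_pi_terms(dos, np.arange(dos.shape[1]))
        got = np.bincount(pos // 10_000, weights=np.nan_to_num(terms),
                          minlength=20) / 10_000
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_dxy_matches_tskit_divergence(self, trees):
        expected = trees.divergence([list(range(8)), list(range(8, 18))],
                                    mode="site") * 200_000
        dos = self._dosage(trees)
        terms = ps.site_dxy_terms(dos, np.arange(4), np.arange(4, 9))
        assert float(np.nansum(terms)) == pytest.approx(float(expected), rel=1e-9)

    def test_tajimas_d_matches_tskit_and_is_near_zero(self, trees):
        expected = trees.Tajimas_D()
        dos = self._dosage(trees)
        terms, _ = ps.site_pi_terms(dos, np.arange(dos.shape[1]))
        seg = terms > 0
        got = ps.tajimas_d(int(seg.sum()), float(terms[seg].sum()), 18)
        assert got == pytest.approx(float(expected), abs=1e-9)
        assert abs(got) < 1.0  # neutral equilibrium: D near 0


class TestRanking:
    def _table(self, n, fst):
        return pd.DataFrame({
            "scaffold": ["s"] * n, "start": np.arange(n) * 10_000,
            "end": (np.arange(n) + 1) * 10_000, "fst": fst,
        })

    def test_top_one_percent_of_200_is_2(self, rng):
        t = self._table(200, rng.random(200))
        top = ps.rank_windows(t, 0.01)
        assert len(top) == 2
        assert top["fst"].tolist() == sorted(t["fst"], reverse=True)[:2]

    def test_ties_broken_by_coordinate(self):
        t = self._table(100, np.full(100, 0.5))
        top = ps.rank_windows(t, 0.02)
        assert top["start"].tolist() == [0, 10_000]

    def test_variant_hits_threshold(self):
        df = pd.DataFrame({"scaffold": ["s"] * 3, "pos0": [1, 2, 3],
                           "fst": [0.71, 0.7, 0.69]})
        assert len(ps.variant_fst_hits(df, 0.7)) == 2


class TestNearestFeature:
    FEATURES = pd.DataFrame({
        "scaffold": ["s"] * 5,
        "start": [1_000, 50_000, 90_000, 150_000, 300_000],
        "end": [5_000, 60_000, 100_000, 160_000, 310_000],
        "strand": ["+", "-", "+", "-", "+"],
        "name": list("abcde"),
    })

    def test_window_inside_gene(self):
        q = pd.DataFrame({"scaffold": ["s"], "start": [52_000], "end": [53_000]})
        res = ps.nearest_feature(q, self.FEATURES)
        assert res.loc[0, "relation"] == "inside" and res.loc[0, "distance"] == 0

    def test_upstream_of_forward_gene(self):
        q = pd.DataFrame({"scaffold": ["s"], "start": [260_000], "end": [270_000]})
        res = ps.nearest_feature(q, self.FEATURES)
        assert res.loc[0, "relation"] == "upstream"
        assert res.loc[0, "distance"] == 30_000

    def test_no_features_on_scaffold(self):
        q = pd.DataFrame({"scaffold": ["t"], "start": [0], "end": [10]})
        assert ps.nearest_feature(q, self.FEATURES).loc[0, "relation"] == "none"

    def test_matches_bruteforce(self, rng):
        feats = [tuple(r) for r in
                 self.FEATURES[["start", "end", "strand", "name"]].itertuples(index=False)]
        starts = rng.integers(0, 350_000, size=15)
        q = pd.DataFrame({"scaffold": "s", "start": starts, "end": starts + 10_000})
        res = ps.nearest_feature(q, self.FEATURES)
        for i, (s, e) in enumerate(zip(q["start"], q["end"])):
            d, rel, name = nearest_feature_brute(s, e, feats)
            assert res.loc[i, "distance"] == d
            assert res.loc[i, "relation"] == rel


class TestDivergenceTime:
    def test_zero_divergence_zero_time(self):
        est = ps.divergence_time(0.0)
        assert est.t_low == est.t_high == 0

    def test_rate_range_brackets_reported_times(self):
        est = ps.divergence_time(0.005, mu_low=1.5625e-9, mu_high=3.3333e-9)
        assert est.t_low == pytest.approx(0.75e6, rel=1e-3)
        assert est.t_high == pytest.approx(1.6e6, rel=1e-3)

    def test_time_halves_when_rate_doubles(self):
        a = ps.divergence_time(0.004, 1e-9, 1e-9)
        b = ps.divergence_time(0.004, 2e-9, 2e-9)
        assert a.t_low == pytest.approx(2 * b.t_low)

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError):
            ps.divergence_time(0.005, 0.0, 1e-9)
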