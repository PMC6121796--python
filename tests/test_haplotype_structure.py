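import numpy as np
import pandas as pd
import pytest

from migradiv import haplotype_structure as hs
from migradiv import synthetic_data as sd
from migradiv.formats_io import MISSING


def region_dosage(rng, n_per_class=(6, 6, 6), n_diag=40):
    """Dosage matrix with three clean clusters: SS (0), NS (1), NN (2)."""
    cols, labels = [], []
    for dosage, cls in zip((0, 1, 2), ("SS", "NS", "NN")):
        for _ in range(n_per_class[dosage]):
            cols.append(np.full(n_diag, dosage, dtype=np.int8))
            labels.append(cls)
    return np.array(cols).T, labels


class TestRegionMds:
    def test_three_diagnostic_genotypes_equally_spaced(self):
        dos = np.array([[0, 1, 2]] * 20, dtype=np.int8)
        mds = hs.region_mds(dos, ["a", "b", "c"])
        x = np.sort(mds.coords[:, 0])
        assert x[1] - x[0] == pytest.approx(x[2] - x[1], abs=1e-6)
        assert mds.coords.mean(axis=0) == pytest.approx([0, 0], abs=1e-6)

    def test_no_structure_small_axis1_share(self, rng):
        dos = rng.integers(0, 3, size=(50, 30)).astype(np.int8)
        mds = hs.region_mds(dos, [f"s{i}" for i in range(30)])
        assert mds.axis1_share < 0.3

    def test_axis_ordering_by_eigenvalue(self, rng):
        dos, _ = region_dosage(rng)
        mds = hs.region_mds(dos, [f"s{i}" for i in range(dos.shape[1])])
        assert mds.eigenvalues[0] >= mds.eigenvalues[1]

    def test_too_few_loci_rejected(self):
        with pytest.raises(ValueError):
            hs.region_mds(np.zeros((1, 5), dtype=np.int8), list("abcde"))

    def test_axis1_ordering_stable_under_locus_subsampling(self, rng):
        pos, ha, hb, _ = sd.divergent_region_haplotypes(
            100_000, 20, 20, 250_000, 1e-8, 0.005, 0.005, rng)
        dos = np.concatenate([sd.haplotypes_to_dosage(ha),
                              sd.haplotypes_to_dosage(hb)], axis=1)
        samples = [f"s{i}" for i in range(20)]
        full = hs.region_mds(dos, samples)
        half = hs.region_mds(dos[rng.random(len(pos)) < 0.5], samples)
        r = np.corrcoef(full.coords[:, 0], half.coords[:, 0])[0, 1]
        assert abs(r) > 0.99  # sign-flip allowed


class TestClassification:
    def _populations(self, labels):
        return {f"s{i}": {"SS": "southern", "NN": "northern", "NS": "unknown"}[c]
                for i, c in enumerate(labels)}

    def test_perfect_clusters_fully_recovered(self, rng):
        dos, labels = region_dosage(rng)
        samples = [f"s{i}" for i in range(len(labels))]
        call = hs.call_region(dos, samples, self._populations(labels), "r1")
        assert call.table["class"].tolist() == labels
        assert call.equidistance < 0.1
        assert (call.table["posterior"] > 0.99).all()

    def test_homozygous_northern_sample_is_nn(self, rng):
        dos, labels = region_dosage(rng)
        samples = [f"s{i}" for i in range(len(labels))]
        call = hs.call_region(dos, samples, self._populations(labels), "r1")
        nn_idx = [i for i, l in enumerate(labels) if l == "NN"]
        assert (call.table.loc[nn_idx, "class"] == "NN").all()

    def test_no_split_degrades_to_single_cluster(self, rng):
        dos = np.zeros((30, 12), dtype=np.int8)
        dos[rng.random(dos.shape) < 0.05] = 1
        samples = [f"s{i}" for i in range(12)]
        call = hs.call_region(dos, samples, {}, "flat")
        assert call.n_clusters < 3
        assert any(f.startswith("degenerate") for f in call.flags)
        assert (call.table["class"] == "unassigned").all()

    def test_polarity_error_without_population_labels(self, rng):
        dos, labels = region_dosage(rng)
        samples = [f"s{i}" for i in range(len(labels))]
        with pytest.raises(ValueError, match="polarize"):
            hs.call_region(dos, samples, {}, "r1")

    def test_synthetic_region_matches_generator_truth(self, rng):
        # clade pairs drawn by the generator; classification must agree 100%
        pos, ha, hb, _ = sd.divergent_region_haplotypes(
            200_000, 24, 16, 250_000, 1e-8, 0.005, 0.005, rng)
        g_n = [0] * 12 + [2] * 8  # 12 SS + 8 NN diploids
        dos = np.concatenate([sd.haplotypes_to_dosage(ha),
                              sd.haplotypes_to_dosage(hb)], axis=1)
        # make 4 heterozygotes by pairing one S and one N haplotype
        het = (ha[:, :4] + hb[:, :4]).astype(np.int8)
        dos = np.concatenate([dos, het], axis=1)
        truth = ["SS"] * 12 + ["NN"] * 8 + ["NS"] * 4
        samples = [f"s{i}" for i in range(24)]
        pops = {s: {"SS": "southern", "NN": "northern", "NS": "unknown"}[t]
                for s, t in zip(samples, truth)}
        call = hs.call_region(dos, samples, pops, "sim")
        assert call.table["class"].tolist() == truth


class TestPca:
    def test_fixed_difference_populations_separate_on_pc1(self):
        dos = np.zeros((50, 20), dtype=np.int8)
        dos[:, 10:] = 2
        coords, explained = hs.genotype_pca(dos, [f"s{i}" for i in range(20)])
        pc1 = coords["PC1"].to_numpy()
        assert (pc1[:10] * pc1[10:] < 0).all()  # opposite signs
        assert explained[0] > 0.99

    def test_excluding_diagnostic_loci_removes_separation(self, rng):
        diag = np.zeros((40, 20), dtype=np.int8)
        diag[:, 10:] = 2
        noise = rng.integers(0, 3, size=(200, 20)).astype(np.int8)
        dos = np.vstack([diag, noise])
        exclude = np.zeros(240, dtype=bool)
        exclude[:40] = True
        coords, _ = hs.genotype_pca(dos, [f"s{i}" for i in range(20)],
                                    exclude=exclude)
        pc1 = coords["PC1"].to_numpy()
        # group means overlap within the spread
        gap = abs(pc1[:10].mean() - pc1[10:].mean())
        assert gap < 2 * pc1.std()

    def test_duplicated_sample_identical_coordinates(self, rng):
        dos = rng.integers(0, 3, size=(100, 10)).astype(np.int8)
        dos = np.concatenate([dos, dos[:, :1]], axis=1)
        coords, _ = hs.genotype_pca(dos, [f"s{i}" for i in range(11)])
        np.testing.assert_allclose(coords.iloc[0, 1:].to_numpy(dtype=float),
                                   coords.iloc[10, 1:].to_numpy(dtype=float),
                                   atol=1e-8)

    def test_monomorphic_only_rejected(self):
        with pytest.raises(ValueError):
            hs.genotype_pca(np.ones((5, 4), dtype=np.int8), list("abcd"))


class TestFrequenciesAndCombinations:
    def _call(self, classes, region="chr1"):
        table = pd.DataFrame({
            "sample": [f"s{i}" for i in range(len(classes))],
            "class": classes,
            "posterior": 1.0,
            "axis1": 0.0, "axis2": 0.0,
        })
        return hs.RegionCall(region, table, {}, 0.0, 3)

    def _meta(self, n, site="x"):
        return pd.DataFrame({"sample": [f"s{i}" for i in range(n)], "site": site})

    def test_counted_frequency(self):
        call = self._call(["NN", "NN", "NS", "SS"])
        out = hs.haplotype_site_frequencies(call, self._meta(4))
        assert out.loc[0, "freq_n"] == pytest.approx(5 / 8)

    def test_all_ss_site_zero(self):
        call = self._call(["SS", "SS", "SS"])
        out = hs.haplotype_site_frequencies(call, self._meta(3))
        assert out.loc[0, "freq_n"] == 0

    def test_unassigned_excluded_site_without_calls_missing(self):
        call = self._call(["unassigned", "unassigned"])
        out = hs.haplotype_site_frequencies(call, self._meta(2))
        assert np.isnan(out.loc[0, "freq_n"])

    def test_single_sample_combination_cell(self):
        a = self._call(["NN"], region="chr1")
        b = self._call(["SS"], region="chr5")
        table = hs.combined_genotype_table(a, b)
        assert table.loc["NN", "SS"] == 1 and table.to_numpy().sum() == 1

    def test_frequency_in_unit_interval(self, rng):
        classes = rng.choice(["SS", "NS", "NN", "unassigned"], size=30)
        call = self._call(list(classes))
        meta = self._meta(30)
        meta["site"] = rng.choice(["a", "b", "c"], size=30)
        out = hs.haplotype_site_frequencies(call, meta)
        f = out["freq_n"].dropna()
        assert ((f >= 0) & (f <= 1)).all()
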