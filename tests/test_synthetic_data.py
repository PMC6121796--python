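import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from migradiv import popgen_stats as ps
from migradiv import synthetic_data as sd
from conftest import tiny_sim_config


class TestNeutralGroup:
    def test_site_count_and_frequency_expectation(self, rng):
        pos, haps, freqs = sd.neutral_group_haplotypes(18, 100_000, 0.005, rng)
        assert len(pos) == round(3 * 0.005 * 100_000)
        assert np.all(np.diff(pos) > 0)
        # E[pi] = theta by construction
        dos = sd.haplotypes_to_dosage(haps)
        terms, _ = ps.site_pi_terms(dos, np.arange(9))
        assert terms.sum() / 100_000 == pytest.approx(0.005, rel=0.1)

    def test_invalid_theta_rejected(self, rng):
        with pytest.raises(ValueError):
            sd.neutral_group_haplotypes(10, 1000, 1.5, rng)


class TestBaldingNichols:
    def test_near_zero_f_gives_near_zero_fst(self):
        rng = np.random.default_rng(0)
        dos = sd.balding_nichols_dosages(50_000, (25, 25), 1e-4, rng)
        a, b, c = ps.wc_fst_components(dos, np.arange(25), np.arange(25, 50))
        ok = ~np.isnan(a)
        est = a[ok].sum() / (a + b + c)[ok].sum()
        assert abs(est) < 0.002

    def test_high_f_recovered(self):
        rng = np.random.default_rng(1)
        dos = sd.balding_nichols_dosages(10_000, (50, 50), 0.5, rng)
        a, b, c = ps.wc_fst_components(dos, np.arange(50), np.arange(50, 100))
        ok = ~np.isnan(a)
        est = a[ok].sum() / (a + b + c)[ok].sum()
        assert est == pytest.approx(0.5, rel=0.05)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.1])
    def test_invalid_f_rejected(self, bad, rng):
        with pytest.raises(ValueError):
            sd.balding_nichols_dosages(10, (5, 5), bad, rng)


class TestDivergentRegion:
    def test_zero_split_time_no_core_differences(self, rng):
        pos, ha, hb, core = sd.divergent_region_haplotypes(
            100_000, 8, 8, 0.0, 1e-8, 0.005, 0.005, rng)
        assert core.sum() == 0

    def test_theta_zero_gives_dxy_equal_da(self, rng):
        pos, ha, hb, core = sd.divergent_region_haplotypes(
            200_000, 8, 8, 250_000, 1e-8, 1e-9, 1e-9, rng)
        dos = np.concatenate([sd.haplotypes_to_dosage(ha),
                              sd.haplotypes_to_dosage(hb)], axis=1)
        g1, g2 = np.arange(4), np.arange(4, 8)
        dxy = ps.site_dxy_terms(dos, g1, g2).sum() / 200_000
        p1, _ = ps.site_pi_terms(dos, g1)
        p2, _ = ps.site_pi_terms(dos, g2)
        assert p1.sum() == pytest.approx(0) and p2.sum() == pytest.approx(0)
        assert dxy == pytest.approx(2 * 1e-8 * 250_000, rel=0.15)

    def test_saturated_divergence_rejected(self, rng):
        with pytest.raises(ValueError, match="saturated"):
            sd.divergent_region_haplotypes(1000, 4, 4, 1e8, 1e-8, 0.005, 0.005, rng)

    def test_unequal_theta_inflates_da_by_delta(self):
        # private polymorphism in the higher-theta clade adds dtheta to E[d_A]
        das = []
        for seed in range(4):
            r = np.random.default_rng(seed)
            pos, ha, hb, _ = sd.divergent_region_haplotypes(
                500_000, 12, 12, 250_000, 1e-8, 0.005, 0.007, r)
            dos = np.concatenate([sd.haplotypes_to_dosage(ha),
                                  sd.haplotypes_to_dosage(hb)], axis=1)
            g1, g2 = np.arange(6), np.arange(6, 12)
            dxy = ps.site_dxy_terms(dos, g1, g2).sum() / 500_000
            p1, _ = ps.site_pi_terms(dos, g1)
            p2, _ = ps.site_pi_terms(dos, g2)
            das.append(dxy - (p1.sum() + p2.sum()) / 2 / 500_000)
        assert np.mean(das) == pytest.approx(0.005 + 0.002, rel=0.05)


class TestTransectSampling:
    def test_site_and_sample_counts(self):
        cfg = tiny_sim_config()
        rng = np.random.default_rng(0)
        meta, geno, sites = sd.simulate_transect_sampling(cfg, rng)
        assert len(sites) == 12
        assert len(meta) == 12 * 10
        assert set(geno.columns) == {"chr1", "chr3", "chr5"}

    def test_frequencies_follow_cline(self):
        cfg = tiny_sim_config()
        rng = np.random.default_rng(0)
        _, geno, sites = sd.simulate_transect_sampling(cfg, rng)
        # southern end low, northern end high for the transect-driven region
        assert sites["freq_chr1"].iloc[0] < 0.1 < 0.9 < sites["freq_chr1"].iloc[-1]

    def test_hardy_weinberg_heterozygotes_present_mid_cline(self):
        cfg = tiny_sim_config()
        rng = np.random.default_rng(3)
        meta, geno, sites = sd.simulate_transect_sampling(cfg, rng)
        mid = sites.iloc[(sites["freq_chr1"] - 0.5).abs().argmin()]["site"]
        g = geno.loc[meta[meta["site"] == mid]["sample"], "chr1"]
        assert (g == 1).any()


class TestPhenotypes:
    def test_noiseless_linkage_perfect_correlation(self):
        cfg = tiny_sim_config()
        cfg.phenotypes.d15n_site_sd = 0.0
        cfg.phenotypes.d15n_individual_sd = 0.0
        rng = np.random.default_rng(0)
        meta, geno, sites = sd.simulate_transect_sampling(cfg, rng)
        meta = sd.simulate_phenotypes(cfg, meta, geno, sites, rng)
        site_means = meta.groupby("site")["d15n"].mean()
        r = np.corrcoef(site_means.reindex(sites["site"]),
                        sites["freq_chr1"])[0, 1]
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_zero_slope_zero_noise_flags_degenerate(self):
        cfg = tiny_sim_config()
        cfg.phenotypes.d15n_slope = 0.0
        cfg.phenotypes.d15n_site_sd = 0.0
        cfg.phenotypes.d15n_individual_sd = 0.0
        rng = np.random.default_rng(0)
        meta, geno, sites = sd.simulate_transect_sampling(cfg, rng)
        meta = sd.simulate_phenotypes(cfg, meta, geno, sites, rng)
        assert meta["d15n"].std() == pytest.approx(0.0, abs=1e-12)

    def test_color_scores_in_range(self):
        cfg = tiny_sim_config()
        rng = np.random.default_rng(0)
        meta, geno, sites = sd.simulate_transect_sampling(cfg, rng)
        meta = sd.simulate_phenotypes(cfg, meta, geno, sites, rng)
        assert meta["color"].between(1, 9).all()


@pytest.fixture(scope="module")
def outdir(tmp_path_factory):
    out = tmp_path_factory.mktemp("sim")
    sd.simulate_study(tiny_sim_config(seed=11), out)
    return out


class TestStudyOutput:
    def test_files_exist_and_vcf_parses(self, outdir):
        from migradiv.formats_io import read_variant_table
        vt = read_variant_table(outdir / "resequencing.vcf")
        assert vt.n_samples == 18
        assert vt.n_sites > 1000
        for name in ["callable.bed", "repeats.bed", "regions.bed",
                     "metadata.tsv", "array_genotypes.tsv", "truth.json"]:
            assert (outdir / name).exists()

    def test_same_seed_identical_checksums(self, outdir, tmp_path):
        sd.simulate_study(tiny_sim_config(seed=11), tmp_path / "again")
        for p in sorted(Path(outdir).iterdir()):
            other = tmp_path / "again" / p.name
            assert (hashlib.sha256(p.read_bytes()).hexdigest()
                    == hashlib.sha256(other.read_bytes()).hexdigest()), p.name

    def test_different_seed_different_genotypes(self, outdir, tmp_path):
        sd.simulate_study(tiny_sim_config(seed=12), tmp_path / "other")
        a = (Path(outdir) / "array_genotypes.tsv").read_bytes()
        b = (tmp_path / "other" / "array_genotypes.tsv").read_bytes()
        assert a != b
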