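"""End-to-end orchestration of the analysis stages.

Stage order: simulate (optional) -> variant QC -> region MDS genotyping
(resequencing and array) -> windowed statistics -> geographic clines ->
phenotype association -> report. Each stage reads only files written by
earlier stages, so a directory produced by ``simulate`` can be re-entered
at any stage; rerunning with the same configuration and seed reproduces
identical numeric outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import (
    cline_analysis,
    formats_io,
    haplotype_structure as hs,
    phenotype_association as pa,
    popgen_stats,
    synthetic_data,
    variant_qc,
)
from .formats_io import MISSING

log = logging.getLogger("migradiv")


@dataclass
class PipelineConfig:
    workdir: Path
    seed: int = 0
    simulate: bool = True
    sim: "synthetic_data.SimConfig | None" = None
    filters: variant_qc.FilterConfig = field(default_factory=variant_qc.FilterConfig)
    window_size: int = 10_000
    min_callable: int = 5_000
    min_snps: int = 25
    top_fraction: float = 0.01
    variant_fst_threshold: float = 0.7
    posterior_threshold: float = 0.95
    n_bootstrap: int = 100

    def __post_init__(self):
        self.workdir = Path(self.workdir)
        if self.sim is None:
            self.sim = synthetic_data.default_config(self.seed)

    @property
    def inputs(self) -> Path:
        return self.workdir / "inputs"


def _read_regions_bed(path) -> list[hs.RegionDefinition]:
    regions: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            scaf, start, end, rid = line.split()[:4]
            regions.setdefault(rid, {}).setdefault(scaf, []).append(
                (int(start), int(end)))
    return [hs.RegionDefinition(rid, iv) for rid, iv in regions.items()]


def stage_simulate(cfg: PipelineConfig) -> dict:
    paths = synthetic_data.simulate_study(cfg.sim, cfg.inputs)
    log.info("simulate: wrote %d files to %s", len(paths), cfg.inputs)
    return {"paths": {k: str(v) for k, v in paths.items()}}


def stage_qc(cfg: PipelineConfig) -> dict:
    inp, out = cfg.inputs, cfg.workdir / "qc"
    out.mkdir(parents=True, exist_ok=True)
    pops = pd.read_csv(inp / "reseq_populations.tsv", sep="\t")
    table = formats_io.read_variant_table(
        inp / "resequencing.vcf",
        dict(zip(pops["sample"], pops["population"])))
    fcfg = cfg.filters
    fcfg.repeat_mask = formats_io.read_intervals(inp / "repeats.bed")
    filtered, report = variant_qc.filter_variants(table, fcfg)
    mask = formats_io.read_intervals(inp / "callable.bed").subtract(fcfg.repeat_mask)
    formats_io.write_variant_table(filtered, out / "filtered.vcf", cfg.sim.layout())
    mask.to_bed(out / "callable_filtered.bed")
    report.to_frame().to_csv(out / "qc_report.tsv", sep="\t", index=False)
    log.info("qc: %d -> %d sites", table.n_sites, filtered.n_sites)
    return {"n_in": table.n_sites, "n_out": filtered.n_sites}


def _load_filtered(cfg: PipelineConfig):
    inp = cfg.inputs
    pops = pd.read_csv(inp / "reseq_populations.tsv", sep="\t")
    table = formats_io.read_variant_table(
        cfg.workdir / "qc" / "filtered.vcf",
        dict(zip(pops["sample"], pops["population"])))
    mask = formats_io.read_intervals(cfg.workdir / "qc" / "callable_filtered.bed")
    return table, mask


def stage_regions(cfg: PipelineConfig) -> dict:
    """MDS genotyping of each divergent region, resequencing and array."""
    inp, out = cfg.inputs, cfg.workdir / "regions"
    out.mkdir(parents=True, exist_ok=True)
    regions = _read_regions_bed(inp / "regions.bed")

    # resequencing samples
    table, _ = _load_filtered(cfg)
    vt = table.biallelic_snps()
    reseq_calls = []
    for region in regions:
        in_r = hs.sites_in_region(vt.scaffold, vt.pos0, region)
        call = hs.call_region(vt.genotypes[in_r], vt.samples, vt.populations,
                              region.region_id, cfg.posterior_threshold, cfg.seed)
        df = call.table.copy()
        df.insert(1, "region", region.region_id)
        df["equidistance"] = call.equidistance
        reseq_calls.append(df)
    pd.concat(reseq_calls).to_csv(out / "reseq_calls.tsv", sep="\t", index=False)

    # array samples
    meta = formats_io.read_sample_metadata(inp / "metadata.tsv")
    loci = pd.read_csv(inp / "array_loci.tsv", sep="\t")
    loci["region"] = loci["region"].fillna("")
    gm = pd.read_csv(inp / "array_genotypes.tsv", sep="\t")
    samples = [c for c in gm.columns if c != "locus"]
    matrix = gm[samples].to_numpy(dtype=np.int8)
    qc = variant_qc.array_qc(matrix, cfg.filters)
    kept_samples = [samples[i] for i in qc.kept_samples]
    loci_kept = loci.iloc[qc.kept_loci].reset_index(drop=True)
    array_pops = dict(zip(meta["sample"], meta["population"])) \
        if "population" in meta.columns else {}

    array_calls, freq_frames = [], []
    for region in regions:
        sel = (loci_kept["region"] == region.region_id).to_numpy()
        call = hs.call_region(qc.genotypes[sel], kept_samples, array_pops,
                              region.region_id, cfg.posterior_threshold, cfg.seed)
        df = call.table.copy()
        df.insert(1, "region", region.region_id)
        df["equidistance"] = call.equidistance
        array_calls.append((region.region_id, call, df))
        freq_frames.append(hs.haplotype_site_frequencies(call, meta))
    pd.concat([d for _, _, d in array_calls]).to_csv(
        out / "array_calls.tsv", sep="\t", index=False)
    pd.concat(freq_frames).to_csv(out / "site_frequencies.tsv", sep="\t", index=False)

    by_id = {rid: call for rid, call, _ in array_calls}
    if "chr1" in by_id and "chr5" in by_id:
        hs.combined_genotype_table(by_id["chr1"], by_id["chr5"]).to_csv(
            out / "combined_genotypes_chr1_chr5.tsv", sep="\t")

    # genome-wide PCA with and without the divergent regions
    region_loci = (loci_kept["region"] != "").to_numpy()
    pca_all, ev_all = hs.genotype_pca(qc.genotypes, kept_samples)
    pca_out, ev_out = hs.genotype_pca(qc.genotypes, kept_samples,
                                      exclude=region_loci)
    pca_all.to_csv(out / "pca_all_loci.tsv", sep="\t", index=False)
    pca_out.to_csv(out / "pca_outside_regions.tsv", sep="\t", index=False)
    json.dump({"all": ev_all.tolist(), "outside_regions": ev_out.tolist()},
              open(out / "pca_explained.json", "w"))
    log.info("regions: called %d regions", len(regions))
    return {"regions": [r.region_id for r in regions]}


def _pure_subsets(cfg: PipelineConfig, table) -> tuple[np.ndarray, np.ndarray]:
    """Sample indices consistently SS (southern) or NN (northern) in all regions."""
    calls = pd.read_csv(cfg.workdir / "regions" / "reseq_calls.tsv", sep="\t")
    wide = calls.pivot(index="sample", columns="region", values="class")
    pure_s = wide.index[(wide == "SS").all(axis=1)]
    pure_n = wide.index[(wide == "NN").all(axis=1)]
    return table.sample_indices(pure_s), table.sample_indices(pure_n)


def stage_stats(cfg: PipelineConfig) -> dict:
    out = cfg.workdir / "stats"
    out.mkdir(parents=True, exist_ok=True)
    table, mask = _load_filtered(cfg)
    layout = cfg.sim.layout()
    regions = _read_regions_bed(cfg.inputs / "regions.bed")

    # F_ST between the full phenotype populations; diversity and divergence
    # between the pure homozygous subsets picked by the region calls
    pop_s = table.population_indices("southern")
    pop_n = table.population_indices("northern")
    pure_s, pure_n = _pure_subsets(cfg, table)

    win = popgen_stats.window_stats_table(
        table, layout, mask, pure_s, pure_n, cfg.window_size,
        cfg.min_callable, cfg.min_snps)
    fst_win = popgen_stats.window_stats_table(
        table, layout, mask, pop_s, pop_n, cfg.window_size,
        cfg.min_callable, cfg.min_snps)
    win["fst"] = fst_win["fst"]  # F_ST column from the phenotype contrast
    formats_io.write_window_stats(win, out / "window_stats.tsv")

    top = popgen_stats.rank_windows(win, cfg.top_fraction)
    formats_io.write_window_stats(top, out / "top_windows.tsv")
    sites = popgen_stats.site_fst_table(table, pop_s, pop_n)
    hits = popgen_stats.variant_fst_hits(sites, cfg.variant_fst_threshold)
    hits.to_csv(out / "variant_fst_hits.tsv", sep="\t", index=False)

    # per-region mean d_A and the implied split-time range
    estimates = {}
    for region in regions:
        rmask = region.mask()
        in_r = np.array([rmask.callable_in(s, st, en) > 0
                         for s, st, en in zip(win["scaffold"], win["start"], win["end"])])
        d_a = float(win.loc[in_r, "da"].mean())
        est = popgen_stats.divergence_time(d_a)
        estimates[region.region_id] = {
            "mean_da": d_a, "t_low_years": est.t_low, "t_high_years": est.t_high}
    json.dump(estimates, open(out / "divergence_time.json", "w"), indent=1)
    log.info("stats: %d windows, %d variant hits", len(win), len(hits))
    return {"n_windows": len(win), "n_hits": len(hits)}


def stage_clines(cfg: PipelineConfig) -> dict:
    out = cfg.workdir / "clines"
    out.mkdir(parents=True, exist_ok=True)
    freqs = pd.read_csv(cfg.workdir / "regions" / "site_frequencies.tsv", sep="\t")
    meta = formats_io.read_sample_metadata(cfg.inputs / "metadata.tsv")
    transects = pd.read_csv(cfg.inputs / "transects.tsv", sep="\t")
    site_info = meta.groupby("site").first().reset_index()

    rows = []
    for _, tr in transects.iterrows():
        tdef = cline_analysis.TransectDefinition(
            tr["transect"], tr["lat_a"], tr["lon_a"], tr["lat_b"], tr["lon_b"])
        sites = site_info[site_info["transect"] == tr["transect"]].copy()
        dist = [cline_analysis.transect_distance(la, lo, tdef)[0]
                for la, lo in zip(sites["latitude"], sites["longitude"])]
        sites["distance_km"] = dist
        for region, f in freqs.groupby("region"):
            merged = sites.merge(f, on="site").dropna(subset=["freq_n"])
            merged = merged[merged["n_assigned"] > 0]
            if len(merged) < 4:
                continue
            n = 2 * merged["n_assigned"].to_numpy()
            k = np.round(merged["freq_n"].to_numpy() * n).astype(int)
            fit = cline_analysis.fit_cline(
                merged["distance_km"].to_numpy(), n, k,
                n_bootstrap=cfg.n_bootstrap, seed=cfg.seed)
            rows.append({
                "transect": tr["transect"], "region": region,
                "center_km": fit.model.center, "width_km": fit.model.width,
                "p_min": fit.model.p_min, "p_max": fit.model.p_max,
                "log_likelihood": fit.log_likelihood,
                "converged": fit.converged, "flags": ";".join(fit.flags),
                "n_sites": fit.n_sites, "n_alleles": fit.n_alleles,
                **{f"{k_}_{b}": v for k_, (lo, hi) in fit.ci.items()
                   for b, v in (("lo", lo), ("hi", hi))},
            })
    df = pd.DataFrame(rows)
    df.to_csv(out / "cline_fits.tsv", sep="\t", index=False)
    neutral = cline_analysis.neutral_diffusion_width(50.0, 100.0)
    json.dump({"sigma_km": neutral.sigma_km, "generations": neutral.generations,
               "width_km": neutral.width_km},
              open(out / "neutral_expectation.json", "w"), indent=1)
    log.info("clines: fitted %d region x transect combinations", len(df))
    return {"n_fits": len(df)}


def stage_associate(cfg: PipelineConfig) -> dict:
    out = cfg.workdir / "assoc"
    out.mkdir(parents=True, exist_ok=True)
    meta = formats_io.read_sample_metadata(cfg.inputs / "metadata.tsv")
    freqs = pd.read_csv(cfg.workdir / "regions" / "site_frequencies.tsv", sep="\t")
    summaries = pa.site_trait_means(meta, freqs)
    summaries.to_csv(out / "site_summary.tsv", sep="\t", index=False)
    regions = sorted(freqs["region"].unique())
    strata = sorted(meta["transect"].unique()) if "transect" in meta.columns else None
    assoc = pa.association_table(summaries, regions, strata=strata)
    assoc.to_csv(out / "associations.tsv", sep="\t", index=False)
    log.info("associate: %d correlations over %d sites", len(assoc), len(summaries))
    return {"n_sites": len(summaries)}


def stage_report(cfg: PipelineConfig) -> dict:
    """Deterministic summary figures from the stage outputs."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = cfg.workdir / "report"
    out.mkdir(parents=True, exist_ok=True)
    layout = cfg.sim.layout()
    win = formats_io.read_window_stats(cfg.workdir / "stats" / "window_stats.tsv")

    # Manhattan-style concatenated F_ST track
    offsets = {name: info.offset for name, info in layout.scaffolds.items()}
    x = win["start"].to_numpy() + np.array([offsets[s] for s in win["scaffold"]])
    fig, ax = plt.subplots(figsize=(10, 3))
    ax.scatter(x / 1e6, win["fst"], s=4, c="steelblue")
    ax.set_xlabel("concatenated position (Mb)")
    ax.set_ylabel("weighted $F_{ST}$ (10 kb)")
    fig.tight_layout()
    fig.savefig(out / "fst_track.png", dpi=150)
    plt.close(fig)

    # PCA with and without the divergent regions
    meta = formats_io.read_sample_metadata(cfg.inputs / "metadata.tsv")
    pops = dict(zip(meta["sample"], meta.get("population", "unknown")))
    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    for ax, name, title in zip(
            axes, ["pca_all_loci.tsv", "pca_outside_regions.tsv"],
            ["all loci", "outside divergent regions"]):
        pca = pd.read_csv(cfg.workdir / "regions" / name, sep="\t")
        colors = pca["sample"].map(pops).map(
            {"southern": "green", "northern": "blue"}).fillna("grey")
        ax.scatter(pca["PC1"], pca["PC2"], s=6, c=colors)
        ax.set_title(title)
        ax.set_xlabel("PC1")
        ax.set_ylabel("PC2")
    fig.tight_layout()
    fig.savefig(out / "pca.png", dpi=150)
    plt.close(fig)

    # MDS panels per region
    calls = pd.read_csv(cfg.workdir / "regions" / "array_calls.tsv", sep="\t")
    regions = sorted(calls["region"].unique())
    fig, axes = plt.subplots(1, len(regions), figsize=(4 * len(regions), 3.5))
    for ax, region in zip(np.atleast_1d(axes), regions):
        sub = calls[calls["region"] == region]
        for cls, color in [("SS", "green"), ("NS", "orange"), ("NN", "blue"),
                           ("unassigned", "grey")]:
            pts = sub[sub["class"] == cls]
            ax.scatter(pts["axis1"], pts["axis2"], s=6, c=color, label=cls)
        ax.set_title(region)
        ax.set_xlabel("MDS axis 1")
    np.atleast_1d(axes)[0].set_ylabel("MDS axis 2")
    np.atleast_1d(axes)[-1].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out / "mds_regions.png", dpi=150)
    plt.close(fig)

    # per-region diversity/divergence tracks
    fig, axes = plt.subplots(3, 1, figsize=(10, 6), sharex=True)
    for ax, col, label in zip(axes, ["pi_s", "dxy", "da"],
                              [r"$\pi$ (southern)", r"$d_{XY}$", r"$d_A$"]):
        ax.plot(x / 1e6, win[col], ".", ms=3)
        ax.set_ylabel(label)
    axes[-1].set_xlabel("concatenated position (Mb)")
    fig.tight_layout()
    fig.savefig(out / "region_tracks.png", dpi=150)
    plt.close(fig)
    return {"figures": 4}


STAGES = {
    "simulate": stage_simulate,
    "qc": stage_qc,
    "genotype-regions": stage_regions,
    "stats": stage_stats,
    "clines": stage_clines,
    "associate": stage_associate,
    "report": stage_report,
}
STAGE_ORDER = list(STAGES)


def run_pipeline(cfg: PipelineConfig, stages: list[str] | None = None) -> Path:
    """Run the requested stages (default: all, in order)."""
    cfg.workdir.mkdir(parents=True, exist_ok=True)
    todo = stages or ([s for s in STAGE_ORDER if s != "simulate" or cfg.simulate])
    manifest = {}
    for name in todo:
        if name not in STAGES:
            raise ValueError(f"unknown stage {name!r}")
        log.info("stage %s ...", name)
        try:
            manifest[name] = STAGES[name](cfg)
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
    manifest["seed"] = cfg.seed
    with open(cfg.workdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return cfg.workdir
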