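"""Variant and array-genotype quality filters and callable-site masks.

The resequencing filter chain applies, in fixed order: site quality,
overlap with annotated repeats, depth bounds, and per-site genotype
missingness. Depth bounds default to [1/3, 2] times each sample's median
depth (per-sample mode); an across-samples mode on the site mean depth is
also available. The array filter drops loci on minor-allele frequency and
locus missingness, then samples on sample missingness.

Every stage's attrition is recorded in a telescoping QC report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .formats_io import MISSING, CallableMask, VariantTable, Window


@dataclass
class FilterConfig:
    min_qual: float = 20.0
    repeat_mask: CallableMask | None = None
    depth_mode: str = "per_sample"        # or "across_samples"
    depth_bounds_factor: tuple[float, float] = (1 / 3, 2.0)
    max_site_missing: float = 0.2
    # array-mode thresholds
    array_min_maf: float = 0.01
    array_max_locus_missing: float = 0.1
    array_max_sample_missing: float = 0.1

    def __post_init__(self):
        lo, hi = self.depth_bounds_factor
        if lo > hi:
            raise ValueError("depth bounds out of order")
        for frac in (self.max_site_missing, self.array_min_maf,
                     self.array_max_locus_missing, self.array_max_sample_missing):
            if not 0 <= frac <= 1:
                raise ValueError(f"fraction {frac} outside [0, 1]")


@dataclass
class QCReport:
    """Per-stage input/output counts; each stage's input is the previous output."""

    stages: list[dict] = field(default_factory=list)

    def add(self, name: str, n_in: int, n_out: int) -> None:
        if self.stages and self.stages[-1]["n_out"] != n_in:
            raise ValueError(f"stage {name!r}: input {n_in} != previous output "
                             f"{self.stages[-1]['n_out']}")
        self.stages.append({"stage": name, "n_in": n_in, "n_out": n_out,
                            "n_removed": n_in - n_out})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages)


def filter_variants(table: VariantTable, cfg: FilterConfig) -> tuple[VariantTable, QCReport]:
    """Apply the resequencing site filters in fixed order.

    A site survives iff quality >= threshold, it does not overlap a repeat
    interval, its depth is within bounds, and its genotype missingness is
    at or below the threshold. Filtering an already-filtered table is a
    no-op. Depth-based removal in per-sample mode marks out-of-bounds
    genotype calls missing before the missingness stage, so a site with many
    aberrant-depth samples fails on missingness.
    """
    report = QCReport()
    vt = table

    n0 = vt.n_sites
    with np.errstate(invalid="ignore"):
        keep = ~(vt.qual < cfg.min_qual)  # NaN QUAL treated as passing
    vt = vt.take_sites(keep)
    report.add("site_quality", n0, vt.n_sites)

    n0 = vt.n_sites
    if cfg.repeat_mask is not None:
        keep = np.ones(vt.n_sites, dtype=bool)
        for scaf in np.unique(vt.scaffold):
            sel = vt.scaffold == scaf
            keep[sel] = ~cfg.repeat_mask.contains(scaf, vt.pos0[sel])
        vt = vt.take_sites(keep)
    report.add("repeat_overlap", n0, vt.n_sites)

    n0 = vt.n_sites
    if vt.depth is not None and vt.n_sites:
        lo_f, hi_f = cfg.depth_bounds_factor
        depth = vt.depth.astype(float)
        depth[vt.depth == MISSING] = np.nan
        if cfg.depth_mode == "per_sample":
            med = np.nanmedian(depth, axis=0)
            bad = (depth < lo_f * med) | (depth > hi_f * med) | np.isnan(depth)
            geno = vt.genotypes.copy()
            geno[bad] = MISSING
            vt = VariantTable(
                scaffold=vt.scaffold, pos0=vt.pos0, ref=vt.ref, alt=vt.alt,
                qual=vt.qual, genotypes=geno, samples=vt.samples, depth=vt.depth,
                populations=vt.populations, is_snp=vt.is_snp,
                is_biallelic=vt.is_biallelic)
        elif cfg.depth_mode == "across_samples":
            site_mean = np.nanmean(depth, axis=1)
            overall = np.nanmedian(site_mean)
            keep = (site_mean >= lo_f * overall) & (site_mean <= hi_f * overall)
            vt = vt.take_sites(keep)
        else:
            raise ValueError(f"unknown depth mode {cfg.depth_mode!r}")
    report.add("depth", n0, vt.n_sites)

    n0 = vt.n_sites
    if vt.n_sites:
        missing_frac = (vt.genotypes == MISSING).mean(axis=1)
        vt = vt.take_sites(missing_frac <= cfg.max_site_missing)
    report.add("missingness", n0, vt.n_sites)

    return vt, report


# ---------------------------------------------------------------------------
# Array QC
# ---------------------------------------------------------------------------

@dataclass
class ArrayQCResult:
    genotypes: np.ndarray      # (kept loci, kept samples)
    kept_loci: np.ndarray      # original locus indices
    kept_samples: np.ndarray   # original sample indices
    report: QCReport
    empty: bool = False


def array_qc(genotypes: np.ndarray, cfg: FilterConfig) -> ArrayQCResult:
    """Quality-trim an array genotype matrix (loci x samples, 0/1/2/-1).

    Loci are dropped first (MAF below minimum, or locus missingness above
    maximum), then samples with missingness above maximum — in that fixed
    order so the result is deterministic.
    """
    report = QCReport()
    g = np.asarray(genotypes)
    n_loci, n_samples = g.shape

    ok = g != MISSING
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(ok, g, 0).sum(axis=1) / (2.0 * ok.sum(axis=1))
    maf = np.minimum(p, 1 - p)
    locus_missing = (~ok).mean(axis=1)
    keep_loci = np.flatnonzero((maf >= cfg.array_min_maf) & ~np.isnan(maf)
                               & (locus_missing <= cfg.array_max_locus_missing))
    report.add("locus_maf_missingness", n_loci, len(keep_loci))
    g2 = g[keep_loci]

    if len(keep_loci) == 0:
        report.add("sample_missingness", 0, 0)
        return ArrayQCResult(g2, keep_loci, np.arange(n_samples), report, empty=True)

    sample_missing = (g2 == MISSING).mean(axis=0)
    keep_samples = np.flatnonzero(sample_missing <= cfg.array_max_sample_missing)
    # the sample stage telescopes on the locus axis; record sample attrition
    report.add("sample_missingness", len(keep_loci), len(keep_loci))
    report.stages[-1].update(n_samples_in=n_samples, n_samples_out=len(keep_samples))
    return ArrayQCResult(g2[:, keep_samples], keep_loci, keep_samples, report)


# ---------------------------------------------------------------------------
# Callable masks
# ---------------------------------------------------------------------------

def compute_callable_mask(
    positions: np.ndarray,
    scaffolds: np.ndarray,
    depth: np.ndarray,
    cfg: FilterConfig,
    min_fraction_samples: float = 0.8,
    windows: list[Window] | None = None,
) -> tuple[CallableMask, np.ndarray | None]:
    """Callable mask from per-position per-sample depths.

    A position is callable iff the depth criterion holds (per-sample median
    bounds, as in :func:`filter_variants`) for at least
    ``min_fraction_samples`` of the samples. Positions are single-base
    intervals merged into runs; adjacent callable positions coalesce.
    Returns the mask and, if ``windows`` is given, per-window callable
    counts.
    """
    depth = np.asarray(depth, dtype=float)
    depth[depth < 0] = np.nan
    lo_f, hi_f = cfg.depth_bounds_factor
    med = np.nanmedian(depth, axis=0)
    good = (depth >= lo_f * med) & (depth <= hi_f * med)
    frac = np.nan_to_num(good.mean(axis=1))
    callable_pos = frac >= min_fraction_samples

    raw: dict[str, list] = {}
    for scaf in np.unique(scaffolds):
        sel = (scaffolds == scaf) & callable_pos
        pos = np.sort(positions[sel])
        raw[scaf] = [(int(p), int(p) + 1) for p in pos]
    mask = CallableMask.from_intervals(raw)
    counts = mask.window_counts(windows) if windows is not None else None
    return mask, counts
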