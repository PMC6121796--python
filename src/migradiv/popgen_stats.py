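"""Windowed differentiation, diversity and divergence statistics.

Estimators operate on unphased diploid dosage matrices (sites x samples,
alt-allele dosage 0/1/2, -1 missing):

* Weir & Cockerham (1984) F_ST from variance components a (among
  populations), b (among individuals within populations) and c (within
  individuals); windows report the ratio of sums sum(a)/sum(a+b+c).
* Nucleotide diversity pi = sum_sites 2*p*q * n/(n-1) / callable sites.
* Tajima's D from the window totals of pairwise differences and
  segregating sites with the standard 1989 normalizing constants.
* Absolute divergence d_XY = sum_sites [p_x(1-p_y) + p_y(1-p_x)] / callable
  and net divergence d_A = d_XY - (pi_x + pi_y)/2, a proxy for split time
  via d_A = 2*mu*T.

Window estimates honour the callable-site and SNP-count filters (defaults:
>= 5000 callable sites per 10-kb window; >= 25 SNPs for F_ST).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .formats_io import (
    MISSING,
    CallableMask,
    GenomeLayout,
    VariantTable,
    Window,
    make_windows,
)

__all__ = [
    "wc_fst_components", "site_fst_table", "window_fst_weighted",
    "site_pi_terms", "site_dxy_terms",
    "tajima_coefficients", "tajimas_d",
    "window_stats_table", "rank_windows", "variant_fst_hits",
    "nearest_feature", "divergence_time", "DivergenceEstimate",
]


# ---------------------------------------------------------------------------
# Per-site estimators (vectorized over sites)
# ---------------------------------------------------------------------------

def _group_counts(dosage: np.ndarray, idx: np.ndarray):
    """Per-site (n individuals, alt frequency, het frequency) for one group."""
    g = dosage[:, idx]
    ok = g != MISSING
    n = ok.sum(axis=1)
    alt = np.where(ok, g, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = alt / (2.0 * n)
        h = np.where(ok, g == 1, False).sum(axis=1) / n
    return n, p, h


def wc_fst_components(dosage: np.ndarray, group_a: np.ndarray, group_b: np.ndarray):
    """Weir-Cockerham (1984) two-population variance components per site.

    Returns arrays ``(a, b, c)``; all three are NaN where no allele
    frequency is defined (a population with zero called genotypes). The
    point estimate a/(a+b+c) is undefined (NaN) when the denominator is 0,
    i.e. at sites monomorphic across both populations.
    """
    n1, p1, h1 = _group_counts(dosage, group_a)
    n2, p2, h2 = _group_counts(dosage, group_b)
    r = 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
    bad = (n1 == 0) | (n2 == 0) | (nbar <= 1)
    for arr in (a, b, c):
        arr[bad] = np.nan
    return a, b, c


def site_fst_table(table: VariantTable, group_a: np.ndarray, group_b: np.ndarray,
                   include_nonbiallelic: bool = True) -> pd.DataFrame:
    """Per-variant Weir-Cockerham components and point estimates.

    Multiallelic sites and indels are included by default with their alt
    dosage treated as biallelic presence/absence (used for the variant-level
    F_ST ranking); the windowed statistics use only biallelic SNPs.
    """
    vt = table if include_nonbiallelic else table.biallelic_snps()
    a, b, c = wc_fst_components(vt.genotypes, group_a, group_b)
    denom = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(denom != 0, a / denom, np.nan)
    return pd.DataFrame({
        "scaffold": vt.scaffold, "pos0": vt.pos0,
        "a": a, "b": b, "c": c, "fst": fst,
        "is_snp": vt.is_snp, "is_biallelic": vt.is_biallelic,
    })


def window_fst_weighted(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Ratio-of-sums weighted F_ST over the sites of one window.

    Negative per-site components are retained (not clamped); sites with
    undefined components (NaN) are skipped.
    """
    ok = ~np.isnan(a)
    denom = (a[ok] + b[ok] + c[ok]).sum()
    if denom == 0:
        return np.nan
    return float(a[ok].sum() / denom)


def site_pi_terms(dosage: np.ndarray, idx: np.ndarray):
    """Per-site mean pairwise difference 2*p*q*n/(n-1) within a group.

    ``n`` is the number of called alleles at the site. Sites with fewer than
    2 alleles called return NaN; monomorphic sites return 0 (they still
    count toward the callable denominator).
    """
    g = dosage[:, idx]
    ok = g != MISSING
    n = 2 * ok.sum(axis=1)
    alt = np.where(ok, g, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = alt / n
        terms = 2.0 * p * (1.0 - p) * n / (n - 1.0)
    terms[n < 2] = np.nan
    return terms, n


def site_dxy_terms(dosage: np.ndarray, idx_x: np.ndarray, idx_y: np.ndarray) -> np.ndarray:
    """Per-site between-group divergence p_x(1-p_y) + p_y(1-p_x)."""
    _, px, _ = _group_counts(dosage, idx_x)
    _, py, _ = _group_counts(dosage, idx_y)
    return px * (1 - py) + py * (1 - px)


# ---------------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TajimaCoefficients:
    """Standard Tajima (1989) constants as functions of sample size n."""

    n: int
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float


def tajima_coefficients(n: int) -> TajimaCoefficients:
    if n < 4:
        raise ValueError(f"Tajima's D requires n >= 4 haplotypes, got {n}")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i ** 2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n ** 2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return TajimaCoefficients(n, a1, a2, b1, b2, c1, c2, e1, e2)


def tajimas_d(n_segregating: int, pi_total: float, n: int) -> float:
    """Tajima's D from window totals.

    ``pi_total`` is the *sum* over sites of mean pairwise differences (not
    the per-callable-site value). Undefined (NaN) when S = 0.
    """
    if n_segregating == 0:
        return np.nan
    k = tajima_coefficients(n)
    var = k.e1 * n_segregating + k.e2 * n_segregating * (n_segregating - 1)
    return float((pi_total - n_segregating / k.a1) / np.sqrt(var))


# ---------------------------------------------------------------------------
# Windowed table
# ---------------------------------------------------------------------------

def window_stats_table(
    table: VariantTable,
    layout: GenomeLayout,
    mask: CallableMask,
    group_s: np.ndarray,
    group_n: np.ndarray,
    window_size: int = 10_000,
    min_callable: int = 5_000,
    min_snps: int = 25,
    include_partial: bool = False,
) -> pd.DataFrame:
    """Per-window F_ST, pi, Tajima's D, d_XY and d_A for two groups.

    Windows failing the callable filter carry no statistics; windows failing
    the SNP-count filter carry no F_ST. Partial terminal windows are emitted
    flagged and, by default, left unfilled.
    """
    vt = table.biallelic_snps()
    windows = make_windows(layout, window_size)
    counts = mask.window_counts(windows)

    a, b, c = wc_fst_components(vt.genotypes, group_s, group_n)
    pi_s_terms, _ = site_pi_terms(vt.genotypes, group_s)
    pi_n_terms, _ = site_pi_terms(vt.genotypes, group_n)
    dxy_terms = site_dxy_terms(vt.genotypes, group_s, group_n)
    seg_s = ~np.isnan(pi_s_terms) & (pi_s_terms > 0)
    seg_n = ~np.isnan(pi_n_terms) & (pi_n_terms > 0)
    n_hap_s, n_hap_n = 2 * len(group_s), 2 * len(group_n)

    # group site rows by (scaffold, window index)
    win_lookup = {(w.scaffold, w.start // window_size): i for i, w in enumerate(windows)}
    site_win = np.array(
        [win_lookup.get((s, p // window_size), -1) for s, p in zip(vt.scaffold, vt.pos0)],
        dtype=np.int64)

    rows = []
    for i, w in enumerate(windows):
        in_w = site_win == i
        n_snps = int(in_w.sum())
        callable_n = int(counts[i])
        pass_callable = callable_n >= min_callable and (include_partial or not w.partial)
        pass_snps = n_snps >= min_snps
        rec = {
            "scaffold": w.scaffold, "start": w.start, "end": w.end,
            "window_index": w.index, "partial": w.partial,
            "n_snps": n_snps, "n_callable": callable_n,
            "fst": np.nan, "pi_s": np.nan, "pi_n": np.nan,
            "tajima_d_s": np.nan, "tajima_d_n": np.nan,
            "dxy": np.nan, "da": np.nan,
            "pass_callable": pass_callable, "pass_snps": pass_snps,
        }
        if pass_callable and callable_n > 0:
            pi_s = float(np.nansum(pi_s_terms[in_w])) / callable_n
            pi_n = float(np.nansum(pi_n_terms[in_w])) / callable_n
            dxy = float(np.nansum(dxy_terms[in_w])) / callable_n
            rec.update(pi_s=pi_s, pi_n=pi_n, dxy=dxy, da=dxy - (pi_s + pi_n) / 2.0)
            s_s = int(seg_s[in_w].sum())
            s_n = int(seg_n[in_w].sum())
            if n_hap_s >= 4:
                rec["tajima_d_s"] = tajimas_d(s_s, float(np.nansum(pi_s_terms[in_w & seg_s])), n_hap_s)
            if n_hap_n >= 4:
                rec["tajima_d_n"] = tajimas_d(s_n, float(np.nansum(pi_n_terms[in_w & seg_n])), n_hap_n)
            if pass_snps:
                rec["fst"] = window_fst_weighted(a[in_w], b[in_w], c[in_w])
        rows.append(rec)
    return pd.DataFrame(rows)


def rank_windows(win_table: pd.DataFrame, top_fraction: float = 0.01) -> pd.DataFrame:
    """Top fraction of windows by weighted F_ST.

    Only windows with a defined F_ST enter the ranking; ties are broken by
    (scaffold, start) so the output is deterministic. The number returned is
    ``ceil(top_fraction * n_ranked)``.
    """
    ranked = win_table.dropna(subset=["fst"]).sort_values(
        ["fst", "scaffold", "start"], ascending=[False, True, True])
    k = int(np.ceil(top_fraction * len(ranked)))
    return ranked.head(k).reset_index(drop=True)


def variant_fst_hits(site_table: pd.DataFrame, threshold: float = 0.7) -> pd.DataFrame:
    """Variants (SNPs and indels) at or above an F_ST threshold."""
    hits = site_table[site_table["fst"] >= threshold]
    return hits.sort_values(["scaffold", "pos0"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Gene-proximity annotation and divergence time
# ---------------------------------------------------------------------------

def nearest_feature(intervals: pd.DataFrame, features: pd.DataFrame) -> pd.DataFrame:
    """Signed distance from each query interval to its nearest feature.

    ``intervals`` needs scaffold/start/end; ``features`` needs
    scaffold/start/end/strand/name. Relation is "inside" on any overlap,
    otherwise upstream/downstream of the *feature* respecting its strand
    (a query before the start of a forward gene is upstream). Scaffolds with
    no features yield relation "none".
    """
    out = []
    by_scaf = {s: f.sort_values("start") for s, f in features.groupby("scaffold")}
    for _, q in intervals.iterrows():
        feats = by_scaf.get(q["scaffold"])
        if feats is None or len(feats) == 0:
            out.append({"distance": np.nan, "relation": "none", "feature": None})
            continue
        gap_left = q["start"] - feats["end"]      # feature entirely left of query
        gap_right = feats["start"] - q["end"]     # feature entirely right of query
        gap = np.maximum(np.maximum(gap_left, gap_right), 0)
        i = int(np.argmin(gap.values))
        row = feats.iloc[i]
        d = int(gap.values[i])
        if d == 0:
            rel = "inside"
        else:
            query_is_left = q["end"] <= row["start"]
            if row.get("strand", "+") == "+":
                rel = "upstream" if query_is_left else "downstream"
            else:
                rel = "downstream" if query_is_left else "upstream"
        out.append({"distance": d if d > 0 else 0, "relation": rel, "feature": row["name"]})
    res = intervals.reset_index(drop=True).copy()
    return pd.concat([res, pd.DataFrame(out)], axis=1)


@dataclass(frozen=True)
class DivergenceEstimate:
    """Split-time range t = d_A / (2 mu) over a substitution-rate range."""

    d_a: float
    mu_low: float      # substitutions/site/year
    mu_high: float
    t_low: float       # years (from mu_high)
    t_high: float      # years (from mu_low)


# Default rate range (substitutions/site/year) spanning typical passerine
# nuclear rates; with d_A = 0.005 it brackets roughly 0.75-1.6 Myr.
DEFAULT_MU_YEAR = (1.5625e-9, 3.3333e-9)


def divergence_time(d_a: float, mu_low: float = DEFAULT_MU_YEAR[0],
                    mu_high: float = DEFAULT_MU_YEAR[1]) -> DivergenceEstimate:
    """Rough split time between haplotype groups from net divergence.

    Uses d_A = 2*mu*t, i.e. t = d_A/(2*mu), evaluated at both ends of the
    configured yearly substitution-rate range (t is decreasing in mu).
    """
    if mu_low <= 0 or mu_high <= 0:
        raise ValueError("substitution rates must be positive")
    if mu_low > mu_high:
        mu_low, mu_high = mu_high, mu_low
    return DivergenceEstimate(
        d_a=d_a, mu_low=mu_low, mu_high=mu_high,
        t_low=d_a / (2 * mu_high), t_high=d_a / (2 * mu_low),
    )
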