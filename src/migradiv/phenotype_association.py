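"""Site-level phenotype summaries and haplotype-frequency correlations.

Analyses operate on sampling-site means rather than individuals because the
migratory proxy (feather delta-15N) varies widely within phenotypes, and
are restricted to males since the sexes differ in size. The three length
measurements (wing, tarsus, bill-head) are collapsed into a single size
score, the first principal component of the standardized traits with its
sign fixed so larger birds score positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

SIZE_TRAITS = ["wing", "tarsus", "bill_head"]


def size_pc1(metadata: pd.DataFrame) -> tuple[pd.Series, float]:
    """First principal component of the standardized length traits.

    Returns the per-individual score (NaN where any trait is missing) and
    the fraction of trait variance it explains. The sign is fixed so that
    all loadings are non-negative (larger birds score positive).
    """
    X = metadata[SIZE_TRAITS].to_numpy(dtype=float)
    ok = ~np.isnan(X).any(axis=1)
    Z = (X[ok] - X[ok].mean(axis=0)) / X[ok].std(axis=0, ddof=1)
    cov = np.cov(Z, rowvar=False)
    vals, vecs = np.linalg.eigh(cov)
    v = vecs[:, -1]
    if v.sum() < 0:
        v = -v
    scores = np.full(len(metadata), np.nan)
    scores[ok] = Z @ v
    share = float(vals[-1] / vals.sum())
    return pd.Series(scores, index=metadata.index, name="size_pc1"), share


def site_trait_means(metadata: pd.DataFrame, site_freqs: pd.DataFrame,
                     min_males: int = 2) -> pd.DataFrame:
    """Per-site male-only phenotype means joined with haplotype frequencies.

    ``site_freqs`` is long-form (site, region, freq_n) as produced by
    :func:`migradiv.haplotype_structure.haplotype_site_frequencies`. Sites
    with no males are dropped; sites below ``min_males`` are flagged but
    kept.
    """
    males = metadata[metadata["sex"] == "M"].copy()
    if len(males) == 0:
        raise ValueError("no male samples in metadata")
    males["size_pc1"], _ = size_pc1(males)
    agg = males.groupby("site").agg(
        latitude=("latitude", "first"),
        longitude=("longitude", "first"),
        altitude=("altitude", "first"),
        n_males=("sample", "count"),
        d15n=("d15n", "mean"),
        size_pc1=("size_pc1", "mean"),
        color=("color", "mean"),
    ).reset_index()
    agg["low_n"] = agg["n_males"] < min_males
    wide = site_freqs.pivot(index="site", columns="region", values="freq_n")
    wide.columns = [f"freq_{c}" for c in wide.columns]
    out = agg.merge(wide.reset_index(), on="site", how="left")
    if "transect" in metadata.columns:
        out = out.merge(metadata.groupby("site")["transect"].first().reset_index(),
                        on="site", how="left")
    return out


@dataclass(frozen=True)
class AssociationResult:
    region: str
    trait: str
    stratum: str | None
    r: float
    n_sites: int
    p_value: float
    flag: str = ""


def correlate_frequency_trait(summaries: pd.DataFrame, region: str, trait: str,
                              stratum: str | None = None,
                              min_sites: int = 3) -> AssociationResult:
    """Pearson correlation of site haplotype frequency with a site trait mean.

    ``stratum`` optionally restricts to one transect. Undefined (NaN, with a
    flag) when fewer than ``min_sites`` sites have both values or either
    variable has zero variance.
    """
    df = summaries
    if stratum is not None:
        df = df[df["transect"] == stratum]
    x = df[f"freq_{region}"]
    y = df[trait]
    ok = x.notna() & y.notna()
    n = int(ok.sum())
    if n < min_sites:
        return AssociationResult(region, trait, stratum, np.nan, n, np.nan,
                                 flag="too_few_sites")
    xv, yv = x[ok].to_numpy(), y[ok].to_numpy()
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        return AssociationResult(region, trait, stratum, np.nan, n, np.nan,
                                 flag="zero_variance")
    r, p = stats.pearsonr(xv, yv)
    return AssociationResult(region, trait, stratum, float(r), n, float(p))


def association_table(summaries: pd.DataFrame, regions: list[str],
                      traits: list[str] = ("d15n", "size_pc1", "color", "altitude", "latitude"),
                      strata: list[str] | None = None) -> pd.DataFrame:
    """All region x trait correlations, pooled and optionally per stratum."""
    rows = []
    for region in regions:
        for trait in traits:
            for st in [None] + list(strata or []):
                res = correlate_frequency_trait(summaries, region, trait, st)
                rows.append({"region": res.region, "trait": res.trait,
                             "stratum": res.stratum or "pooled", "r": res.r,
                             "n_sites": res.n_sites, "p_value": res.p_value,
                             "flag": res.flag})
    return pd.DataFrame(rows)
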