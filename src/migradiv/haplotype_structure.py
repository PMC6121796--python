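"""MDS-based genotyping of divergent haplotype-block regions.

Within a region where two deeply diverged haplotype clades do not recombine
with each other, diploid samples fall into three clusters along the first
axis of a multidimensional scaling of genotype distances: homozygotes for
the southern haplotype (SS) and the northern haplotype (NN) at the ends and
heterozygotes (NS) exactly in between — the same geometry as two hybridizing
populations that only produce F1s. Classification fits a one-dimensional
three-component Gaussian mixture to axis 1; the middle cluster is NS and the
end clusters are polarized S vs N by the majority population of origin of
their members.

Also provides an EIGENSOFT-style genotype PCA (allele-frequency centering,
sqrt(p(1-p)) scaling, per-locus mean imputation) with optional exclusion of
the divergent regions, used to show that outside the regions the two
phenotypes are genetically inseparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.mixture import GaussianMixture

from .formats_io import MISSING, CallableMask

CLASSES = ("SS", "NS", "NN")


@dataclass(frozen=True)
class RegionDefinition:
    """A divergent region: member scaffold intervals (0-based half-open)."""

    region_id: str
    intervals: dict[str, "np.ndarray | list"]  # scaffold -> (k, 2)

    def mask(self) -> CallableMask:
        return CallableMask.from_intervals(self.intervals)


def sites_in_region(scaffold: np.ndarray, pos0: np.ndarray,
                    region: RegionDefinition) -> np.ndarray:
    mask = region.mask()
    out = np.zeros(len(pos0), dtype=bool)
    for scaf in mask.intervals:
        sel = scaffold == scaf
        if sel.any():
            out[sel] = mask.contains(scaf, pos0[sel])
    return out


# ---------------------------------------------------------------------------
# Distances and classical MDS
# ---------------------------------------------------------------------------

def allele_sharing_distance(dosage: np.ndarray) -> np.ndarray:
    """Pairwise mean |dosage difference| over loci called in both samples.

    ``dosage`` is (loci, samples). Pairs with no shared called locus get a
    NaN distance.
    """
    X = dosage.T.astype(float)
    X[dosage.T == MISSING] = np.nan
    n = X.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(X - X[i])
        with np.errstate(invalid="ignore"):
            D[i] = np.nanmean(diff, axis=1)
    np.fill_diagonal(D, 0.0)
    return D


@dataclass
class MdsResult:
    """Classical (Torgerson) scaling of a distance matrix, first two axes."""

    coords: np.ndarray      # (n_samples, 2), centered at 0
    eigenvalues: np.ndarray  # all non-trivial eigenvalues, descending
    samples: list[str]
    region_id: str = ""

    @property
    def axis1_share(self) -> float:
        pos = self.eigenvalues[self.eigenvalues > 0]
        return float(self.eigenvalues[0] / pos.sum()) if len(pos) else 0.0


def classical_mds(D: np.ndarray, samples: list[str], region_id: str = "") -> MdsResult:
    n = D.shape[0]
    if n < 3:
        raise ValueError("MDS needs at least 3 samples")
    if np.isnan(D).any():
        raise ValueError("distance matrix contains NaN (samples with no shared loci)")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    vals, vecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    coords = vecs[:, :2] * np.sqrt(np.clip(vals[:2], 0, None))
    return MdsResult(coords=coords, eigenvalues=vals, samples=list(samples),
                     region_id=region_id)


def region_mds(dosage: np.ndarray, samples: list[str], region_id: str = "") -> MdsResult:
    """MDS of the allele-sharing distance over one region's loci."""
    if dosage.shape[0] < 2:
        raise ValueError(f"region {region_id!r}: need >=2 polymorphic loci, "
                         f"got {dosage.shape[0]}")
    return classical_mds(allele_sharing_distance(dosage), samples, region_id)


# ---------------------------------------------------------------------------
# Three-cluster classification
# ---------------------------------------------------------------------------

@dataclass
class RegionCall:
    """Per-sample SS/NS/NN assignment for one region."""

    region_id: str
    table: pd.DataFrame          # sample, class, posterior, axis1, axis2
    cluster_means: dict[str, float]
    equidistance: float          # |d(SS,NS) - d(NS,NN)| / d(SS,NN)
    n_clusters: int
    flags: list[str] = field(default_factory=list)

    def classes(self) -> pd.Series:
        return self.table.set_index("sample")["class"]


def classify_region_genotypes(
    mds: MdsResult,
    populations: dict[str, str],
    posterior_threshold: float = 0.95,
    seed: int = 0,
    region_dosage: np.ndarray | None = None,
) -> RegionCall:
    """Assign SS / NS / NN (or unassigned) from MDS axis-1 coordinates.

    A three-component 1-D Gaussian mixture (EM, k-means initialization,
    fixed seed) is fitted to axis 1. The middle component is NS; the end
    components are polarized southern vs northern by the majority population
    of origin of their members. If the end-cluster majorities do not
    disagree, mean heterozygosity at the region loci (if provided) confirms
    the NS cluster only and a polarity error is raised. With fewer than 3
    occupied clusters the call degrades to a flagged 1- or 2-cluster report
    with every sample unassigned.
    """
    x = mds.coords[:, 0].reshape(-1, 1)
    n = len(x)
    if n < 3:
        raise ValueError("classification needs at least 3 samples")

    km = KMeans(n_clusters=min(3, n), n_init=10, random_state=seed).fit(x)
    occupied = len(np.unique(km.labels_))
    if mds.axis1_share < 0.5:
        # no dominant axis of variation: a structured region would put the
        # bulk of the distance variance on axis 1
        occupied = 1
    if occupied == 3:
        # clusters must be separated beyond their internal spread, otherwise
        # k-means has merely trisected a single cloud
        centers = np.sort(km.cluster_centers_.ravel())
        within = np.sqrt(np.mean([
            np.var(x[km.labels_ == lab]) for lab in np.unique(km.labels_)]))
        gaps = np.diff(centers)
        occupied = 1 + int(np.sum(gaps > 2 * within + 1e-12))
    flags: list[str] = []
    if occupied < 3:
        flags.append(f"degenerate_{occupied}_cluster")
        table = pd.DataFrame({
            "sample": mds.samples, "class": "unassigned", "posterior": np.nan,
            "axis1": mds.coords[:, 0], "axis2": mds.coords[:, 1],
        })
        return RegionCall(mds.region_id, table, {}, np.nan, occupied, flags)

    gm = GaussianMixture(n_components=3, covariance_type="full",
                         means_init=np.sort(km.cluster_centers_, axis=0),
                         random_state=seed, max_iter=500)
    gm.fit(x)
    post = gm.predict_proba(x)
    comp = np.argmax(post, axis=1)
    means = gm.means_.ravel()
    order = np.argsort(means)               # left, middle, right on axis 1
    left, middle, right = order

    def majority(component: int) -> tuple[str, int, int]:
        members = [mds.samples[i] for i in range(n) if comp[i] == component]
        s = sum(populations.get(m) == "southern" for m in members)
        nn = sum(populations.get(m) == "northern" for m in members)
        return ("southern" if s > nn else "northern" if nn > s else "tie"), s, nn

    maj_left, _, _ = majority(left)
    maj_right, _, _ = majority(right)
    if maj_left == maj_right or "tie" in (maj_left, maj_right):
        # population labels cannot polarize the ends; heterozygosity can only
        # confirm the middle cluster, not the S/N polarity
        if region_dosage is not None:
            het = (region_dosage == 1).mean(axis=0)
            het_by_comp = [het[comp == cpt].mean() for cpt in (left, middle, right)]
            if np.argmax(het_by_comp) == 1:
                flags.append("ns_confirmed_by_heterozygosity")
        raise ValueError(
            f"region {mds.region_id!r}: cannot polarize end clusters "
            f"(majorities {maj_left}/{maj_right})")

    labels_by_comp = {middle: "NS",
                      left: "SS" if maj_left == "southern" else "NN",
                      right: "SS" if maj_right == "southern" else "NN"}
    classes = np.array([labels_by_comp[cpt] for cpt in comp], dtype=object)
    posterior = post[np.arange(n), comp]
    classes[posterior < posterior_threshold] = "unassigned"

    cluster_means = {labels_by_comp[cpt]: float(means[cpt]) for cpt in order}
    d_sn = abs(cluster_means["SS"] - cluster_means["NN"])
    equi = (abs(abs(cluster_means["SS"] - cluster_means["NS"])
                - abs(cluster_means["NS"] - cluster_means["NN"])) / d_sn
            if d_sn > 0 else np.nan)

    table = pd.DataFrame({
        "sample": mds.samples, "class": classes, "posterior": posterior,
        "axis1": mds.coords[:, 0], "axis2": mds.coords[:, 1],
    })
    return RegionCall(mds.region_id, table, cluster_means, equi, 3, flags)


def call_region(dosage_region: np.ndarray, samples: list[str],
                populations: dict[str, str], region_id: str = "",
                posterior_threshold: float = 0.95, seed: int = 0) -> RegionCall:
    """Convenience: MDS + classification for one region's dosage matrix."""
    mds = region_mds(dosage_region, samples, region_id)
    return classify_region_genotypes(mds, populations, posterior_threshold,
                                     seed, region_dosage=dosage_region)


# ---------------------------------------------------------------------------
# Genome-wide PCA
# ---------------------------------------------------------------------------

def genotype_pca(dosage: np.ndarray, samples: list[str],
                 exclude: np.ndarray | None = None, n_components: int = 10):
    """EIGENSOFT-style PCA of a (loci, samples) dosage matrix.

    Loci are centered by twice the allele frequency and scaled by
    sqrt(p(1-p)); missing genotypes are mean-imputed per locus. ``exclude``
    is an optional boolean mask of loci to drop (e.g. loci inside the
    divergent regions). Returns (coords DataFrame, explained-variance
    fractions).
    """
    X = dosage.astype(float)
    X[dosage == MISSING] = np.nan
    if exclude is not None:
        X = X[~np.asarray(exclude, dtype=bool)]
    with np.errstate(invalid="ignore"):
        p = np.nanmean(X, axis=1) / 2.0
        var = np.nanvar(X, axis=1)
    poly = ~np.isnan(p) & (p > 0) & (p < 1) & (var > 0)
    if not poly.any():
        raise ValueError("no polymorphic loci left for PCA")
    X, p = X[poly], p[poly]
    X = (X - 2 * p[:, None]) / np.sqrt(p * (1 - p))[:, None]
    X[np.isnan(X)] = 0.0  # mean imputation after centering
    # samples x loci
    U, S, _ = np.linalg.svd(X.T, full_matrices=False)
    k = min(n_components, len(S))
    coords = U[:, :k] * S[:k]
    explained = (S ** 2 / (S ** 2).sum())[:k]
    df = pd.DataFrame(coords, columns=[f"PC{i + 1}" for i in range(k)])
    df.insert(0, "sample", samples)
    return df, explained


# ---------------------------------------------------------------------------
# Frequencies and genotype-combination tables
# ---------------------------------------------------------------------------

def haplotype_site_frequencies(calls: RegionCall, metadata: pd.DataFrame) -> pd.DataFrame:
    """Per-site northern-haplotype frequency, (2*NN + NS) / (2*assigned).

    Unassigned samples are excluded from the denominator; sites with no
    assigned sample get NaN.
    """
    cls = calls.table.set_index("sample")["class"]
    merged = metadata[["sample", "site"]].copy()
    merged["class"] = merged["sample"].map(cls)
    rows = []
    for site, grp in merged.groupby("site", sort=True):
        counts = grp["class"].value_counts()
        assigned = int(counts.get("SS", 0) + counts.get("NS", 0) + counts.get("NN", 0))
        freq = ((2 * counts.get("NN", 0) + counts.get("NS", 0)) / (2 * assigned)
                if assigned else np.nan)
        rows.append({"site": site, "region": calls.region_id,
                     "n_assigned": assigned, "freq_n": freq})
    return pd.DataFrame(rows)


def combined_genotype_table(calls_a: RegionCall, calls_b: RegionCall) -> pd.DataFrame:
    """3x3 counts of genotype combinations across two regions.

    Counts samples assigned in both regions; an all-zero table signals no
    overlapping assigned samples (e.g. SS/SS plus NN/NN mass in allopatry,
    NS/NS hybrids in the contact zones).
    """
    a = calls_a.classes()
    b = calls_b.classes()
    shared = a.index.intersection(b.index)
    out = pd.DataFrame(0, index=list(CLASSES), columns=list(CLASSES))
    for s in shared:
        if a[s] in CLASSES and b[s] in CLASSES:
            out.loc[a[s], b[s]] += 1
    out.index.name = calls_a.region_id
    out.columns.name = calls_b.region_id
    return out
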