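"""Synthetic study generator.

Emulates the statistical structure of a two-phenotype migratory-divide
study: near-zero genome-wide differentiation between two populations of
nine resequenced diploids each, three multi-megabase regions each carrying
two deeply diverged and mutually non-recombining haplotype clades, ~74
sampling sites along two hybrid-zone transects with sigmoid
haplotype-frequency clines, and site-level phenotype means tied to
haplotype frequency (feather delta-15N for the chr1/chr5 analogues) or to
altitude and latitude (chr3 analogue).

The generator is site-independent (infinite sites, free recombination), so
the expectation of every target statistic is exact by construction:

* neutral group: S = 3*theta*L segregating sites with Uniform(0,1)
  frequencies gives E[pi] = theta (E[2pq] = 1/3);
* two populations: Balding-Nichols frequencies Beta(a*p, a*(1-p)) with
  a = (1-F)/F give E[weighted F_ST] = F;
* divergent region: clade cores differ at sites drawn with per-site
  probability 2*mu*T, and within-clade variation is shared ancestral
  polymorphism (one underlying frequency per site, realized independently
  in each clade), so E[d_A] = 2*mu*T exactly; a clade with higher theta
  receives extra private sites, which add (theta_hi - theta_lo) to E[d_A].

All randomness flows from a single numpy Generator; the same seed
reproduces byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cline_analysis import ClineModel, TransectDefinition, cline_predict, haversine_km
from .formats_io import (
    MISSING,
    GenomeLayout,
    VariantTable,
    CallableMask,
    write_variant_table,
)

from scipy.special import expit


# ---------------------------------------------------------------------------
# Low-level generators (the acceptance-surface primitives)
# ---------------------------------------------------------------------------

def neutral_group_haplotypes(n_hap: int, length: int, theta: float,
                             rng: np.random.Generator):
    """Haplotypes of one panmictic group under the infinite-sites generator.

    Draws S = round(3*theta*L) segregating sites at distinct positions with
    underlying frequencies Uniform(0, 1), realized independently per
    haplotype, so that E[pi] = theta.

    Returns (positions 0-based sorted, haplotypes (S, n_hap) int8,
    frequencies).
    """
    if not 0 < theta < 1:
        raise ValueError(f"theta must be in (0, 1), got {theta}")
    n_sites = int(round(3 * theta * length))
    pos = np.sort(rng.choice(length, size=n_sites, replace=False))
    freqs = rng.uniform(0, 1, size=n_sites)
    haps = (rng.random((n_sites, n_hap)) < freqs[:, None]).astype(np.int8)
    return pos, haps, freqs


def haplotypes_to_dosage(haps: np.ndarray) -> np.ndarray:
    """Pair consecutive haplotype columns into diploid alt dosages."""
    if haps.shape[1] % 2:
        raise ValueError("odd number of haplotypes cannot form diploids")
    return (haps[:, 0::2] + haps[:, 1::2]).astype(np.int8)


def balding_nichols_dosages(n_snps: int, n_per_pop: tuple[int, int], fst: float,
                            rng: np.random.Generator,
                            p_range: tuple[float, float] = (0.05, 0.95),
                            ancestral: np.ndarray | None = None) -> np.ndarray:
    """Diploid dosages for two populations under the Balding-Nichols model.

    Ancestral frequencies are Uniform over ``p_range`` (or supplied);
    population frequencies are Beta(a*p, a*(1-p)) with a = (1-F)/F, so their
    variance is F*p*(1-p) and the expected Weir-Cockerham estimate is F.
    """
    if not 0 < fst < 1:
        raise ValueError(f"F must be in (0, 1), got {fst}")
    a = (1 - fst) / fst
    p = (rng.uniform(*p_range, size=n_snps) if ancestral is None
         else np.clip(np.asarray(ancestral, dtype=float), 1e-6, 1 - 1e-6))
    cols = []
    for n_dip in n_per_pop:
        pf = rng.beta(a * p, a * (1 - p))
        cols.append(rng.binomial(2, pf[:, None], size=(n_snps, n_dip)))
    return np.concatenate(cols, axis=1).astype(np.int8)


def divergent_region_haplotypes(
    length: int,
    n_hap_a: int,
    n_hap_b: int,
    t_split: float,
    mu: float,
    theta_a: float,
    theta_b: float,
    rng: np.random.Generator,
):
    """Two clades of haplotypes for one divergent region.

    Three site classes over distinct positions:

    * core fixed differences, per-site probability 2*mu*T (clade a carries
      ref, clade b the alternate) — the clade label fully determines the
      core, emulating the absence of recombination between clades;
    * shared ancestral polymorphism, 3*min(theta)*L sites with one
      Uniform(0,1) frequency realized independently in both clades;
    * private polymorphism for the higher-theta clade, 3*(dtheta)*L sites
      segregating in that clade only.

    With equal thetas, E[d_A] = 2*mu*T and E[pi] = theta exactly.

    Returns (positions, hap_a, hap_b, core-site boolean mask).
    """
    d_core = 2.0 * mu * t_split
    if d_core >= 1:
        raise ValueError(f"2*mu*T = {d_core} >= 1: divergence saturated")
    theta_lo, theta_hi = sorted((theta_a, theta_b))
    n_core = rng.binomial(length, d_core)
    n_shared = int(round(3 * theta_lo * length))
    n_priv = int(round(3 * (theta_hi - theta_lo) * length))
    total = n_core + n_shared + n_priv
    pos_all = rng.choice(length, size=total, replace=False)
    order = np.argsort(pos_all)

    hap_a = np.zeros((total, n_hap_a), dtype=np.int8)
    hap_b = np.zeros((total, n_hap_b), dtype=np.int8)
    is_core = np.zeros(total, dtype=bool)

    is_core[:n_core] = True
    hap_b[:n_core, :] = 1  # clade b fixed for the alternate core allele

    sl = slice(n_core, n_core + n_shared)
    u = rng.uniform(0, 1, size=n_shared)
    hap_a[sl] = rng.random((n_shared, n_hap_a)) < u[:, None]
    hap_b[sl] = rng.random((n_shared, n_hap_b)) < u[:, None]

    if n_priv:
        sl = slice(n_core + n_shared, total)
        v = rng.uniform(0, 1, size=n_priv)
        if theta_a >= theta_b:
            hap_a[sl] = rng.random((n_priv, n_hap_a)) < v[:, None]
        else:
            hap_b[sl] = rng.random((n_priv, n_hap_b)) < v[:, None]

    return pos_all[order], hap_a[order], hap_b[order], is_core[order]


# ---------------------------------------------------------------------------
# Study configuration
# ---------------------------------------------------------------------------

@dataclass
class EnvironmentModel:
    """Logistic dependence of northern-clade probability on altitude/latitude."""

    intercept: float = 0.0
    beta_altitude: float = 2.5
    beta_latitude: float = 0.8
    altitude_ref: float = 400.0   # m
    altitude_scale: float = 250.0
    latitude_ref: float = 60.0    # degrees
    latitude_scale: float = 4.0

    def clade_probability(self, altitude, latitude) -> np.ndarray:
        eta = (self.intercept
               + self.beta_altitude * (np.asarray(altitude) - self.altitude_ref) / self.altitude_scale
               + self.beta_latitude * (np.asarray(latitude) - self.latitude_ref) / self.latitude_scale)
        return expit(eta)


@dataclass
class RegionPlan:
    region_id: str
    scaffold: str
    start: int
    end: int
    t_split: float = 250_000.0      # generations
    mu: float = 1e-8                # per site per generation
    theta_s: float = 0.005
    theta_n: float = 0.005
    driver: str = "transect"        # or "environment"
    clines: dict[str, ClineModel] = field(default_factory=dict)
    environment: EnvironmentModel | None = None

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class TransectPlan:
    transect_id: str
    lat_a: float
    lon_a: float
    lat_b: float
    lon_b: float
    n_sites: int
    n_per_site: int

    def definition(self) -> TransectDefinition:
        return TransectDefinition(self.transect_id, self.lat_a, self.lon_a,
                                  self.lat_b, self.lon_b)

    @property
    def length_km(self) -> float:
        return haversine_km(self.lat_a, self.lon_a, self.lat_b, self.lon_b)


@dataclass
class PhenotypeModel:
    """Site/individual phenotype generation.

    delta-15N is linear in the site's northern-haplotype frequency at the
    chr1 analogue; the three size traits share a latent individual size
    factor with a weak phenotype shift; the color score is a discretized
    1-9 latent scale.
    """

    d15n_intercept: float = 8.0
    d15n_slope: float = 3.0          # per unit haplotype frequency
    d15n_site_sd: float = 0.3
    d15n_individual_sd: float = 0.8
    wing_base: float = 66.0          # mm
    wing_size_loading: float = 1.2
    wing_phenotype_shift: float = 0.8
    wing_sd: float = 0.8
    tarsus_base: float = 20.5
    tarsus_size_loading: float = 0.45
    tarsus_phenotype_shift: float = 0.1
    tarsus_sd: float = 0.35
    bill_head_base: float = 31.0
    bill_head_size_loading: float = 0.7
    bill_head_phenotype_shift: float = 0.15
    bill_head_sd: float = 0.5
    color_base: float = 5.0
    color_phenotype_shift: float = -1.0  # per northern haplotype copy beyond het
    color_sd: float = 1.5
    female_wing_shift: float = -2.0
    male_fraction: float = 0.93


@dataclass
class ArrayPlan:
    n_background_loci: int = 300
    n_diagnostic_per_region: int = 40
    n_polymorphic_per_region: int = 20
    missing_rate: float = 0.01


@dataclass
class SimConfig:
    seed: int = 0
    scaffold_lengths: dict[str, int] = field(default_factory=dict)
    scaffold_chromosomes: dict[str, str] = field(default_factory=dict)
    regions: list[RegionPlan] = field(default_factory=list)
    transects: list[TransectPlan] = field(default_factory=list)
    n_south: int = 9
    n_north: int = 9
    background_fst: float = 0.007
    theta: float = 0.005
    window_size: int = 10_000
    phenotypes: PhenotypeModel = field(default_factory=PhenotypeModel)
    array: ArrayPlan = field(default_factory=ArrayPlan)
    # per-sample impurities: sample id -> {region_id: northern-copy count}
    reseq_impurities: dict[str, dict[str, int]] = field(default_factory=dict)
    repeat_fraction: float = 0.02
    low_qual_fraction: float = 0.02
    mean_depth: float = 9.0

    def __post_init__(self):
        if not 0 < self.background_fst < 1:
            raise ValueError("background F must be in (0, 1)")
        if not 0 < self.theta < 1:
            raise ValueError("theta must be in (0, 1)")
        for region in self.regions:
            for model in region.clines.values():
                if model.p_min >= model.p_max:
                    raise ValueError("cline pMin must be below pMax")

    def layout(self) -> GenomeLayout:
        return GenomeLayout.from_lengths(self.scaffold_lengths, self.scaffold_chromosomes)

    @property
    def reseq_samples(self) -> list[str]:
        return ([f"S{i + 1:02d}" for i in range(self.n_south)]
                + [f"N{i + 1:02d}" for i in range(self.n_north)])

    @property
    def reseq_populations(self) -> dict[str, str]:
        return {s: ("southern" if s.startswith("S") else "northern")
                for s in self.reseq_samples}


def default_config(seed: int = 0) -> SimConfig:
    """The default synthetic study.

    Parameter choices mirror the study conditions being emulated: background
    F = 0.007, theta = 0.005 (northern clade 0.007 in the chr1/chr5
    analogues), clade split 250,000 generations at mu = 1e-8 (d_A = 0.005),
    74 sampling sites on two transects, sigmoid clines with widths within
    the reported 249-688 km range (373 and 249 km on the second transect),
    and 9+9 resequenced diploids of which 8 southern and 6 northern are
    pure homozygotes across all three regions. The genome itself is scaled
    to ~4.6 Mb so the full pipeline stays interactive.
    """
    sweden = TransectPlan("sweden", 55.5, 13.0, 68.5, 21.0, n_sites=40, n_per_site=14)
    poland = TransectPlan("poland_lithuania", 48.0, 19.0, 59.5, 27.0, n_sites=34,
                          n_per_site=16)
    sw_len, pl_len = sweden.length_km, poland.length_km
    regions = [
        RegionPlan(
            "chr1", "scf_chr1", 200_000, 1_000_000, theta_n=0.007,
            clines={
                "sweden": ClineModel(0.5 * sw_len, 350.0, 0.02, 0.98),
                "poland_lithuania": ClineModel(0.5 * pl_len, 373.0, 0.02, 0.98),
            }),
        RegionPlan(
            "chr3", "scf_chr3", 200_000, 1_000_000, driver="environment",
            environment=EnvironmentModel()),
        RegionPlan(
            "chr5", "scf_chr5", 150_000, 650_000, theta_n=0.007,
            clines={
                "sweden": ClineModel(0.5 * sw_len, 271.0, 0.02, 0.98),
                "poland_lithuania": ClineModel(0.5 * pl_len, 249.0, 0.02, 0.98),
            }),
    ]
    return SimConfig(
        seed=seed,
        scaffold_lengths={
            "scf_chr1": 1_200_000, "scf_bg2": 600_000, "scf_chr3": 1_200_000,
            "scf_bg4": 600_000, "scf_chr5": 800_000,
        },
        scaffold_chromosomes={
            "scf_chr1": "1", "scf_bg2": "2", "scf_chr3": "3",
            "scf_bg4": "4", "scf_chr5": "5",
        },
        regions=regions,
        transects=[sweden, poland],
        reseq_impurities={
            "S09": {"chr3": 1},
            "N07": {"chr1": 1},
            "N08": {"chr3": 1},
            "N09": {"chr5": 1},
        },
    )


# ---------------------------------------------------------------------------
# Study-shaped operations
# ---------------------------------------------------------------------------

def reseq_region_truth(cfg: SimConfig) -> pd.DataFrame:
    """True northern-copy count per resequenced sample and region."""
    rows = []
    for sample in cfg.reseq_samples:
        base = 0 if sample.startswith("S") else 2
        for region in cfg.regions:
            g = cfg.reseq_impurities.get(sample, {}).get(region.region_id, base)
            rows.append({"sample": sample, "region": region.region_id, "n_copies": g})
    return pd.DataFrame(rows)


def simulate_background(cfg: SimConfig, rng: np.random.Generator) -> VariantTable:
    """Genome-wide background variation outside the divergent regions.

    Site count 3*theta*L over the non-region genome; ancestral frequencies
    Uniform(0,1) (so E[pi] = theta) dispersed between the two populations by
    the Balding-Nichols model at the configured background F.
    """
    layout = cfg.layout()
    region_mask = CallableMask.from_intervals(
        {r.scaffold: [(r.start, r.end)] for r in cfg.regions})
    scaffolds, positions = [], []
    for name, info in layout.scaffolds.items():
        n_sites = int(round(3 * cfg.theta * (info.length - region_mask.callable_in(name, 0, info.length))))
        allowed = np.flatnonzero(~region_mask.contains(name, np.arange(info.length)))
        pos = np.sort(rng.choice(allowed, size=n_sites, replace=False))
        scaffolds.append(np.full(n_sites, name, dtype=object))
        positions.append(pos)
    scaffold = np.concatenate(scaffolds)
    pos0 = np.concatenate(positions)
    ancestral = rng.uniform(0, 1, size=len(pos0))
    dosage = balding_nichols_dosages(
        len(pos0), (cfg.n_south, cfg.n_north), cfg.background_fst, rng,
        ancestral=ancestral)
    return _as_table(cfg, scaffold, pos0, dosage, rng)


def simulate_divergent_region(cfg: SimConfig, region: RegionPlan,
                              rng: np.random.Generator,
                              truth: pd.DataFrame | None = None):
    """Resequencing genotypes for one divergent region plus per-site truth."""
    if truth is None:
        truth = reseq_region_truth(cfg)
    g_n = (truth[truth["region"] == region.region_id]
           .set_index("sample")["n_copies"].reindex(cfg.reseq_samples).to_numpy())
    n_hap_n = int(g_n.sum())
    n_hap_s = int((2 - g_n).sum())
    pos, hap_s, hap_n, is_core = divergent_region_haplotypes(
        region.length, n_hap_s, n_hap_n, region.t_split, region.mu,
        region.theta_s, region.theta_n, rng)
    dosage = np.empty((len(pos), len(cfg.reseq_samples)), dtype=np.int8)
    i_s = i_n = 0
    for j, g in enumerate(g_n):
        hap_cols = []
        for _ in range(int(2 - g)):
            hap_cols.append(hap_s[:, i_s]); i_s += 1
        for _ in range(int(g)):
            hap_cols.append(hap_n[:, i_n]); i_n += 1
        dosage[:, j] = hap_cols[0] + hap_cols[1]
    table = _as_table(cfg, np.full(len(pos), region.scaffold, dtype=object),
                      pos + region.start, dosage, rng)
    return table, is_core


def _as_table(cfg: SimConfig, scaffold, pos0, dosage, rng) -> VariantTable:
    """Wrap a dosage matrix as a VariantTable with QUAL and DP fields."""
    n = len(pos0)
    qual = rng.uniform(30, 60, size=n)
    low = rng.random(n) < cfg.low_qual_fraction
    qual[low] = rng.uniform(2, 19.5, size=int(low.sum()))
    depth = rng.poisson(cfg.mean_depth, size=dosage.shape).astype(np.int32)
    bases = np.array(list("ACGT"), dtype=object)
    ref_i = rng.integers(0, 4, size=n)
    alt_i = (ref_i + rng.integers(1, 4, size=n)) % 4
    return VariantTable(
        scaffold=np.asarray(scaffold, dtype=object), pos0=np.asarray(pos0),
        ref=bases[ref_i], alt=bases[alt_i], qual=qual,
        genotypes=np.asarray(dosage, dtype=np.int8),
        samples=cfg.reseq_samples, depth=depth,
        populations=cfg.reseq_populations)


def _concat_tables(cfg: SimConfig, tables: list[VariantTable]) -> VariantTable:
    scaffold = np.concatenate([t.scaffold for t in tables])
    pos0 = np.concatenate([t.pos0 for t in tables])
    order = np.lexsort((pos0, np.array([list(cfg.scaffold_lengths).index(s)
                                        for s in scaffold])))
    merged = VariantTable(
        scaffold=scaffold[order], pos0=pos0[order],
        ref=np.concatenate([t.ref for t in tables])[order],
        alt=np.concatenate([t.alt for t in tables])[order],
        qual=np.concatenate([t.qual for t in tables])[order],
        genotypes=np.concatenate([t.genotypes for t in tables])[order],
        samples=cfg.reseq_samples,
        depth=np.concatenate([t.depth for t in tables])[order],
        populations=cfg.reseq_populations)
    return merged


def simulate_transect_sampling(cfg: SimConfig, rng: np.random.Generator):
    """Sites along the transects with per-sample region clade genotypes.

    Sites are equally spaced between the transect endpoints; per site the
    northern-haplotype frequency of each region comes from its sigmoid
    cline (or from the altitude/latitude logistic for environment-driven
    regions) and individuals draw two clade copies under Hardy-Weinberg.

    Returns (metadata DataFrame without phenotypes, genotype DataFrame of
    northern-copy counts per sample x region, site truth DataFrame).
    """
    meta_rows, site_rows = [], []
    geno: dict[str, list[int]] = {r.region_id: [] for r in cfg.regions}
    sample_no = 0
    for tr in cfg.transects:
        frac = np.linspace(0.02, 0.98, tr.n_sites)
        lats = tr.lat_a + frac * (tr.lat_b - tr.lat_a)
        lons = tr.lon_a + frac * (tr.lon_b - tr.lon_a)
        alts = rng.uniform(0, 800, size=tr.n_sites)
        for i in range(tr.n_sites):
            site_id = f"{tr.transect_id[:2].upper()}{i + 1:02d}"
            x_km = frac[i] * tr.length_km
            freqs = {}
            for region in cfg.regions:
                if region.driver == "environment":
                    p = float(region.environment.clade_probability(alts[i], lats[i]))
                else:
                    model = region.clines.get(tr.transect_id)
                    if model is None:
                        raise ValueError(
                            f"region {region.region_id}: no cline for transect "
                            f"{tr.transect_id}")
                    p = float(cline_predict(x_km, model))
                freqs[region.region_id] = p
            site_rows.append({"site": site_id, "transect": tr.transect_id,
                              "distance_km": x_km, "latitude": lats[i],
                              "longitude": lons[i], "altitude": alts[i],
                              **{f"freq_{k}": v for k, v in freqs.items()}})
            chr1_like = [r.region_id for r in cfg.regions if r.driver == "transect"]
            pop = ("southern" if all(freqs[k] < 0.2 for k in chr1_like)
                   else "northern" if all(freqs[k] > 0.8 for k in chr1_like)
                   else "unknown")
            for _ in range(tr.n_per_site):
                sample_no += 1
                sample = f"A{sample_no:04d}"
                sex = "M" if rng.random() < cfg.phenotypes.male_fraction else "F"
                meta_rows.append({"sample": sample, "site": site_id,
                                  "transect": tr.transect_id,
                                  "latitude": lats[i], "longitude": lons[i],
                                  "altitude": alts[i], "sex": sex,
                                  "population": pop})
                for region in cfg.regions:
                    geno[region.region_id].append(
                        int(rng.binomial(2, freqs[region.region_id])))
    metadata = pd.DataFrame(meta_rows)
    genotypes = pd.DataFrame(geno, index=metadata["sample"]).rename_axis("sample")
    return metadata, genotypes, pd.DataFrame(site_rows)


def simulate_phenotypes(cfg: SimConfig, metadata: pd.DataFrame,
                        genotypes: pd.DataFrame, sites: pd.DataFrame,
                        rng: np.random.Generator) -> pd.DataFrame:
    """Attach phenotype columns to the transect metadata.

    Site-mean delta-15N is linear in the site's true chr1-analogue northern
    frequency with Gaussian site and individual noise; size traits load on
    a latent individual size factor plus a weak phenotype shift; the color
    score is discretized to 1-9.
    """
    ph = cfg.phenotypes
    freq_col = next(c for c in sites.columns if c == "freq_chr1")
    site_freq = sites.set_index("site")[freq_col]
    site_effect = (ph.d15n_intercept + ph.d15n_slope * site_freq
                   + rng.normal(0, ph.d15n_site_sd, size=len(site_freq)))
    site_effect = pd.Series(site_effect, index=site_freq.index)

    out = metadata.copy()
    n = len(out)
    g1 = genotypes["chr1"].reindex(out["sample"]).to_numpy()
    size_factor = rng.normal(0, 1, size=n)
    shift = g1 / 2.0
    out["d15n"] = (site_effect.reindex(out["site"]).to_numpy()
                   + rng.normal(0, ph.d15n_individual_sd, size=n))
    wing = (ph.wing_base + ph.wing_size_loading * size_factor
            + ph.wing_phenotype_shift * shift + rng.normal(0, ph.wing_sd, size=n))
    wing += np.where(out["sex"] == "F", ph.female_wing_shift, 0.0)
    out["wing"] = wing
    out["tarsus"] = (ph.tarsus_base + ph.tarsus_size_loading * size_factor
                     + ph.tarsus_phenotype_shift * shift
                     + rng.normal(0, ph.tarsus_sd, size=n))
    out["bill_head"] = (ph.bill_head_base + ph.bill_head_size_loading * size_factor
                        + ph.bill_head_phenotype_shift * shift
                        + rng.normal(0, ph.bill_head_sd, size=n))
    latent = (ph.color_base + ph.color_phenotype_shift * (g1 - 1)
              + rng.normal(0, ph.color_sd, size=n))
    out["color"] = np.clip(np.round(latent), 1, 9).astype(int)
    return out


def simulate_array_genotypes(cfg: SimConfig, genotypes: pd.DataFrame,
                             rng: np.random.Generator):
    """SNP-array genotype matrix for the transect samples.

    Diagnostic loci within each region carry the clade's core allele, so a
    sample's dosage equals its northern-copy count; polymorphic region loci
    and background loci segregate at shared frequencies (no population
    structure). A small fraction of calls is set missing.
    """
    samples = list(genotypes.index)
    n = len(samples)
    loci_rows, blocks = [], []
    layout = cfg.layout()
    for region in cfg.regions:
        plan = cfg.array
        pos_d = np.sort(rng.choice(np.arange(region.start, region.end),
                                   size=plan.n_diagnostic_per_region +
                                   plan.n_polymorphic_per_region, replace=False))
        is_diag = np.zeros(len(pos_d), dtype=bool)
        is_diag[rng.choice(len(pos_d), size=plan.n_diagnostic_per_region,
                           replace=False)] = True
        g = genotypes[region.region_id].to_numpy()
        for k, p in enumerate(pos_d):
            loci_rows.append({"locus": f"{region.region_id}_{p}",
                              "scaffold": region.scaffold, "pos0": int(p),
                              "region": region.region_id,
                              "diagnostic": bool(is_diag[k])})
        block = np.empty((len(pos_d), n), dtype=np.int8)
        u = rng.uniform(0.1, 0.9, size=len(pos_d))
        for k in range(len(pos_d)):
            if is_diag[k]:
                block[k] = g
            else:
                block[k] = rng.binomial(2, u[k], size=n)
        blocks.append(block)
    bg_scaffolds = [s for s in cfg.scaffold_lengths
                    if s not in {r.scaffold for r in cfg.regions}]
    n_bg = cfg.array.n_background_loci
    for k in range(n_bg):
        scaf = bg_scaffolds[k % len(bg_scaffolds)]
        p = int(rng.integers(0, layout.length(scaf)))
        loci_rows.append({"locus": f"bg_{scaf}_{k}", "scaffold": scaf, "pos0": p,
                          "region": "", "diagnostic": False})
    u = rng.uniform(0.1, 0.9, size=n_bg)
    blocks.append(rng.binomial(2, u[:, None], size=(n_bg, n)).astype(np.int8))

    matrix = np.vstack(blocks)
    miss = rng.random(matrix.shape) < cfg.array.missing_rate
    matrix[miss] = MISSING
    return pd.DataFrame(loci_rows), matrix, samples


def simulate_study(cfg: SimConfig, outdir) -> dict[str, Path]:
    """Generate the complete, internally consistent input set.

    Writes resequencing VCF, callable/repeat BED masks, region BED,
    transect TSV, sample metadata TSV, array locus/genotype TSVs, the
    generative truth JSON and a YAML echo of the configuration. The same
    seed yields byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    layout = cfg.layout()

    truth_reseq = reseq_region_truth(cfg)
    tables = [simulate_background(cfg, rng)]
    core_positions = {}
    for region in cfg.regions:
        table, is_core = simulate_divergent_region(cfg, region, rng, truth_reseq)
        core_positions[region.region_id] = (table.pos0[is_core]).tolist()
        tables.append(table)
    reseq = _concat_tables(cfg, tables)

    metadata, genotypes, sites = simulate_transect_sampling(cfg, rng)
    metadata = simulate_phenotypes(cfg, metadata, genotypes, sites, rng)
    loci, array_matrix, array_samples = simulate_array_genotypes(cfg, genotypes, rng)

    paths = {k: outdir / v for k, v in {
        "vcf": "resequencing.vcf", "callable": "callable.bed",
        "repeats": "repeats.bed", "regions": "regions.bed",
        "transects": "transects.tsv", "metadata": "metadata.tsv",
        "array_loci": "array_loci.tsv", "array_genotypes": "array_genotypes.tsv",
        "reseq_populations": "reseq_populations.tsv",
        "truth": "truth.json", "config": "config.yaml",
    }.items()}

    write_variant_table(reseq, paths["vcf"], layout)
    CallableMask.full(layout).to_bed(paths["callable"])
    _repeat_mask(cfg, rng).to_bed(paths["repeats"])
    with open(paths["regions"], "w") as fh:
        for r in cfg.regions:
            fh.write(f"{r.scaffold}\t{r.start}\t{r.end}\t{r.region_id}\n")
    pd.DataFrame([{"transect": t.transect_id, "lat_a": t.lat_a, "lon_a": t.lon_a,
                   "lat_b": t.lat_b, "lon_b": t.lon_b} for t in cfg.transects]
                 ).to_csv(paths["transects"], sep="\t", index=False)
    metadata.to_csv(paths["metadata"], sep="\t", index=False)
    loci.to_csv(paths["array_loci"], sep="\t", index=False)
    gm = pd.DataFrame(array_matrix, columns=array_samples)
    gm.insert(0, "locus", loci["locus"])
    gm.to_csv(paths["array_genotypes"], sep="\t", index=False)
    pd.DataFrame({"sample": cfg.reseq_samples,
                  "population": [cfg.reseq_populations[s] for s in cfg.reseq_samples]}
                 ).to_csv(paths["reseq_populations"], sep="\t", index=False)

    truth = {
        "seed": cfg.seed,
        "config": _config_dict(cfg),
        "reseq_region_genotypes": {
            s: grp.set_index("region")["n_copies"].to_dict()
            for s, grp in truth_reseq.groupby("sample")},
        "array_region_genotypes": genotypes.to_dict(orient="index"),
        "site_truth": sites.to_dict(orient="records"),
        "n_core_sites": {k: len(v) for k, v in core_positions.items()},
    }
    paths["truth"].write_text(json.dumps(truth, indent=1, sort_keys=True))
    paths["config"].write_text(yaml.safe_dump(_config_dict(cfg), sort_keys=True))
    return paths


def _repeat_mask(cfg: SimConfig, rng: np.random.Generator) -> CallableMask:
    """A sparse synthetic repeat annotation covering ~repeat_fraction of it."""
    raw = {}
    for name, length in cfg.scaffold_lengths.items():
        n_iv = max(1, int(cfg.repeat_fraction * length / 2000))
        starts = np.sort(rng.choice(length - 2000, size=n_iv, replace=False))
        raw[name] = [(int(s), int(s) + 2000) for s in starts]
    return CallableMask.from_intervals(raw)


def _config_dict(cfg: SimConfig) -> dict:
    d = asdict(cfg)
    for region in d["regions"]:
        region["clines"] = {k: asdict(v) if not isinstance(v, dict) else v
                            for k, v in region["clines"].items()}
    return d
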