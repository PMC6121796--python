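"""Geographic cline fitting across hybrid-zone transects.

Sampling sites are projected onto a transect (great-circle path between two
endpoints) and the frequency of the northern haplotype is modelled as the
four-parameter sigmoid

    p(x) = pMin + (pMax - pMin) / (1 + exp(-4 (x - c) / w))

where c is the cline centre (km along the transect) and w the cline width,
defined as the inverse of the maximum slope so that dp/dx at x = c equals
(pMax - pMin)/w. Parameters are estimated by maximizing the binomial
log-likelihood of per-site haplotype counts from several deterministic
starting points; uncertainty comes from a seeded parametric bootstrap.

The fitted widths can be compared with the width expected under pure
neutral diffusion after secondary contact, w_n = 2.51 * sigma * sqrt(T).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit
from scipy.stats import norm

EARTH_RADIUS_KM = 6371.0


# ---------------------------------------------------------------------------
# Transect geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TransectDefinition:
    transect_id: str
    lat_a: float
    lon_a: float
    lat_b: float
    lon_b: float

    def __post_init__(self):
        if (self.lat_a, self.lon_a) == (self.lat_b, self.lon_b):
            raise ValueError(f"transect {self.transect_id}: endpoints coincide")


def _unit_vector(lat: float, lon: float) -> np.ndarray:
    la, lo = np.radians(lat), np.radians(lon)
    return np.array([np.cos(la) * np.cos(lo), np.cos(la) * np.sin(lo), np.sin(la)])


def haversine_km(lat1, lon1, lat2, lon2) -> float:
    """Great-circle distance (km) between two points."""
    la1, lo1, la2, lo2 = map(np.radians, (lat1, lon1, lat2, lon2))
    h = np.sin((la2 - la1) / 2) ** 2 + np.cos(la1) * np.cos(la2) * np.sin((lo2 - lo1) / 2) ** 2
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(h)))


def transect_distance(lat: float, lon: float, transect: TransectDefinition,
                      off_axis_tolerance_km: float = 300.0):
    """Signed km from endpoint A to a site's projection onto the transect.

    The site is projected orthogonally onto the great circle through the two
    endpoints; the returned distance is the arc length from A to that
    projection, signed so that B lies at +|AB|. Sites farther off-axis than
    the tolerance are flagged (second return value).
    """
    a = _unit_vector(transect.lat_a, transect.lon_a)
    b = _unit_vector(transect.lat_b, transect.lon_b)
    s = _unit_vector(lat, lon)
    normal = np.cross(a, b)
    normal /= np.linalg.norm(normal)
    off_axis = abs(float(np.arcsin(np.clip(s @ normal, -1, 1)))) * EARTH_RADIUS_KM
    proj = s - (s @ normal) * normal
    proj /= np.linalg.norm(proj)
    dist = float(np.arccos(np.clip(a @ proj, -1, 1))) * EARTH_RADIUS_KM
    # sign: negative if the projection lies behind A relative to B
    along = np.cross(normal, a)  # tangent at A pointing toward B
    if proj @ along < 0:
        dist = -dist
    return dist, off_axis > off_axis_tolerance_km


# ---------------------------------------------------------------------------
# Cline model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClineModel:
    """Sigmoid cline: p_min is the tail frequency as x -> -inf, p_max as
    x -> +inf. Generative configurations use p_min < p_max (frequency rising
    toward the northern end); fitted models may come out reversed when the
    transect is traversed in the opposite direction."""

    center: float   # km along transect
    width: float    # km, 1 / max slope
    p_min: float
    p_max: float

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError(f"cline width must be positive, got {self.width}")
        if not (0 <= self.p_min <= 1 and 0 <= self.p_max <= 1):
            raise ValueError(f"tail frequencies outside [0, 1]: {self.p_min}, {self.p_max}")
        if self.p_min == self.p_max:
            raise ValueError("tail frequencies coincide: cline undefined")


def cline_predict(x, model: ClineModel) -> np.ndarray:
    """Expected northern-haplotype frequency at transect distance x (km)."""
    x = np.asarray(x, dtype=float)
    return model.p_min + (model.p_max - model.p_min) * expit(4.0 * (x - model.center) / model.width)


@dataclass
class ClineFit:
    model: ClineModel
    log_likelihood: float
    converged: bool
    n_sites: int
    n_alleles: int
    flags: list[str] = field(default_factory=list)
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    bootstrap: "np.ndarray | None" = None  # (n_rep, 4) [center, width, p_min, p_max]


_P_EPS = 1e-9


def _nll(theta: np.ndarray, x: np.ndarray, n: np.ndarray, k: np.ndarray,
         width_bounds: tuple[float, float]) -> float:
    c, log_w, lg_min, lg_max = theta
    w = float(np.exp(log_w))
    p_min, p_max = expit(lg_min), expit(lg_max)
    if not (width_bounds[0] <= w <= width_bounds[1]):
        return 1e12
    p = np.clip(p_min + (p_max - p_min) * expit(4.0 * (x - c) / w), _P_EPS, 1 - _P_EPS)
    return float(-(k * np.log(p) + (n - k) * np.log1p(-p)).sum())


def _pack(model: ClineModel) -> np.ndarray:
    return np.array([model.center, np.log(model.width),
                     logit(np.clip(model.p_min, 1e-6, 1 - 1e-6)),
                     logit(np.clip(model.p_max, 1e-6, 1 - 1e-6))])


def _unpack(theta: np.ndarray) -> ClineModel:
    c, log_w, lg_min, lg_max = theta
    return ClineModel(float(c), float(np.exp(log_w)),
                      float(expit(lg_min)), float(expit(lg_max)))


def fit_cline(x, n, k, init: ClineModel | None = None,
              width_bounds: tuple[float, float] = (1.0, 1e5),
              n_bootstrap: int = 0, seed: int = 0) -> ClineFit:
    """Maximum-likelihood sigmoid cline fit to per-site haplotype counts.

    Parameters
    ----------
    x, n, k
        Transect distance (km), number of sampled alleles and number of
        northern alleles per site.
    init
        Optional extra starting point; a deterministic grid of starts over
        centre x width is always explored as well.
    n_bootstrap
        Parametric bootstrap replicates for 95% CIs (seeded).
    """
    x = np.asarray(x, dtype=float)
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    if len(x) < 4:
        raise ValueError("cline fitting needs at least 4 sites")

    span = float(x.max() - x.min()) or 1.0
    freqs = k / np.maximum(n, 1)
    p_lo = float(np.clip(freqs.min(), 0.01, 0.4))
    p_hi = float(np.clip(freqs.max(), 0.6, 0.99))
    with np.errstate(invalid="ignore", divide="ignore"):
        if np.corrcoef(x, freqs)[0, 1] < 0:
            p_lo, p_hi = p_hi, p_lo  # frequency falls along the transect
    starts = [init] if init is not None else []
    for frac_c in (0.3, 0.5, 0.7):
        for frac_w in (0.1, 0.3, 0.8):
            starts.append(ClineModel(float(x.min()) + frac_c * span,
                                     max(frac_w * span, width_bounds[0] * 1.5),
                                     p_lo, p_hi))

    best = None
    for m in starts:
        res = minimize(_nll, _pack(m), args=(x, n, k, width_bounds),
                       method="Nelder-Mead",
                       options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 4000})
        res = minimize(_nll, res.x, args=(x, n, k, width_bounds),
                       method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000})
        if best is None or res.fun < best.fun:
            best = res

    model = _unpack(best.x)
    flags = []
    if not best.success:
        flags.append("non_convergence")
    if model.width <= width_bounds[0] * 1.05:
        flags.append("width_at_lower_bound")
    if model.width >= span * 20:
        flags.append("width_unidentifiable")
    if k.sum() == 0 or k.sum() == n.sum():
        flags.append("boundary_frequencies")
    # flat likelihood: no detectable frequency change along the transect
    if np.ptp(freqs) < 1e-9:
        flags.append("flat_likelihood")

    fit = ClineFit(model=model, log_likelihood=-float(best.fun),
                   converged=bool(best.success), n_sites=len(x),
                   n_alleles=int(n.sum()), flags=flags)

    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        p_hat = cline_predict(x, model)
        reps = np.empty((n_bootstrap, 4))
        for r in range(n_bootstrap):
            k_b = rng.binomial(n.astype(int), p_hat)
            res = minimize(_nll, _pack(model), args=(x, n, k_b, width_bounds),
                           method="Nelder-Mead",
                           options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 2000})
            m_b = _unpack(res.x)
            reps[r] = (m_b.center, m_b.width, m_b.p_min, m_b.p_max)
        fit.bootstrap = reps
        # bias-corrected percentile intervals: the bootstrap distribution of
        # the width is right-skewed and median-shifted relative to the point
        # estimate, so plain percentiles undercover
        z = norm.ppf(0.975)
        for j, name in enumerate(["center", "width", "p_min", "p_max"]):
            point = getattr(model, name)
            frac_below = np.clip(np.mean(reps[:, j] < point),
                                 1 / (2 * n_bootstrap), 1 - 1 / (2 * n_bootstrap))
            z0 = norm.ppf(frac_below)
            q_lo, q_hi = 100 * norm.cdf(2 * z0 - z), 100 * norm.cdf(2 * z0 + z)
            lo, hi = np.percentile(reps[:, j], [q_lo, q_hi])
            fit.ci[name] = (min(float(lo), point), max(float(hi), point))
    return fit


# ---------------------------------------------------------------------------
# Neutral diffusion expectation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NeutralExpectation:
    sigma_km: float
    generations: float
    width_km: float


def neutral_diffusion_width(sigma_km: float, generations: float) -> NeutralExpectation:
    """Cline width expected from pure neutral diffusion after contact.

    Barton-Gale approximation w_n = 2.51 * sigma * sqrt(T): with dispersal
    sigma = 50 km/generation^0.5 and T = 100 generations since secondary
    contact this gives 1255 km, far wider than observed hybrid-zone clines
    maintained by selection.
    """
    if sigma_km <= 0 or generations <= 0:
        raise ValueError("sigma and generations must be positive")
    return NeutralExpectation(sigma_km, generations,
                              2.51 * sigma_km * np.sqrt(generations))
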