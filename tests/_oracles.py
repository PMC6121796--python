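"""Independent brute-force oracles for the population-genetic estimators.

Everything here is deliberately naive — explicit allele enumeration and
O(n^2) pairwise comparison, scalar Python arithmetic — so it shares no code
path with the vectorized estimators it checks.
"""

from itertools import combinations

import numpy as np

MISSING = -1

_ALLELES = {0: (0, 0), 1: (0, 1), 2: (1, 1)}


def _alleles(dosages):
    """Expand diploid dosages of one site into a flat allele list."""
    out = []
    for d in dosages:
        if d != MISSING:
            out.extend(_ALLELES[int(d)])
    return out


def site_pairwise_pi(dosages) -> float:
    """Mean difference over all C(n,2) allele pairs at one site (NaN if n<2)."""
    alleles = _alleles(dosages)
    if len(alleles) < 2:
        return float("nan")
    pairs = list(combinations(alleles, 2))
    return sum(a != b for a, b in pairs) / len(pairs)


def site_pairwise_dxy(dos_x, dos_y) -> float:
    """Mean difference over all cross-group allele pairs at one site."""
    ax, ay = _alleles(dos_x), _alleles(dos_y)
    if not ax or not ay:
        return float("nan")
    return sum(a != b for a in ax for b in ay) / (len(ax) * len(ay))


def window_pi(dosage, idx, callable_sites) -> float:
    return sum(np.nan_to_num(site_pairwise_pi(row[idx])) for row in dosage) / callable_sites


def window_dxy(dosage, idx_x, idx_y, callable_sites) -> float:
    return sum(np.nan_to_num(site_pairwise_dxy(row[idx_x], row[idx_y]))
               for row in dosage) / callable_sites


def wc_components_site(dos_1, dos_2):
    """Weir-Cockerham (1984) a, b, c for one biallelic site, two populations.

    Direct scalar transcription of the published variance-component
    formulas; returns (nan, nan, nan) when either sample is empty.
    """
    d1 = [int(d) for d in dos_1 if d != MISSING]
    d2 = [int(d) for d in dos_2 if d != MISSING]
    n1, n2 = len(d1), len(d2)
    if n1 == 0 or n2 == 0 or n1 + n2 <= 2:
        return (float("nan"),) * 3
    r = 2
    p1 = sum(d1) / (2 * n1)
    p2 = sum(d2) / (2 * n2)
    h1 = sum(d == 1 for d in d1) / n1
    h2 = sum(d == 1 for d in d2) / n2
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = nbar / nc * (s2 - 1 / (nbar - 1)
                     * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4))
    b = nbar / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2
                             - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return a, b, c


def tajimas_d_direct(dosage, idx) -> float:
    """Tajima's D for one window from explicit pairwise allele comparison."""
    n = 2 * len(idx)
    seg, k_total = 0, 0.0
    for row in dosage:
        alleles = _alleles(row[idx])
        if len(set(alleles)) > 1:
            seg += 1
            pairs = list(combinations(alleles, 2))
            k_total += sum(a != b for a, b in pairs) / len(pairs)
    if seg == 0:
        return float("nan")
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i ** 2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n ** 2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return (k_total - seg / a1) / (e1 * seg + e2 * seg * (seg - 1)) ** 0.5


def nearest_feature_brute(q_start, q_end, feats):
    """Exhaustive nearest feature: feats = [(start, end, strand, name)]."""
    best = None
    for start, end, strand, name in feats:
        if q_start < end and start < q_end:
            return 0, "inside", name
        gap = start - q_end if start >= q_end else q_start - end
        if best is None or gap < best[0]:
            query_left = q_end <= start
            if strand == "+":
                rel = "upstream" if query_left else "downstream"
            else:
                rel = "downstream" if query_left else "upstream"
            best = (gap, rel, name)
    return best
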