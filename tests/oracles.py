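"""Independent, deliberately naive oracle implementations used by tests.

Everything here is loop-based and written directly from the published
formulas / first principles, independent of the package's vectorized
code paths.
"""

from __future__ import annotations

import math

import numpy as np

MISSING = -1


def alleles_of(dosage: int) -> list[int]:
    return {0: [0, 0], 1: [0, 1], 2: [1, 1]}[dosage]


def site_pi_bruteforce(dosages: np.ndarray) -> float:
    """Fraction of differing haploid allele pairs at one site (enumerated)."""
    alleles: list[int] = []
    for d in dosages:
        if d != MISSING:
            alleles.extend(alleles_of(int(d)))
    m = len(alleles)
    if m < 2:
        return float("nan")
    diff = total = 0
    for i in range(m):
        for j in range(i + 1, m):
            total += 1
            diff += alleles[i] != alleles[j]
    return diff / total


def window_pi_bruteforce(dosage: np.ndarray, pos: np.ndarray,
                         start: int, end: int, length_bp: int) -> float:
    """Windowed pi: summed per-site enumerated diversity / window length."""
    total = 0.0
    for j in range(dosage.shape[1]):
        if start <= pos[j] <= end:
            v = site_pi_bruteforce(dosage[:, j])
            if not math.isnan(v):
                total += v
    return total / length_bp


def wc_components_site(groups: list[np.ndarray]) -> tuple[float, float, float]:
    """Weir & Cockerham (1984) a, b, c for one diploid site, scalar math."""
    r = len(groups)
    n, p, h = [], [], []
    for g in groups:
        g = np.asarray(g)
        g = g[g != MISSING]
        ni = len(g)
        n.append(ni)
        p.append(float(g.sum()) / (2 * ni))
        h.append(float((g == 1).sum()) / ni)
    nsum = sum(n)
    nbar = nsum / r
    nc = (nsum - sum(x * x for x in n) / nsum) / (r - 1)
    pbar = sum(ni * pi for ni, pi in zip(n, p)) / nsum
    s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * nbar)
    hbar = sum(ni * hi for ni, hi in zip(n, h)) / nsum
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4)
                       / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - s2 * (r - 1) / r
                               - hbar * (2 * nbar - 1) / (4 * nbar))
    c = hbar / 2
    return a, b, c


def wc_fst_site(groups: list[np.ndarray]) -> float:
    a, b, c = wc_components_site(groups)
    denom = a + b + c
    return a / denom if denom != 0 else float("nan")


def tajimas_d_window(dosage: np.ndarray) -> float:
    """Tajima's D for one window of genotypes, everything from scratch.

    Uses the modal called-allele count for the constants and enumerated
    pairwise diversity per site (count scale).
    """
    n_sites = dosage.shape[1]
    called_counts = []
    theta_pi = 0.0
    S = 0
    for j in range(n_sites):
        col = dosage[:, j]
        col = col[col != MISSING]
        m = 2 * len(col)
        if m == 0:
            continue
        called_counts.append(m)
        alt = int(col.sum())
        if 0 < alt < m:
            S += 1
        v = site_pi_bruteforce(dosage[:, j])
        if not math.isnan(v):
            theta_pi += v
    if S == 0 or not called_counts:
        return float("nan")
    counts: dict[int, int] = {}
    for m in called_counts:
        counts[m] = counts.get(m, 0) + 1
    modal = max(sorted(counts), key=lambda k: counts[k])
    if modal < 4:
        return float("nan")
    a1 = sum(1.0 / i for i in range(1, modal))
    a2 = sum(1.0 / i ** 2 for i in range(1, modal))
    b1 = (modal + 1) / (3.0 * (modal - 1))
    b2 = 2.0 * (modal ** 2 + modal + 3) / (9.0 * modal * (modal - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (modal + 2) / (a1 * modal) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    theta_w = S / a1
    var = e1 * S + e2 * S * (S - 1)
    return (theta_pi - theta_w) / math.sqrt(var)


def ols_slope_t(x: np.ndarray, y: np.ndarray) -> float:
    """Textbook simple-regression t statistic for the slope."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    xb, yb = x.mean(), y.mean()
    sxx = ((x - xb) ** 2).sum()
    sxy = ((x - xb) * (y - yb)).sum()
    b = sxy / sxx
    a = yb - b * xb
    rss = ((y - a - b * x) ** 2).sum()
    se = math.sqrt(rss / (n - 2) / sxx)
    return b / se


def two_proportion_z(x1: int, n1: int, x2: int, n2: int) -> tuple[float, float]:
    """Pooled two-proportion z and two-sided normal p, from the formula."""
    p1, p2 = x1 / n1, x2 / n2
    pool = (x1 + x2) / (n1 + n2)
    se = math.sqrt(pool * (1 - pool) * (1 / n1 + 1 / n2))
    z = (p1 - p2) / se
    p = math.erfc(abs(z) / math.sqrt(2))
    return z, p
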