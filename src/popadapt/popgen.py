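"""Core population-genetic statistics.

Windowed nucleotide diversity (pi), Weir & Cockerham (1984) F_ST,
Tajima's D and linkage-disequilibrium decay, all computed from unphased
diploid dosages with missing data handled per site.

Window conventions follow the VCFtools defaults used for resequencing
panels: 100-kb windows advanced in 1-kb steps; windowed pi divides the
summed per-site diversity by the physical window length, and windowed
F_ST is the "weighted" ratio sum(a) / sum(a+b+c) over sites.  Undefined
windows are emitted as NaN, never dropped, so parallel tracks stay
alignable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window definition (1-based inclusive starts)."""

    length_bp: int = 100_000
    step_bp: int = 1_000

    def __post_init__(self) -> None:
        if not self.length_bp >= self.step_bp >= 1:
            raise ValueError("need length_bp >= step_bp >= 1")

    def starts(self, chrom_end: int) -> np.ndarray:
        last = max(1, chrom_end - self.length_bp + 1)
        starts = np.arange(1, last + 1, self.step_bp)
        if starts[-1] + self.length_bp - 1 < chrom_end:
            starts = np.append(starts, starts[-1] + self.step_bp)
        return starts


@dataclass
class WindowedStatTrack:
    """Per-window values of one statistic along the genome."""

    frame: pd.DataFrame  # chrom, start, end, n_sites, value
    statistic: str
    focal: str | None = None
    reference: str | None = None

    @property
    def values(self) -> np.ndarray:
        return self.frame["value"].to_numpy()

    def defined(self) -> pd.DataFrame:
        return self.frame[np.isfinite(self.frame["value"])]

    def same_grid(self, other: "WindowedStatTrack") -> bool:
        a = self.frame[["chrom", "start", "end"]]
        b = other.frame[["chrom", "start", "end"]]
        return a.equals(b)

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False, float_format="%.10g")


@dataclass
class LDDecayCurve:
    """Mean r^2 per physical-distance bin, with a decay-distance helper."""

    bin_edges: np.ndarray     # length n_bins + 1, bp
    mean_r2: np.ndarray       # NaN for empty bins
    n_pairs: np.ndarray

    @property
    def bin_mid(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def decay_distance_at(self, threshold: float = 0.2) -> float:
        """First bin midpoint where the monotone-smoothed curve is <= threshold.

        The raw curve is smoothed by a pool-adjacent-violators fit
        constrained to be non-increasing in distance.  NaN when the curve
        never crosses the threshold.
        """
        ok = np.isfinite(self.mean_r2) & (self.n_pairs > 0)
        if not ok.any():
            return float("nan")
        y = _pava_decreasing(self.mean_r2[ok], self.n_pairs[ok].astype(float))
        mids = self.bin_mid[ok]
        hit = np.flatnonzero(y <= threshold)
        return float(mids[hit[0]]) if hit.size else float("nan")


def _pava_decreasing(y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Weighted isotonic (non-increasing) regression, pool-adjacent-violators."""
    vals = list(y.astype(float))
    wts = list(w.astype(float))
    sizes = [1] * len(vals)
    out_v, out_w, out_n = [], [], []
    for v, wt, s in zip(vals, wts, sizes):
        out_v.append(v); out_w.append(wt); out_n.append(s)
        while len(out_v) > 1 and out_v[-2] < out_v[-1]:
            v2, w2, n2 = out_v.pop(), out_w.pop(), out_n.pop()
            v1, w1, n1 = out_v.pop(), out_w.pop(), out_n.pop()
            out_v.append((v1 * w1 + v2 * w2) / (w1 + w2))
            out_w.append(w1 + w2)
            out_n.append(n1 + n2)
    return np.repeat(out_v, out_n)


# ---------------------------------------------------------------------------
# allele frequencies and per-site diversity
# ---------------------------------------------------------------------------

def _resolve_subset(G: GenotypeMatrix, subset: Sequence[str] | None) -> np.ndarray:
    if subset is None:
        return np.arange(G.n_samples)
    idx = G.sample_indices(list(subset))
    if idx.size == 0:
        raise ValueError("empty sample subset")
    return idx


def allele_frequencies(G: GenotypeMatrix, subset: Sequence[str] | None = None,
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus ALT frequency and called-allele count over a sample subset.

    Loci with zero called alleles get frequency NaN (undefined, not 0).
    """
    idx = _resolve_subset(G, subset)
    d = G.dosage[idx]
    called = d != MISSING
    m = 2 * called.sum(axis=0)
    alt = np.where(called, d, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(m > 0, alt / np.maximum(m, 1), np.nan)
    return p, m


def site_pi(G: GenotypeMatrix, subset: Sequence[str] | None = None) -> np.ndarray:
    """Per-site nucleotide diversity: fraction of differing haploid pairs.

    Equals ``2*p*q * m/(m-1)`` with ``m`` called alleles; NaN when m < 2.
    """
    p, m = allele_frequencies(G, subset)
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = 2.0 * p * (1.0 - p) * m / np.maximum(m - 1, 1)
    pi = np.where(m >= 2, pi, np.nan)
    return pi


def _window_grid(G: GenotypeMatrix, window: WindowSpec) -> pd.DataFrame:
    frames = []
    for chrom, sub in G.loci.groupby("chrom", sort=True):
        starts = window.starts(int(sub["pos"].max()))
        frames.append(pd.DataFrame({
            "chrom": chrom, "start": starts,
            "end": starts + window.length_bp - 1}))
    return pd.concat(frames, ignore_index=True)


def _window_sums(G: GenotypeMatrix, window: WindowSpec,
                 site_values: np.ndarray) -> pd.DataFrame:
    """Sum `site_values` (NaN treated as 0) and count defined sites per window."""
    grid = _window_grid(G, window)
    pos = G.loci["pos"].to_numpy()
    chroms = G.loci["chrom"].to_numpy()
    out_sum = np.zeros(len(grid))
    out_n = np.zeros(len(grid), dtype=int)
    vals = np.nan_to_num(site_values, nan=0.0)
    defined = np.isfinite(site_values).astype(int)
    for chrom, gidx in grid.groupby("chrom", sort=False).groups.items():
        cmask = chroms == chrom
        cpos = pos[cmask]
        cum_v = np.concatenate([[0.0], np.cumsum(vals[cmask])])
        cum_n = np.concatenate([[0], np.cumsum(defined[cmask])])
        starts = grid.loc[gidx, "start"].to_numpy()
        ends = grid.loc[gidx, "end"].to_numpy()
        lo = np.searchsorted(cpos, starts, side="left")
        hi = np.searchsorted(cpos, ends, side="right")
        out_sum[gidx] = cum_v[hi] - cum_v[lo]
        out_n[gidx] = cum_n[hi] - cum_n[lo]
    grid["n_sites"] = out_n
    grid["sum"] = out_sum
    return grid


def windowed_pi(G: GenotypeMatrix, subset: Sequence[str] | None = None,
                window: WindowSpec | None = None,
                denominator: str = "window_length") -> WindowedStatTrack:
    """Sliding-window nucleotide diversity.

    ``denominator='window_length'`` divides the summed site diversity by
    the physical window size (VCFtools ``--window-pi``); ``'callable'``
    divides by the number of polymorphic+monomorphic *called* sites in the
    matrix, i.e. the sites present in the window.
    """
    window = window or WindowSpec()
    pi = site_pi(G, subset)
    grid = _window_sums(G, window, pi)
    if denominator == "window_length":
        value = grid["sum"] / window.length_bp
    elif denominator == "callable":
        with np.errstate(invalid="ignore", divide="ignore"):
            value = grid["sum"] / grid["n_sites"].replace(0, np.nan)
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    frame = grid[["chrom", "start", "end", "n_sites"]].copy()
    frame["value"] = value
    return WindowedStatTrack(frame, statistic="pi")


# ---------------------------------------------------------------------------
# Weir & Cockerham (1984) F_ST
# ---------------------------------------------------------------------------

def wc_site_components(G: GenotypeMatrix,
                       groups: Mapping[str, Sequence[str]],
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site Weir-Cockerham variance components (a, b, c) for diploids.

    Uses observed heterozygote counts (no HWE shortcut).  Sites where any
    group has no called genotype, or that are monomorphic overall, yield
    NaN components.  Returns arrays of shape (n_sites,).
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    r = len(groups)
    n_gi, p_gi, h_gi = [], [], []
    for name, members in groups.items():
        idx = G.sample_indices(list(members))
        d = G.dosage[idx]
        called = d != MISSING
        n = called.sum(axis=0).astype(float)
        if (n < 2).all():
            raise ValueError(f"group {name!r} has < 2 called individuals at every site")
        alt = np.where(called, d, 0).sum(axis=0)
        het = np.where(called, d == 1, False).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = alt / (2 * np.maximum(n, 1))
            h = het / np.maximum(n, 1)
        n_gi.append(n); p_gi.append(p); h_gi.append(h)
    n = np.vstack(n_gi)       # r x L
    p = np.vstack(p_gi)
    h = np.vstack(h_gi)

    valid = (n >= 1).all(axis=0)
    nbar = n.mean(axis=0)
    nsum = n.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (nsum - (n ** 2).sum(axis=0) / nsum) / (r - 1)
        pbar = (n * p).sum(axis=0) / nsum
        s2 = (n * (p - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n * h).sum(axis=0) / nsum
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r
                                 - hbar / 4.0) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - s2 * (r - 1) / r
                                   - hbar * (2 * nbar - 1) / (4 * nbar))
        c = hbar / 2.0
    mono = (pbar <= 0) | (pbar >= 1)
    bad = ~valid | mono | (nbar <= 1) | (nc <= 0)
    for arr in (a, b, c):
        arr[bad] = np.nan
    return a, b, c


def site_fst(G: GenotypeMatrix, groups: Mapping[str, Sequence[str]]) -> np.ndarray:
    """Per-site WC F_ST estimate a/(a+b+c); NaN when the denominator is 0.

    Negative estimates are retained.
    """
    a, b, c = wc_site_components(G, groups)
    denom = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(np.abs(denom) > 0, a / denom, np.nan)
    return f


def wc_fst(G: GenotypeMatrix, groups: Mapping[str, Sequence[str]],
           window: WindowSpec | None = None) -> WindowedStatTrack:
    """Windowed "weighted" WC F_ST: sum(a) / sum(a+b+c) over sites.

    The per-window mean of per-site ratios is exported alongside for
    comparison.  With ``window=None`` a per-site track is returned.
    """
    a, b, c = wc_site_components(G, groups)
    denom = a + b + c
    if window is None:
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(np.abs(denom) > 0, a / denom, np.nan)
        frame = G.loci[["chrom", "pos"]].copy()
        frame = frame.rename(columns={"pos": "start"})
        frame["end"] = frame["start"]
        frame["n_sites"] = 1
        frame["value"] = f
        return WindowedStatTrack(frame[["chrom", "start", "end", "n_sites", "value"]],
                                 statistic="fst")
    num = _window_sums(G, window, a)
    den = _window_sums(G, window, denom)
    with np.errstate(invalid="ignore", divide="ignore"):
        value = np.where(np.abs(den["sum"].to_numpy()) > 0,
                         num["sum"].to_numpy() / den["sum"].to_numpy(), np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(np.abs(denom) > 0, a / denom, np.nan)
    mean_ratio = _window_sums(G, window, ratio)
    with np.errstate(invalid="ignore", divide="ignore"):
        mr = mean_ratio["sum"].to_numpy() / np.maximum(mean_ratio["n_sites"], 1)
    frame = num[["chrom", "start", "end"]].copy()
    frame["n_sites"] = den["n_sites"]
    frame["value"] = value
    frame["mean_of_ratios"] = np.where(mean_ratio["n_sites"] > 0, mr, np.nan)
    return WindowedStatTrack(frame, statistic="fst")


def genomewide_wc_fst(G: GenotypeMatrix,
                      groups: Mapping[str, Sequence[str]]) -> float:
    """Genome-wide weighted WC F_ST (sum a / sum a+b+c over all sites)."""
    a, b, c = wc_site_components(G, groups)
    denom = a + b + c
    ok = np.isfinite(denom) & np.isfinite(a)
    if not ok.any():
        raise ValueError("no sites with defined WC components")
    return float(a[ok].sum() / denom[ok].sum())


# ---------------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------------

def tajima_constants(m: int) -> dict[str, float]:
    """Tajima (1989) normalising constants for m sampled alleles."""
    if m < 4:
        raise ValueError("Tajima's D requires at least 4 alleles")
    i = np.arange(1, m)
    a1 = float((1.0 / i).sum())
    a2 = float((1.0 / i ** 2).sum())
    b1 = (m + 1) / (3.0 * (m - 1))
    b2 = 2.0 * (m ** 2 + m + 3) / (9.0 * m * (m - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (m + 2) / (a1 * m) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2,
            "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_d(G: GenotypeMatrix, subset: Sequence[str] | None = None,
              window: WindowSpec | None = None) -> WindowedStatTrack:
    """Sliding-window Tajima's D.

    Theta-pi is the summed per-site pairwise diversity (count scale);
    theta-W is S/a1 with S the number of segregating sites.  The sample
    size m entering the constants is the modal per-site called-allele
    count within the window; sites with other call counts contribute their
    own per-site pairwise terms (a documented approximation to the
    fixed-n assumption of the standard estimator).  Windows with S = 0 or
    m < 4 are NaN.
    """
    window = window or WindowSpec()
    idx = _resolve_subset(G, subset)
    p, m = allele_frequencies(G, list(np.array(G.samples)[idx]))
    pi = site_pi(G, list(np.array(G.samples)[idx]))
    seg = ((p > 0) & (p < 1) & (m >= 2)).astype(float)

    grid = _window_sums(G, window, np.where(m > 0, pi, np.nan))
    seg_sums = _window_sums(G, window, np.where(seg > 0, 1.0, np.nan))

    pos = G.loci["pos"].to_numpy()
    chroms = G.loci["chrom"].to_numpy()
    values = np.full(len(grid), np.nan)
    const_cache: dict[int, dict[str, float]] = {}
    for chrom, gidx in grid.groupby("chrom", sort=False).groups.items():
        cmask = chroms == chrom
        cpos = pos[cmask]
        cm = m[cmask]
        starts = grid.loc[gidx, "start"].to_numpy()
        ends = grid.loc[gidx, "end"].to_numpy()
        lo = np.searchsorted(cpos, starts, side="left")
        hi = np.searchsorted(cpos, ends, side="right")
        for row, (l, h) in zip(gidx, zip(lo, hi)):
            if h <= l:
                continue
            mm = cm[l:h]
            mm = mm[mm > 0]
            if mm.size == 0:
                continue
            modal = int(np.bincount(mm).argmax())
            if modal < 4:
                continue
            S = float(seg_sums.loc[row, "sum"])
            if S <= 0:
                continue
            if modal not in const_cache:
                const_cache[modal] = tajima_constants(modal)
            k = const_cache[modal]
            theta_pi = float(grid.loc[row, "sum"])
            theta_w = S / k["a1"]
            var = k["e1"] * S + k["e2"] * S * (S - 1)
            if var <= 0:
                continue
            values[row] = (theta_pi - theta_w) / np.sqrt(var)
    frame = grid[["chrom", "start", "end", "n_sites"]].copy()
    frame["value"] = values
    return WindowedStatTrack(frame, statistic="tajima_d")


# ---------------------------------------------------------------------------
# LD decay
# ---------------------------------------------------------------------------

def pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Composite (dosage-correlation) r^2 for one locus pair; NaN if < 3
    jointly called samples or either locus is monomorphic among them."""
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 3:
        return float("nan")
    xs, ys = x[ok].astype(float), y[ok].astype(float)
    if xs.std() == 0 or ys.std() == 0:
        return float("nan")
    r = np.corrcoef(xs, ys)[0, 1]
    return float(r * r)


def ld_decay(G: GenotypeMatrix, subset: Sequence[str] | None = None,
             max_dist: int = 500_000, n_bins: int = 50,
             max_pairs: int = 500_000, seed: int = 0) -> LDDecayCurve:
    """LD decay curve: mean dosage r^2 per physical-distance bin.

    All pairs within ``max_dist`` on the same chromosome are enumerated;
    if their number exceeds ``max_pairs`` a seeded uniform subsample is
    used.  Pairs with fewer than 3 jointly called samples are skipped.
    """
    idx = _resolve_subset(G, subset)
    d = G.dosage[idx]
    pos = G.loci["pos"].to_numpy()
    chroms = G.loci["chrom"].to_numpy()

    pair_i, pair_j = [], []
    for chrom in pd.unique(chroms):
        where = np.flatnonzero(chroms == chrom)
        if where.size < 2:
            continue
        cpos = pos[where]
        hi = np.searchsorted(cpos, cpos + max_dist, side="right")
        for k in range(where.size - 1):
            if hi[k] > k + 1:
                pair_i.append(np.full(hi[k] - k - 1, where[k]))
                pair_j.append(where[k + 1:hi[k]])
    if not pair_i:
        raise ValueError("need >= 2 loci on some chromosome")
    ii = np.concatenate(pair_i)
    jj = np.concatenate(pair_j)
    if ii.size > max_pairs:
        keep = np.random.default_rng(seed).choice(ii.size, max_pairs, replace=False)
        keep.sort()
        ii, jj = ii[keep], jj[keep]

    dist = pos[jj] - pos[ii]
    edges = np.linspace(0, max_dist, n_bins + 1)

    r2 = np.empty(ii.size)
    chunk = 20_000
    for s in range(0, ii.size, chunk):
        e = min(s + chunk, ii.size)
        X = d[:, ii[s:e]].astype(float)
        Y = d[:, jj[s:e]].astype(float)
        okm = (X != MISSING) & (Y != MISSING)
        X = np.where(okm, X, np.nan)
        Y = np.where(okm, Y, np.nan)
        n = okm.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            mx = np.nansum(X, axis=0) / n
            my = np.nansum(Y, axis=0) / n
            cov = np.nansum((X - mx) * (Y - my), axis=0) / n
            vx = np.nansum((X - mx) ** 2, axis=0) / n
            vy = np.nansum((Y - my) ** 2, axis=0) / n
            rr = cov ** 2 / (vx * vy)
        rr[(n < 3) | (vx <= 0) | (vy <= 0)] = np.nan
        r2[s:e] = rr

    which = np.clip(np.digitize(dist, edges) - 1, 0, n_bins - 1)
    mean_r2 = np.full(n_bins, np.nan)
    n_pairs = np.zeros(n_bins, dtype=int)
    okr = np.isfinite(r2)
    for b in range(n_bins):
        sel = okr & (which == b)
        n_pairs[b] = int(sel.sum())
        if n_pairs[b]:
            mean_r2[b] = float(r2[sel].mean())
    return LDDecayCurve(edges, mean_r2, n_pairs)
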