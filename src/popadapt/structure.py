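"""Population structure and isolation-by-distance/environment machinery.

PCA follows the Patterson/GCTA genetic-relationship-matrix convention:
dosages are mean-imputed per locus, centred by 2p and scaled by
sqrt(2p(1-p)) before eigen-decomposition of the sample-by-sample kernel.
Mantel tests permute the rows and columns of one matrix jointly and
report the one-sided (positive association) permutation p-value
(1 + #{r* >= r}) / (n_perm + 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .core import DistanceMatrix, EnvFrame, GenotypeMatrix
from .popgen import genomewide_wc_fst

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0088


@dataclass
class PCAResult:
    scores: pd.DataFrame          # samples x K, columns PC1..PCK
    explained: np.ndarray         # variance fraction per component
    loadings: pd.DataFrame        # loci x K
    n_monomorphic_dropped: int

    def summary(self) -> str:
        lines = ["Genotype PCA", "-" * 40]
        for i, f in enumerate(self.explained, 1):
            lines.append(f"PC{i}: {100 * f:6.2f}% variance")
        if self.n_monomorphic_dropped:
            lines.append(f"(dropped {self.n_monomorphic_dropped} monomorphic loci)")
        return "\n".join(lines)


def standardized_dosage(G: GenotypeMatrix, subset: Sequence[str] | None = None,
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Mean-imputed, 2p-centred, sqrt(2p(1-p))-scaled dosage matrix.

    Returns (X, kept_locus_indices); monomorphic loci are dropped.
    """
    sub = G if subset is None else G.take_samples(list(subset))
    d = sub.dosage_float()
    p = np.nanmean(d, axis=0) / 2.0
    keep = np.isfinite(p) & (p > 0) & (p < 1)
    d = d[:, keep]
    p = p[keep]
    d = np.where(np.isnan(d), 2.0 * p, d)
    X = (d - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    return X, np.flatnonzero(keep)


def genotype_pca(G: GenotypeMatrix, subset: Sequence[str] | None = None,
                 k: int = 10) -> PCAResult:
    """PCA of the genotype kernel with a deterministic sign convention
    (the largest-|loading| locus of each component is positive)."""
    samples = list(G.samples) if subset is None else list(subset)
    X, kept = standardized_dosage(G, subset)
    n, L = X.shape
    if k >= min(n, L):
        raise ValueError(f"K={k} must be < min(n_samples, n_loci) = {min(n, L)}")
    K_mat = X @ X.T / L
    evals, evecs = np.linalg.eigh(K_mat)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    total = evals.sum()
    evals_k = evals[:k]
    evecs_k = evecs[:, :k]
    loadings = X.T @ evecs_k                     # loci x k, up to scale
    for j in range(k):
        i_max = np.argmax(np.abs(loadings[:, j]))
        if loadings[i_max, j] < 0:
            loadings[:, j] *= -1
            evecs_k[:, j] *= -1
    scores = evecs_k * np.sqrt(np.maximum(evals_k, 0.0) * n)
    cols = [f"PC{i + 1}" for i in range(k)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=samples, columns=cols),
        explained=np.where(total > 0, evals_k / total, 0.0),
        loadings=pd.DataFrame(loadings, index=kept, columns=cols),
        n_monomorphic_dropped=G.n_loci - len(kept),
    )


# ---------------------------------------------------------------------------
# distance matrices
# ---------------------------------------------------------------------------

def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in km (Earth radius 6371.0088 km)."""
    la1, lo1, la2, lo2 = map(np.radians, (lat1, lon1, lat2, lon2))
    dlat = la2 - la1
    dlon = lo2 - lo1
    h = np.sin(dlat / 2) ** 2 + np.cos(la1) * np.cos(la2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))


def geographic_distance_km(samples: pd.DataFrame,
                           level: str = "population") -> DistanceMatrix:
    """Pairwise haversine distances between population centroids (or samples)."""
    if level == "population":
        pts = samples.groupby("population_id")[["latitude", "longitude"]].mean()
    elif level == "sample":
        pts = samples.set_index("sample_id")[["latitude", "longitude"]]
    else:
        raise ValueError(f"unknown level {level!r}")
    pts = pts.sort_index()
    lat = pts["latitude"].to_numpy()
    lon = pts["longitude"].to_numpy()
    mat = haversine_km(lat[:, None], lon[:, None], lat[None, :], lon[None, :])
    np.fill_diagonal(mat, 0.0)
    mat = 0.5 * (mat + mat.T)
    return DistanceMatrix(list(pts.index), mat, kind="geographic_km")


def env_distance(env: EnvFrame | pd.DataFrame,
                 evs: Sequence[str] | None = None) -> DistanceMatrix:
    """Euclidean distance on per-EV z-scored population values.

    Zero-variance EVs are dropped with a warning.
    """
    cur = env.current if isinstance(env, EnvFrame) else env
    cur = cur.sort_index()
    cols = list(evs) if evs is not None else list(cur.columns)
    missing = [c for c in cols if c not in cur.columns]
    if missing:
        raise KeyError(f"EVs not present: {missing}")
    sub = cur[cols]
    sd = sub.std(ddof=1)
    drop = sd[sd == 0].index.tolist()
    if drop:
        logger.warning("dropping zero-variance EVs: %s", drop)
        sub = sub.drop(columns=drop)
        sd = sd.drop(drop)
    z = (sub - sub.mean()) / sd
    mat = squareform(pdist(z.to_numpy(), metric="euclidean"))
    return DistanceMatrix(list(sub.index), mat, kind="env_euclidean")


def fst_linearized(G: GenotypeMatrix, samples: pd.DataFrame,
                   min_inds: int = 2) -> DistanceMatrix:
    """Pairwise population F_ST/(1-F_ST) with negative F_ST floored at 0.

    Genome-wide weighted WC estimates over all sites per population pair.
    """
    members = samples.groupby("population_id")["sample_id"].apply(list)
    pops = [p for p in sorted(members.index) if len(members[p]) >= min_inds]
    if len(pops) < 2:
        raise ValueError("need >= 2 populations with enough samples")
    n = len(pops)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            fst = genomewide_wc_fst(
                G, {pops[i]: members[pops[i]], pops[j]: members[pops[j]]})
            fst = max(0.0, fst)
            if fst >= 1.0:
                raise ValueError(f"F_ST >= 1 between {pops[i]} and {pops[j]}")
            mat[i, j] = mat[j, i] = fst / (1.0 - fst)
    return DistanceMatrix(pops, mat, kind="fst_linearized")


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------

@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int

    def summary(self) -> str:
        return (f"Mantel test: r = {self.r:.4f}, one-sided p = {self.p:.4g} "
                f"({self.n_perm} permutations)")


def mantel_test(A: DistanceMatrix, B: DistanceMatrix, n_perm: int = 999,
                seed: int | None = None) -> MantelResult:
    """One-sided Mantel test of matrix association.

    r is the Pearson correlation of the upper triangles; significance
    comes from jointly permuting the rows and columns of B.  Symmetric in
    its arguments for a fixed seed.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    if set(A.labels) != set(B.labels):
        raise ValueError("label sets differ")
    order = sorted(A.labels)
    Aa = A.align(order)
    Bb = B.align(order)
    x = Aa.condensed()
    y = Bb.condensed()
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant distance matrix: Mantel r undefined")

    # permuting A's labels and permuting B's labels give the same null; a
    # content-based canonical orientation (in canonical label order) keeps
    # the test exactly symmetric in (A, B) for a fixed seed
    import hashlib

    def _key(M: DistanceMatrix) -> str:
        return hashlib.md5(
            M.kind.encode() + np.round(M.values, 10).tobytes()).hexdigest()

    if _key(Aa) > _key(Bb):
        perm_target, fixed = Aa.values, y
    else:
        perm_target, fixed = Bb.values, x

    def _r(u, v):
        return float(np.corrcoef(u, v)[0, 1])

    r_obs = _r(x, y)
    rng = np.random.default_rng(seed)
    n = len(order)
    iu = np.triu_indices(n, k=1)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        pm = perm_target[np.ix_(perm, perm)][iu]
        if _r(pm, fixed) >= r_obs:
            count += 1
    p = (1.0 + count) / (n_perm + 1.0)
    return MantelResult(r=r_obs, p=p, n_perm=n_perm)


# ---------------------------------------------------------------------------
# LD pruning (for the "neutral variants" Mantel contrast)
# ---------------------------------------------------------------------------

def ld_prune(G: GenotypeMatrix, r2_threshold: float = 0.2,
             window_bp: int = 50_000) -> np.ndarray:
    """Greedy LD pruning: keep a locus iff its r^2 with every already-kept
    locus within ``window_bp`` is <= threshold.  Returns kept indices.

    r^2 is the squared dosage correlation on mean-imputed genotypes.
    """
    d = G.dosage_float()
    col_mean = np.nanmean(d, axis=0)
    X = np.where(np.isnan(d), col_mean[None, :], d)
    X = X - X.mean(axis=0)
    norms = np.sqrt((X ** 2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        X = np.where(norms > 0, X / norms, 0.0)

    pos = G.loci["pos"].to_numpy()
    chroms = G.loci["chrom"].to_numpy()
    kept: list[int] = []
    for chrom in pd.unique(chroms):
        where = np.flatnonzero(chroms == chrom)
        cpos = pos[where]
        kept_local: list[int] = []
        kept_pos: list[int] = []
        lo = 0
        for k, i in enumerate(where):
            while lo < len(kept_pos) and cpos[k] - kept_pos[lo] > window_bp:
                lo += 1
            cands = kept_local[lo:]
            if cands:
                r2 = (X[:, i] @ X[:, cands]) ** 2
                if (r2 > r2_threshold).any():
                    continue
            kept_local.append(i)
            kept_pos.append(int(cpos[k]))
        kept.extend(kept_local)
    return np.array(sorted(kept), dtype=int)
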