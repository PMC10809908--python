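"""Genotype-environment association via a latent-factor linear model.

The scan is the standard two-stage latent-factor scheme: population
structure is summarised by the top-K genotype principal components, each
locus is regressed on [intercept, EV, U] by least squares, and the
resulting z-scores are recalibrated with the genomic inflation factor
lambda = median(z^2) / 0.4549 (the median of chi-square with 1 df).
Adjusted p-values are the upper chi-square tail of z^2 / lambda.  Loci
with |z| >= 4 and adjusted P <= 1e-5 for at least one EV are flagged as
key environment-association loci (EALs).

An optional empirical F_ST-outlier prescreen restricts the scan to
high-differentiation loci; the default is a genome-wide scan.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import EnvFrame, GenotypeMatrix
from .popgen import site_fst
from .structure import genotype_pca

logger = logging.getLogger(__name__)

CHI2_MEDIAN_1DF = float(stats.chi2.ppf(0.5, df=1))  # 0.45493642...


@dataclass(frozen=True)
class EVSpec:
    """The environmental variables entering the scan, after pruning."""

    names: tuple[str, ...]
    units: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.names) < 1:
            raise ValueError("EVSpec needs at least one variable")


def prune_evs(env: EnvFrame | pd.DataFrame, threshold: float = 0.8,
              priority: Sequence[str] | None = None) -> EVSpec:
    """Greedy correlation pruning: iterate EVs in priority order and keep
    one iff |Pearson r| <= threshold with every EV already kept."""
    cur = env.current if isinstance(env, EnvFrame) else env
    if len(cur) < 2:
        raise ValueError("need >= 2 populations to compute correlations")
    order = list(priority) if priority is not None else list(cur.columns)
    corr = cur[order].corr()
    kept: list[str] = []
    for ev in order:
        if all(abs(corr.loc[ev, k]) <= threshold for k in kept):
            kept.append(ev)
    if not kept:
        raise ValueError("no EVs survive pruning")
    return EVSpec(names=tuple(kept))


def fit_latent_factors(G: GenotypeMatrix, k: int,
                       subset: Sequence[str] | None = None) -> pd.DataFrame:
    """Top-K genotype PCA score columns as latent structure factors.

    K = 0 returns an empty frame (the scan reduces to simple regression).
    """
    samples = list(G.samples) if subset is None else list(subset)
    if k == 0:
        return pd.DataFrame(index=samples)
    return genotype_pca(G, subset, k=k).scores


def fst_outlier_prescreen(G: GenotypeMatrix, samples: pd.DataFrame,
                          q: float = 0.01) -> np.ndarray:
    """Indices of loci strictly above the (1-q) quantile of per-site
    multi-population WC F_ST (an empirical differentiation prescreen)."""
    pops = samples.groupby("population_id")["sample_id"].apply(list).to_dict()
    f = site_fst(G, pops)
    finite = f[np.isfinite(f)]
    if q >= 1.0:
        return np.flatnonzero(np.isfinite(f))
    thr = np.quantile(finite, 1.0 - q)
    return np.flatnonzero(np.isfinite(f) & (f > thr))


class GEAScan:
    """Latent-factor genotype-environment association model.

    Parameters
    ----------
    G : genotype matrix (samples x loci).
    samples : sample table mapping samples to populations.
    env : population-level environment; values are broadcast to member
        samples.
    evs : variables to scan (default: every current EV).
    k : number of latent factors (default: number of groups - 1).
    prescreen : optional locus index subset to scan.
    """

    def __init__(self, G: GenotypeMatrix, samples: pd.DataFrame, env: EnvFrame,
                 evs: Sequence[str] | EVSpec | None = None, k: int | None = None,
                 prescreen: np.ndarray | None = None) -> None:
        self.G = G
        self.samples = samples.set_index("sample_id").loc[G.samples].reset_index()
        self.env = env
        if isinstance(evs, EVSpec):
            self.evs = list(evs.names)
        else:
            self.evs = list(evs) if evs is not None else list(env.current.columns)
        missing = [e for e in self.evs if e not in env.current.columns]
        if missing:
            raise KeyError(f"EVs not in environment table: {missing}")
        if k is None:
            k = max(0, self.samples["group_id"].nunique() - 1)
        self.k = k
        self.prescreen = (np.sort(np.asarray(prescreen, dtype=int))
                          if prescreen is not None else None)

    def fit(self, z_min: float = 4.0, p_max: float = 1e-5) -> "GEAScanResults":
        G = self.G if self.prescreen is None else self.G.take_loci(self.prescreen)
        locus_ids = (self.prescreen if self.prescreen is not None
                     else np.arange(self.G.n_loci))
        U = fit_latent_factors(self.G, self.k)  # factors from ALL loci
        n = G.n_samples
        # mean-imputed dosage response
        d = G.dosage_float()
        col_mean = np.nanmean(d, axis=0)
        Y = np.where(np.isnan(d), col_mean[None, :], d)

        pop_of = self.samples.set_index("sample_id")["population_id"]
        records = []
        lambdas = {}
        for ev in self.evs:
            e = self.env.current[ev].reindex(pop_of.loc[G.samples]).to_numpy()
            D = np.column_stack([np.ones(n), e, U.to_numpy()])
            if np.linalg.cond(D) > 1e10:
                raise ValueError(
                    f"design for EV {ev!r} is near-collinear with the latent "
                    f"factors; reduce K")
            p_params = D.shape[1]
            DtD_inv = np.linalg.inv(D.T @ D)
            beta = DtD_inv @ (D.T @ Y)            # p_params x L
            resid = Y - D @ beta
            dof = n - p_params
            rss = (resid ** 2).sum(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                sigma2 = rss / dof
                se = np.sqrt(sigma2 * DtD_inv[1, 1])
                z = np.where(se > 0, beta[1] / se, np.nan)
            p_raw = 2.0 * stats.t.sf(np.abs(z), dof)
            lam = float(np.nanmedian(z ** 2) / CHI2_MEDIAN_1DF)
            lambdas[ev] = lam
            p_adj = stats.chi2.sf(z ** 2 / lam, df=1)
            records.append(pd.DataFrame({
                "locus": locus_ids,
                "chrom": G.loci["chrom"].to_numpy(),
                "pos": G.loci["pos"].to_numpy(),
                "ev": ev,
                "effect": beta[1],
                "se": se,
                "z": z,
                "p_raw": p_raw,
                "p_adj": p_adj,
            }))
        table = pd.concat(records, ignore_index=True)
        # Benjamini-Hochberg within each EV
        from statsmodels.stats.multitest import multipletests
        q = np.full(len(table), np.nan)
        for ev in self.evs:
            mask = (table["ev"] == ev).to_numpy()
            pv = table.loc[mask, "p_adj"].to_numpy()
            ok = np.isfinite(pv)
            if ok.any():
                qv = np.full(ok.size, np.nan)
                qv[ok] = multipletests(pv[ok], method="fdr_bh")[1]
                q[mask] = qv
        table["q"] = q
        table["key_eal"] = ((np.abs(table["z"]) >= z_min)
                            & (table["p_adj"] <= p_max))
        return GEAScanResults(table=table, lambda_by_ev=pd.Series(lambdas),
                              k=self.k, n_samples=n, z_min=z_min, p_max=p_max,
                              latent_factors=U)


@dataclass
class GEAScanResults:
    """Per-(locus, EV) association estimates with GIF calibration."""

    table: pd.DataFrame
    lambda_by_ev: pd.Series
    k: int
    n_samples: int
    z_min: float
    p_max: float
    latent_factors: pd.DataFrame

    @property
    def lambda_gif(self) -> float:
        """Scan-level genomic inflation: median of the per-EV factors."""
        return float(self.lambda_by_ev.median())

    def key_eals(self) -> pd.DataFrame:
        """Records flagged by the |z| >= z_min and P_adj <= p_max rule."""
        return self.table[self.table["key_eal"]]

    def key_eal_loci(self) -> np.ndarray:
        """Loci flagged for at least one EV (sorted unique indices)."""
        return np.sort(self.key_eals()["locus"].unique())

    def loci_below(self, p_threshold: float = 1e-3, ev: str | None = None,
                   use_adjusted: bool = True) -> np.ndarray:
        """Loci with (adjusted) p below a threshold, optionally for one EV."""
        t = self.table if ev is None else self.table[self.table["ev"] == ev]
        col = "p_adj" if use_adjusted else "p_raw"
        return np.sort(t.loc[t[col] < p_threshold, "locus"].unique())

    def manhattan_frame(self, ev: str) -> pd.DataFrame:
        t = self.table[self.table["ev"] == ev]
        out = t[["chrom", "pos"]].copy()
        out["neglog10_p_adj"] = -np.log10(t["p_adj"])
        return out

    def summary(self) -> str:
        lines = [
            "Latent-factor genotype-environment association scan",
            "=" * 55,
            f"samples: {self.n_samples}   latent factors K: {self.k}",
            f"loci scanned: {self.table['locus'].nunique()}   "
            f"EVs: {', '.join(self.lambda_by_ev.index)}",
            f"genomic inflation lambda (median over EVs): {self.lambda_gif:.3f}",
            "-" * 55,
            f"{'EV':>10} {'lambda':>8} {'key EALs':>9}",
        ]
        for ev, lam in self.lambda_by_ev.items():
            n_key = int(self.table[(self.table["ev"] == ev)
                                   & self.table["key_eal"]].shape[0])
            lines.append(f"{ev:>10} {lam:8.3f} {n_key:9d}")
        lines.append("-" * 55)
        lines.append(f"key EAL rule: |z| >= {self.z_min:g} and "
                     f"adjusted P <= {self.p_max:g}; "
                     f"{self.key_eal_loci().size} unique key loci")
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# annotation-category enrichment
# ---------------------------------------------------------------------------

def two_proportion_ztest(x1: int, n1: int, x2: int, n2: int,
                         ) -> tuple[float, float]:
    """Pooled two-proportion Z test; returns (z, two-sided p)."""
    if min(n1, n2) <= 0:
        raise ValueError("group sizes must be positive")
    p1, p2 = x1 / n1, x2 / n2
    pool = (x1 + x2) / (n1 + n2)
    se = np.sqrt(pool * (1 - pool) * (1 / n1 + 1 / n2))
    if se == 0:
        return 0.0, 1.0
    z = (p1 - p2) / se
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


def eal_annotation_classes(classes: pd.Series, eal_idx: np.ndarray,
                           background_idx: np.ndarray | None = None,
                           ) -> pd.DataFrame:
    """Per-class proportion comparison of EAL loci against a background.

    ``classes`` maps locus index -> annotation class (nonsynonymous,
    synonymous, 5UTR, 3UTR, intron, intergenic, ...).  Classes with a
    zero count in either set are flagged for an exact-test fallback
    (Fisher), whose p-value is reported in that case.
    """
    if background_idx is None:
        background_idx = classes.index.to_numpy()
    eal = classes.loc[np.intersect1d(eal_idx, classes.index)]
    bg = classes.loc[np.intersect1d(background_idx, classes.index)]
    n1, n2 = len(eal), len(bg)
    rows = []
    for cls in sorted(classes.unique()):
        x1 = int((eal == cls).sum())
        x2 = int((bg == cls).sum())
        exact = (x1 == 0) or (x2 == 0)
        if exact:
            _, p = stats.fisher_exact([[x1, n1 - x1], [x2, n2 - x2]])
            z = float("nan")
        else:
            z, p = two_proportion_ztest(x1, n1, x2, n2)
        rows.append({"class": cls, "eal_count": x1, "eal_prop": x1 / n1 if n1 else np.nan,
                     "bg_count": x2, "bg_prop": x2 / n2 if n2 else np.nan,
                     "z": z, "p": p, "exact_fallback": exact})
    return pd.DataFrame(rows)
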