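"""Partial redundancy analysis (RDA) of candidate loci on environment.

RDA regresses a multivariate genotype response (individuals x loci) on
environmental predictors; the *partial* form first residualizes both the
response and the predictors on conditioning covariates (here longitude
and latitude), so that constrained axes capture environmental structure
not explained by geography alone.  Outlier loci load on the tails of the
axis-loading distributions; model/axis significance comes from a
permutation pseudo-F test on the residualized response.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

TWO_SIDED_95 = 1.959964  # normal two-sided 95% cutoff


def _residualize(M: np.ndarray, Z: np.ndarray | None) -> np.ndarray:
    """Residuals of the columns of M on [1, Z] by least squares."""
    n = M.shape[0]
    D = np.ones((n, 1)) if Z is None or Z.size == 0 else np.column_stack(
        [np.ones(n), Z])
    coef, *_ = np.linalg.lstsq(D, M, rcond=None)
    return M - D @ coef


class PartialRDA:
    """Partial redundancy analysis model.

    Parameters
    ----------
    Y : (n x L) response — candidate-locus dosages per individual; mean-
        imputed and column-centred internally.
    X : (n x E) explanatory environmental variables; z-scored internally.
    Z : (n x C) conditioning covariates (e.g. lon/lat), or None for plain
        RDA.
    locus_ids, ev_names : optional labels for outputs.
    """

    def __init__(self, Y, X, Z=None, locus_ids: Sequence | None = None,
                 ev_names: Sequence[str] | None = None) -> None:
        if isinstance(Y, pd.DataFrame):
            locus_ids = locus_ids if locus_ids is not None else list(Y.columns)
            Y = Y.to_numpy(dtype=float)
        Y = np.asarray(Y, dtype=float)
        if isinstance(X, pd.DataFrame):
            ev_names = ev_names if ev_names is not None else list(X.columns)
            X = X.to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if Z is not None:
            Z = np.asarray(Z, dtype=float)
            if Z.ndim == 1:
                Z = Z[:, None]
            if Z.shape[0] != Y.shape[0]:
                raise ValueError("Z row count differs from Y")
        if X.shape[0] != Y.shape[0]:
            raise ValueError("X row count differs from Y")
        n = Y.shape[0]
        rank_budget = X.shape[1] + (0 if Z is None else Z.shape[1]) + 1
        if n <= rank_budget:
            raise ValueError(f"need n_samples > rank(X)+rank(Z)+1 = {rank_budget}")

        self.locus_ids = (list(locus_ids) if locus_ids is not None
                          else list(range(Y.shape[1])))
        self.ev_names = (list(ev_names) if ev_names is not None
                         else [f"EV{i + 1}" for i in range(X.shape[1])])
        # mean-impute + centre response
        col_mean = np.nanmean(Y, axis=0)
        Y = np.where(np.isnan(Y), col_mean[None, :], Y)
        self.Y = Y - Y.mean(axis=0)
        # z-score predictors (constant columns are an error downstream)
        sd = X.std(axis=0, ddof=1)
        if (sd == 0).any():
            bad = [self.ev_names[i] for i in np.flatnonzero(sd == 0)]
            raise ValueError(f"constant EVs: {bad}")
        self.X = (X - X.mean(axis=0)) / sd
        self.Z = Z

    def fit(self) -> "PartialRDAResults":
        # collinearity among the EVs themselves is an input error; EVs
        # annihilated by the conditioning variables are legitimate and
        # simply contribute no constrained variance
        if len(self.ev_names) > 1:
            rank_x = np.linalg.matrix_rank(self.X)
            if rank_x < self.X.shape[1]:
                corr = np.corrcoef(self.X, rowvar=False)
                pairs = [
                    (self.ev_names[i], self.ev_names[j])
                    for i in range(len(self.ev_names))
                    for j in range(i + 1, len(self.ev_names))
                    if abs(corr[i, j]) > 0.999999
                ]
                raise ValueError(f"rank-deficient predictors; collinear: {pairs}")
        Y_res = _residualize(self.Y, self.Z)
        X_res = _residualize(self.X, self.Z)
        # predictors annihilated by the conditioning variables (residual
        # norm at rounding level) carry no constrained signal; zero them so
        # lstsq does not rescale numerical noise into a real axis
        x_scale = np.sqrt((self.X ** 2).sum(axis=0))
        annihilated = np.sqrt((X_res ** 2).sum(axis=0)) < 1e-8 * x_scale
        X_res[:, annihilated] = 0.0
        if annihilated.all():
            Y_fit = np.zeros_like(Y_res)
        else:
            B, *_ = np.linalg.lstsq(X_res[:, ~annihilated], Y_res, rcond=None)
            Y_fit = X_res[:, ~annihilated] @ B
        U, s, Vt = np.linalg.svd(Y_fit, full_matrices=False)
        tol = max(Y_fit.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
        n_axes = int((s > tol).sum())
        n_axes = min(n_axes, len(self.ev_names))
        U, s = U[:, :n_axes], s[:n_axes]
        scores = U * s

        # covariance-type species scores (vegan convention): proportional to
        # the covariance of each locus with the unit axis
        n = Y_res.shape[0]
        snp_loadings = (Y_res - Y_res.mean(axis=0)).T @ U / (n - 1)
        biplot = _safe_corr(X_res, scores)
        # deterministic sign: largest-|snp loading| per axis positive
        for j in range(n_axes):
            i_max = int(np.nanargmax(np.abs(snp_loadings[:, j])))
            if snp_loadings[i_max, j] < 0:
                snp_loadings[:, j] *= -1
                biplot[:, j] *= -1
                scores[:, j] *= -1

        total = float((self.Y ** 2).sum())
        conditioned = total - float((Y_res ** 2).sum())
        constrained = float((s ** 2).sum())
        residual = float((Y_res ** 2).sum()) - constrained
        eig = s ** 2
        axis_names = [f"RDA{i + 1}" for i in range(n_axes)]
        return PartialRDAResults(
            model=self,
            scores=pd.DataFrame(scores, columns=axis_names),
            snp_loadings=pd.DataFrame(snp_loadings, index=self.locus_ids,
                                      columns=axis_names),
            biplot_scores=pd.DataFrame(biplot, index=self.ev_names,
                                       columns=axis_names),
            eigenvalues=eig,
            total_variance=total,
            conditioned_variance=conditioned,
            constrained_variance=constrained,
            residual_variance=residual,
            y_residual=Y_res, x_residual=X_res,
        )


def _safe_corr(M: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """Column-wise Pearson correlation of M with each score column."""
    Mc = M - M.mean(axis=0)
    Sc = scores - scores.mean(axis=0)
    m_sd = np.sqrt((Mc ** 2).sum(axis=0))
    s_sd = np.sqrt((Sc ** 2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (Mc.T @ Sc) / np.outer(m_sd, s_sd)
    return out


@dataclass
class PartialRDAResults:
    model: PartialRDA
    scores: pd.DataFrame            # samples x axes (site scores, scaled by s)
    snp_loadings: pd.DataFrame      # loci x axes (correlations)
    biplot_scores: pd.DataFrame     # EVs x axes (correlations)
    eigenvalues: np.ndarray         # singular values squared
    total_variance: float
    conditioned_variance: float
    constrained_variance: float
    residual_variance: float
    y_residual: np.ndarray
    x_residual: np.ndarray

    @property
    def n_axes(self) -> int:
        return self.scores.shape[1]

    @property
    def explained_fraction(self) -> np.ndarray:
        """Per-axis fraction of *total* variance (constrained share)."""
        if self.eigenvalues.sum() == 0:
            return np.zeros(self.n_axes)
        return self.eigenvalues / self.total_variance

    @property
    def variance_fractions(self) -> dict[str, float]:
        t = self.total_variance
        return {"conditioned": self.conditioned_variance / t,
                "constrained": self.constrained_variance / t,
                "residual": self.residual_variance / t}

    def outliers(self, axes: Sequence[int] = (1, 2, 3),
                 cutoff_sd: float = TWO_SIDED_95) -> pd.DataFrame:
        """Tail-loading outliers: loci outside mean +/- cutoff_sd * SD of an
        axis's loading distribution, unioned over the requested axes.

        Each outlier is attributed to its max-|loading| axis and to the EV
        with the largest |biplot correlation| on that axis.
        """
        axes = [a for a in axes if a <= self.n_axes]
        if not axes:
            raise ValueError("no axes available")
        flagged: dict = {}
        for a in axes:
            col = f"RDA{a}"
            load = self.snp_loadings[col]
            sd = float(load.std(ddof=1))
            if not np.isfinite(sd) or sd == 0:
                raise ValueError(f"degenerate loadings on axis {a}")
            mean = float(load.mean())
            hits = load[(load > mean + cutoff_sd * sd)
                        | (load < mean - cutoff_sd * sd)]
            for locus in hits.index:
                flagged.setdefault(locus, set()).add(a)
        rows = []
        for locus, hit_axes in flagged.items():
            row = self.snp_loadings.loc[locus, [f"RDA{a}" for a in axes]]
            best_axis = axes[int(np.argmax(np.abs(row.to_numpy())))]
            ev = self.biplot_scores[f"RDA{best_axis}"].abs().idxmax()
            rows.append({"locus": locus, "axis": best_axis,
                         "loading": float(self.snp_loadings.loc[locus, f"RDA{best_axis}"]),
                         "ev": ev, "n_axes_flagged": len(hit_axes)})
        out = pd.DataFrame(rows, columns=["locus", "axis", "loading", "ev",
                                          "n_axes_flagged"])
        return out.sort_values("locus").reset_index(drop=True)

    def permutation_test(self, n_perm: int = 999, seed: int | None = None,
                         axes: bool = False) -> pd.DataFrame:
        """Permutation pseudo-F significance.

        The global model test permutes rows of the residualized response
        (the partial-model default).  With ``axes=True``, each axis is
        tested sequentially: previous constrained axes join the
        conditioning set and the first remaining axis is tested.
        """
        if n_perm < 99:
            raise ValueError("n_perm must be >= 99")
        rng = np.random.default_rng(seed)
        rows = [self._model_f_test(self.y_residual, self.x_residual,
                                   n_perm, rng, label="model")]
        if axes:
            for a in range(1, self.n_axes + 1):
                rows.append(self._axis_f_test(a, n_perm, rng))
        return pd.DataFrame(rows)

    def _model_f_test(self, Y_res, X_res, n_perm, rng, label) -> dict:
        n = Y_res.shape[0]
        rank_x = np.linalg.matrix_rank(X_res)
        if rank_x == 0:  # all predictors annihilated by conditioning
            return {"term": label, "f": 0.0, "p": 1.0, "n_perm": n_perm}
        rank_z = 0 if self.model.Z is None else np.linalg.matrix_rank(
            np.column_stack([np.ones(n), self.model.Z])) - 1
        df_resid = n - 1 - rank_x - rank_z

        def pseudo_f(Yr):
            B, *_ = np.linalg.lstsq(X_res, Yr, rcond=None)
            fit = X_res @ B
            cons = (fit ** 2).sum()
            resid = (Yr ** 2).sum() - cons
            return (cons / rank_x) / (resid / df_resid)

        f_obs = pseudo_f(Y_res)
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            # re-residualize the permuted response on the conditioning
            # variables (vegan's reduced-model permutation scheme); without
            # this the null F is deflated and the test anti-conservative
            Yp = _residualize(Y_res[perm], self.model.Z)
            if pseudo_f(Yp) >= f_obs:
                count += 1
        return {"term": label, "f": float(f_obs),
                "p": (1.0 + count) / (n_perm + 1.0), "n_perm": n_perm}

    def _axis_f_test(self, axis: int, n_perm, rng) -> dict:
        prev = self.scores.to_numpy()[:, : axis - 1]
        Y_res = _residualize(self.y_residual, prev if prev.size else None)
        X_res = _residualize(self.x_residual, prev if prev.size else None)
        n = Y_res.shape[0]
        rank_x = max(1, np.linalg.matrix_rank(X_res))
        df_resid = Y_res.shape[0] - 1 - rank_x

        def first_eig(Yr):
            B, *_ = np.linalg.lstsq(X_res, Yr, rcond=None)
            fit = X_res @ B
            s = np.linalg.svd(fit, compute_uv=False)
            resid = (Yr ** 2).sum() - (s ** 2).sum()
            return (s[0] ** 2) / (resid / df_resid) if s.size else 0.0

        cond = [np.ones((n, 1))]
        if self.model.Z is not None:
            cond.append(self.model.Z)
        if prev.size:
            cond.append(prev)
        cond_mat = np.column_stack(cond)[:, 1:]  # _residualize adds intercept

        f_obs = first_eig(Y_res)
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            Yp = _residualize(Y_res[perm], cond_mat if cond_mat.size else None)
            if first_eig(Yp) >= f_obs:
                count += 1
        return {"term": f"RDA{axis}", "f": float(f_obs),
                "p": (1.0 + count) / (n_perm + 1.0), "n_perm": n_perm}

    def summary(self) -> str:
        vf = self.variance_fractions
        lines = [
            "Partial redundancy analysis",
            "=" * 50,
            f"samples: {self.scores.shape[0]}   loci: {self.snp_loadings.shape[0]}"
            f"   EVs: {len(self.model.ev_names)}"
            f"   conditioned: {'yes' if self.model.Z is not None else 'no'}",
            f"variance fractions — conditioned: {vf['conditioned']:.4f}  "
            f"constrained: {vf['constrained']:.4f}  residual: {vf['residual']:.4f}",
            "-" * 50,
            f"{'axis':>6} {'eigenvalue':>12} {'% total':>9}",
        ]
        for i, (eig, frac) in enumerate(zip(self.eigenvalues,
                                            self.explained_fraction), 1):
            lines.append(f"RDA{i:>3} {eig:12.4f} {100 * frac:8.3f}%")
        return "\n".join(lines)
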