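"""Risk of non-adaptedness (RONA).

For each environmental variable, the allele frequencies of the loci the
association scan linked to that variable are regressed on the current EV
value across populations.  Projecting the fitted line to a future EV
value gives the theoretically required allele frequency; RONA for a
population is the (R^2-weighted) mean absolute difference between the
required and the observed current frequency over those loci.  Averaging
across climate models yields per-population means and standard errors
per scenario.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import MISSING, EnvFrame, GenotypeMatrix

logger = logging.getLogger(__name__)


def pop_allele_freqs(G: GenotypeMatrix, samples: pd.DataFrame,
                     min_inds: int = 7) -> pd.DataFrame:
    """Population x locus ALT-allele frequencies over called alleles.

    Populations with fewer than ``min_inds`` individuals are dropped (the
    "more than six individuals" retention rule) and logged.
    """
    members = samples.groupby("population_id")["sample_id"].apply(list)
    retained = {p: m for p, m in members.items() if len(m) >= min_inds}
    dropped = sorted(set(members.index) - set(retained))
    if dropped:
        logger.info("dropping %d populations with < %d individuals: %s",
                    len(dropped), min_inds, dropped)
    if not retained:
        raise ValueError(f"no populations with >= {min_inds} individuals")
    rows = {}
    for pop, m in retained.items():
        idx = G.sample_indices(m)
        d = G.dosage[idx]
        called = d != MISSING
        n_alleles = 2 * called.sum(axis=0)
        alt = np.where(called, d, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            rows[pop] = np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1),
                                 np.nan)
    return pd.DataFrame(rows, index=np.arange(G.n_loci)).T.sort_index()


class RONAModel:
    """Per-population RONA under future climate scenarios.

    Parameters
    ----------
    pop_freqs : population x locus frequency table (retained populations).
    env : population-level EnvFrame with future (scenario, model) columns.
    loci_by_ev : mapping EV -> locus indices to use for that EV (the
        association hits for the EV, e.g. scan p < 1e-3).
    """

    def __init__(self, pop_freqs: pd.DataFrame, env: EnvFrame,
                 loci_by_ev: Mapping[str, Sequence[int]]) -> None:
        pops = [p for p in pop_freqs.index if p in env.current.index]
        if len(pops) < 3:
            raise ValueError("need >= 3 retained populations with environment data")
        self.pop_freqs = pop_freqs.loc[pops]
        self.env = env
        self.loci_by_ev = {ev: np.asarray(list(loci), dtype=int)
                           for ev, loci in loci_by_ev.items()}
        for ev in self.loci_by_ev:
            if ev not in env.current.columns:
                raise KeyError(f"EV {ev!r} not in environment table")

    def fit(self, weight_by_r2: bool = True,
            current: str = "observed") -> "RONAResults":
        """Compute the RONA cells.

        ``current`` selects the baseline frequency the required future
        frequency is compared against: the population's ``"observed"``
        frequency (default) or the regression-``"fitted"`` value at the
        current EV.  With the fitted baseline, a zero future shift gives
        exactly zero RONA regardless of regression residuals.
        """
        if current not in {"observed", "fitted"}:
            raise ValueError(f"unknown current baseline {current!r}")
        pops = list(self.pop_freqs.index)
        cells = []
        regressions = []
        for ev, loci in self.loci_by_ev.items():
            e = self.env.current.loc[pops, ev].to_numpy()
            if np.std(e) == 0:
                logger.warning("EV %s constant across populations; skipped", ev)
                continue
            if loci.size == 0:
                logger.warning("no loci for EV %s; cell undefined", ev)
                continue
            F = self.pop_freqs.loc[pops, loci].to_numpy()     # pops x loci
            e_c = e - e.mean()
            denom = float((e_c ** 2).sum())
            # per-locus OLS of frequency on current EV (NaN-frequency pops
            # would need masking; synthetic frequencies are complete)
            f_mean = np.nanmean(F, axis=0)
            slope = np.nansum(e_c[:, None] * (F - f_mean), axis=0) / denom
            intercept = f_mean - slope * e.mean()
            fitted = intercept[None, :] + slope[None, :] * e[:, None]
            ss_res = np.nansum((F - fitted) ** 2, axis=0)
            ss_tot = np.nansum((F - f_mean) ** 2, axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                r2 = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, 0.0)
            w = r2 if weight_by_r2 else np.ones_like(r2)
            regressions.append(pd.DataFrame({
                "ev": ev, "locus": loci, "intercept": intercept,
                "slope": slope, "r2": r2}))
            if w.sum() <= 0:
                logger.warning("all-zero weights for EV %s; cell undefined", ev)
                continue
            for scen in self.env.scenarios:
                for model in self.env.models:
                    if (ev, scen, model) not in self.env.future.columns:
                        continue
                    e_fut = self.env.future[(ev, scen, model)].loc[pops].to_numpy()
                    required_raw = intercept[None, :] + slope[None, :] * e_fut[:, None]
                    required = np.clip(required_raw, 0.0, 1.0)
                    base = F if current == "observed" else np.clip(fitted, 0.0, 1.0)
                    dist = np.abs(required - base)
                    dist_raw = np.abs(required_raw - base)
                    rona = np.nansum(dist * w[None, :], axis=1) / w.sum()
                    rona_raw = np.nansum(dist_raw * w[None, :], axis=1) / w.sum()
                    for j, pop in enumerate(pops):
                        cells.append({
                            "population": pop, "ev": ev, "scenario": scen,
                            "model": model, "rona": float(rona[j]),
                            "rona_unclamped": float(rona_raw[j]),
                            "n_loci": int(loci.size)})
        table = pd.DataFrame(cells)
        reg = (pd.concat(regressions, ignore_index=True)
               if regressions else pd.DataFrame(
                   columns=["ev", "locus", "intercept", "slope", "r2"]))
        return RONAResults(table=table, regressions=reg,
                           weight_by_r2=weight_by_r2, current_baseline=current)


@dataclass
class RONAResults:
    """Per population x EV x scenario x model RONA cells."""

    table: pd.DataFrame
    regressions: pd.DataFrame
    weight_by_r2: bool
    current_baseline: str = "observed"

    def aggregate(self) -> pd.DataFrame:
        """Across-model mean and standard error per population x EV x scenario.

        SE = sd / sqrt(m) over the m climate models; with a single model
        the SE is NaN (undefined) with a warning.
        """
        if self.table.empty:
            raise ValueError("no RONA cells to aggregate")
        g = self.table.groupby(["population", "ev", "scenario"])["rona"]
        out = g.agg(mean_rona="mean", sd="std", n_models="count").reset_index()
        if (out["n_models"] < 2).any():
            logger.warning("single climate model: SE undefined")
        out["se"] = out["sd"] / np.sqrt(out["n_models"])
        return out.drop(columns="sd")

    def scenario_contrast(self, high: str = "SSP585", low: str = "SSP126",
                          ) -> pd.DataFrame:
        """Across-model mean RONA difference (high - low) per population x EV."""
        agg = self.aggregate()
        hi = agg[agg["scenario"] == high].set_index(["population", "ev"])["mean_rona"]
        lo = agg[agg["scenario"] == low].set_index(["population", "ev"])["mean_rona"]
        out = (hi - lo).rename("delta_rona").reset_index()
        return out

    def summary(self) -> str:
        agg = self.aggregate()
        lines = [
            "Risk of non-adaptedness (RONA)",
            "=" * 50,
            f"populations: {self.table['population'].nunique()}   "
            f"EVs: {sorted(self.table['ev'].unique())}",
            f"scenarios: {sorted(self.table['scenario'].unique())}   "
            f"models: {sorted(self.table['model'].unique())}",
            f"weighting: {'R^2' if self.weight_by_r2 else 'uniform'}",
            "-" * 50,
        ]
        piv = agg.pivot_table(index="ev", columns="scenario",
                              values="mean_rona", aggfunc="mean")
        lines.append("mean RONA across populations:")
        lines.append(piv.round(4).to_string())
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.10g")
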