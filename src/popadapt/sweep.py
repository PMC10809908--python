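"""Joint top-quantile F_ST x theta-pi-ratio selective-sweep scan.

A sweep in the focal group leaves a window of locally reduced diversity
and elevated differentiation.  Windows above the empirical (1-q)
quantiles of *both* the windowed F_ST track and the pi_reference /
pi_focal ratio track are selected and merged into candidate regions;
genes overlapping a region by >= 1 bp are its candidates.

The ratio is oriented reference-over-focal so that a sweep in the focal
group lands in the top tail (matching a "top 5%" rule); the orientation
is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import GeneModel, GenotypeMatrix
from .popgen import WindowSpec, WindowedStatTrack, wc_fst, windowed_pi


@dataclass
class SweepRegion:
    chrom: str
    start: int
    end: int
    mean_fst: float
    mean_pi_ratio: float
    n_windows: int
    focal_group: str | None = None
    gene_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.end < self.start or self.n_windows < 1:
            raise ValueError("invalid sweep region")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def pi_ratio_scan(G: GenotypeMatrix, samples: pd.DataFrame, focal_group: str,
                  reference_groups: Sequence[str] | None = None,
                  window: WindowSpec | None = None,
                  orientation: str = "ref_over_focal") -> WindowedStatTrack:
    """Windowed diversity ratio between a focal group and the rest.

    Windows where both group diversities are 0 are NaN; windows with
    pi_focal = 0 but pi_reference > 0 become +inf, which ranks above all
    finite ratios in the joint outlier scan.
    """
    window = window or WindowSpec()
    groups = samples.groupby("group_id")["sample_id"].apply(list)
    if focal_group not in groups.index:
        raise KeyError(f"unknown group {focal_group!r}")
    focal = groups[focal_group]
    if reference_groups is None:
        reference = [s for g in groups.index if g != focal_group for s in groups[g]]
        ref_label = "rest"
    else:
        reference = [s for g in reference_groups for s in groups[g]]
        ref_label = "+".join(reference_groups)
    if len(focal) < 2 or len(reference) < 2:
        raise ValueError("both focal and reference need >= 2 samples")

    pi_f = windowed_pi(G, focal, window)
    pi_r = windowed_pi(G, reference, window)
    f = pi_f.values
    r = pi_r.values
    with np.errstate(invalid="ignore", divide="ignore"):
        if orientation == "ref_over_focal":
            ratio = r / f
        elif orientation == "focal_over_ref":
            ratio = f / r
        else:
            raise ValueError(f"unknown orientation {orientation!r}")
    both_zero = (f == 0) & (r == 0)
    ratio = np.where(both_zero, np.nan, ratio)
    if not np.any(np.isfinite(ratio) | np.isinf(ratio)):
        raise ValueError("no defined windows in the ratio scan")
    frame = pi_f.frame[["chrom", "start", "end", "n_sites"]].copy()
    frame["value"] = ratio
    return WindowedStatTrack(frame, statistic="pi_ratio",
                             focal=focal_group, reference=ref_label)


def _top_threshold(values: np.ndarray, q: float) -> float:
    finite = values[np.isfinite(values)]
    if finite.size == 0:
        raise ValueError("no finite values to take a quantile of")
    return float(np.quantile(finite, 1.0 - q))  # type-7 empirical quantile


def joint_outlier_regions(fst_track: WindowedStatTrack,
                          ratio_track: WindowedStatTrack,
                          q: float = 0.05, merge_gap: int = 0,
                          ) -> list[SweepRegion]:
    """Windows strictly above the (1-q) quantiles of both tracks, merged.

    +inf ratio windows always pass the ratio cut.  Adjacent or
    overlapping selected windows (gap <= merge_gap bp) merge into one
    region carrying summary statistics.
    """
    if not fst_track.same_grid(ratio_track):
        raise ValueError("tracks are on different window grids")
    fst = fst_track.values
    ratio = ratio_track.values
    if q >= 1.0:
        sel = np.isfinite(fst) & (np.isfinite(ratio) | np.isposinf(ratio))
    else:
        thr_f = _top_threshold(fst, q)
        thr_r = _top_threshold(ratio, q)
        sel = (np.isfinite(fst) & (fst > thr_f)
               & ((np.isfinite(ratio) & (ratio > thr_r)) | np.isposinf(ratio)))

    frame = fst_track.frame
    regions: list[SweepRegion] = []
    current: dict | None = None
    for i in np.flatnonzero(sel):
        chrom = frame.at[i, "chrom"]
        start = int(frame.at[i, "start"])
        end = int(frame.at[i, "end"])
        if (current is not None and current["chrom"] == chrom
                and start <= current["end"] + merge_gap + 1):
            current["end"] = max(current["end"], end)
            current["idx"].append(i)
        else:
            if current is not None:
                regions.append(_finalize(current, fst, ratio, ratio_track.focal))
            current = {"chrom": chrom, "start": start, "end": end, "idx": [i]}
    if current is not None:
        regions.append(_finalize(current, fst, ratio, ratio_track.focal))
    return regions


def _finalize(cur: dict, fst: np.ndarray, ratio: np.ndarray,
              focal: str | None) -> SweepRegion:
    idx = np.array(cur["idx"])
    rat = ratio[idx]
    finite = rat[np.isfinite(rat)]
    mean_ratio = float(finite.mean()) if finite.size else float("inf")
    return SweepRegion(chrom=cur["chrom"], start=cur["start"], end=cur["end"],
                       mean_fst=float(np.nanmean(fst[idx])),
                       mean_pi_ratio=mean_ratio,
                       n_windows=len(idx), focal_group=focal)


def annotate_regions(regions: Sequence[SweepRegion],
                     genes: Sequence[GeneModel]) -> list[SweepRegion]:
    """Attach genes overlapping each region by >= 1 bp (1-based inclusive),
    sorted by gene start.  Returns the same region objects, mutated."""
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for lst in by_chrom.values():
        lst.sort(key=lambda g: g.start)
    for region in regions:
        hits = [g for g in by_chrom.get(region.chrom, [])
                if g.start <= region.end and g.end >= region.start]
        region.gene_ids = [g.gene_id for g in hits]
    return list(regions)


def regions_to_frame(regions: Sequence[SweepRegion]) -> pd.DataFrame:
    return pd.DataFrame([{
        "chrom": r.chrom, "start": r.start, "end": r.end,
        "n_windows": r.n_windows, "mean_fst": r.mean_fst,
        "mean_pi_ratio": r.mean_pi_ratio, "focal_group": r.focal_group,
        "genes": ",".join(r.gene_ids),
    } for r in regions])


def sweep_scan(G: GenotypeMatrix, samples: pd.DataFrame, focal_group: str,
               window: WindowSpec | None = None, q: float = 0.05,
               merge_gap: int = 0, genes: Sequence[GeneModel] | None = None,
               ) -> list[SweepRegion]:
    """Convenience wrapper: F_ST (focal vs rest) + pi-ratio joint scan."""
    window = window or WindowSpec()
    groups = samples.groupby("group_id")["sample_id"].apply(list)
    rest = [s for g in groups.index if g != focal_group for s in groups[g]]
    fst_track = wc_fst(G, {focal_group: groups[focal_group], "rest": rest}, window)
    ratio_track = pi_ratio_scan(G, samples, focal_group, window=window)
    regions = joint_outlier_regions(fst_track, ratio_track, q=q, merge_gap=merge_gap)
    if genes is not None:
        annotate_regions(regions, genes)
    return regions
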