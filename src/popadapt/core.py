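"""Core in-memory containers shared across the pipeline.

Conventions
-----------
* Coordinates are 1-based and inclusive throughout (VCF/GFF native);
  conversion to half-open 0-based intervals happens only at BED export.
* Genotypes are diploid ALT-dosage codes ``{0, 1, 2}`` with ``-1`` marking a
  missing call.  Half-calls (``./1``) are treated as missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

MISSING: int = -1

SAMPLE_COLUMNS = ["sample_id", "population_id", "group_id",
                  "latitude", "longitude", "altitude"]


@dataclass(frozen=True)
class Locus:
    """A biallelic SNP site."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    id: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"locus position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"REF and ALT must differ at {self.chrom}:{self.pos}")


@dataclass(frozen=True)
class GeneModel:
    """A gene span from a GFF3 file (1-based inclusive)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start {self.start} > end {self.end}")
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")


class GenotypeMatrix:
    """Samples x loci dosage matrix with locus bookkeeping.

    Parameters
    ----------
    samples : ordered sample identifiers.
    loci : DataFrame with columns ``chrom, pos, ref, alt, id`` sorted by
        (chrom, pos) without duplicate coordinates.
    dosage : int array of shape (n_samples, n_loci); entries in {0, 1, 2}
        or :data:`MISSING`.
    """

    def __init__(self, samples: Sequence[str], loci: pd.DataFrame,
                 dosage: np.ndarray) -> None:
        self.samples = list(samples)
        self.loci = loci.reset_index(drop=True)
        self.dosage = np.asarray(dosage, dtype=np.int8)
        self._validate()

    def _validate(self) -> None:
        if self.dosage.shape != (len(self.samples), len(self.loci)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.samples)} samples x {len(self.loci)} loci")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample IDs")
        bad = ~np.isin(self.dosage, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosage entries must be in {0,1,2} or missing (-1)")
        key = list(zip(self.loci["chrom"], self.loci["pos"]))
        if key != sorted(key):
            raise ValueError("loci must be sorted by (chrom, pos)")
        if len(set(key)) != len(key):
            raise ValueError("duplicate (chrom, pos) loci")

    # -- shape --------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    # -- views --------------------------------------------------------------
    def sample_indices(self, subset: Sequence[str]) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.samples)}
        missing = [s for s in subset if s not in pos]
        if missing:
            raise KeyError(f"unknown sample IDs: {missing}")
        return np.array([pos[s] for s in subset], dtype=int)

    def take_samples(self, subset: Sequence[str]) -> "GenotypeMatrix":
        idx = self.sample_indices(subset)
        return GenotypeMatrix(list(subset), self.loci, self.dosage[idx])

    def take_loci(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(self.samples, self.loci.iloc[idx], self.dosage[:, idx])

    def dosage_float(self) -> np.ndarray:
        """Dosage as float with missing entries as NaN."""
        d = self.dosage.astype(float)
        d[self.dosage == MISSING] = np.nan
        return d

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (self.samples == other.samples
                and self.loci[["chrom", "pos", "ref", "alt"]].equals(
                    other.loci[["chrom", "pos", "ref", "alt"]])
                and np.array_equal(self.dosage, other.dosage))

    def __repr__(self) -> str:
        return f"<GenotypeMatrix {self.n_samples} samples x {self.n_loci} loci>"


def validate_sample_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalise a sample metadata table.

    Required columns: sample_id, population_id, group_id, latitude,
    longitude, altitude.
    """
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sample table missing columns: {missing}")
    df = df[SAMPLE_COLUMNS].copy()
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample IDs: {dup}")
    if (df["latitude"].abs() > 90).any():
        raise ValueError("latitude out of range [-90, 90]")
    if (df["longitude"].abs() > 180).any():
        raise ValueError("longitude out of range [-180, 180]")
    return df.reset_index(drop=True)


@dataclass
class EnvFrame:
    """Population-level environmental variables, current and future.

    Attributes
    ----------
    current : DataFrame indexed by population_id, one column per EV.
    future : DataFrame indexed by population_id with MultiIndex columns
        (ev, scenario, model); may be empty.
    """

    current: pd.DataFrame
    future: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.current = self.current.sort_index()
        if not self.future.empty:
            self.future = self.future.sort_index()
            if self.future.columns.nlevels != 3:
                raise ValueError("future columns must be (ev, scenario, model)")
            if not self.future.index.equals(self.current.index):
                raise ValueError("future and current population sets differ")

    @property
    def populations(self) -> list[str]:
        return list(self.current.index)

    @property
    def evs(self) -> list[str]:
        return list(self.current.columns)

    @property
    def scenarios(self) -> list[str]:
        if self.future.empty:
            return []
        return sorted(self.future.columns.get_level_values("scenario").unique())

    @property
    def models(self) -> list[str]:
        if self.future.empty:
            return []
        return sorted(self.future.columns.get_level_values("model").unique())

    def future_values(self, ev: str, scenario: str, model: str) -> pd.Series:
        return self.future[(ev, scenario, model)]


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix over labelled units."""

    labels: list[str]
    values: np.ndarray
    kind: str = "generic"  # geographic_km | env_euclidean | fst_linearized | ...

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal not zero")

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries, row-major (scipy condensed order)."""
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]

    def align(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)], self.kind)
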