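"""Readers and writers for the standard formats the pipeline touches.

VCF ingestion applies the site-level filters used for the resequencing
panel (VCFtools semantics): biallelic SNPs only, QUAL >= 30, site mean
depth >= 3, call rate >= 0.2 and MAF >= 0.05 by default.  Depth and
quality filters are best-effort: when the VCF carries no DP/QUAL they are
skipped with a logged warning, since such filters are normally applied
upstream by the caller.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from gffutils.iterators import DataIterator

from .core import MISSING, EnvFrame, GeneModel, GenotypeMatrix, validate_sample_frame

logger = logging.getLogger(__name__)


class VcfParseError(ValueError):
    """Malformed VCF input."""


class EmptyResultError(ValueError):
    """No sites survived filtering."""


class UnsupportedPloidyError(ValueError):
    """Genotypes are not diploid."""


@dataclass(frozen=True)
class FilterConfig:
    """Site-level ingestion filters (VCFtools-style semantics).

    ``min_call_rate`` follows VCFtools ``--max-missing`` where 1 means no
    missing data allowed; 0.2 keeps sites with at least 20% of genotypes
    called.  MAF is computed on non-missing alleles.
    """

    maf: float = 0.05
    min_call_rate: float = 0.2
    min_qual: float | None = 30.0
    min_mean_dp: float | None = 3.0
    biallelic_snp_only: bool = True

    @classmethod
    def none(cls) -> "FilterConfig":
        """A no-op configuration (round-trip / pre-filtered input)."""
        return cls(maf=0.0, min_call_rate=0.0, min_qual=None, min_mean_dp=None,
                   biallelic_snp_only=True)


def read_vcf_filtered(path: str | Path, filters: FilterConfig | None = None,
                      ) -> GenotypeMatrix:
    """Read a (possibly gzipped) VCF and apply site filters on the fly.

    Returns a :class:`GenotypeMatrix` of the surviving biallelic SNPs,
    coordinate-sorted.  Raises :class:`EmptyResultError` when nothing
    survives and :class:`UnsupportedPloidyError` on non-diploid GTs.
    """
    from cyvcf2 import VCF

    filters = filters or FilterConfig()
    try:
        vcf = VCF(str(path), gts012=False)
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception
        raise VcfParseError(f"cannot open VCF {path}: {exc}") from exc

    samples = list(vcf.samples)
    n = len(samples)
    if n == 0:
        raise VcfParseError(f"VCF {path} has no samples")

    chroms: list[str] = []
    poss: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    ids: list[str | None] = []
    rows: list[np.ndarray] = []
    warned_qual = warned_dp = False

    for line_no, v in enumerate(vcf, start=1):
        if filters.biallelic_snp_only:
            if len(v.ALT) != 1:
                continue
            if len(v.REF) != 1 or len(v.ALT[0]) != 1:
                continue  # indel / MNP
            if v.REF not in "ACGT" or v.ALT[0] not in "ACGT":
                continue
        if filters.min_qual is not None:
            if v.QUAL is None:
                if not warned_qual:
                    logger.warning("QUAL absent; skipping quality filter")
                    warned_qual = True
            elif v.QUAL < filters.min_qual:
                continue
        if filters.min_mean_dp is not None:
            fmt_dp = v.format("DP")
            depths = None if fmt_dp is None else fmt_dp.astype(np.int64).ravel()
            if depths is None or (depths < 0).all():
                if not warned_dp:
                    logger.warning("DP absent; skipping mean-depth filter")
                    warned_dp = True
            else:
                d = depths[depths >= 0]
                if d.size and d.mean() < filters.min_mean_dp:
                    continue

        gts = v.genotypes
        if len(gts) != n:
            raise VcfParseError(
                f"record {v.CHROM}:{v.POS}: {len(gts)} genotypes for {n} samples")
        dos = np.full(n, MISSING, dtype=np.int8)
        for i, g in enumerate(gts):
            alleles = g[:-1]  # last element is the phase flag
            if len(alleles) != 2:
                raise UnsupportedPloidyError(
                    f"record {v.CHROM}:{v.POS}: ploidy {len(alleles)} unsupported")
            a, b = alleles
            if a < 0 or b < 0:  # half-calls count as missing
                continue
            dos[i] = a + b
        called = int((dos != MISSING).sum())
        if called < filters.min_call_rate * n or called == 0:
            continue
        alt_count = int(dos[dos != MISSING].sum())
        p = alt_count / (2 * called)
        if min(p, 1 - p) < filters.maf:
            continue

        chroms.append(v.CHROM)
        poss.append(v.POS)
        refs.append(v.REF)
        alts.append(v.ALT[0])
        ids.append(v.ID)
        rows.append(dos)

    if not rows:
        raise EmptyResultError(f"no sites in {path} survived filtering")

    loci = pd.DataFrame({"chrom": chroms, "pos": poss, "ref": refs,
                         "alt": alts, "id": ids})
    dosage = np.column_stack(rows)
    order = np.lexsort((loci["pos"].to_numpy(), loci["chrom"].to_numpy()))
    loci = loci.iloc[order]
    dosage = dosage[:, order]
    return GenotypeMatrix(samples, loci, dosage)


def write_vcf(G: GenotypeMatrix, path: str | Path, qual: float = 60.0,
              mean_dp: int = 30, extra_records: list[str] | None = None) -> None:
    """Write a minimal diploid VCF 4.2 for a genotype matrix.

    Emits QUAL and per-sample DP so that ingestion filters have fields to
    act on.  ``extra_records`` are pre-formatted VCF body lines (used by
    the simulator to plant filter-failing sites); they are merged in
    coordinate order.
    """
    lines: list[tuple[str, int, str]] = []
    dp_field = str(mean_dp)
    for j in range(G.n_loci):
        row = G.loci.iloc[j]
        gts = []
        for d in G.dosage[:, j]:
            if d == MISSING:
                gts.append("./.:.")
            else:
                gt = {0: "0/0", 1: "0/1", 2: "1/1"}[int(d)]
                gts.append(f"{gt}:{dp_field}")
        vid = row["id"] if isinstance(row.get("id"), str) and row["id"] else "."
        body = "\t".join([row["chrom"], str(int(row["pos"])), vid, row["ref"],
                          row["alt"], f"{qual:g}", "PASS", ".", "GT:DP", *gts])
        lines.append((row["chrom"], int(row["pos"]), body))
    for rec in extra_records or []:
        f = rec.split("\t")
        lines.append((f[0], int(f[1]), rec))
    lines.sort(key=lambda t: (t[0], t[1]))

    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        for chrom in dict.fromkeys(c for c, _, _ in lines):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(G.samples) + "\n")
        for _, _, body in lines:
            fh.write(body + "\n")


def read_gff_genes(path: str | Path) -> list[GeneModel]:
    """Extract gene features from a GFF3 file (1-based inclusive coords).

    Unsorted input is accepted; genes are returned sorted by (chrom,
    start).  A missing ID attribute gets a synthesized stable identifier.
    """
    genes: list[GeneModel] = []
    for feat in DataIterator(str(path)):
        if feat.featuretype != "gene":
            continue
        ids = feat.attributes.get("ID")
        if ids:
            gene_id = ids[0]
        else:
            gene_id = f"gene:{feat.seqid}:{feat.start}-{feat.end}"
            logger.warning("gene without ID at %s:%s-%s; synthesized %s",
                           feat.seqid, feat.start, feat.end, gene_id)
        strand = feat.strand if feat.strand in {"+", "-"} else "."
        genes.append(GeneModel(gene_id, feat.seqid, feat.start, feat.end, strand))
    genes.sort(key=lambda g: (g.chrom, g.start, g.end))
    return genes


def write_gff_genes(genes: list[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start, g.end)):
            fh.write(f"{g.chrom}\tpopadapt\tgene\t{g.start}\t{g.end}\t.\t"
                     f"{g.strand}\t.\tID={g.gene_id}\n")


def _read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python")


def parse_future_column(name: str) -> tuple[str, str, str] | None:
    """Parse an ``ev:scenario:model`` future-EV column name; None if current."""
    parts = name.split(":")
    if len(parts) == 3:
        return parts[0], parts[1], parts[2]
    if len(parts) != 1:
        raise ValueError(f"bad environment column name {name!r}; "
                         "expected 'EV' or 'EV:scenario:model'")
    return None


def read_tables(sample_path: str | Path, env_path: str | Path,
                ) -> tuple[pd.DataFrame, EnvFrame]:
    """Read and cross-validate the sample and environment tables."""
    samples = validate_sample_frame(_read_table(sample_path))
    env_raw = _read_table(env_path)
    if "population_id" not in env_raw.columns:
        raise ValueError("environment table needs a population_id column")
    if env_raw["population_id"].duplicated().any():
        raise ValueError("duplicate population rows in environment table")
    env_raw = env_raw.set_index("population_id")

    sample_pops = set(samples["population_id"])
    env_pops = set(env_raw.index)
    missing = sorted(sample_pops - env_pops)
    if missing:
        raise ValueError(f"populations missing from environment table: {missing}")

    cur_cols, fut_cols = [], []
    for c in env_raw.columns:
        (fut_cols if parse_future_column(c) else cur_cols).append(c)
    current = env_raw[cur_cols].astype(float)
    if fut_cols:
        triples = [parse_future_column(c) for c in fut_cols]
        future = env_raw[fut_cols].astype(float)
        future.columns = pd.MultiIndex.from_tuples(
            triples, names=["ev", "scenario", "model"])
    else:
        future = pd.DataFrame(index=env_raw.index)
    return samples, EnvFrame(current=current, future=future)


def write_tables(samples: pd.DataFrame, env: EnvFrame,
                 sample_path: str | Path, env_path: str | Path) -> None:
    samples.to_csv(sample_path, sep="\t", index=False, float_format="%.10g")
    flat = env.current.copy()
    if not env.future.empty:
        for col in env.future.columns:
            flat[":".join(col)] = env.future[col]
    flat.index.name = "population_id"
    flat.to_csv(env_path, sep="\t", float_format="%.10g")


def write_bed(intervals: pd.DataFrame, path: str | Path) -> None:
    """Write BED6.  Input has 1-based inclusive ``chrom,start,end`` columns
    (a single position may be given as ``pos``); output is 0-based
    half-open."""
    df = intervals.copy()
    if "pos" in df.columns and "start" not in df.columns:
        df["start"] = df["pos"]
        df["end"] = df["pos"]
    out = pd.DataFrame({
        "chrom": df["chrom"],
        "start": df["start"].astype(int) - 1,
        "end": df["end"].astype(int),
        "name": df["name"] if "name" in df.columns else ".",
        "score": df["score"] if "score" in df.columns else 0,
        "strand": df["strand"] if "strand" in df.columns else ".",
    })
    out.to_csv(path, sep="\t", header=False, index=False, float_format="%.10g")
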