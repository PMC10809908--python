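"""Seeded synthetic landscape-genomics datasets with known ground truth.

The generator emulates a hierarchically structured tree population sampled
across an environmental gradient: four geographic groups, several
populations per group, Balding-Nichols drift at both levels, linkage
blocks copied from small haplotype pools, planted adaptive loci whose
population allele frequencies follow a logistic cline on an environmental
variable, planted selective-sweep regions with locally collapsed
diversity, and future-climate shifts per scenario and climate model.

The Balding-Nichols model draws a population allele frequency from
``Beta(p(1-F)/F, (1-p)(1-F)/F)`` around an ancestral frequency ``p`` so
that the divergence parameter ``F`` is the expected F_ST-like variance
ratio.  Group-level divergence is applied first, then within-group drift,
giving nested structure.  LD arises because loci in the same physical
block are copied from a finite pool of haplotypes per population; blocks
recombine freely.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from .core import MISSING, EnvFrame, GeneModel, GenotypeMatrix
from .io import write_gff_genes, write_tables, write_vcf

DEFAULT_EVS = ["Bio1", "Bio2", "Bio3", "Bio13", "Bio19",
               "Srad6", "Srad12", "Vapr6", "altitude"]
#: EVs with future-climate projections (temperature/precipitation set).
FUTURE_EVS = ["Bio1", "Bio2", "Bio3", "Bio13", "Bio19"]
DEFAULT_MODELS = ["BCC-CSM2-MR", "ACCESS-CM2", "CMCC-ESM2"]
DEFAULT_SCENARIOS = {"SSP126": 0.6, "SSP585": 1.5}

# per-EV spatial trend: (lat, lon, alt weights on standardised geography,
# noise sd on the trend scale, display offset, display scale)
_EV_TRENDS: dict[str, tuple[float, float, float, float, float, float]] = {
    "Bio1":  (-0.8,  0.1, -0.6, 0.5, 8.0, 4.0),
    "Bio2":  (0.3,  -0.4,  0.3, 0.6, 12.0, 1.5),
    "Bio3":  (-0.5, -0.3,  0.4, 0.6, 30.0, 5.0),
    "Bio13": (-0.4,  0.6, -0.2, 0.5, 90.0, 30.0),
    "Bio19": (0.2,   0.7, -0.3, 0.6, 12.0, 6.0),
    "Srad6": (0.5,  -0.7,  0.5, 0.5, 20000.0, 2500.0),
    "Srad12": (0.4, -0.5,  0.3, 0.6, 12000.0, 1800.0),
    "Vapr6": (-0.6,  0.4, -0.5, 0.6, 1.6, 0.4),
}

_GROUP_GEO = {  # group -> (lat, lon, altitude) centres
    "NW": (36.0, 100.0, 2600.0),
    "SW": (30.0, 101.0, 2400.0),
    "TH": (37.0, 113.0, 1300.0),
    "NC": (40.0, 115.0, 1100.0),
}

_FAIL_CATEGORIES = ("indel", "multiallelic", "low_maf",
                    "low_callrate", "low_qual", "low_dp")


@dataclass(frozen=True)
class AdaptiveEffect:
    """Logistic cline of a locus on a (z-scored) environmental variable."""

    ev: str
    a: float = 0.0   # intercept (logit scale)
    b: float = 3.0   # slope per EV standard deviation


@dataclass(frozen=True)
class SweepSpec:
    """A planted selective sweep in one group."""

    group: str
    chrom: str
    start: int
    end: int
    reduction: float = 0.1          # heterozygosity multiplier in the focal group
    divergence_boost: float = 2.5   # multiplier on the group-level F inside the span


@dataclass(frozen=True)
class FutureShift:
    """Future EV deltas, in units of the current across-population SD."""

    base: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SCENARIOS))
    spatial_gradient: float = 0.5   # modulation by z-scored latitude
    model_jitter_sd: float = 0.15   # per (EV, model) offset across populations


@dataclass
class SimConfig:
    seed: int
    n_groups: int = 4
    pops_per_group: int = 3
    inds_per_pop: int = 10
    n_chrom: int = 2
    chrom_length_bp: int = 1_000_000
    n_neutral_loci: int = 19_950
    n_adaptive_loci: int = 50
    fst_between_groups: float = 0.25
    fst_within_group: float = 0.03
    adaptive_effects: list[AdaptiveEffect] | None = None
    sweep_regions: list[SweepSpec] | None = None
    ld_block_length_bp: int = 5_000
    haplotype_pool_size: int = 24
    missing_rate: float = 0.02
    maf_floor: float = 0.05
    #: ancestral-frequency distribution: "uniform" emulates a MAF-filtered
    #: panel (U(0.1, 0.9)); "neutral" draws from the 1/p standing-variation
    #: spectrum truncated to [spectrum_min, 1 - spectrum_min].
    ancestral_spectrum: str = "uniform"
    spectrum_min: float = 0.005
    evs: list[str] = field(default_factory=lambda: list(DEFAULT_EVS))
    env_noise_sd: float = 0.5
    future_shift: FutureShift = field(default_factory=FutureShift)
    planted_fail_per_category: int = 4

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("SimConfig.seed is mandatory")
        for name in ("n_groups", "pops_per_group", "inds_per_pop", "n_chrom",
                     "chrom_length_bp", "n_neutral_loci"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("fst_between_groups", "fst_within_group"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.n_adaptive_loci > self.n_neutral_loci + self.n_adaptive_loci:
            raise ValueError("infeasible: adaptive loci exceed total loci")
        if self.n_adaptive_loci < 0:
            raise ValueError("n_adaptive_loci must be >= 0")

    @property
    def n_pops(self) -> int:
        return self.n_groups * self.pops_per_group

    @property
    def n_samples(self) -> int:
        return self.n_pops * self.inds_per_pop

    def group_names(self) -> list[str]:
        if self.n_groups <= 4:
            return list(_GROUP_GEO)[: self.n_groups]
        return list(_GROUP_GEO) + [f"G{i}" for i in range(5, self.n_groups + 1)]

    def default_sweeps(self) -> list[SweepSpec]:
        sweeps = []
        for gi, g in enumerate(self.group_names()):
            chrom = f"chr{(gi % self.n_chrom) + 1}"
            start = 200_001 + (gi // self.n_chrom) * 300_000
            end = min(start + 100_000 - 1, self.chrom_length_bp)
            sweeps.append(SweepSpec(g, chrom, start, end))
        return sweeps


@dataclass
class GroundTruth:
    """Everything needed to score downstream stages against the generator."""

    locus_class: np.ndarray            # per emitted locus: neutral|adaptive|sweep
    adaptive: pd.DataFrame             # chrom, pos, ev, a, b
    sweeps: list[SweepSpec]
    filter_pass: np.ndarray            # per emitted locus, default-filter survival
    planted_fail: dict[str, int]       # fail-site counts per category (VCF only)
    sweep_gene_ids: list[str]
    env: EnvFrame
    ev_sd: pd.Series                   # across-population SD of each current EV
    config: SimConfig

    def n_pass(self) -> int:
        return int(self.filter_pass.sum())

    def adaptive_key(self) -> set[tuple[str, int]]:
        return set(zip(self.adaptive["chrom"], self.adaptive["pos"].astype(int)))

    def class_of(self, loci: pd.DataFrame) -> np.ndarray:
        """Locus classes aligned to an arbitrary (filtered) locus table."""
        lookup = {(c, int(p)): cl for c, p, cl in
                  zip(self.adaptive["chrom"], self.adaptive["pos"],
                      ["adaptive"] * len(self.adaptive))}
        out = []
        for c, p in zip(loci["chrom"], loci["pos"]):
            cl = lookup.get((c, int(p)))
            if cl is None:
                cl = "sweep" if any(s.chrom == c and s.start <= p <= s.end
                                    for s in self.sweeps) else "neutral"
            out.append(cl)
        return np.array(out)

    def to_json(self, path: str | Path) -> None:
        cfg = dataclasses.asdict(self.config)
        payload = {
            "version": 1,
            "config": cfg,
            "locus_class": self.locus_class.tolist(),
            "adaptive": self.adaptive.to_dict(orient="list"),
            "sweeps": [dataclasses.asdict(s) for s in self.sweeps],
            "filter_pass": self.filter_pass.astype(int).tolist(),
            "planted_fail": self.planted_fail,
            "sweep_gene_ids": self.sweep_gene_ids,
            "ev_sd": self.ev_sd.to_dict(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


class SimBundle(NamedTuple):
    genotypes: GenotypeMatrix
    samples: pd.DataFrame
    env: EnvFrame
    genes: list[GeneModel]
    truth: GroundTruth


def gea_validation_config(seed: int, n_neutral_loci: int = 5_000,
                          n_adaptive_loci: int = 0,
                          cline_slope: float = 3.0) -> SimConfig:
    """Study conditions for validating the association scan.

    120 individuals in 4 groups of 6 populations (5 each), with
    within-group drift set near zero so the latent structure has exactly
    the group dimension the scan's K = n_groups - 1 factors presume — the
    regime in which a latent-factor scan is expected to be calibrated.
    Planted clines use slope +/-3 per EV standard deviation, emulating
    near-complete clinal allele-frequency turnover across the sampled
    environmental range (the behaviour of strongly selected loci).
    """
    evs = [e for e in DEFAULT_EVS if e != "altitude"]
    effects = [AdaptiveEffect(ev=evs[i % len(evs)], a=0.0,
                              b=cline_slope * (1 if i % 2 == 0 else -1))
               for i in range(n_adaptive_loci)]
    return SimConfig(
        seed=seed, pops_per_group=6, inds_per_pop=5,
        n_neutral_loci=n_neutral_loci, n_adaptive_loci=n_adaptive_loci,
        adaptive_effects=effects or None,
        fst_within_group=1e-3, haplotype_pool_size=1_000)


def _balding_nichols(rng: np.random.Generator, p: np.ndarray, F: float,
                     size=None) -> np.ndarray:
    """Beta draw with mean p and variance F*p*(1-p); clipped for stability."""
    p = np.clip(np.asarray(p, dtype=float), 1e-6, 1 - 1e-6)
    k = (1.0 - F) / F
    return np.clip(rng.beta(p * k, (1.0 - p) * k, size=size), 1e-9, 1 - 1e-9)


def _reduce_heterozygosity(p: np.ndarray, factor: float) -> np.ndarray:
    """Move frequencies toward the nearest boundary so 2pq scales by ``factor``."""
    pq = np.clip(factor * p * (1.0 - p), 0.0, 0.25)
    root = np.sqrt(0.25 - pq)
    return np.where(p <= 0.5, 0.5 - root, 0.5 + root)


def _make_geography(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    names = cfg.group_names()
    for gi, g in enumerate(names):
        lat0, lon0, alt0 = _GROUP_GEO.get(g, (30.0 + 3 * gi, 95.0 + 4 * gi, 1800.0))
        for pi in range(cfg.pops_per_group):
            rows.append({
                "population_id": f"P{gi * cfg.pops_per_group + pi + 1:02d}",
                "group_id": g,
                "latitude": lat0 + rng.normal(0.0, 1.2),
                "longitude": lon0 + rng.normal(0.0, 1.5),
                "altitude": max(400.0, alt0 + rng.normal(0.0, 250.0)),
            })
    return pd.DataFrame(rows)


def _make_env(cfg: SimConfig, geo: pd.DataFrame, rng: np.random.Generator,
              ) -> tuple[EnvFrame, pd.Series]:
    lat_z = (geo["latitude"] - geo["latitude"].mean()) / geo["latitude"].std()
    lon_z = (geo["longitude"] - geo["longitude"].mean()) / geo["longitude"].std()
    alt_z = (geo["altitude"] - geo["altitude"].mean()) / geo["altitude"].std()
    current = {}
    for ev in cfg.evs:
        if ev == "altitude":
            current[ev] = geo["altitude"].to_numpy()
            continue
        wlat, wlon, walt, nsd, off, scale = _EV_TRENDS.get(
            ev, (0.5, 0.5, 0.0, cfg.env_noise_sd, 0.0, 1.0))
        raw = (wlat * lat_z + wlon * lon_z + walt * alt_z
               + rng.normal(0.0, max(nsd, cfg.env_noise_sd), size=len(geo)))
        z = (raw - raw.mean()) / raw.std()
        current[ev] = off + scale * z.to_numpy()
    cur = pd.DataFrame(current, index=geo["population_id"])
    cur.index.name = "population_id"
    ev_sd = cur.std(ddof=1)

    shift = cfg.future_shift
    cols, vals = [], []
    for ev in [e for e in FUTURE_EVS if e in cfg.evs]:
        for scen, base in shift.base.items():
            for model in DEFAULT_MODELS:
                jitter = rng.normal(0.0, shift.model_jitter_sd)
                delta_sd = base * (1.0 + shift.spatial_gradient * lat_z.to_numpy()) + jitter
                cols.append((ev, scen, model))
                vals.append(cur[ev].to_numpy() + delta_sd * ev_sd[ev])
    future = pd.DataFrame(
        np.column_stack(vals) if vals else np.empty((len(cur), 0)),
        index=cur.index,
        columns=pd.MultiIndex.from_tuples(cols, names=["ev", "scenario", "model"])
        if cols else pd.MultiIndex.from_arrays([[], [], []],
                                               names=["ev", "scenario", "model"]))
    return EnvFrame(current=cur, future=future), ev_sd


def _make_genes(cfg: SimConfig, sweeps: list[SweepSpec]) -> tuple[list[GeneModel], list[str]]:
    genes: list[GeneModel] = []
    gid = 0
    for ci in range(cfg.n_chrom):
        chrom = f"chr{ci + 1}"
        for start in range(10_001, cfg.chrom_length_bp - 2_000, 20_000):
            gid += 1
            strand = "+" if gid % 2 else "-"
            genes.append(GeneModel(f"gene{gid:05d}", chrom, start, start + 1_999, strand))
    sweep_gene_ids = [g.gene_id for g in genes
                      if any(s.chrom == g.chrom and g.start <= s.end and g.end >= s.start
                             for s in sweeps)]
    return genes, sweep_gene_ids


def simulate_dataset(cfg: SimConfig) -> SimBundle:
    """Generate a complete ground-truth-annotated dataset.

    Deterministic for a fixed :class:`SimConfig` (including the seed).
    """
    rng = np.random.default_rng(cfg.seed)
    geo = _make_geography(cfg, rng)
    env, ev_sd = _make_env(cfg, geo, rng)

    # sample table: individuals inherit the population site
    samples = geo.loc[geo.index.repeat(cfg.inds_per_pop)].reset_index(drop=True)
    samples["sample_id"] = [f"{p}_{i % cfg.inds_per_pop + 1:02d}"
                            for i, p in enumerate(samples["population_id"])]
    samples = samples[["sample_id", "population_id", "group_id",
                       "latitude", "longitude", "altitude"]]
    pop_ids = geo["population_id"].tolist()
    pop_of_sample = samples["population_id"].to_numpy()
    group_of_pop = dict(zip(geo["population_id"], geo["group_id"]))

    sweeps = cfg.sweep_regions if cfg.sweep_regions is not None else cfg.default_sweeps()

    # -- locus positions ----------------------------------------------------
    n_total = cfg.n_neutral_loci + cfg.n_adaptive_loci
    per_chrom = np.full(cfg.n_chrom, n_total // cfg.n_chrom)
    per_chrom[: n_total % cfg.n_chrom] += 1
    chrom_names, positions = [], []
    for ci in range(cfg.n_chrom):
        pos = np.sort(rng.choice(
            np.arange(100, cfg.chrom_length_bp - 2_000),
            size=per_chrom[ci], replace=False))
        positions.append(pos)
        chrom_names.append(f"chr{ci + 1}")
    all_chrom = np.concatenate([[c] * len(p) for c, p in zip(chrom_names, positions)])
    all_pos = np.concatenate(positions)
    L = len(all_pos)

    # choose adaptive loci uniformly, but outside sweep spans
    in_sweep = np.zeros(L, dtype=bool)
    for s in sweeps:
        in_sweep |= (all_chrom == s.chrom) & (all_pos >= s.start) & (all_pos <= s.end)
    eligible = np.flatnonzero(~in_sweep)
    adaptive_idx = np.sort(rng.choice(eligible, size=cfg.n_adaptive_loci,
                                      replace=False)) if cfg.n_adaptive_loci else \
        np.array([], dtype=int)
    is_adaptive = np.zeros(L, dtype=bool)
    is_adaptive[adaptive_idx] = True

    effects = cfg.adaptive_effects
    if effects is None:
        clinal_evs = [e for e in cfg.evs if e != "altitude"] or cfg.evs
        effects = [AdaptiveEffect(ev=clinal_evs[i % len(clinal_evs)],
                                  a=0.0, b=3.0 * (1 if i % 2 == 0 else -1))
                   for i in range(cfg.n_adaptive_loci)]
    if len(effects) != cfg.n_adaptive_loci:
        raise ValueError("adaptive_effects length must equal n_adaptive_loci")

    env_z = (env.current - env.current.mean()) / env.current.std(ddof=1)

    # -- per-population allele frequencies ----------------------------------
    n_pops = cfg.n_pops
    F_b, F_w = cfg.fst_between_groups, cfg.fst_within_group
    if cfg.ancestral_spectrum == "uniform":
        p0 = rng.uniform(0.1, 0.9, size=L)
    elif cfg.ancestral_spectrum == "neutral":
        lo, hi = cfg.spectrum_min, 1.0 - cfg.spectrum_min
        p0 = lo * (hi / lo) ** rng.random(L)  # density proportional to 1/p
    else:
        raise ValueError(f"unknown ancestral_spectrum {cfg.ancestral_spectrum!r}")
    group_names = cfg.group_names()
    p_group = np.empty((len(group_names), L))
    for gi in range(len(group_names)):
        p_group[gi] = _balding_nichols(rng, p0, F_b)
    p_pop = np.empty((n_pops, L))
    for pi, pop in enumerate(pop_ids):
        gi = group_names.index(group_of_pop[pop])
        p_pop[pi] = _balding_nichols(rng, p_group[gi], F_w)

    # adaptive loci: logistic cline on the (z-scored) EV, then mild drift
    for k, li in enumerate(adaptive_idx):
        eff = effects[k]
        z = env_z[eff.ev].reindex(pop_ids).to_numpy()
        cline = 1.0 / (1.0 + np.exp(-(eff.a + eff.b * z)))
        p_pop[:, li] = _balding_nichols(rng, cline, F_w)

    # sweep spans: boosted divergence + collapsed diversity in the focal group
    sweep_pool_size = {}
    for s in sweeps:
        mask = (all_chrom == s.chrom) & (all_pos >= s.start) & (all_pos <= s.end)
        li = np.flatnonzero(mask)
        if li.size == 0:
            continue
        gi = group_names.index(s.group)
        boosted = _balding_nichols(
            rng, p0[li], min(0.95, F_b * s.divergence_boost))
        swept = _reduce_heterozygosity(boosted, s.reduction)
        for pi, pop in enumerate(pop_ids):
            if group_of_pop[pop] == s.group:
                p_pop[pi, li] = _balding_nichols(rng, swept, F_w * s.reduction)
                sweep_pool_size[(pi, s.chrom, s.start, s.end)] = max(
                    2, int(round(cfg.haplotype_pool_size * s.reduction)))

    # -- genotypes: haplotype-pool blocks for LD ----------------------------
    dosage = np.empty((cfg.n_samples, L), dtype=np.int8)
    sample_rows_of_pop = {p: np.flatnonzero(pop_of_sample == p) for p in pop_ids}
    block_id = np.array([f"{c}:{pos // cfg.ld_block_length_bp}"
                         for c, pos in zip(all_chrom, all_pos)])
    H = cfg.haplotype_pool_size
    order = np.arange(L)
    for blk in dict.fromkeys(block_id):  # preserves genomic order
        li = order[block_id == blk]
        li_block = li[~is_adaptive[li]]
        # adaptive loci segregate independently (their own effective block)
        for la in li[is_adaptive[li]]:
            for pi, pop in enumerate(pop_ids):
                rows = sample_rows_of_pop[pop]
                dosage[rows, la] = rng.binomial(2, p_pop[pi, la], size=rows.size)
        if li_block.size == 0:
            continue
        chrom0, pos0 = all_chrom[li_block[0]], all_pos[li_block[0]]
        for pi, pop in enumerate(pop_ids):
            rows = sample_rows_of_pop[pop]
            h = H
            for (ppi, c, s, e), hs in sweep_pool_size.items():
                if ppi == pi and c == chrom0 and s <= pos0 <= e:
                    h = hs
                    break
            pool = (rng.random((h, li_block.size))
                    < p_pop[pi, li_block][None, :]).astype(np.int8)
            picks = rng.integers(0, h, size=(rows.size, 2))
            dosage[np.ix_(rows, li_block)] = pool[picks[:, 0]] + pool[picks[:, 1]]

    # -- missingness ---------------------------------------------------------
    if cfg.missing_rate > 0:
        mask = rng.random(dosage.shape) < cfg.missing_rate
        dosage[mask] = MISSING

    loci = pd.DataFrame({"chrom": all_chrom, "pos": all_pos,
                         "ref": "A", "alt": "T", "id": None})
    G = GenotypeMatrix(samples["sample_id"].tolist(), loci, dosage)

    # -- ground truth --------------------------------------------------------
    locus_class = np.where(is_adaptive, "adaptive",
                           np.where(in_sweep, "sweep", "neutral"))
    called = (dosage != MISSING)
    n_called = called.sum(axis=0)
    alt = np.where(called, dosage, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_hat = alt / (2 * n_called)
    maf = np.minimum(p_hat, 1 - p_hat)
    filter_pass = ((n_called >= 0.2 * cfg.n_samples)
                   & (n_called > 0) & (maf >= cfg.maf_floor))

    adaptive_df = pd.DataFrame({
        "chrom": all_chrom[adaptive_idx],
        "pos": all_pos[adaptive_idx].astype(int),
        "ev": [e.ev for e in effects],
        "a": [e.a for e in effects],
        "b": [e.b for e in effects],
    })
    genes, sweep_gene_ids = _make_genes(cfg, sweeps)
    truth = GroundTruth(
        locus_class=locus_class, adaptive=adaptive_df, sweeps=sweeps,
        filter_pass=filter_pass,
        planted_fail={c: cfg.planted_fail_per_category for c in _FAIL_CATEGORIES},
        sweep_gene_ids=sweep_gene_ids, env=env, ev_sd=ev_sd, config=cfg)
    return SimBundle(G, samples, env, genes, truth)


def _fail_site_records(cfg: SimConfig, n_samples: int) -> list[str]:
    """Pre-formatted VCF lines that each fail exactly one default filter."""
    recs = []
    base = cfg.chrom_length_bp - 1_500
    all_ref = ["0/0:30"] * n_samples

    def line(pos, ref, alt, qual, gts):
        return "\t".join(["chr1", str(pos), ".", ref, alt, qual, "PASS", ".",
                          "GT:DP", *gts])

    k = cfg.planted_fail_per_category
    for i in range(k):
        gts_poly = ["0/1:30" if s < n_samples // 3 else "0/0:30"
                    for s in range(n_samples)]
        recs.append(line(base + i * 12 + 0, "AT", "A", "60", gts_poly))      # indel
        recs.append(line(base + i * 12 + 1, "A", "C,T", "60", gts_poly))     # multiallelic
        one_het = ["0/1:30"] + ["0/0:30"] * (n_samples - 1)
        recs.append(line(base + i * 12 + 2, "A", "G", "60", one_het))        # low MAF
        few = ["0/1:30" if s < max(1, int(0.1 * n_samples)) else "./.:."
               for s in range(n_samples)]
        recs.append(line(base + i * 12 + 3, "A", "G", "60", few))            # low call rate
        recs.append(line(base + i * 12 + 4, "A", "G", "10", gts_poly))       # low QUAL
        low_dp = [g.replace(":30", ":1") for g in gts_poly]
        recs.append(line(base + i * 12 + 5, "A", "G", "60", low_dp))         # low DP
    return recs


def write_fixture(bundle: SimBundle, out_dir: str | Path,
                  overwrite: bool = False) -> dict[str, Path]:
    """Write VCF + samples.tsv + env.tsv + genes.gff3 + truth.json.

    Re-reading through :mod:`popadapt.io` reproduces the in-memory objects
    (modulo the site filters, whose survivors are recorded in the truth).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    existing = list(out.iterdir())
    if existing and not overwrite:
        raise FileExistsError(f"{out} is not empty; pass overwrite=True")

    cfg = bundle.truth.config
    manifest = {
        "vcf": out / "dataset.vcf",
        "samples": out / "samples.tsv",
        "env": out / "env.tsv",
        "gff": out / "genes.gff3",
        "truth": out / "truth.json",
    }
    extra = _fail_site_records(cfg, bundle.genotypes.n_samples)
    write_vcf(bundle.genotypes, manifest["vcf"], extra_records=extra)
    write_tables(bundle.samples, bundle.env, manifest["samples"], manifest["env"])
    write_gff_genes(bundle.genes, manifest["gff"])
    bundle.truth.to_json(manifest["truth"])
    return manifest
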