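"""End-to-end pipeline orchestration with config, manifests and seeding.

Stages run in a fixed order (io -> stats -> structure -> sweep -> gea ->
rda -> rona); each writes TSV/BED outputs plus a JSON manifest with
input hashes, the resolved thresholds and headline counts.  All
randomness flows from the master seed through named per-stage substreams,
so adding a stage never perturbs earlier stages' draws.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import gea, rda, rona, structure, sweep
from .core import EnvFrame
from .io import FilterConfig, read_gff_genes, read_tables, read_vcf_filtered, write_bed
from .popgen import WindowSpec, ld_decay, tajimas_d, wc_fst, windowed_pi
from .simulate import SimConfig, simulate_dataset, write_fixture
from .sweep import regions_to_frame

logger = logging.getLogger(__name__)

STAGES = ["io", "stats", "structure", "sweep", "gea", "rda", "rona"]


@dataclass
class PipelineConfig:
    vcf: str
    samples: str
    env: str
    outdir: str
    gff: str | None = None
    filters: FilterConfig = field(default_factory=FilterConfig)
    window_length_bp: int = 100_000
    window_step_bp: int = 1_000
    k_latent: int | None = None        # default: n_groups - 1
    sweep_q: float = 0.05
    z_min: float = 4.0
    p_max: float = 1e-5
    rda_cutoff_sd: float = rda.TWO_SIDED_95
    rda_axes: tuple[int, ...] = (1, 2, 3)
    rona_p: float = 1e-3
    min_inds: int = 7
    n_perm: int = 999
    ld_max_dist: int = 500_000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "filters" in raw and isinstance(raw["filters"], dict):
            raw["filters"] = FilterConfig(**raw["filters"])
        if "rda_axes" in raw:
            raw["rda_axes"] = tuple(raw["rda_axes"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["rda_axes"] = list(self.rda_axes)
        return d

    def config_hash(self) -> str:
        """Hash of the analysis parameters (paths excluded, so a run moved
        to a different directory keeps the same hash)."""
        d = {k: v for k, v in self.to_dict().items()
             if k not in {"vcf", "samples", "env", "gff", "outdir"}}
        return hashlib.sha256(
            json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]

    def stage_seed(self, stage: str) -> int:
        """Named substream: stable per stage, derived from the master seed."""
        ss = np.random.SeedSequence(
            entropy=self.seed, spawn_key=(zlib.crc32(stage.encode()),))
        return int(ss.generate_state(1, dtype=np.uint32)[0]) % (2 ** 31)

    def window(self) -> WindowSpec:
        return WindowSpec(self.window_length_bp, self.window_step_bp)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(outdir: Path, stage: str, cfg: PipelineConfig,
                    outputs: list[Path], counts: dict) -> Path:
    payload = {
        "stage": stage,
        "config_hash": cfg.config_hash(),
        "seed": cfg.stage_seed(stage),
        "counts": counts,
        "outputs": {p.name: _sha256(p) for p in outputs},
    }
    path = outdir / f"{stage}.manifest.json"
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
    return path


def _tsv(df: pd.DataFrame, path: Path, index: bool = False) -> Path:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")
    return path


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception, cfg: PipelineConfig):
        super().__init__(
            f"stage '{stage}' failed: {cause}\n"
            f"reproduce with: popadapt {stage if stage in STAGES else 'run-all'} "
            f"--outdir {cfg.outdir} --seed {cfg.seed}")
        self.stage = stage


def run_pipeline(cfg: PipelineConfig, upto: str = "rona") -> dict:
    """Execute the pipeline through stage ``upto``; returns the run manifest."""
    if upto not in STAGES:
        raise ValueError(f"unknown stage {upto!r}")
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    wanted = STAGES[: STAGES.index(upto) + 1]
    manifest: dict[str, str] = {}
    state: dict = {}
    for stage in wanted:
        fn = globals()[f"_stage_{stage}"]
        try:
            stage_manifest = fn(cfg, outdir, state)
        except Exception as exc:  # noqa: BLE001 — halts with the stage name
            raise StageError(stage, exc, cfg) from exc
        manifest[stage] = stage_manifest.name
        logger.info("stage %s complete", stage)
    params = {k: v for k, v in cfg.to_dict().items()
              if k not in {"vcf", "samples", "env", "gff", "outdir"}}
    with open(outdir / "run.manifest.json", "w") as fh:
        json.dump({"config_hash": cfg.config_hash(), "parameters": params,
                   "stages": manifest}, fh, indent=1, sort_keys=True)
    with open(outdir / "run_config.yaml", "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
    return manifest


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_io(cfg: PipelineConfig, outdir: Path, state: dict) -> Path:
    G = read_vcf_filtered(cfg.vcf, cfg.filters)
    samples, env = read_tables(cfg.samples, cfg.env)
    unknown = set(G.samples) - set(samples["sample_id"])
    if unknown:
        raise ValueError(f"VCF samples missing from sample table: {sorted(unknown)}")
    samples = samples.set_index("sample_id").loc[G.samples].reset_index()
    genes = read_gff_genes(cfg.gff) if cfg.gff else []
    state.update(G=G, samples=samples, env=env, genes=genes)
    out = _tsv(G.loci.assign(idx=np.arange(G.n_loci)), outdir / "loci.tsv")
    counts = {"samples": G.n_samples, "loci": G.n_loci,
              "populations": samples["population_id"].nunique(),
              "genes": len(genes)}
    return _write_manifest(outdir, "io", cfg, [out], counts)


def _stage_stats(cfg: PipelineConfig, outdir: Path, state: dict) -> Path:
    G, samples = state["G"], state["samples"]
    win = cfg.window()
    groups = samples.groupby("group_id")["sample_id"].apply(list)
    outputs = []
    group_pi = {}
    for g in groups.index:
        track = windowed_pi(G, groups[g], win)
        outputs.append(_tsv(track.frame, outdir / f"pi.{g}.tsv"))
        group_pi[g] = float(np.nanmean(track.values))
        d_track = tajimas_d(G, groups[g], win)
        outputs.append(_tsv(d_track.frame, outdir / f"tajima_d.{g}.tsv"))
    fst_rows = []
    for i, g1 in enumerate(groups.index):
        for g2 in groups.index[i + 1:]:
            from .popgen import genomewide_wc_fst
            fst_rows.append({"group1": g1, "group2": g2,
                             "fst": genomewide_wc_fst(
                                 G, {g1: groups[g1], g2: groups[g2]})})
    fst_df = pd.DataFrame(fst_rows)
    outputs.append(_tsv(fst_df, outdir / "group_fst.tsv"))
    curve = ld_decay(G, max_dist=cfg.ld_max_dist, seed=cfg.stage_seed("stats"))
    ld_df = pd.DataFrame({"dist_bp": curve.bin_mid, "mean_r2": curve.mean_r2,
                          "n_pairs": curve.n_pairs})
    outputs.append(_tsv(ld_df, outdir / "ld_decay.tsv"))
    state.update(group_pi=group_pi, group_fst=fst_df, ld_curve=curve)
    counts = {"groups": len(groups),
              "mean_group_pi": group_pi,
              "mean_pairwise_group_fst": float(fst_df["fst"].mean()),
              "ld_decay_bp_at_r2_0.2": curve.decay_distance_at(0.2)}
    return _write_manifest(outdir, "stats", cfg, outputs, counts)


def _stage_structure(cfg: PipelineConfig, outdir: Path, state: dict) -> Path:
    G, samples = state["G"], state["samples"]
    k = cfg.k_latent or max(1, samples["group_id"].nunique() - 1)
    pca = structure.genotype_pca(G, k=min(k + 2, G.n_samples - 1))
    scores = pca.scores.copy()
    scores.insert(0, "group_id", samples.set_index("sample_id")["group_id"]
                  .loc[scores.index].to_numpy())
    outputs = [_tsv(scores, outdir / "pca_scores.tsv", index=True)]
    geo = structure.geographic_distance_km(samples)
    fst_lin = structure.fst_linearized(G, samples)
    ibd = structure.mantel_test(fst_lin, geo, n_perm=cfg.n_perm,
                                seed=cfg.stage_seed("structure"))
    outputs.append(_tsv(pd.DataFrame(geo.values, index=geo.labels,
                                     columns=geo.labels),
                        outdir / "geo_km.tsv", index=True))
    outputs.append(_tsv(pd.DataFrame(fst_lin.values, index=fst_lin.labels,
                                     columns=fst_lin.labels),
                        outdir / "fst_linearized.tsv", index=True))
    state.update(pca=pca, geo_dist=geo, fst_lin=fst_lin, ibd=ibd)
    counts = {"pca_explained": [round(float(x), 6) for x in pca.explained],
              "ibd_mantel_r": ibd.r, "ibd_mantel_p": ibd.p}
    return _write_manifest(outdir, "structure", cfg, outputs, counts)


def _stage_sweep(cfg: PipelineConfig, outdir: Path, state: dict) -> Path:
    G, samples, genes = state["G"], state["samples"], state["genes"]
    win = cfg.window()
    all_regions = []
    outputs = []
    for g in sorted(samples["group_id"].unique()):
        regions = sweep.sweep_scan(G, samples, g, window=win, q=cfg.sweep_q,
                                   genes=genes or None)
        all_regions.extend(regions)
    frame = regions_to_frame(all_regions)
    outputs.append(_tsv(frame, outdir / "sweep_regions.tsv"))
    if len(frame):
        bed = frame[["chrom", "start", "end"]].copy()
        bed["name"] = frame["focal_group"]
        bed["score"] = frame["n_windows"]
        write_bed(bed, outdir / "sweep_regions.bed")
        outputs.append(outdir / "sweep_regions.bed")
    state.update(sweep_regions=all_regions)
    counts = {"regions": len(all_regions),
              "candidate_genes": int(frame["genes"].str.len().gt(0).sum())
              if len(frame) else 0}
    return _write_manifest(outdir, "sweep", cfg, outputs, counts)


def _stage_gea(cfg: PipelineConfig, outdir: Path, state: dict) -> Path:
    G, samples, env = state["G"], state["samples"], state["env"]
    evspec = gea.prune_evs(env)
    k = cfg.k_latent or max(0, samples["group_id"].nunique() - 1)
    scan = gea.GEAScan(G, samples, env, evs=evspec, k=k)
    res = scan.fit(z_min=cfg.z_min, p_max=cfg.p_max)
    outputs = [outdir / "eal_records.tsv"]
    res.to_tsv(outputs[0])
    key_loci = res.key_eal_loci()

    # IBE contrast: adaptive (key EAL) vs neutral (LD-pruned non-outlier) variants
    ibe = {}
    env_d = structure.env_distance(env, evspec.names)
    seed = cfg.stage_seed("gea")
    if key_loci.size >= 5:
        fst_adapt = structure.fst_linearized(G.take_loci(key_loci), samples)
        ibe["adaptive"] = structure.mantel_test(fst_adapt, env_d,
                                                n_perm=cfg.n_perm, seed=seed)
    neutral_pool = np.setdiff1d(np.arange(G.n_loci), key_loci)
    G_neu = G.take_loci(neutral_pool)
    pruned = structure.ld_prune(G_neu)
    if pruned.size >= 5:
        fst_neu = structure.fst_linearized(G_neu.take_loci(pruned), samples)
        ibe["neutral"] = structure.mantel_test(fst_neu, env_d,
                                               n_perm=cfg.n_perm, seed=seed)
    state.update(gea_results=res, evspec=evspec, ibe=ibe)
    counts = {"evs": list(evspec.names),
              "lambda_gif": res.lambda_gif,
              "key_eal_loci": int(key_loci.size),
              "ibe": {k: {"r": v.r, "p": v.p} for k, v in ibe.items()}}
    return _write_manifest(outdir, "gea", cfg, outputs, counts)


def _stage_rda(cfg: PipelineConfig, outdir: Path, state: dict) -> Path:
    G, samples, env = state["G"], state["samples"], state["env"]
    res = state["gea_results"]
    evspec = state["evspec"]
    candidates = res.key_eal_loci()
    if candidates.size < 10:  # fall back to the strongest association tail
        best = (res.table.groupby("locus")["p_adj"].min()
                .sort_values().index[:50].to_numpy())
        candidates = np.sort(best)
    Gc = G.take_loci(candidates)
    pop_of = samples.set_index("sample_id")["population_id"]
    X = env.current.loc[pop_of.loc[Gc.samples], list(evspec.names)].to_numpy()
    Z = samples.set_index("sample_id").loc[Gc.samples, ["longitude", "latitude"]]
    model = rda.PartialRDA(Gc.dosage_float(), X, Z.to_numpy(),
                           locus_ids=list(candidates),
                           ev_names=list(evspec.names))
    fit = model.fit()
    outliers = fit.outliers(axes=cfg.rda_axes, cutoff_sd=cfg.rda_cutoff_sd)
    sig = fit.permutation_test(n_perm=max(99, cfg.n_perm // 5),
                               seed=cfg.stage_seed("rda"))
    outputs = [
        _tsv(fit.snp_loadings.reset_index(names="locus"),
             outdir / "rda_snp_loadings.tsv"),
        _tsv(outliers, outdir / "rda_outliers.tsv"),
        _tsv(sig, outdir / "rda_significance.tsv"),
        _tsv(pd.DataFrame([fit.variance_fractions]), outdir / "rda_variance.tsv"),
    ]
    lfmm_set = set(res.key_eal_loci())
    rda_set = set(outliers["locus"])
    state.update(rda_results=fit, rda_outliers=outliers)
    counts = {"candidate_loci": int(candidates.size),
              "rda_outliers": len(rda_set),
              "lfmm_intersection": len(lfmm_set & rda_set),
              "lfmm_union": len(lfmm_set | rda_set),
              "model_p": float(sig.loc[sig["term"] == "model", "p"].iloc[0])}
    return _write_manifest(outdir, "rda", cfg, outputs, counts)


def _stage_rona(cfg: PipelineConfig, outdir: Path, state: dict) -> Path:
    G, samples, env = state["G"], state["samples"], state["env"]
    res = state["gea_results"]
    freqs = rona.pop_allele_freqs(G, samples, min_inds=cfg.min_inds)
    future_evs = ([str(e) for e in env.future.columns.get_level_values("ev").unique()]
                  if not env.future.empty else [])
    loci_by_ev = {ev: res.loci_below(cfg.rona_p, ev=ev)
                  for ev in future_evs if ev in set(res.table["ev"])}
    loci_by_ev = {ev: loci for ev, loci in loci_by_ev.items() if loci.size}
    if not loci_by_ev:
        raise ValueError("no association hits for any future-projected EV")
    model = rona.RONAModel(freqs, env, loci_by_ev)
    fit = model.fit()
    agg = fit.aggregate()
    outputs = [outdir / "rona_cells.tsv", _tsv(agg, outdir / "rona_aggregated.tsv")]
    fit.to_tsv(outputs[0])
    state.update(rona_results=fit)
    counts = {"populations": int(fit.table["population"].nunique()),
              "evs": sorted(loci_by_ev),
              "mean_rona": {s: float(agg.loc[agg["scenario"] == s, "mean_rona"].mean())
                            for s in agg["scenario"].unique()}}
    return _write_manifest(outdir, "rona", cfg, outputs, counts)


# ---------------------------------------------------------------------------
# demo: fixture + full run + ground-truth scorecard
# ---------------------------------------------------------------------------

def rona_closed_form_check(n_pops: int = 12, shift: float = 3.0) -> float:
    """Max |RONA - |b|*delta_e| over populations on noiseless planted clines.

    Builds exact linear allele-frequency clines (R^2 = 1), applies a
    uniform future shift and compares the module output against the
    closed form.  Returns the maximum absolute error.
    """
    ev_vals = np.linspace(4.0, 15.0, n_pops)
    pops = [f"P{i + 1:02d}" for i in range(n_pops)]
    slopes = np.array([0.02, -0.015, 0.01])
    intercepts = np.array([0.1, 0.6, 0.3])
    freqs = pd.DataFrame(
        np.clip(intercepts[None, :] + slopes[None, :] * ev_vals[:, None], 0, 1),
        index=pops, columns=[0, 1, 2])
    current = pd.DataFrame({"EVX": ev_vals}, index=pd.Index(pops, name="population_id"))
    future = pd.DataFrame(
        {("EVX", "SSPX", "m1"): ev_vals + shift}, index=current.index)
    future.columns = pd.MultiIndex.from_tuples(future.columns,
                                               names=["ev", "scenario", "model"])
    env = EnvFrame(current=current, future=future)
    fit = rona.RONAModel(freqs, env, {"EVX": [0, 1, 2]}).fit()
    expected = float(np.mean(np.abs(slopes)) * shift)  # uniform weights: R^2=1
    got = fit.table.groupby("population")["rona"].mean()
    return float(np.max(np.abs(got - expected)))


def make_demo(outdir: str | Path, seed: int = 0,
              sim_config: SimConfig | None = None) -> dict:
    """Generate the default fixture, run the full pipeline and score it
    against the generator's ground truth."""
    outdir = Path(outdir)
    fixture_dir = outdir / "fixture"
    run_dir = outdir / "run"
    cfg_sim = sim_config or SimConfig(seed=seed)
    bundle = simulate_dataset(cfg_sim)
    files = write_fixture(bundle, fixture_dir, overwrite=True)
    cfg = PipelineConfig(
        vcf=str(files["vcf"]), samples=str(files["samples"]),
        env=str(files["env"]), gff=str(files["gff"]),
        outdir=str(run_dir), seed=seed,
        n_perm=499,
    )
    run_pipeline(cfg)

    # score against ground truth
    truth = bundle.truth
    G = read_vcf_filtered(files["vcf"], cfg.filters)
    records = pd.read_csv(run_dir / "eal_records.tsv", sep="\t")
    key = records[records["key_eal"]]
    key_pos = set(zip(key["chrom"], key["pos"].astype(int)))
    adaptive_pos = truth.adaptive_key()
    pass_pos = {(c, int(p)) for c, p in
                zip(G.loci["chrom"], G.loci["pos"])}
    adaptive_detectable = adaptive_pos & pass_pos
    eal_recall = (len(key_pos & adaptive_detectable) / len(adaptive_detectable)
                  if adaptive_detectable else float("nan"))
    eal_precision = (len(key_pos & adaptive_pos) / len(key_pos)
                     if key_pos else float("nan"))

    regions = pd.read_csv(run_dir / "sweep_regions.tsv", sep="\t")
    hit = 0
    for s in truth.sweeps:
        sub = regions[(regions["focal_group"] == s.group)
                      & (regions["chrom"] == s.chrom)
                      & (regions["start"] <= s.end)
                      & (regions["end"] >= s.start)]
        hit += int(len(sub) > 0)
    sweep_recall = hit / len(truth.sweeps) if truth.sweeps else float("nan")

    scorecard = {
        "sweep_recall": sweep_recall,
        "eal_recall": eal_recall,
        "eal_precision": eal_precision,
        "rona_closed_form_max_error": rona_closed_form_check(),
    }
    with open(outdir / "scorecard.json", "w") as fh:
        json.dump(scorecard, fh, indent=1, sort_keys=True)
    return {"fixture": {k: str(v) for k, v in files.items()},
            "run": str(run_dir), "scorecard": scorecard}
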