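# popadapt

Landscape genomics for structured plant populations: windowed diversity
and differentiation scans, selective-sweep detection, latent-factor
genotype–environment association (GEA), partial redundancy analysis
(RDA), isolation-by-distance/environment (IBD/IBE) tests, and
risk-of-non-adaptedness (RONA) projection of climate maladaptation —
with a seeded synthetic-cohort generator so every stage can be validated
against known ground truth.

The package is aimed at population geneticists analysing whole-genome
resequencing panels of wild populations sampled along environmental
gradients (the motivating system is a montane poplar cohort: 4
geographic groups, tens of populations, hundreds of individuals), and at
methodologists who want a fully scripted, reproducible reference
pipeline for these analyses.

## What it computes

**Windowed statistics.** Nucleotide diversity per sliding window
(default 100 kb windows, 1 kb steps),

&nbsp;&nbsp;π̂ = Σ_sites 2p̂q̂·m/(m−1) / L_window,

the Weir–Cockerham (1984) F_ST from variance components *a, b, c* with
windowed "weighted" form Σa / Σ(a+b+c), Tajima's D with
constants-from-scratch normalisation, and LD decay as mean dosage r²
per distance bin (≤ 500 kb).

**Sweep scan.** Windows strictly above the empirical 95th percentiles
of *both* F_ST (focal group vs rest) and the diversity ratio
θπ_ref/θπ_focal are merged into candidate sweep regions; genes
overlapping a region by ≥ 1 bp are its candidates.

**GEA scan** (`GEAScan(...).fit() -> GEAScanResults`). Per locus and
environmental variable (EV), least squares of dosage on
[1, EV, U₁..U_K] with K latent factors (top genotype PCs); z = β̂/SE;
genomic-inflation calibration λ = median(z²)/0.4549; key
environment-association loci (EALs) flagged at |z| ≥ 4 and adjusted
P ≤ 10⁻⁵. EVs are pre-pruned at |r| > 0.8.

**Partial RDA** (`PartialRDA(Y, X, Z).fit()`). Y (candidate-locus
dosages) and X (EVs) are residualized on the conditioning matrix Z
(longitude/latitude); constrained axes come from the SVD of the fitted
multivariate regression; loci loading outside mean ± 1.96 SD on axes
1–3 are outliers; significance by reduced-model permutation pseudo-F.

**RONA** (`RONAModel(...).fit()`). Per EV, allele frequencies of the
scan's hits (P < 10⁻³) are regressed on the current EV across
populations (≥ 7 individuals each); RONA_j is the R²-weighted mean
|required − current| frequency change under each scenario × climate
model (SSP126/SSP585, 2081–2100-style shifts), with across-model mean
± SE.

## Worked example

```bash
popadapt demo --seed 1 --outdir demo_out
```

simulates the default cohort (4 groups × 3 populations × 10
individuals, ~20 000 SNPs on two 1-Mb chromosomes, planted adaptive
clines, sweeps and future-climate shifts), writes the fixture
(VCF + samples.tsv + env.tsv + genes.gff3 + truth.json), runs every
stage into `demo_out/run/`, and prints the ground-truth scorecard:

```json
{
 "eal_precision": 0.5652173913043478,
 "eal_recall": 0.52,
 "rona_closed_form_max_error": 3.469446951953614e-17,
 "sweep_recall": 1.0
}
```

All four planted sweep regions are recovered by the joint top-5% scan
(`sweep_recall = 1.0`), and RONA on noiseless clines matches the
closed form |b|·Δe to machine precision. EAL recall on this cohort is
partial (0.52) because the demo deliberately keeps nested
within-group population structure that K = 3 latent factors cannot
fully absorb (the run's manifest reports the resulting genomic
inflation, λ ≈ 2.2); on a cohort whose structure matches K the scan
recovers ≥ 90% of planted clines at a false-positive rate below 10⁻³
(see `docs/methods.md` and the validation suite).

Stage outputs are TSVs: `pi.<group>.tsv`, `tajima_d.<group>.tsv`,
`group_fst.tsv`, `ld_decay.tsv`, `pca_scores.tsv`, `sweep_regions.tsv`
(+ BED), `eal_records.tsv`, `rda_*.tsv`, `rona_*.tsv`, each with a JSON
manifest carrying input hashes, the stage seed and headline counts.

The same pipeline runs on real data from a YAML config:

```bash
popadapt run-all --config pipeline.yaml --seed 1
```

with `vcf`, `samples`, `env`, `gff` paths and thresholds as keys
(see `popadapt.pipeline.PipelineConfig`).

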