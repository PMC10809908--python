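# Methods

This note documents the statistical models, the synthetic cohort the
validation suite runs on, and the numerical and design choices made
where more than one defensible option existed.

## Synthetic cohort

The generator emulates a resequenced wild tree cohort sampled across
China-scale environmental gradients. Default configuration: 4
geographic groups (NW/SW/TH/NC-style centres), 3 populations per group,
10 diploids per population (120 individuals; the real cohorts this
emulates run ~3–4× larger), two 1-Mb chromosomes carrying ~20 000
biallelic SNPs, 2% missing genotypes.

**Allele frequencies.** Each locus draws an ancestral frequency
(default U(0.1, 0.9), emulating a MAF-filtered panel; a `neutral`
option draws from the 1/p standing-variation spectrum for tests that
need a neutral site-frequency shape). Group frequencies follow
Balding–Nichols Beta(p(1−F_b)/F_b, q(1−F_b)/F_b) with F_b = 0.25;
population frequencies drift again within groups with F_w = 0.03.
The realized group-level Weir–Cockerham F_ST of the default cohort is
~0.30: the nested drift layers compose roughly as
F_b + (1−F_b)(F_w + 1/H) with H the haplotype-pool size below, which
keeps the cohort inside the moderate-to-high differentiation regime
(0.14–0.39) the pipeline targets. With the nuisance layers minimised,
the realized group F_ST matches F_b, which the test suite checks.

**LD.** Within each population, loci in the same physical block
(default 5 kb) are copied from a finite pool of H = 24 haplotypes whose
alleles are Bernoulli draws at the population frequencies; blocks
recombine freely. This produces distance-limited LD and an extra
1/H drift layer; it does not reproduce realistic recombination maps or
long-range LD decay shapes.

**Adaptive loci.** A planted adaptive locus has population frequency
logistic(a + b·z_EV) with z_EV the z-scored environmental variable,
perturbed by Balding–Nichols drift at F_w and segregating independently
of the LD blocks. The default slope is |b| = 3 per EV standard
deviation, i.e. near-complete clinal turnover (frequency span ≈ 0.95
across the sampled range) — the behaviour of strongly selected loci,
which in real cohorts show alternative alleles essentially fixed at
the opposite ends of the gradient.

**Sweeps.** A planted sweep re-draws the focal group's frequencies in
the swept span with boosted divergence (2.5 × F_b) and moves them
toward the nearest boundary so heterozygosity scales by the reduction
factor (default 0.1), and collapses the haplotype pool by the same
factor. This mimics the differentiation + diversity-loss signature of a
hard sweep without simulating hitchhiking dynamics.

**Environment.** Nine EVs (Bio1, Bio2, Bio3, Bio13, Bio19, Srad6,
Srad12, Vapr6, altitude) are linear functions of latitude, longitude
and altitude plus noise, so they are mutually correlated through shared
geography (exercising the |r| > 0.8 pruning) and carry both between-
and within-group variation. Future values exist for the five
temperature/precipitation EVs under two scenarios (SSP126: +0.6 SD,
SSP585: +1.5 SD by default) × three climate models, with a
latitude-dependent gradient and per-model jitter, emulating 2081–2100
projections.

**What passing tests do and do not show.** The generator produces
HWE-within-population genotypes, free recombination between blocks,
exact logistic clines and linear EV geography. Passing recovery tests
therefore demonstrates correctness and calibration of the estimators
under the model's assumptions; they do not demonstrate robustness to
demographic model misspecification, background selection, genotyping
error structure, or EV measurement error.

## Estimators and conventions

* **π**: per-site 2p̂q̂·m/(m−1) on called alleles, summed per window and
  divided by the physical window length (the convention of the standard
  VCF windowing tools); division by the number of genotyped sites is
  available behind `denominator="callable"`. Windows are emitted on a
  full grid with NaN where undefined, never dropped.
* **F_ST**: Weir–Cockerham (1984) variance components from genotype
  counts including observed heterozygosity; windowed statistic is the
  "weighted" Σa/Σ(a+b+c) (the mean of per-site ratios is exported
  alongside). Negative estimates are retained per site; pairwise
  population F_ST is floored at 0 before the x/(1−x) linearisation.
* **Tajima's D**: count-scale θπ against θ_W = S/a₁ with constants
  computed at the modal per-site called-allele count of the window;
  sites with other call counts contribute their own per-site pairwise
  terms. This is an explicit approximation to the fixed-n assumption of
  the classical estimator; it is exact when missingness is uniform.
* **LD r²**: squared Pearson correlation of unphased dosages
  (composite LD) over jointly called samples; pairs with < 3 such
  samples are skipped; pair count capped (seeded subsample) for large
  panels. The decay distance is read off a pool-adjacent-violators
  monotone fit of the binned curve.
* **PCA**: Patterson/GCTA scaling (mean-imputed, centred by 2p̂, scaled
  by √(2p̂q̂)), eigendecomposition of the sample kernel, deterministic
  sign (largest-|loading| locus positive).
* **Mantel**: one-sided (positive association) permutation p
  (1+#{r* ≥ r})/(n_perm+1), joint row/column permutation. A
  content-based canonical orientation decides which matrix is permuted,
  making the test exactly symmetric in its arguments for a fixed seed.
* **GEA**: the latent-factor scan is the two-stage scheme (genotype PCs
  as fixed latent factors, per-locus OLS, genomic-inflation
  recalibration of z²), the standard fast approximation to the ridge
  latent-factor mixed model; decision thresholds are |z| ≥ 4 with
  adjusted P ≤ 10⁻⁵, Benjamini–Hochberg q within each EV, no cross-EV
  correction. λ is computed per EV; the scan-level λ reported is the
  median across EVs. The Bayesian F_ST-outlier prescreen used upstream
  in some studies is replaced by an empirical top-quantile per-site
  F_ST prescreen; the default is a genome-wide scan.
* **Partial RDA**: Y and X residualized on [1, Z] by least squares;
  axes from the SVD of the fitted values; SNP loadings are
  covariance-type species scores (proportional to the covariance of
  each locus with the unit axis), biplot scores are correlations of the
  residualized EVs with the axes. Outliers at mean ± 1.959964 SD of the
  per-axis loading distribution (a ±3 SD option exists; the literature
  uses both). Predictors annihilated by the conditioning variables are
  zeroed rather than rescaled from rounding noise, so an EV inside
  span(lon, lat) contributes exactly no constrained variance.
  Permutation significance re-residualizes the permuted response on the
  conditioning matrix (the reduced-model scheme); without that step the
  null F is deflated and the test anti-conservative, which the
  calibration suite would catch.
* **RONA**: per-locus OLS of population frequency on the current EV;
  required future frequency clamped to [0, 1]; distance to the
  *observed* current frequency by default (a `fitted` baseline is
  available and makes RONA exactly 0 under a zero climate shift);
  R²-weighted mean across loci (unweighted optional); mean ± sd/√m
  across the m climate models per scenario. Populations need ≥ 7
  individuals (the "more than six" retention rule) and each EV uses the
  scan's hits at adjusted P < 10⁻³ for that EV.

## Validation design

Estimator correctness is established against independent oracles:
a scalar clean-room Weir–Cockerham implementation, brute-force
enumeration of allele pairs for π, constants-from-scratch Tajima's D
(including a window constructed so θπ = S/a₁ exactly, where D must be
identically zero), the textbook OLS t for the K = 0 scan, and the
closed-form RONA = |b|·Δe on noiseless clines.

Calibration and power use a dedicated validation cohort
(`gea_validation_config`): 120 individuals in 4 groups × 6 populations
× 5, with within-group drift set near zero (F_w = 10⁻³, haplotype pool
1000) so that the latent structure has exactly the dimension the K = 3
factors presume. In that regime the null scan is calibrated
(λ ≈ 1, ≲ 5 key EALs among 45 000 tests) and planted |b| = 3 clines
are recovered with ≥ 90% recall at a neutral false-positive rate below
10⁻³. Under the default nested cohort (12 populations, F_w = 0.03,
pool 24) the same K = 3 scan is residually confounded — λ ≈ 2.2 and
partial recall — which is the expected behaviour of latent-factor
methods when K understates the structure; the demo reports this
honestly in its scorecard rather than tuning the cohort to hide it.

Permutation tests (Mantel, RDA model F) are checked for null
uniformity with Kolmogorov–Smirnov tests over 500 replicate datasets.

## Pipeline mechanics

One master seed feeds named per-stage substreams
(`SeedSequence(master, spawn_key=(crc32(stage),))`), so adding a stage
never perturbs earlier stages' draws and reruns are byte-identical
(verified file-by-file in the suite; the one file excluded from the
comparison is `run_config.yaml`, which records absolute input paths).
Each stage writes TSV outputs plus a JSON manifest with a
parameters-only config hash, the stage seed, output SHA-256 digests and
headline counts; the manifests form an auditable chain but stages are
recomputed in memory on every run rather than resumed from cache. The
`--threads` CLI flag is accepted for interface compatibility and does
not affect results (all computation is single-threaded BLAS/numpy).

## Known limitations

* The latent-factor scan estimates factors from the same genotype
  matrix it scans; with very few loci the factors can absorb real
  signal.
* Tajima's D under heavily non-uniform missingness deviates from the
  fixed-n estimator (documented approximation above).
* The block-copy LD model cannot generate realistic decay-curve shapes
  beyond "high within a block, background between blocks".
* RONA inherits the linearity assumption of the frequency–EV
  regressions; clamping makes projections conservative near fixation.
* Per-axis RDA permutation tests use the sequential scheme; marginal
  axis tests conditioned on all other axes are not implemented.
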