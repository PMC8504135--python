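# Methods

`atrcn` implements an adaptive transfer-learning pipeline for survival
prediction from gene expression: candidate cohorts are summarized by 22
descriptors, clustered to find the cohorts most similar to a target, a
deep Cox proportional-hazards network is pre-trained on the selected
cohorts and fine-tuned on the target, and the result is evaluated with
Harrell's concordance index and log-rank risk stratification.  This note
records the model, the defaults, the numerical choices, and what the
synthetic studies do and do not demonstrate.

## The model

Under proportional hazards the conditional hazard of patient `i` with
expression profile `x_i` is

    λ(t | x_i) = λ0(t) · exp(h(x_i))

where `h` is the log relative hazard.  `h` is parameterized as a fully
connected relu network with hidden widths `[50, 20, 10]` mapping the
(z-scaled) gene expression vector to a scalar; with an empty hidden stack
it degenerates to the classical linear Cox model `h(x) = w·x`.  Training
minimizes the negative log partial likelihood

    l(θ) = − Σ_{i : E_i = 1} [ h(x_i) − log Σ_{j : T_j ≥ T_i} exp(h(x_j)) ]

with Breslow handling of tied times (every sample with `T_j ≥ T_i` stays
in the risk set, ties included).  The partial likelihood couples samples
through risk sets, so optimization is full-batch; gradients are computed
analytically and the log-sum-exp is stabilized by subtracting the global
score maximum (the loss is invariant to a constant shift of all scores,
so this is exact).  The optimizer is Adam (β₁ = 0.9, β₂ = 0.999); the
learning rate is chosen from {1e-3, 1e-4, 1e-5} by event-stratified
10-fold cross-validation on the target cohort, ties broken toward the
larger rate.  Weights start from a seeded Glorot-uniform draw, biases at
zero; optional L2 weight decay defaults to off.  The network is written
directly in numpy — forward, backward and the Adam step are a few dense
matrix products — which keeps the exact full-batch loss and makes the
gradients directly checkable against central finite differences (the
test suite verifies agreement to 1e-5).

A divergent configuration (non-finite loss) aborts training with a
diagnostic; during hyperparameter search it simply scores the candidate
as worst rather than failing the search.

## Cohort descriptors

Each cohort is summarized by 12 phenotype and 10 genotype features.

Phenotype: Kaplan–Meier survival probability at 3 and 5 years (Y3, Y5);
mean and SD of observed times (SAVE, STD); quartiles T1–T3 (linear
interpolation between order statistics) and maximum T4; and the fractions
S1–S4 of patients whose observed time falls in the four equal
subdivisions of (0, T4].  The intervals are half-open (lo, hi]; survival
times are strictly positive, so the four intervals partition the cohort
and times {1, 2, 3, 4} give S1 = S2 = S3 = S4 = 0.25.  SAVE, STD and the
quartiles are computed over *all* patients, censored included — excluding
censored patients would be inconsistent with S1–S4, which count everyone.
Y3/Y5 default to the Kaplan–Meier estimator (the naive
fraction-surviving-past-the-horizon reading is available via
`survival_rate_estimator="naive"`); horizons beyond the last observed
time are clamped to it.

Genotype: the expression matrix is compressed to two kernel-PCA
components (rbf kernel, γ = 1/n_genes, fitted per cohort over its
samples), and each component is summarized by mean, median, SD (n−1
denominator), excess kurtosis and skewness (plain moment estimators).
The sign of each component is fixed so its largest-magnitude coordinate
is positive, making descriptors reproducible; a constant component
reports SD = KURT = SKEW = 0 with a warning.

Descriptor vectors of all candidate cohorts are stacked and each feature
column z-scored across cohorts; constant columns map to zeros.

## Cohort selection

k-means (10 restarts, seeded) clusters cohorts on the normalized
descriptors; candidate k ranges over the integers in [⌈N/4⌉, ⌊3N/4⌋]
(raised to a minimum of 2), and the clustering with the largest mean
silhouette coefficient (Euclidean, matching the k-means metric) wins,
ties toward smaller k — fewer clusters mean larger pre-training sets.
The target's cluster mates form the pre-training set; a singleton target
falls back to the nearest other cluster by centroid distance, with a
warning, rather than failing on small studies.  `rank_clusters_by_distance`
orders all clusters by centroid distance from the target's, supporting
similarity-ordered ablations.

## Transfer

Pre-training pools the selected source cohorts with *cohort-stratified*
risk sets: the loss is the sum of per-cohort partial likelihoods, so
survival times are never compared across cohorts whose baseline hazards
differ.  Defaults: 200 pre-training epochs, 500 fine-tuning epochs, all
layers fine-tuned (`freeze_layers` supports freezing leading hidden
layers).  Gene features are z-scaled per gene with statistics fitted on
the pooled pre-training cohorts and reused unchanged for the target and
any external cohort.  The candidate filter (uncensored count > 50 and
sample size > 100, both strict) applies to source cohorts only.

## Evaluation

Harrell's C counts every ordered pair in which the patient with the
shorter time had an event (pairs tied in time are permissible only when
exactly one of the two had the event); tied predicted risks contribute
0.5.  Patients are stratified at the median predicted risk — scores
strictly above the median are high-risk, scores at the median go to the
low-risk group so the high-risk group is never empty — and group
separation is tested with the two-group log-rank statistic (1 df).
Clinical covariates are tested against the risk groups with Pearson
chi-square on the 2×L contingency table; continuous covariates are first
binned into quartile intervals, and raw p-values are reported without
multiple-testing correction.  Cross-validated concordance is reported as
mean ± fold SD.

## Synthetic studies

The generator realizes the hazard model generatively.  Per cohort:
latent factors `Z ~ N(0, I)` (n_samples × latent_rank), expression
`X = Z·L + σ·ε` shifted to be non-negative so the `log2(v+1)`
preprocessing step is exercisable, true risk `h* = Z·β`, survival times
exponential with rate `λ0·exp(h*)`, censoring times uniform on (0, c)
with `c` calibrated by bisection to the requested censoring fraction
(tolerance floors at 2/n, the resolution of a realized fraction).

Cohorts belong to families.  The latent-to-gene loadings `L` are shared
across families — co-expression structure is conserved biology — while
families differ in the risk direction `β`, the baseline rate (×
`family_shift` per family) and the expression scale (× `√family_shift`
per family, independently controllable via `expression_scale_shift`).
The scale shift makes family membership visible to the genotype half of
the descriptor; the shared loadings make off-family supervision
genuinely conflicting for transfer rather than merely irrelevant.
Same-family cohorts share parameters up to a small jitter (default
0.05).  Defaults emulate a hepatocellular-like cohort: 370 patients,
censoring rate 0.655 (roughly a third uncensored), times in months with
λ0 = 0.02 per month, 200 genes with rank-5 latent structure.  The gene
count is deliberately compact; the latent structure, not the ambient
dimension, drives every pipeline stage.

What the generator does *not* emulate: negative-binomial count noise,
library-size effects, batch effects, or non-proportional hazards.
Passing tests therefore demonstrate that the pipeline's statistics and
learning behave correctly under its own model assumptions, not that the
defaults match any particular real cohort.

## Benchmark studies used by the tests and the acceptance script

* **Family recovery** — 50 studies of 8 cohorts in 2 families (120
  samples, 80 genes, 30% censoring, family shift 3); the descriptor +
  silhouette-k-means pipeline should recover the planted partition
  (adjusted Rand = 1) in ≥ 90% of runs.
* **Transfer benchmark** — three arms sharing seeds per replicate:
  *adaptive* (pre-train on the 2 same-family sources), *all-cohort*
  (pre-train on all 8 sources, 6 of which belong to a family with
  inverted risk direction β_off = −β_target), and *no-transfer* (train on
  the target alone).  The target is deliberately event-poor (n = 50, 75%
  censoring — the heavy-censoring regime of liver cohorts), sources are
  event-rich (n = 250, 30% censoring), and all arms are scored on an
  independent same-family cohort (n = 400), playing the role of external
  validation data.  Latent rank is 15 so that a handful of target events
  cannot by themselves pin down the risk direction.  Adaptive transfer
  should beat both ablations by at least two standard errors of the
  paired difference over 20 replicates.
* **Calibration** — under simulated nulls (exchangeable groups), log-rank
  and chi-square p-values should be uniform (KS test not rejected at 1%).
* **Analytic anchors** — random scores give C = 0.5 ± 0.02; the loss and
  C-index match naive brute-force enumerations; the loss gradient matches
  central finite differences; the linear model recovers the generating
  coefficient direction (cosine ≥ 0.95 at n = 2000, p = 5).

Problem sizes in these studies are chosen so the full suite runs in a
few minutes on one CPU; they are desk-scale stand-ins for the
pan-cancer datasets the pipeline is designed for.

## Known limitations

* Exponential baseline hazard only (constant λ0); Weibull shapes and
  time-varying baselines are out of scope of the generator.
* Breslow ties only; Efron's correction is not implemented.
* The learning-rate grid is shared between pre-training and fine-tuning;
  per-phase grids would require nested cross-validation.
* Whether the descriptor KPCA should be fitted per cohort or on pooled
  samples is an open modelling choice; per-cohort fitting is used, since
  descriptors are per-cohort summaries.
* No batch-effect correction: cohorts are assumed internally consistent,
  and cross-cohort comparability is addressed only through per-gene
  scaling and cohort-stratified risk sets.
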