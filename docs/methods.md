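# Methods

This note documents the models implemented in `envage`, their assumptions,
the defaults that matter, and the design decisions taken where the
methodology leaves the operational details open.

## PhenoAge

PhenoAge maps a linear predictor of 10-year all-cause mortality onto an age
scale through a Gompertz proportional-hazards model. The linear predictor is

```
xb = −19.907 − 0.0336·albumin + 0.0095·creatinine + 0.1953·glucose
     + 0.0954·ln(CRP) − 0.012·lymphocyte% + 0.0268·MCV + 0.3306·RDW
     + 0.00188·ALP + 0.0554·WBC + 0.0804·age
```

with units g/L (albumin), µmol/L (creatinine), mmol/L (glucose), mg/L (CRP,
entering as its natural log), %, fL, %, U/L, 10⁹/L and years. The 10-year
(120-month) risk is `risk = 1 − exp(−e^xb·(e^{120γ}−1)/γ)` with γ = 0.0076927,
and `PhenoAge = 141.50225 + ln(−0.00553·ln(1−risk))/0.090165`.

Numerical notes. The three published equations compose to an *affine*
function of xb, `PhenoAge = 141.50225 + (xb + ln(0.00553·(e^{120γ}−1)/γ))/0.090165`,
so `compute_phenoage` evaluates through log-survival and never saturates;
`phenoage_from_risk` additionally accepts the survival complement `1 − risk`
because risks within ~1e−17 of 1 are not representable in float64. Units are
validated as broad plausibility ranges that warn rather than fail (the
source convention is assumed but cannot be enforced from numbers alone).

## Frailty phenotype

The Fried score counts the present criteria among unintentional weight
loss, exhaustion, weakness, slow gait and low physical activity (0–5). The
rule is complete-case: any missing component makes the score missing.
Deriving the five binary components from raw questionnaire items is a
cohort-specific step outside this package's scope; the synthetic generator
emits already-binarized components with age-increasing prevalence.

## Outcome standardization

Brain volumes and similar continuous outcomes are z-scored with the n−1
divisor. Cognitive scores pass a normality screen first — |sample skewness|
> 1 triggers a rank-based inverse normal transform (Blom offset 3/8) before
z-scoring. The skewness cut-off is this package's concrete operationalization
of "normalize if not normally distributed"; it is rank-preserving either way.

## Exposure preparation

- **Quantile scores**: q = 4 (quartiles) by default — the conventional
  choice of WQS software; q is configurable and results can be
  quantile-count sensitive. Cut points are the q−1 interior empirical
  quantiles with type-7 (linear-interpolation) quantiles, so boundaries are
  bit-for-bit reproducible; intervals are right-closed (boundary values fall
  into the lower bin) and out-of-range values clamp to the end bins.
  Boundaries are always fit on the training split and reused on validation
  data — never refit.
- **Protective reversal**: green- and blue-space scores are flipped
  (s → q−1−s) so larger scores always mean a less favourable environment
  and all index components share one direction.
- **IQR scaling** divides by Q3 − Q1 (type-7) so single-exposure slopes
  read "per IQR increase".
- **Noise aggregation**: the Lden-style 24-h level is the energy average
  with +5 dB evening and +10 dB night penalties,
  `10·log10((h_d·10^{L_d/10} + h_e·10^{(L_e+5)/10} + h_n·10^{(L_n+10)/10})/24)`,
  defaulting to 12/4/8-hour spans (day 07–19, evening 19–23, night 23–07,
  matching the 23:00–07:00 night window).

## Weighted quantile sum regression

Model: `y = β₀ + β₁·Σⱼ wⱼ qⱼ + γᵀc + ε`, with w on the simplex and the sign
of β₁ fixed by the model direction (a positive and a negative model are fit
separately when both directions are requested). Defaults follow the
standard protocol: 40% training / 60% validation split, 500 bootstrap
resamples of the training set (tests and demos scale this down), final
weights the arithmetic mean of converged bootstrap solutions renormalized
to the simplex, and validation-set OLS of the outcome on the resulting
index plus covariates for inference (normal-theory 95% CI β ± 1.96·SE,
two-sided t-test p).

Solver. For fixed weights the optimal linear coefficients are closed-form,
so covariates are residualized from y and the score matrix once per
bootstrap sample (Frisch–Waugh) and the profiled residual sum of squares is
minimized over softmax-reparameterized weights by L-BFGS from multiple
starts: the uniform vector, one near-vertex start per exposure, and 5
random starts. Exact vertices and the uniform vector are also evaluated
directly (they are feasible limits of the softmax), and the lowest RSS
wins. The sign constraint binds at the boundary β₁ = 0. A bootstrap counts
as converged when a successful optimizer run attains the returned optimum;
non-converged bootstraps are excluded from averaging and counted.
Bootstraps with near-zero |β₁| still contribute weights; significance-
weighted averaging variants are out of scope. The solver is validated
against an exhaustive 0.05-resolution simplex grid search on 3-exposure
problems (SSE within 1e−6).

Under a null outcome the validation index is independent of the validation
outcome by construction (weights depend only on exposures and training
outcomes), so the validation test is exactly sized; the test suite checks
the ~5% rejection rate over 500 seeded replicates, a count chosen to keep
the binomial Monte-Carlo error of the estimated rate (~1 percentage point
SD) well inside the 3-point tolerance.

## SOM subpopulations

A rows×cols self-organizing map (default 10×10 — the grid, epochs and
two-stage design are not prescribed by the methodology and are documented
choices) is batch-trained on column-wise z-scored exposures: codebook
initialized from a seeded random sample of the data, 20 epochs, Gaussian
neighborhood with radius decaying linearly from max(grid)/2 to 0.5,
Euclidean distances, BMU ties resolved to the lowest unit index.
Quantization error is tracked per epoch.

Cluster count. Occupied codebook units are grouped by Ward hierarchical
clustering (empty units carry zero weight and are excluded; occupancy
enters through the evaluation on participants). Each candidate k induces a
participant partition via the BMU map; its WSS(k) and BSS(k) are computed
on the participants and satisfy WSS + BSS = TSS (checked at 1e−8). Because
`fcluster` cuts of one Ward tree are nested, WSS(k) is non-increasing. The
selected k maximizes the second difference (curvature) of **log** WSS/TSS
over interior candidates: on curves whose early drops shrink geometrically,
the raw-ratio curvature peaks one or two steps before the true flattening
point, while the log curvature is scale-invariant and lands on it (this was
decisive on the default generator, where the raw rule picked k = 3 on some
seeds despite a clean 5-cluster structure).

Naming. Per cluster, mean standardized exposures are averaged within the
four families (air pollution, green space, blue space, noise) and centered
at the across-cluster median of each family before the largest-magnitude
family names the cluster; all centered magnitudes below 0.25 names it the
rural–urban fringe (moderate-everything) group. The median centering makes
naming robust to heavy-tailed marginals — a single extreme cluster (blue
space %) otherwise drags the grand mean and mislabels the moderate group.
With fewer than three clusters raw means are used (a median profile is not
meaningful). Duplicate names get numeric suffixes. Aging metrics are
contrasted against the green-space group (the most favourable profile;
configurable) by dummy-coded covariate-adjusted OLS.

## Association testing

OLS with dummy-coded categorical covariates (alphabetically first level as
reference), complete-case per model with dropped-row counts logged, CI
convention β ± 1.96·SE. The default covariate set is age, sex, ethnicity,
nSES, smoking, BMI category, alcohol, exercise, diet, CVD and cancer
history. P-values are adjusted within configurable analysis families by the
Benjamini–Hochberg step-up procedure at FDR 0.05 (BH controls the false
discovery rate — not, despite a common conflation, the family-wise error
rate); the family size m is whatever the run actually fits and is reported,
never hard-coded. Sensitivity variants: per-stratum scans (sex, age ≥ 60,
smoking, alcohol; the stratifying covariate is dropped from the model),
a ≥ 5-year residence filter, and an individual-SES swap.

Individual SES is built by latent class analysis of categorical income,
education and employment indicators: an EM algorithm for a multinomial
mixture (responsibilities in the E-step; mixing proportions and
item-response probabilities with a 1e−10 smoothing floor in the M-step),
best of 5 random starts, a guard raising on any log-likelihood decrease.
Classes are ordered by expected income rank and labelled high/medium/low
for k = 3.

## Synthetic cohorts

The generator emulates the *stated* structure of the restricted study data;
its defaults are the study's printed values wherever one exists.

- **Copula mode**: rank-correlation targets are mapped to Gaussian-copula
  correlations by r = 2·sin(π·ρs/6); a nearest-PSD repair (eigenvalue
  clipping) is applied with a warning if a user matrix needs it; marginals
  are strictly monotone transforms, so empirical Spearman correlations
  converge to the targets. Stated targets: green buffers 0.813, blue
  buffers 0.629, green–blue 1000 m 0.18, pollutant block 0.70 with the
  coarse fraction at 0.35 (it is excluded from the reported strong block).
  Unstated entries are interpolated at 0.20 and the noise pair set to 0.75
  — flagged as package choices, not study facts. Pairs with a unit target
  are made exactly comonotone.
- **Marginals** (package choices; no marginal distributions are published):
  pollutants log-normal (medians 16, 10, 6.2, 26, 42 µg/m³; log-SDs
  0.10–0.40), green/blue space logit-normal on [0, 100]% (green ~45–50%,
  blue ~1–1.5% typical), noise truncated-normal on [30, 90] dB (means 55
  and 47 dB).
- **Ages** are truncated-normal on the cohort window [40, 70] with parent
  parameters solved so the realized mean and SD equal the imaging-subcohort
  profile (55.46, 7.37 years).
- **Biomarkers**: plausible adult reference marginals with mild age trends
  chosen so that derived PhenoAge is finite, physiologically ranged, and
  strongly age-correlated (r ≈ 0.88 at defaults; the empirical benchmark is
  r = 0.85).
- **Archetype mode**: five exposure patterns (air pollution, green space,
  rural–urban fringe, noise, blue space) as an isotropic Gaussian mixture in
  standardized exposure space (scatter SD 0.5, proportions
  0.18/0.22/0.34/0.12/0.14 with the fringe largest), pushed through the same
  monotone marginal transforms.
- **Planted outcomes**: `y = β·Σwⱼqⱼ + γᵀc + ε` on the direction-aligned
  quantile scores with an air-pollution-heavy default weight profile;
  PhenoAge additionally carries a planted exposure acceleration of 0.8
  years per index unit on top of its biomarker composition. True archetype
  labels, per-outcome true indices and the latent SES class are kept in
  `truth_`-prefixed columns that `read_cohort` strips by default.

What the generator does **not** emulate: spatial autocorrelation and
geography, exposure measurement error, missing data (beyond none),
selection into the imaging subsample, real marginal shapes, and any
nonlinearity or interaction in exposure effects. Tests passing on these
cohorts therefore demonstrate internal correctness (planted-truth recovery,
calibration, type-I control) — not that the pipeline's estimates on real
data would be unbiased under confounding structures the generator lacks.

## Problem sizes and reproducibility

Default desk-scale sizes: cohorts of 5000–20000 participants, 100 or fewer
bootstraps in tests (500 is the analysis default), 10×10 SOM, candidate
k ∈ [2, 8]. All randomness flows from integer seeds through
`numpy.random.default_rng`; the pipeline derives per-stage child seeds
(< 2³¹) from one global seed and records them, with output checksums, in a
run manifest. Identical configuration and seed reproduce every output
byte-for-byte.

## Known limitations

- The WQS validation CI is normal-theory from a single split; repeated
  holdout or bootstrap CIs are not implemented.
- The SOM uses a rectangular Euclidean topology only.
- `describe_cohort` compares exactly two groups (Mann–Whitney U /
  chi-squared), mirroring the two-group descriptive tables it reproduces.
- Brain age is a pass-through input column; the gradient-boosting model
  that would produce it from imaging features is out of scope.
- The LCA assumes conditional independence of indicators given class, and
  its class labels are identified only through the income ordering.
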