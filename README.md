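# envage

Multiplexed environmental exposures and multidimensional aging metrics: a
reusable analysis pipeline for estimating how correlated residential
exposures — air pollutants (PM10, PM2.5, PM2.5–10, NO2, NOx), green and blue
space, and road-traffic noise — jointly and individually relate to aging
outcomes such as phenotypic age (PhenoAge), the Fried frailty phenotype,
brain volumes and brain age.

It is written for epidemiologists and biostatisticians who face the two
standard problems of exposure-mixture studies: the exposures are strongly
collinear (so single-pollutant regressions are confounded by co-exposures),
and joint exposure *patterns* matter (so populations should be segmented,
not just adjusted). The package provides:

- **Weighted quantile sum (WQS) regression** — the mixture is summarized as
  one index `WQS = Σⱼ wⱼ qⱼ` over quantile-scored exposures with weights on
  the simplex (wⱼ ≥ 0, Σwⱼ = 1). The sample splits 40/60 into training and
  validation; weights are estimated on bootstrap resamples of the training
  set under a direction constraint on the index coefficient and averaged;
  the validation set tests the index by covariate-adjusted OLS. Protective
  exposures (green/blue space) are reversed so every component shares one
  direction.
- **SOM subpopulation discovery** — a self-organizing map trained on
  z-scored exposures, Ward clustering of the codebook, number of groups
  chosen from within/between sum of squares (WSS/BSS), clusters named by
  their dominant exposure family, and aging metrics contrasted against the
  green-space group by adjusted OLS.
- **Aging metrics** — PhenoAge from the published nine-biomarker Gompertz
  mortality model
  (`PhenoAge = 141.50225 + ln(−0.00553·ln(1−risk))/0.090165` with
  `risk = 1 − exp(−e^xb(e^{120γ}−1)/γ)`, γ = 0.0076927), the Fried frailty
  count (0–5), and z-scoring / rank-inverse-normal standardization of
  continuous outcomes.
- **Association testing** — covariate-adjusted linear models per IQR of
  exposure, Benjamini–Hochberg FDR within analysis families, stratified and
  residence-duration sensitivity analyses, a 3-class latent class analysis
  building an individual SES variable, and descriptive group comparisons.
- **Synthetic cohorts** — the study data this design mirrors (UK Biobank)
  is access-restricted, so a seeded generator reproduces its stated
  structure: a Gaussian copula hits the reported exposure rank correlations
  (green buffers ρs = 0.813, blue 0.629, green–blue 0.18, a strongly
  correlated pollutant block), ages match the imaging subcohort (mean 55.46,
  SD 7.37 years), five exposure archetypes are planted as a mixture, and
  outcomes carry known ("planted") mixture weights and effects so every
  stage can be tested against ground truth.

## Worked example

```python
from envage import GeneratorConfig, generate_cohort, run_wqs, WQSConfig
from envage.synthetic_cohort import EXPOSURES, PROTECTIVE
from envage import som

cohort = generate_cohort(GeneratorConfig(n=5000, seed=1))
res = run_wqs(cohort, "brain_age_gap", list(EXPOSURES),
              covariates=["age", "sex", "smoking"],
              config=WQSConfig(n_boot=50, seed=1), reverse=list(PROTECTIVE))
print(res.weight_table.sort_values(ascending=False).round(3).head(5))
print(f"index effect: beta = {res.beta:.3f} "
      f"(95% CI {res.ci[0]:.3f}, {res.ci[1]:.3f}; p = {res.p_value:.2e})")
```

```
pm2_5         0.291
pm10          0.221
no2           0.153
blue_300m     0.071
green_300m    0.056
Name: weight, dtype: float64
index effect: beta = 0.507 (95% CI 0.467, 0.548; p = 1.25e-120)
```

The weights are each exposure's estimated share of the mixture effect: air
pollutants dominate (PM2.5 29%, PM10 22%, NO2 15%), matching the generator's
planted air-pollution-heavy weight profile, and the index effect (0.507)
recovers the planted effect of 0.5 outcome units per quantile step of the
whole mixture.

```python
Xz = som.standardize(cohort[list(EXPOSURES)])
model = som.train_som(Xz.to_numpy(), grid=(10, 10), seed=1)
sel = som.select_k(model, Xz.to_numpy(), range(2, 9))
labels = som.assign(Xz.to_numpy(), model, sel)
asg = som.name_subpopulations(labels, Xz)
print("selected k =", sel.selected_k, "->", sorted(asg.names.values()))
table = som.compare_subpopulations(asg, cohort, "phenoage", ["age", "sex", "smoking"])
print(table[["subpopulation", "beta", "ci_low", "ci_high", "p_value"]].round(3).to_string(index=False))
```

```
selected k = 5 -> ['air pollution', 'blue space', 'green space', 'noise', 'rural-urban fringe']
     subpopulation  beta  ci_low  ci_high  p_value
             noise 1.628   1.191    2.065      0.0
     air pollution 2.486   2.098    2.874      0.0
rural-urban fringe 1.546   1.207    1.884      0.0
        blue space 1.126   0.702    1.551      0.0
```

The WSS/BSS elbow recovers the five planted archetypes; relative to the
green-space group, the air-pollution subpopulation shows the largest
PhenoAge excess (+2.5 years), as planted through the exposure index.

The same stages run from the shell:

```bash
envage simulate --n 5000 --seed 1 --out cohort.csv
envage phenoage --in cohort.csv --out scored.csv
envage wqs --in scored.csv --outcome brain_age_gap --n-boot 100 --seed 1 --out wqs.json
envage som --in scored.csv --grid 10x10 --k-range 2:8 --seed 1 --out subpops.csv
envage run --seed 1 --n 5000 --out-dir demo_run   # full pipeline + manifest
```

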