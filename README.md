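# gliosurv

Image-derived glioblastoma growth kinetics and sex-stratified survival
analysis.

Glioblastoma (GBM) outcomes differ between men and women, but the imaging
and kinetic features that drive those differences are rarely analyzed
per sex. `gliosurv` implements, as one tested pipeline, the analysis a
quantitative neuro-oncology group would run on a pre-treatment MRI
cohort:

1. **Imaging geometry** — segmented T1Gd, T2/FLAIR and necrosis volumes
   are reduced to spherically-equivalent radii
   (r = (3V/4π)^(1/3)), the contrast-enhancing rim thickness is the
   T1Gd-minus-necrosis radius, and each subject is labeled an extreme
   survivor (EXS, overall survival ≥ 1825 days), short-term survivor
   (STS, ≤ 210 days) or neither.
2. **Proliferation-Invasion (PI) model** — tumor cell density c(r, t)
   follows the Fisher-KPP reaction-diffusion equation
   ∂c/∂t = D∇²c + ϱc(1 − c/K), with net invasion rate D (mm²/year) and
   net proliferation rate ϱ (1/year). The mismatch between the T2/FLAIR
   radius (low-density threshold, 0.16 K) and the T1Gd radius
   (high-density threshold, 0.80 K) measures the slope of the traveling
   density front, which scales as √(D/ϱ); inverting a precomputed
   traveling-wave table turns one imaging timepoint into the relative
   invasiveness D/ϱ (mm²).
3. **PIHNA model** — a five-species extension (normoxic, hypoxic and
   necrotic cells, vasculature, angiogenic factor) whose necrotic core
   provides an absolute clock, so the triple (necrosis, T1Gd, T2/FLAIR
   radius) from a single timepoint identifies patient-specific D *and*
   ϱ by nearest-match against a library of forward simulations.
4. **Survival statistics** — run separately for males and females: Welch
   t-tests of the eight quantitative variables across survival groups,
   univariate Cox proportional hazards with promotion of covariates at
   p < 0.10 into a multivariate model, Kaplan-Meier curves with log-rank
   tests, Cochran-Armitage trend tests over resection extent, and
   categorical reports (laterality, resection, IDH1, MGMT).
5. **Decision trees** — six CART trees (per sex × {EXS vs rest, EXS vs
   STS, STS vs rest}) on the eight quantitative variables, with a 70/30
   stratified split, cost-complexity pruning chosen by 10-fold
   cross-validation and the one-standard-error rule.
6. **Synthetic cohorts** — clinical imaging cohorts of this kind are not
   publicly distributable, so a generator emulates the published cohort
   structure (covariate marginals per sex, 60.5% male, Weibull
   proportional-hazards survival carrying the published hazard ratios),
   making every stage testable end to end.

## Worked example

```python
from gliosurv import (GeneratorConfig, generate_cohort, estimate_D_over_rho)
from gliosurv.cli import run_full_pipeline

cohort = generate_cohort(GeneratorConfig(n=494, seed=7))
results = run_full_pipeline(cohort, "analysis_out", seed=7)
print(open("analysis_out/report.txt").read())
```

prints (abbreviated):

```
Main cohort: n = 494
Imaging sub-cohort (kinetic variables): n = 494

Cohort composition (percent of each survival group by sex):
   all: male 291 (58.9%), female 203 (41.1%)
   EXS: male 17 (65.4%), female 9 (34.6%)
   STS: male 75 (54.3%), female 63 (45.7%)

t-test matrix: 48 comparisons, 7 with p < 0.05

Multivariate Cox (promoted covariates):
    male age_years            HR 1.033 (1.024-1.043) p = 4.98e-12
  female age_years            HR 1.013 (1.003-1.023) p = 0.0119
  female pihna_D              HR 1.010 (1.006-1.014) p = 5.31e-06
```

The synthetic cohort was generated with male survival driven by age
(HR 1.030/year) and tumor radius, and female survival by age (1.021) and
the invasion rate D (1.011/mm²·yr⁻¹); the refitted multivariate Cox
models recover exactly that sex-specific structure. The single-subject
kinetic estimate works the same way:

```python
ratio = estimate_D_over_rho(t1gd_radius_mm=20.0, t2flair_radius_mm=27.6)
# -> 1.63 mm^2 : moderately diffuse
```

A command-line interface wraps the same functions:

```bash
gliosurv generate --n 494 --seed 7 -o cohort.csv
gliosurv report --cohort cohort.csv --seed 7 -o analysis_out
gliosurv pihna build-library -o lib && \
gliosurv pihna estimate --library lib --t1gd 20 --t2flair 28 --necrosis 12
```

## Layout

```
src/gliosurv/
  geometry.py   radii, rim thickness, survival groups, cohort I/O
  pi_model.py   Fisher-KPP radial solver, traveling-wave D/rho inversion
  pihna.py      five-species model, simulation library, (D, rho) estimator
  survstats.py  Welch / Cox / Kaplan-Meier / log-rank / trend tests
  trees.py      CART survival-group trees with CV pruning
  cohort.py     synthetic cohort generator
  cli.py        command-line interface and composite reports
docs/methods.md the model, numerics and design notes
```
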