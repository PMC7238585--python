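# Methods

This note documents the models, numerics and design choices behind
`gliosurv`, in the order the pipeline runs.

## Imaging geometry

Segmented MRI abnormality volumes are reduced to spherically-equivalent
radii, r = (3V/4π)^(1/3). All internal units are fixed: radii in mm,
volumes in mm³, D in mm²/year, ϱ in 1/year, overall survival in days,
age in years; loaders convert on entry. The geometric invariants
necrosis ≤ T1Gd ≤ T2/FLAIR are enforced at load time and rows violating
them are rejected with a logged reason rather than silently repaired.

Survival groups: extreme survivors (EXS) at overall survival ≥ 1825 days
and short-term survivors (STS) at ≤ 210 days, both boundaries inclusive
and configurable. When an event indicator is missing, all subjects are
treated as deceased (event = 1) with a logged warning — the analysis is
of overall survival in a retrospective cohort, and no censoring scheme
is assumed by default; an administrative censoring horizon is available
in the generator for sensitivity work.

## Proliferation-Invasion model

Tumor cell density c(r, t), normalized to carrying capacity K = 1,
follows Fisher-KPP dynamics in spherical symmetry:

    ∂c/∂t = D ∇²c + ϱ c (1 − c/K)

**Discretization.** Conservative finite volumes on a uniform radial
grid: interface fluxes A D Δc/Δr with shell areas A = r², cell volumes
(r³₊ − r³₋)/3, no-flux boundaries at r = 0 and r_max. Because fluxes
telescope, pure diffusion conserves mass to rounding error, which the
tests assert. Time stepping is explicit Euler with the step validated
against D·dt/dr² ≤ 0.25 (and a reaction-rate margin); violations raise
rather than blow up. An optional crowding factor (1 − c/K) on the
motility flux — with the interface coefficient limited by the smaller
neighbouring factor, so nothing flows into a full cell — supports the
occupancy-limited variant used by the five-species model.

**Imaging thresholds.** The T1Gd abnormality is read at 0.80 K and the
T2/FLAIR abnormality at 0.16 K of the simulated density, the convention
of the invasion-modelling literature this pipeline follows; both are
configurable, and the estimation contracts (round-trip recovery) do not
depend on the specific values.

**D/ϱ inversion.** The traveling-wave profile of Fisher-KPP depends on
(D, ϱ) only through the length scale √(D/ϱ), so the radius mismatch
Δr = r(0.16K) − r(0.80K) of the converged wave is √(D/ϱ) times a
universal width. The implementation simulates each tabulated ratio to
the traveling-wave regime (front speed change < 0.5% between successive
1/ϱ windows), with the grid resolving the front width (dr = √(D/ϱ)/12)
and the domain long enough (60 √(D/ϱ)) that the exponential leading tail
never reaches the boundary. Front speed is reported by fitting the known
slow transient speed(t) = a + b/t of pulled fronts and returning a; this
removes an otherwise ~8% bias at feasible run lengths and brings the
measured speed within ~1% of the analytic 2√(Dϱ).

An independent check frozen into the tests: solving the planar minimal-
wave ODE c'' + 2c' + c(1 − c) = 0 by shooting gives a dimensionless
0.16–0.80 width of 6.106, and the converged radial simulations
reproduce it to within a few percent (slightly below, from front
curvature at finite radius). Note the naive linearization
Δr ≈ √(D/ϱ)·ln(0.80/0.16) ≈ 1.6·√(D/ϱ) underestimates this width nearly
four-fold — the minimal-speed front decays as (A + Bx)e^(−x√(ϱ/D)), not
as a pure exponential, and the interior profile is wide — so the BVP
value, not the linearization, is the oracle.

The inversion table holds 64 log-spaced ratios in [0.003, 11] mm²
(covering the observed clinical span), interpolated monotonically
(PCHIP) in both directions; estimates outside the tabulated mismatch
range clamp to the bounds with a warning.

## PIHNA model

The five-species extension tracks normoxic cells c, hypoxic cells h,
necrotic debris n, vasculature v and an angiogenic factor a, with
occupancy F = max(0, 1 − (c+h+n+v)/K), vascular sufficiency
s = v/(v + k_v(c+h)) and crowding gate g = min(1, (c+h+n+v)/K)²:

    ∂c/∂t = ∇·(D F ∇c) + ϱ c F − β_ch(1−s) c + γ_hc s h − α_n g (n/K) c
    ∂h/∂t = ∇·(D F ∇h) + β_ch(1−s) c − γ_hc s h − β_hn h − α_n g (n/K) h
    ∂n/∂t = β_hn h + α_n g (n/K)(c + h)
    ∂v/∂t = ∇·(D_v F ∇v) + μ_v v (1 − v/v_cap) F a/(a_half + a) − α_n g (n/K) v
    ∂a/∂t = δ_a (c + h) − λ_a a − ω_a a v

Only (D, ϱ) vary per patient. The fixed rates are population constants
of this package's own design, chosen so the model reproduces GBM
phenomenology across the clinically observed (D, ϱ) ranges: tumors
densify to imaging-visible levels first and necrose afterwards, fast
proliferators develop large necrotic cores within months, and the three
radii stay nested. Defaults: β_ch = 10, γ_hc = 50, β_hn = 1, α_n = 10,
μ_v = 10, λ_a = 10, ω_a = 10 (all /year), D_v = 0.5 mm²/year, k_v = 0.2,
v_cap = 0.1, a_half = 0.02, δ_a = 1, initial vasculature v₀ = 0.05.
Two modelling points deserve emphasis:

* **Crowding-gated contact necrosis.** Contact necrosis spreads at
  α_n(n/K) scaled by the *squared* local occupancy. Without the gate the
  necrotic conversion overruns the viable rim while tissue is still
  loose, freezing total cellular density just at or below the 0.80 K
  T1Gd threshold — a razor-thin enhancing rim and an ill-conditioned
  observable. Gating necrosis to crowded tissue lets slow-proliferating
  tumors reach full density before the core necroses.
* **The necrotic core is the clock.** The radius mismatch fixes D/ϱ, but
  along a ray (κD, κϱ) the density profiles are time-reparametrizations
  of each other; only the necrotic fraction, which grows with absolute
  tumor age at rates that do not scale with κ, separates fast-large-young
  from slow-small-old. Tumors observed without necrosis therefore have
  weakly identified ϱ — which the estimator reports honestly through its
  residual and boundary diagnostics rather than hiding.

**Observables.** T1Gd radius: outermost r with c+h+n ≥ 0.80 K; T2/FLAIR:
≥ 0.16 K; necrosis: outermost r where n is at least half the local
cellular density (a scale-free composition rule for the non-enhancing
core), clipped inside the T1Gd radius.

**Estimation.** A library of forward simulations over a 16×16 log-spaced
grid (D ∈ [0.3, 300] mm²/year, ϱ ∈ [1.8, 200] /year; the grid, bounds
and fixed rates are configurable and recorded in the library metadata)
stores the three radii along each trajectory. Estimation scans every
(D, ϱ, time) triple for the smallest root-mean-square radius mismatch
(ties toward smaller D, then smaller ϱ), then refines within the winning
cell on radii interpolated bilinearly in (log D, log ϱ) and linearly in
time, with a golden-section search over time per refined candidate.
Per-simulation grids adapt to the front width (dr = √(D/ϱ)/6 clipped to
[0.15, 0.6] mm, domain 70 mm); runs stop when the T1Gd radius passes the
largest clinically observed size (~36 mm) or at 15 years. Recovery
experiments snapshot the simulated truth at *clinical detection size*
(first time the T1Gd radius reaches 20 mm, the cohort-median
presentation size) — that is how patients enter an imaging cohort, and
trajectories are well separated there, whereas near the maximal size
they converge. Median relative recovery error over truths spanning the
observed ranges is ~10–13%; the failures concentrate in
necrosis-free (high-D/ϱ) corners for the identifiability reason above.

## Survival statistics

All tests are two-sided; p-values are reported raw (the published
analysis style), with an optional Benjamini-Hochberg column available as
a clearly marked extension. Welch t-tests use the Satterthwaite degrees
of freedom, reported unrounded; degenerate zero-variance comparisons
resolve to p = 1 (equal means) or a flagged p = 0 limit. Cox models
maximize the partial likelihood with Efron tie handling (the de facto
standard of the survival ecosystem); fits are backed by `lifelines` and
cross-checked in the tests against a brute-force partial-likelihood
oracle, and the log-rank statistic against a hand-computed Cox score
test. Separation or non-convergence raises a diagnostic error. The
promotion rule into the multivariate model is strict: univariate
p < 0.10. The Cochran-Armitage trend statistic is the standard
conditional-variance z with equally spaced scores by default, validated
against a permutation null. Kinetic variables are automatically
restricted to the imaging sub-cohort (subjects with T2/FLAIR), and every
exclusion is counted in the pipeline manifest.

## Decision trees

Greedy binary Gini partitioning (thresholds at midpoints of adjacent
observed values) with minsplit = 20, minbucket = 7, depth ≤ 30, then
cost-complexity pruning with the complexity chosen by 10-fold stratified
cross-validated misclassification under the one-standard-error rule —
the defaults of the recursive-partitioning tradition. The 70/30
train/test split is stratified by outcome and deterministic given the
seed. The extreme-vs-short-term trees use only subjects in those two
groups. scikit-learn's CART provides the partitioning engine (its
float32 threshold storage explains ~1e-7 threshold jitter against a
float64 brute-force search); the structure exposed to users carries
per-node class concentrations and sample counts.

## Synthetic cohorts

The generator emulates the published cohort structure; its defaults are
the study conditions, not tuning knobs:

* sex ~ Bernoulli(0.605 male);
* age and T1Gd radius: per-sex range-truncated normals (male
  57.58 years, 19.52 mm; female 58.41, 19.27) with SD = printed
  range / 6, so ±3 SD of the untruncated law spans the printed range;
* D, ϱ: per-sex range-truncated log-normals (medians 28.99/23.03
  mm²/year and 18.25/18.25 /year) with log-SD = log-range / 6, jointly
  rejection-sampled so D/ϱ stays inside the observed [0.0034, 10.7] mm²;
* contrast-enhancing rim: truncated normal (per-sex means 8.16/7.89 mm,
  floor 0.32 mm); necrosis radius = max(0, T1Gd − rim);
* parametric mode: T2/FLAIR radius = T1Gd + Δr(D/ϱ) through the same
  traveling-wave table the estimator inverts, closing the generator →
  estimator loop exactly; mechanistic mode instead runs the five-species
  model per subject and snapshots it at the subject's detection size
  (orders of magnitude slower; used for small cross-checks);
* survival: Weibull proportional hazards, shape 1.2, baseline scale set
  so the baseline median is 450 days (the middle of the 9–15-month
  range typical of this disease); sex-specific linear predictors carry
  the published multivariate hazard ratios — male:
  ln(1.030)(age − 58) + ln(1.027)(T1Gd − 19.5); female:
  ln(1.021)(age − 58) + ln(1.011)(D − 30). Everyone is an observed death
  unless an administrative censoring horizon is configured;
* categorical covariates are assigned independently with prevalences
  matching the published margins; optional per-level log-hazards (e.g. a
  planted MGMT-methylation benefit) and per-survival-group covariate
  shifts support the power and calibration tests.

What the generator does **not** emulate: correlations among age, size
and kinetics beyond the mechanistic radii couplings, institutional
heterogeneity, treatment-era effects, or the real joint distribution of
the categorical markers. A Weibull with median 450 days also yields
~5% extreme and ~28% short-term survivors rather than the enriched 9.5%
/ 17.8% of the published registry cohort (which oversampled extreme
survivors by design); matching both tails and the median is outside a
two-parameter baseline and was not forced. Passing tests therefore
demonstrate the pipeline's correctness and calibration under a faithful
proportional-hazards world, not distributional identity with any real
cohort.

## Problem sizes and determinism

Default problem sizes keep the full test suite and the acceptance script
comfortably within a desk-scale run: the inversion table at 24–64
ratios, the simulation library at 16×16, hazard-ratio coverage at 25–50
replicates of 2000 subjects per sex, type-I calibration at 300–500 null
cohorts, trees at n = 600. Every stochastic component takes an explicit
seed (NumPy `default_rng`), simulation outputs are pure functions of
their configuration, and the library and report bundles are byte-stable
on rebuild, which the tests assert.
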