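# Methods

## Dose feature space

Each structure's cumulative DVH is sampled at 2, 4, ..., 70 Gy (35 points);
`V_d` is the fraction of the structure's volume receiving at least `d` Gy
(≥ versus > is immaterial on a continuous dose distribution; we document ≥).
Volumes are stored as fractions in [0, 1], never percent: the PCA operates
on the raw centered matrix and is scale sensitive, so the unit is a frozen
contract. The six structures of the active set (combined lungs, whole
heart, and the four chambers — or the four coronary arteries for the
secondary variant) are flattened structure-major, dose-ascending into a
210-column matrix; the column order (`V2_Lung ... V70_VentricleLeft`) is
pinned by a regression test because downstream PCA weights are indexed
by it.

The planned tumor dose is converted to the equivalent dose in 2 Gy
fractions under the linear-quadratic model, `EQD2 = D (d + α/β)/(2 + α/β)`
with `d = D/n` and α/β = 10 Gy, because fractionation varies slightly
across prescriptions. Gross tumor volume enters models as the natural log
(skewed distribution; the base only rescales the coefficient).

## Dose-pattern PCA

The PCA is a covariance (not correlation) decomposition of the centered
matrix: weights are interpretable in raw volume units. All `min(n-1, 210)`
components are kept internally — full-rank reconstruction then reproduces
the input to < 1e-8 relative Frobenius error, which the tests assert — and
the retained count follows the cumulative-explained-variance rule
(threshold 0.95, inclusive at the boundary) capped at 8, because the
best-subset search downstream doubles in cost per candidate variable.
Variance fractions use denominator n − 1.

Component signs are arbitrary in any eigendecomposition, so a deterministic
convention fixes them: a component is flipped so its whole-heart weight sum
is positive, unless the right-minus-left structure contrast (right atrium +
right ventricle − left atrium − left ventricle; RCA − LMCA − LAD − CX for
the coronary set) is larger in magnitude, in which case that contrast is
made positive. The second clause exists because the left/right
dose-balance pattern leaves the whole-heart DVH nearly unchanged — its
heart weight sum is noise, and orienting by it would make the component's
sign cohort-dependent. Under this convention larger first-component scores
mean more overall heart irradiation and positive balance scores mean
right-sided irradiation. Only sign-invariant quantities (HR magnitude per
SD, reconstruction geometry) should be compared across backends.

Score SDs (ddof = 1) are reported alongside hazard ratios: HRs for
dose-pattern terms are quoted per one cohort SD of the score, which makes
them invariant to the volume unit; per-unit HRs are also exported.

## Cox engine

The log partial likelihood uses Efron's tie correction (registry survival
times are often recorded coarsely; Efron is less biased than Breslow under
ties) and reduces to the exact partial likelihood when event times are
unique, which the tests verify against an independently written brute-force
implementation. Fitting is Newton iteration from zero with step halving on
likelihood decrease, convergence at gradient max-norm < 1e-7, at most 100
iterations; a coefficient norm above 200 is treated as monotone-likelihood
separation and flagged as non-convergence. Standard errors come from the
inverse observed information. The engine exposes likelihood evaluation at
arbitrary coefficients on arbitrary data, which the cross-validation
requires; a `PreparedSurvival` cache of the time ordering and tie structure
makes the thousands of subset fits in the selection loop cheap. Estimates
agree with lifelines' `CoxPHFitter` to 1e-5 on shared fixtures, but
lifelines is used only as an independent cross-check (and for Kaplan-Meier
curves with Greenwood log-log CIs and the reverse-KM median follow-up, in
which the censoring indicator is inverted).

Predicted survival uses the Breslow baseline cumulative hazard,
`S_i(t) = exp(-H0(t) e^{x_i β})`, with the uncentered linear predictor
(the centering constant cancels against the baseline).

## Selection procedure

Missing covariates (only BMI and pack-years may be missing) are imputed
once, before any bootstrap, by chained-equations regression
(scikit-learn's iterative imputer; single completed dataset, values
constrained to the observed range, categoricals entering the imputation
model as numeric codes, outcome excluded). Multiple-imputation pooling is
out of scope.

Each of B bootstrap resamples splits the cohort into an in-boot multiset of
size n and the out-of-boot complement (empty complements are redrawn and
logged; the expected unique in-boot fraction is 1 − 1/e ≈ 0.632). For
every subset of the candidate units — a categorical factor's indicators
enter and leave together — the model is fitted in-boot and scored by the
out-of-boot log partial likelihood at the in-boot coefficients divided by
the number of out-of-boot patients. That per-patient correction makes
scores comparable across splits with different out-of-boot sizes; the
Verweij–van Houwelingen variant (full-data minus in-boot likelihood at the
in-boot coefficients, same divisor) is available behind `cv_method="vvh"`.
All 2^k subsets see the same B splits, so comparisons are paired and split
noise cancels out of subset contrasts. A failed in-boot fit scores the
subset at that split's null-model value, penalizing instability rather
than silently dropping the split. Ties in the mean score go to the smaller
subset, then lexicographic order. Split RNG streams are derived from the
master seed by counter, so changing B or subset order never reshuffles
earlier splits. The candidate count is capped at 20 (cost doubles per
candidate).

The selected subset is refitted on the full data; 95% CIs are the
2.5th/97.5th percentiles of the coefficients over B_ci = 2000 in-boot
refits (minimum 100 enforced; non-converged refits dropped and counted).
The selection bootstraps and the CI bootstraps use independent streams.

## Risk tertiles and calibration

Patients are grouped at the 25th/75th percentiles of the linear predictor
(type-7 linear-interpolation percentiles, documented because percentile
conventions differ across ecosystems). Values exactly on a threshold fall
into the middle group — in particular a constant linear predictor puts
everyone mid. Within each group the observed Kaplan-Meier curve is
compared with the model curve, defined as the mean of the patient-level
predicted survival curves in the group (not the curve of the mean
predictor), with a 95% band formed by the percentile envelope over
bootstrap refits of the *selected* model (selection itself is not re-run
per bootstrap; re-running it would fold selection noise into the band and
is out of scope). The point prediction is included in the envelope so the
band always contains it.

## Synthetic cohort generator

The generator emulates a ~644-patient national cohort: clinical covariates
with realistic marginals (age ~ N(68, 9²) years, 55% male, BMI ~ N(24.8,
4.5²) kg/m², 16% performance status ≥ 2, 78% stage ≥ IIIA, gamma-distributed
pack-years, four calcium-score groups, baseline cardiac disease and risk
factors, fractionation schedules of 55–66 Gy in 20–33 fractions converted
through EQD2, log-normal tumor volumes), and by default 57 missing BMI and
49 missing pack-years values (MCAR; the missingness mechanism of the
original data is unknown).

Tumor position is a scaled location in a lung bounding box: lateral
x ∈ [0, 250] (0 = most right), craniocaudal y ∈ [0, 200] (0 = most caudal).
Each structure's DVH is a logistic curve in dose, `V(d) = A / (1 +
exp((d − D50)/k))` with k = 4.5 Gy — smooth, monotone, bounded — whose
plateau A and midpoint D50 increase with caudal proximity `c = (200 −
y)/200` for every heart structure (the heart sits caudally, so mean heart
dose increases strictly as tumors sit lower), and whose chamber plateaus
are additionally multiplied by `1 ± λ·side·heart_level` where λ is the
scaled lateral position and `heart_level` a Gaussian window around the
heart's craniocaudal position: at heart level, left-sided tumors load the
left ventricle (weight 0.55) and left atrium (0.22) and unload the right
atrium/right ventricle symmetrically, leaving the whole-heart curve
untouched. Lognormal noise (σ = 0.20) on the plateau and Gaussian noise
(2 Gy) on the midpoint give realistic within-structure scatter. This
plants exactly two dominant dose patterns — overall heart irradiation and
right/left balance — that the PCA recovers as its first two components,
with component-1 weights all positive.

Survival is a Weibull-baseline Cox model: shape 1.1, scale 36 months
(baseline median ≈ 26 months, matching the target cohort's survival), with
a linear predictor combining the clinical covariates and the cohort's own
fitted dose-pattern scores (per-unit log-HRs of 0.131 for the
heart-irradiation pattern and −0.083 for the balance pattern by default,
i.e. the hazard contrasts the method is meant to detect), centered so the
baseline describes the average patient. Censoring is administrative at an
84-month horizon (≈ 7-year follow-up) plus uniform dropout whose width is
bisected to hit the target censoring fraction — 0.30 by default, a knob
because the real fraction is not published; a moderate value is implied by
the long follow-up relative to the median survival. A target of zero
yields a fully observed cohort. Everything derives from one seed through
named substreams; identical configs give byte-identical cohorts.

What the generator does *not* emulate: 3-D dose grids or segmentation
geometry, informative censoring, non-proportional hazards, measurement
error in registry covariates, or inter-center heterogeneity. Passing tests
therefore demonstrate that the pipeline recovers known structure of this
form, not that the clinical findings generalize. The synthetic dose-pattern
score SDs (≈ 1.3 and 0.4) are smaller than those of the real cohort; per-SD
hazard ratios are the comparable scale.

## Problem sizes in the tests and acceptance script

Statistical checks use sizes chosen to keep Monte-Carlo error well below
the asserted margins: coverage of the Cox fitter and of percentile
bootstrap CIs (B = 200) over 200 replicate cohorts of n = 2000 (pooled
over three coefficients); selection operating characteristics over 20
replicates of n = 644 with B = 10 splits and 2^8 subsets; calibration
self-consistency on n = 300 with B = 200 bands; the end-to-end demo at
n = 200 with 8 candidates, run twice to assert byte-reproducibility. The
acceptance script repeats these with 100 coverage replicates and 10
selection replicates and runs the full B = 50 selection with B = 2000 CIs
on one 644-patient cohort.

## Known limitations

- Best-subset selection is exponential in the candidate count; the cap and
  the component cap are the only defenses. No penalized or stepwise
  alternatives are provided by design.
- The percentile bootstrap ignores selection uncertainty: CIs condition on
  the selected subset.
- Efron handling of heavy ties (many events at one time) is an
  approximation; with continuous synthetic times this is untested beyond
  small fixtures.
- The imputer is a single-imputation shortcut; standard errors downstream
  do not reflect imputation uncertainty.
- Tumor geometry uses one scaled bounding box for all patients; real
  anatomies vary in ways the two planted patterns cannot express.
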