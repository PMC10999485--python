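# lungdose

Dose-pattern survival modelling for lung-cancer radiotherapy: principal
component analysis of dose-volume histograms (DVHs) for the lungs, heart and
cardiac substructures, combined with bootstrap cross-validated best-subset
Cox regression of overall survival.

## The problem

In definitive radiotherapy for locally advanced non-small-cell lung cancer,
dose spills into the lungs and heart, and irradiation of the different heart
substructures is strongly mutually correlated: a survival association with
any single DVH metric (V5, V30, mean heart dose, ...) can be a proxy for a
different structure entirely, and the sheer number of candidate metrics
invites false positives. This package addresses that by

1. flattening each patient's six cumulative DVHs (combined lungs, whole
   heart, and either the four chambers or the four coronary arteries),
   sampled at V2, V4, ..., V70 (35 points each, 210 variables), into a
   mean-centered feature vector;
2. decomposing the cohort with PCA, so a patient is described by a few
   uncorrelated dose-pattern scores, `PCA_k = sum_i w_ki (V_i - mean(V_i))`,
   each measuring deviation from the cohort-mean DVH along one irradiation
   pattern — the components retained are those explaining 95% of the
   variance, capped at eight;
3. selecting a multivariable Cox proportional-hazards model for overall
   survival over clinical covariates (age, sex, BMI, performance status,
   stage, pack-years, calcium-score group, baseline cardiac disease,
   cardiac risk factors, tumor EQD2 and log tumor volume) plus the
   dose-pattern scores, by exhaustive best-subset search: every subset is
   scored on B bootstrap resamples by the out-of-boot log partial
   likelihood at in-boot coefficients, divided by the out-of-boot size, and
   the subset with the best mean score wins;
4. quantifying uncertainty by percentile bootstrap (95% CIs over 2000
   refits) and checking calibration by comparing Kaplan-Meier curves with
   model-predicted survival within risk tertiles (cut at the 25th/75th
   percentiles of the linear predictor).

The Cox engine (Efron-tie log partial likelihood evaluable at arbitrary
coefficients, Newton fitting, Breslow baseline) is implemented in-package
because the cross-validation must score held-out data at fixed
coefficients; Kaplan-Meier estimation and chained-equations imputation use
lifelines and scikit-learn.

Because the registry cohort the method was developed for is not publicly
available, the package ships a synthetic cohort generator with known ground
truth: tumor position inside a lung bounding box drives correlated
sigmoid-family DVHs (caudal tumors irradiate the whole heart more;
left/right position at heart level shifts dose between the left ventricle
and right atrium), and survival follows a Weibull-baseline Cox model whose
linear predictor uses the cohort's own fitted dose-pattern scores. Every
statistical guarantee in the test suite is checked against this ground
truth.

## Worked example

```python
import numpy as np
import lungdose as ld

cohort = ld.generate_cohort(ld.CohortConfig(n_patients=644, seed=1))
features = ld.build_feature_matrix(cohort.dvh, "chambers",
                                   patient_ids=cohort.patient_ids)
model = ld.fit_pca(features)
print(f"components retained: {model.n_components} "
      f"({100 * model.explained_fraction[:model.n_components].sum():.1f}% of variance)")

km = ld.kaplan_meier(cohort.patients.time, cohort.patients.event)
print(f"median survival: {km.median:.1f} months")

data = ld.impute(cohort, seed=1).patients.copy()
data["PCA_1"], data["PCA_2"] = model.scores[:, 0], model.scores[:, 1]
result = ld.best_subset_select(
    data, ("age", "sex", "bmi", "ps", "log_gtv", "PCA_1", "PCA_2"),
    B=10, seed=1,
)
print("selected:", ";".join(result.selected))
sd = ld.score_sd(model)
for unit in ("PCA_1", "PCA_2"):
    if unit in result.selected:
        k = int(unit[-1]) - 1
        beta = result.final_fit.beta[result.final_fit.columns.index(unit)]
        print(f"{unit}: HR per SD = {np.exp(beta * sd[k]):.3f}")
```

prints

```
components retained: 5 (95.6% of variance)
median survival: 27.7 months
selected: age;sex;bmi;ps;log_gtv;PCA_1;PCA_2
PCA_1: HR per SD = 1.156
PCA_2: HR per SD = 0.888
```

Five dose patterns carry 95.6% of the DVH variance in this cohort. The
selection keeps both dose-pattern scores alongside the clinical covariates:
one cohort-SD more overall heart/lung irradiation (PCA_1) raises the hazard
of death by ~16%, while a one-SD shift of dose from the left ventricle
toward the right atrium (PCA_2, positive = right-sided) lowers it by ~11% —
the planted effects of the generator, recovered end to end.

The same pipeline runs from the shell:

```sh
lungdose synth --n 644 --seed 1 --out cohort/
lungdose run --config run.yaml     # cohort -> validate -> pca -> select -> report
```

producing `pca_model.json`, `selection_table.csv`, `final_model.json`,
`calibration.csv`, `forest.csv`, `hr_map.csv` and a `manifest.json` with
checksums that reproduce bit-for-bit from the same config.

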