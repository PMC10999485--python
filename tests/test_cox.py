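import math

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter

import lungdose as ld
from lungdose.cox import SurvivalDesign


def make_design(X, time, event, names=None):
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(time):
        X = X.T
    names = names or [f"x{i}" for i in range(X.shape[1])]
    return SurvivalDesign(
        X=X, time=np.asarray(time, dtype=float),
        event=np.asarray(event, dtype=int),
        columns=names, term_map={n: [i] for i, n in enumerate(names)},
    )


def efron_loglik_brute(X, time, event, beta):
    """Independent brute-force Efron log partial likelihood (plain loops)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(time):
        X = X.T
    eta = X @ np.asarray(beta, dtype=float)
    w = np.exp(eta)
    ll = 0.0
    for t in np.unique(np.asarray(time)[np.asarray(event) == 1]):
        D = [i for i in range(len(time)) if time[i] == t and event[i] == 1]
        R = [i for i in range(len(time)) if time[i] >= t]
        d = len(D)
        tie_sum = sum(w[i] for i in D)
        ll += sum(eta[i] for i in D)
        for l in range(d):
            ll -= math.log(sum(w[i] for i in R) - (l / d) * tie_sum)
    return ll


# ---------------------------------------------------------------------------
# partial likelihood
# ---------------------------------------------------------------------------

def test_null_loglik_three_subjects():
    # 3 distinct event times, beta=0: risk sets of size 3, 2, 1
    d = make_design(np.zeros((3, 1)), [1.0, 2.0, 3.0], [1, 1, 1])
    assert ld.log_partial_likelihood(d, [0.0]) == pytest.approx(-math.log(6), abs=1e-12)


def test_null_loglik_closed_form_general():
    rng = np.random.default_rng(0)
    n = 40
    time = rng.exponential(10, n).round(2)
    event = (rng.random(n) < 0.7).astype(int)
    d = make_design(rng.normal(size=(n, 3)), time, event)
    expected = -sum(
        math.log(np.sum(time >= t)) for t, e in zip(time, event) if e == 1
    )
    assert ld.log_partial_likelihood(d, np.zeros(3)) == pytest.approx(expected, abs=1e-10)


def test_efron_matches_brute_force_with_ties():
    rng = np.random.default_rng(1)
    time = np.array([1.0, 1.0, 2.0, 2.0, 2.0, 3.0, 4.0, 4.0])
    event = np.array([1, 1, 1, 0, 1, 1, 1, 0])
    X = rng.normal(size=(8, 2))
    for _ in range(5):
        beta = rng.normal(scale=0.8, size=2)
        d = make_design(X, time, event)
        assert ld.log_partial_likelihood(d, beta) == pytest.approx(
            efron_loglik_brute(X, time, event, beta), abs=1e-10
        )


def test_efron_reduces_to_exact_without_ties():
    """With unique event times the implementation equals the exact partial
    likelihood (brute force, no tie correction); with mild 2-way ties the
    Efron value stays close to the exact value of the tie-broken data."""
    rng = np.random.default_rng(2)
    n = 30
    time = rng.exponential(10, n)  # unique with probability 1
    event = (rng.random(n) < 0.6).astype(int)
    X = rng.normal(size=(n, 2))
    beta = np.array([0.5, -0.3])
    eta = X @ beta
    w = np.exp(eta)
    exact = sum(
        eta[i] - math.log(w[time >= time[i]].sum())
        for i in range(n) if event[i] == 1
    )
    assert ld.log_partial_likelihood(make_design(X, time, event), beta) == \
        pytest.approx(exact, abs=1e-10)

    tied_time = np.round(time, 0) + 1.0
    tied = ld.log_partial_likelihood(make_design(X, tied_time, event), beta)
    jitter = tied_time + 1e-9 * rng.permutation(n)
    untied = ld.log_partial_likelihood(make_design(X, jitter, event), beta)
    assert tied == pytest.approx(untied, rel=0.05)


def test_loglik_rejects_wrong_beta_length():
    d = make_design(np.zeros((3, 2)), [1, 2, 3], [1, 1, 1])
    with pytest.raises(ValueError):
        ld.log_partial_likelihood(d, [0.0])


def test_design_requires_events():
    with pytest.raises(ValueError, match="event"):
        make_design(np.zeros((3, 1)), [1, 2, 3], [0, 0, 0])


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def test_fit_agrees_with_lifelines(data300):
    units = ("age", "sex", "bmi", "ps", "PCA_1")
    design = ld.build_design(data300, units)
    fit = ld.fit_cox(design)
    assert fit.converged
    df = pd.DataFrame(design.X, columns=design.columns)
    df["time"], df["event"] = design.time, design.event
    cph = CoxPHFitter().fit(df, "time", "event",
                            fit_options={"precision": 1e-9})
    np.testing.assert_allclose(fit.beta, cph.params_.values, atol=1e-5)
    assert fit.loglik == pytest.approx(cph.log_likelihood_, abs=1e-6)
    np.testing.assert_allclose(fit.se, cph.standard_errors_.values, atol=1e-5)


def test_null_covariate_recovers_zero():
    rng = np.random.default_rng(3)
    n = 2000
    x = rng.normal(size=n)
    time = rng.exponential(20, n)  # independent of x: true HR 1
    event = np.ones(n, dtype=int)
    fit = ld.fit_cox(make_design(x, time, event))
    assert abs(fit.beta[0]) < 2 * fit.se[0]


def test_parameter_recovery_generator_cohort():
    cfg = ld.CohortConfig(n_patients=2000, seed=2, missing_counts={})
    c = ld.generate_cohort(cfg)
    data = c.patients.copy()
    data["PCA_1"] = c.truth["pca_scores"][:, 0]
    data["PCA_2"] = c.truth["pca_scores"][:, 1]
    design = ld.build_design(data, ("age", "sex", "log_gtv", "PCA_1", "PCA_2"))
    fit = ld.fit_cox(design)
    true = {"age": 0.025, "sex[male]": 0.35, "log_gtv": 0.30,
            "PCA_1": 0.131, "PCA_2": -0.083}
    for name, b, s in zip(design.columns, fit.beta, fit.se):
        assert abs(b - true[name]) < 2 * s, name


def test_empty_covariate_set_gives_null_loglik():
    rng = np.random.default_rng(4)
    n = 25
    time = rng.exponential(10, n)
    event = (rng.random(n) < 0.8).astype(int)
    d = SurvivalDesign(np.empty((n, 0)), time, event, [], {})
    fit = ld.fit_cox(d)
    assert fit.loglik == pytest.approx(fit.null_loglik, abs=1e-12)
    assert fit.converged


def test_loglik_not_below_null(data300):
    design = ld.build_design(data300, ("age", "sex"))
    fit = ld.fit_cox(design)
    assert fit.loglik >= fit.null_loglik


def test_affine_rescaling_invariance(data300):
    design = ld.build_design(data300, ("age", "bmi"))
    fit = ld.fit_cox(design)
    scaled = SurvivalDesign(
        design.X * np.array([10.0, 0.25]), design.time, design.event,
        design.columns, design.term_map,
    )
    fit2 = ld.fit_cox(scaled)
    np.testing.assert_allclose(fit2.beta, fit.beta / np.array([10.0, 0.25]), rtol=1e-6)
    assert fit2.loglik == pytest.approx(fit.loglik, abs=1e-8)


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

def test_km_hand_computed_product_limit():
    km = ld.kaplan_meier([1, 2, 3, 4, 5], [1, 1, 1, 1, 1])
    assert km.evaluate(2.5)[0] == pytest.approx(0.6)
    assert km.evaluate(5.0)[0] == pytest.approx(0.0)
    assert km.evaluate(0.5)[0] == pytest.approx(1.0)


def test_km_no_events_flat():
    km = ld.kaplan_meier([3, 6, 9], [0, 0, 0])
    assert np.all(km.survival == 1.0)


def test_km_single_subject():
    km = ld.kaplan_meier([4.0], [1])
    assert km.evaluate(3.9)[0] == pytest.approx(1.0)
    assert km.evaluate(4.0)[0] == pytest.approx(0.0)


def test_km_monotone_right_continuous(cohort644):
    km = ld.kaplan_meier(cohort644.patients.time, cohort644.patients.event)
    assert np.all(np.diff(km.survival) <= 1e-12)
    assert km.evaluate(0.0)[0] == pytest.approx(1.0)
    assert np.all(km.ci_lower <= km.survival + 1e-12)
    assert np.all(km.ci_upper >= km.survival - 1e-12)


# ---------------------------------------------------------------------------
# reverse Kaplan-Meier follow-up
# ---------------------------------------------------------------------------

def test_reverse_km_all_censored():
    assert ld.reverse_km_median_followup([84, 84, 84], [0, 0, 0]) == pytest.approx(84)


def test_reverse_km_all_events_undefined():
    with pytest.warns(UserWarning):
        assert math.isnan(ld.reverse_km_median_followup([1, 2, 3], [1, 1, 1]))


def test_reverse_km_hand_computed():
    # censoring events at 5 and 9; at-risk 3 then 1:
    # S_inv(5) = 2/3, S_inv(9) = 0 -> median follow-up 9
    t = [3, 5, 7, 9]
    e = [1, 0, 1, 0]
    assert ld.reverse_km_median_followup(t, e) == pytest.approx(9.0)


# ---------------------------------------------------------------------------
# linear predictor
# ---------------------------------------------------------------------------

def test_linear_predictor_basics(data300):
    design = ld.build_design(data300, ("age",))
    assert np.all(ld.linear_predictor(design, [0.0]) == 0)
    lp = ld.linear_predictor(design, [0.3])
    assert np.array_equal(np.argsort(lp), np.argsort(design.X[:, 0]))


def test_per_patient_hr_is_exp_beta_score(data300):
    design = ld.build_design(data300, ("PCA_1",))
    beta = 0.131
    lp = ld.linear_predictor(design, [beta], center=False)
    np.testing.assert_allclose(np.exp(lp), np.exp(beta * design.X[:, 0]), rtol=1e-12)
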