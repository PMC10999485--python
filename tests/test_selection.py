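import numpy as np
import pandas as pd
import pytest

import lungdose as ld
from lungdose.cox import PreparedSurvival
from lungdose.selection import MIN_CI_BOOTSTRAPS, _subset_sort_key
from conftest import merge_scores


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------

def test_impute_complete_cohort_identity(cohort300):
    out = ld.impute(cohort300, seed=0)
    pd.testing.assert_frame_equal(out.patients, cohort300.patients)


def test_impute_fills_all_blanks_within_range(cohort644):
    out = ld.impute(cohort644, seed=0)
    assert out.patients["bmi"].notna().all()
    assert out.patients["pack_years"].notna().all()
    observed = cohort644.patients["bmi"].dropna()
    imputed_mask = cohort644.patients["bmi"].isna()
    imputed = out.patients.loc[imputed_mask, "bmi"]
    assert imputed.between(observed.min(), observed.max()).all()
    # observed values untouched
    keep = ~imputed_mask
    np.testing.assert_array_equal(
        out.patients.loc[keep, "bmi"], cohort644.patients.loc[keep, "bmi"]
    )


def test_impute_reproducible(cohort644):
    a = ld.impute(cohort644, seed=3).patients["bmi"]
    b = ld.impute(cohort644, seed=3).patients["bmi"]
    pd.testing.assert_series_equal(a, b)


def test_impute_error_below_marginal_sd(cohort644):
    """MCAR-blanked values are recovered with mean absolute error below the
    marginal SD (the regression pulls in correlated covariates)."""
    truth = cohort644.truth["complete_patients"]
    out = ld.impute(cohort644, seed=0)
    mask = cohort644.patients["bmi"].isna()
    mae = (out.patients.loc[mask, "bmi"] - truth.loc[mask, "bmi"]).abs().mean()
    assert mae < truth["bmi"].std(ddof=1)


def test_impute_rejects_missing_survival(cohort644):
    broken = cohort644.patients.copy()
    broken.iloc[0, broken.columns.get_loc("time")] = np.nan
    cohort = ld.Cohort(broken, cohort644.dvh, cohort644.structure_set)
    with pytest.raises(ValueError, match="mandatory"):
        ld.impute(cohort, seed=0)


# ---------------------------------------------------------------------------
# bootstrap splits
# ---------------------------------------------------------------------------

def test_split_shapes_and_determinism():
    a_in, a_out = ld.bootstrap_split(644, seed=5)
    b_in, b_out = ld.bootstrap_split(644, seed=5)
    assert a_in.size == 644
    assert a_out.size > 0
    assert np.array_equal(a_in, b_in) and np.array_equal(a_out, b_out)
    assert np.intersect1d(np.unique(a_in), a_out).size == 0


def test_unique_in_boot_fraction_approaches_632():
    fracs = [
        np.unique(ld.bootstrap_split(644, seed=s)[0]).size / 644
        for s in range(300)
    ]
    assert abs(np.mean(fracs) - (1 - np.exp(-1))) < 0.01


def test_tiny_n_out_of_boot_never_empty():
    for s in range(60):
        _, out = ld.bootstrap_split(2, seed=s)
        assert out.size >= 1


# ---------------------------------------------------------------------------
# cross-validated likelihood
# ---------------------------------------------------------------------------

def _strong_cohort(n=644, seed=0):
    cfg = ld.CohortConfig(
        n_patients=n, seed=seed, missing_counts={},
        true_betas={"age": 0.05, "sex": 0.8, "PCA_1": 0.4},
    )
    c = ld.generate_cohort(cfg)
    data = c.patients.copy()
    data["PCA_1"] = c.truth["pca_scores"][:, 0]
    return data


def test_null_subset_score_is_scaled_null_loglik():
    data = _strong_cohort(200, seed=1)
    design = ld.build_design(data, ("age",))
    in_idx, out_idx = ld.bootstrap_split(200, seed=0)
    score = ld.cv_likelihood(design.take(in_idx), design.take(out_idx), ())
    out_design = design.take(out_idx)
    expected = PreparedSurvival.from_design(out_design).fit(
        cols=np.array([], dtype=int)
    ).loglik / out_idx.size
    assert score == pytest.approx(expected, abs=1e-12)


def test_noise_covariate_does_not_improve_cv_score():
    data = _strong_cohort(644, seed=2)
    res = ld.best_subset_select(data, ("age", "sex", "PCA_1", "bmi"), B=50, seed=0)
    scores = res.per_split_scores
    subsets = list(res.score_table["subset"])
    i_true = subsets.index("age;sex;PCA_1")
    i_noise = subsets.index("age;sex;PCA_1;bmi")
    diff = scores[i_noise] - scores[i_true]
    assert diff.mean() < 2 * diff.std(ddof=1) / np.sqrt(diff.size)


def test_true_signal_beats_null_across_replicates():
    wins = 0
    for rep in range(8):
        data = _strong_cohort(644, seed=100 + rep)
        res = ld.best_subset_select(data, ("PCA_1",), B=10, seed=rep)
        table = res.score_table.set_index("subset")["mean_cv_loglik"]
        wins += table["PCA_1"] > table[""]
    assert wins >= 7


def test_failed_fit_scores_at_null(cohort300, data300):
    # a degenerate constant covariate cannot separate; selection still runs
    data = data300.copy()
    data["PCA_1"] = 0.0  # zero-variance column: fit is singular but converged at 0
    res = ld.best_subset_select(data, ("age", "PCA_1"), B=3, seed=0)
    assert res.score_table.shape[0] == 4


# ---------------------------------------------------------------------------
# best-subset selection
# ---------------------------------------------------------------------------

def test_enumerates_all_subsets():
    data = _strong_cohort(200, seed=3)
    res = ld.best_subset_select(
        data, ("age", "sex", "PCA_1", "bmi", "stage"), B=2, seed=0
    )
    assert len(res.score_table) == 2**5
    assert res.score_table["size"].max() == 5


def test_candidate_cap_enforced(data300):
    too_many = tuple(f"PCA_{k}" for k in range(1, 22))
    with pytest.raises(ValueError, match="screen"):
        ld.best_subset_select(data300, too_many, B=2, seed=0)


def test_selection_finds_planted_signal():
    data = _strong_cohort(644, seed=4)
    res = ld.best_subset_select(
        data, ("age", "sex", "PCA_1", "bmi", "pack_years", "stage"), B=10, seed=0
    )
    assert {"age", "sex", "PCA_1"} <= set(res.selected)


def test_selection_deterministic():
    data = _strong_cohort(300, seed=5)
    a = ld.best_subset_select(data, ("age", "sex", "PCA_1"), B=5, seed=7)
    b = ld.best_subset_select(data, ("age", "sex", "PCA_1"), B=5, seed=7)
    assert a.selected == b.selected
    np.testing.assert_array_equal(a.per_split_scores, b.per_split_scores)


def test_splits_are_paired_across_subsets():
    data = _strong_cohort(200, seed=6)
    res = ld.best_subset_select(data, ("age", "sex"), B=4, seed=1)
    # the recorded splits are the single source used for every subset
    assert len(res.splits) == 4
    redrawn = [ld.bootstrap_split(200, np.random.default_rng(
        np.random.SeedSequence([1, 10, b]))) for b in range(4)]
    for (i1, o1), (i2, o2) in zip(res.splits, redrawn):
        assert np.array_equal(i1, i2) and np.array_equal(o1, o2)


def test_tie_break_prefers_smaller_then_lexicographic():
    assert _subset_sort_key(("a",), 1.0) < _subset_sort_key(("a", "b"), 1.0)
    assert _subset_sort_key(("a",), 1.0) < _subset_sort_key(("b",), 1.0)
    assert _subset_sort_key(("a", "b"), 2.0) < _subset_sort_key(("a",), 1.0)


def test_full_data_loglik_monotone_in_nested_subsets(data300):
    chain = [(), ("age",), ("age", "sex"), ("age", "sex", "bmi"),
             ("age", "sex", "bmi", "PCA_1")]
    lls = []
    for units in chain:
        design = ld.build_design(data300, units)
        lls.append(ld.fit_cox(design).loglik)
    assert all(b >= a - 1e-9 for a, b in zip(lls, lls[1:]))


# ---------------------------------------------------------------------------
# bootstrap confidence intervals
# ---------------------------------------------------------------------------

def test_ci_minimum_bootstraps_guard(data300):
    with pytest.raises(ValueError, match=str(MIN_CI_BOOTSTRAPS)):
        ld.bootstrap_ci(data300, ("age",), B=2, seed=0)


def test_ci_table_ordered_and_reproducible(data300):
    a = ld.bootstrap_ci(data300, ("age", "sex"), B=120, seed=0)
    b = ld.bootstrap_ci(data300, ("age", "sex"), B=120, seed=0)
    assert (a["beta_ci_low"] <= a["beta_ci_high"]).all()
    assert (a["hr_ci_low"] <= a["hr_ci_high"]).all()
    pd.testing.assert_frame_equal(a, b)
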