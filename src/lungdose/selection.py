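"""Bootstrap cross-validated best-subset selection for the Cox survival model.

The selection procedure: impute missing covariates once (before any
bootstrap), draw B bootstrap resamples, fit every candidate subset on each
in-boot sample and score it by the out-of-boot log partial likelihood at the
in-boot coefficients, corrected for (divided by) the number of out-of-boot
patients; average over the B resamples and pick the subset with the highest
mean score.  Every subset is evaluated on the *same* B splits so subset
comparisons are paired.  Confidence intervals for the selected model are
percentile bootstrap over refits.

Cross-validation score variants:

``mean_oob`` (default)
    mean per-patient out-of-boot log partial likelihood,
    ``loglik_oob(beta_in) / n_oob`` — comparable across splits with
    different out-of-boot sizes.
``vvh``
    the Verweij-van Houwelingen cross-validated likelihood,
    ``(loglik_full(beta_in) - loglik_in(beta_in)) / n_oob``, which
    evaluates the held-out contribution within the full risk sets.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.experimental import enable_iterative_imputer  # noqa: F401
from sklearn.impute import IterativeImputer

from .cox import CoxFit, PreparedSurvival, SurvivalDesign, build_design
from .dvh import CATEGORICAL_LEVELS, Cohort
from .synthetic import IMPUTABLE_FIELDS

logger = logging.getLogger(__name__)

MAX_CANDIDATES = 20
MIN_CI_BOOTSTRAPS = 100


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------

def impute(cohort: Cohort, seed: int = 0) -> Cohort:
    """Chained-equations regression imputation, single completed dataset.

    Only BMI and pack-years may be missing; observed values are never
    altered, imputed values are constrained to the observed range, and the
    result is reproducible from the seed.  The imputation model regresses
    each incomplete variable on the other covariates (categoricals as
    numeric codes); outcome columns are not used.
    """
    patients = cohort.patients
    mandatory = [c for c in patients.columns if c not in IMPUTABLE_FIELDS]
    bad = patients[mandatory].isna().any()
    if bad.any():
        raise ValueError(
            f"missing values in mandatory field(s) {list(bad[bad].index)}"
        )
    if not patients[list(IMPUTABLE_FIELDS)].isna().any().any():
        return cohort

    work = pd.DataFrame(index=patients.index)
    for col in ("age", "bmi", "pack_years", "eqd2", "log_gtv"):
        work[col] = patients[col].astype(float)
    for col, levels in CATEGORICAL_LEVELS.items():
        work[col] = patients[col].map({lv: i for i, lv in enumerate(levels)}).astype(float)
    work["cardiac_risk_factor"] = patients["cardiac_risk_factor"].astype(float)

    obs_min = work.min(skipna=True).to_numpy()
    obs_max = work.max(skipna=True).to_numpy()
    imputer = IterativeImputer(
        random_state=int(seed) % (2**31), sample_posterior=False,
        max_iter=20, min_value=obs_min, max_value=obs_max,
    )
    completed = imputer.fit_transform(work.to_numpy())
    out = patients.copy()
    for col in IMPUTABLE_FIELDS:
        j = work.columns.get_loc(col)
        mask = patients[col].isna()
        out.loc[mask, col] = completed[mask.to_numpy(), j]
    return Cohort(
        patients=out, dvh=cohort.dvh,
        structure_set=cohort.structure_set, truth=cohort.truth,
    )


# ---------------------------------------------------------------------------
# bootstrap machinery
# ---------------------------------------------------------------------------

def bootstrap_split(
    n: int, seed: int | np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """One bootstrap resample: in-boot multiset of size n (with replacement)
    and the out-of-boot complement of the unique in-boot ids.  An empty
    out-of-boot set (possible at tiny n) triggers a logged redraw."""
    if n < 2:
        raise ValueError("bootstrap_split requires n >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    for _ in range(1000):
        in_boot = rng.integers(0, n, size=n)
        out_boot = np.setdiff1d(np.arange(n), in_boot)
        if out_boot.size:
            return in_boot, out_boot
        logger.info("empty out-of-boot set at n=%d; redrawing", n)
    raise RuntimeError("could not draw a split with a non-empty out-of-boot set")


def _split_rng(master_seed: int, index: int) -> np.random.Generator:
    # counter-derived substreams: changing B or subset order never reshuffles
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), 10, int(index)]))


@dataclass
class _Split:
    in_boot: np.ndarray
    out_boot: np.ndarray
    prep_in: PreparedSurvival
    prep_out: PreparedSurvival
    prep_full: PreparedSurvival | None
    null_score: float


def _make_splits(
    design: SurvivalDesign, B: int, seed: int, cv_method: str
) -> list[_Split]:
    prep_full = PreparedSurvival.from_design(design) if cv_method == "vvh" else None
    splits: list[_Split] = []
    for b in range(B):
        in_idx, out_idx = bootstrap_split(design.n, _split_rng(seed, b))
        prep_in = PreparedSurvival.from_design(design.take(in_idx))
        prep_out = PreparedSurvival.from_design(design.take(out_idx))
        null_beta = np.zeros(0)
        null = _cv_score_from_parts(
            prep_in, prep_out, prep_full, np.zeros(design.X.shape[1])[:0],
            np.array([], dtype=int), cv_method,
        )
        splits.append(_Split(in_idx, out_idx, prep_in, prep_out, prep_full, null))
    return splits


def _cv_score_from_parts(
    prep_in: PreparedSurvival,
    prep_out: PreparedSurvival,
    prep_full: PreparedSurvival | None,
    beta: np.ndarray,
    cols: np.ndarray,
    cv_method: str,
) -> float:
    n_out = prep_out.n
    if cv_method == "mean_oob":
        return prep_out.loglik(beta, cols) / n_out
    elif cv_method == "vvh":
        assert prep_full is not None
        return (prep_full.loglik(beta, cols) - prep_in.loglik(beta, cols)) / n_out
    raise ValueError(f"unknown cv_method {cv_method!r}")


def cv_likelihood(
    in_design: SurvivalDesign,
    out_design: SurvivalDesign,
    subset: tuple[str, ...] | list[str],
    cv_method: str = "mean_oob",
    full_design: SurvivalDesign | None = None,
) -> float:
    """Cross-validated score of one subset on one split: fit on in-boot,
    evaluate out-of-boot at the in-boot coefficients, divide by the number
    of out-of-boot patients.  A failed in-boot fit returns NaN (the caller
    substitutes the null-model score for that split)."""
    cols = in_design.subset_columns(tuple(subset))
    prep_in = PreparedSurvival.from_design(in_design)
    fit = prep_in.fit(cols)
    if not fit.converged:
        return float("nan")
    prep_out = PreparedSurvival.from_design(out_design)
    prep_full = (
        PreparedSurvival.from_design(full_design)
        if (cv_method == "vvh" and full_design is not None) else None
    )
    return _cv_score_from_parts(prep_in, prep_out, prep_full, fit.beta, cols, cv_method)


# ---------------------------------------------------------------------------
# best-subset selection
# ---------------------------------------------------------------------------

@dataclass
class SelectionResult:
    candidates: tuple[str, ...]
    score_table: pd.DataFrame          # subset, size, mean_cv_loglik
    per_split_scores: np.ndarray       # (n_subsets, B)
    selected: tuple[str, ...]
    final_fit: CoxFit
    splits: list[tuple[np.ndarray, np.ndarray]]
    cv_method: str
    n_failed_fits: int
    seed: int

    @property
    def selected_score(self) -> float:
        return float(self.score_table["mean_cv_loglik"].max())


def _subset_sort_key(subset: tuple[str, ...], score: float):
    # argmax of score; ties: smaller subset wins, then lexicographic
    return (-score, len(subset), subset)


def best_subset_select(
    data: pd.DataFrame,
    candidates: list[str] | tuple[str, ...],
    B: int = 50,
    seed: int = 0,
    cv_method: str = "mean_oob",
) -> SelectionResult:
    """Exhaustive best-subset selection by paired bootstrap cross-validation.

    `data` is a complete patients table (PCA score columns merged in).
    All 2^k subsets of the candidate units are scored on the same B splits;
    the subset maximizing the mean corrected CV likelihood wins, refitted on
    the full data.  Cost doubles per candidate, hence the hard cap.
    """
    candidates = tuple(candidates)
    if len(set(candidates)) != len(candidates):
        raise ValueError("candidate unit names must be unique")
    if len(candidates) > MAX_CANDIDATES:
        raise ValueError(
            f"{len(candidates)} candidates would require 2^{len(candidates)} "
            "subset fits; screen the candidate set first"
        )
    design = build_design(data, candidates)
    splits = _make_splits(design, B, seed, cv_method)

    subsets = [
        tuple(c for c in candidates if c in comb)
        for r in range(len(candidates) + 1)
        for comb in map(set, itertools.combinations(candidates, r))
    ]
    n_sub = len(subsets)
    scores = np.empty((n_sub, B))
    n_failed = 0
    for b, sp in enumerate(splits):
        for i, subset in enumerate(subsets):
            cols = design.subset_columns(subset)
            if cols.size == 0:
                scores[i, b] = sp.null_score
                continue
            fit = sp.prep_in.fit(cols)
            if not fit.converged:
                n_failed += 1
                scores[i, b] = sp.null_score  # penalize unstable subsets
                continue
            scores[i, b] = _cv_score_from_parts(
                sp.prep_in, sp.prep_out, sp.prep_full, fit.beta, cols, cv_method
            )
        logger.info(
            "bootstrap %d/%d: evaluated %d subsets (%d candidates)",
            b + 1, B, n_sub, len(candidates),
        )
    mean_scores = scores.mean(axis=1)
    order = sorted(
        range(n_sub), key=lambda i: _subset_sort_key(subsets[i], mean_scores[i])
    )
    best = subsets[order[0]]
    table = pd.DataFrame({
        "subset": [";".join(s) for s in subsets],
        "size": [len(s) for s in subsets],
        "mean_cv_loglik": mean_scores,
    })
    final_design = build_design(data, best) if best else build_design(data, ())
    final_fit = PreparedSurvival.from_design(final_design).fit()
    final_fit.columns = list(final_design.columns)
    return SelectionResult(
        candidates=candidates,
        score_table=table,
        per_split_scores=scores,
        selected=best,
        final_fit=final_fit,
        splits=[(sp.in_boot, sp.out_boot) for sp in splits],
        cv_method=cv_method,
        n_failed_fits=n_failed,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# bootstrap confidence intervals
# ---------------------------------------------------------------------------

def bootstrap_ci(
    data: pd.DataFrame,
    units: list[str] | tuple[str, ...],
    B: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Percentile bootstrap 95% CIs for the selected model's coefficients.

    B in-boot refits; the 2.5th/97.5th percentiles of each coefficient give
    the CI, reported on both the log-hazard and hazard-ratio scales.
    Non-converged refits are dropped and counted (`n_dropped` attr).
    """
    units = tuple(units)
    if B < MIN_CI_BOOTSTRAPS:
        raise ValueError(f"B must be >= {MIN_CI_BOOTSTRAPS}, got {B}")
    design = build_design(data, units)
    point = PreparedSurvival.from_design(design).fit()
    betas = np.full((B, design.X.shape[1]), np.nan)
    n_dropped = 0
    for b in range(B):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 20, b]))
        idx = rng.integers(0, design.n, size=design.n)
        sub = design.take(idx)
        if sub.event.sum() == 0:
            n_dropped += 1
            continue
        fit = PreparedSurvival.from_design(sub).fit(beta0=point.beta)
        if fit.converged:
            betas[b] = fit.beta
        else:
            n_dropped += 1
    ok = ~np.isnan(betas).any(axis=1)
    lo, hi = np.percentile(betas[ok], [2.5, 97.5], axis=0)
    out = pd.DataFrame({
        "term": design.columns,
        "beta": point.beta,
        "hr": np.exp(point.beta),
        "beta_ci_low": lo,
        "beta_ci_high": hi,
        "hr_ci_low": np.exp(lo),
        "hr_ci_high": np.exp(hi),
    })
    out.attrs["n_dropped"] = n_dropped
    out.attrs["B"] = B
    return out
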