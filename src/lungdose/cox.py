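"""Cox proportional-hazards core.

Implements the log partial likelihood (Efron tie handling, exact when event
times are unique), its gradient and observed information in fully vectorized
form, a Newton fitter with step halving, the Breslow baseline cumulative
hazard, and Kaplan-Meier / reverse Kaplan-Meier estimators (via lifelines).

The partial likelihood must be evaluable at arbitrary coefficients on data
the model was *not* fitted to: the bootstrap cross-validation machinery
scores out-of-boot patients at in-boot coefficients, so evaluation and
fitting are deliberately separate entry points.  `PreparedSurvival` caches
the time-ordering and tie structure of one data set so that the best-subset
loop can fit thousands of column subsets without re-sorting.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .dvh import CATEGORICAL_LEVELS

# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------
# Candidate units expand to reference-coded indicator columns; a categorical
# factor's indicators always enter and leave a model together.  Reference
# levels: female, PS 0-1, stage <=IIB, CACS 0, no baseline cardiac disease,
# no cardiac risk factor.

_INDICATOR_UNITS: dict[str, tuple[str, tuple[str, ...]]] = {
    # unit -> (source column, non-reference levels)
    "sex": ("sex", ("male",)),
    "ps": ("performance_status", (">=2",)),
    "stage": ("stage", (">=IIIA",)),
    "cacs_group": ("cacs_group", ("1-99", "100-399", ">=400")),
    "baseline_cardiac": ("baseline_cardiac", ("arrhythmia", "other")),
}
_CONTINUOUS_UNITS = ("age", "bmi", "eqd2", "log_gtv", "pack_years")

#: Clinical candidate units in the order they are reported.
CLINICAL_UNITS: tuple[str, ...] = (
    "age", "bmi", "sex", "ps", "eqd2", "log_gtv", "pack_years", "stage",
    "cacs_group", "baseline_cardiac", "cardiac_risk_factor",
)


@dataclass
class SurvivalDesign:
    """Expanded covariate matrix with outcome, ready for the Cox engine."""

    X: np.ndarray               # (n, p) float, no missing values
    time: np.ndarray            # (n,) months
    event: np.ndarray           # (n,) 0/1
    columns: list[str]
    term_map: dict[str, list[int]]  # unit -> its column indices

    def __post_init__(self) -> None:
        if np.isnan(self.X).any():
            raise ValueError("design matrix contains missing values; impute first")
        if int(self.event.sum()) < 1:
            raise ValueError("design has no events")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    def subset_columns(self, units: tuple[str, ...] | list[str]) -> np.ndarray:
        cols: list[int] = []
        for u in units:
            cols.extend(self.term_map[u])
        return np.asarray(cols, dtype=int)

    def take(self, idx: np.ndarray) -> "SurvivalDesign":
        return SurvivalDesign(
            self.X[idx], self.time[idx], self.event[idx],
            list(self.columns), dict(self.term_map),
        )


def build_design(data: pd.DataFrame, units: list[str] | tuple[str, ...]) -> SurvivalDesign:
    """Expand candidate units from a complete patients table (with any PCA
    score columns already merged in) into a SurvivalDesign."""
    cols: list[np.ndarray] = []
    names: list[str] = []
    term_map: dict[str, list[int]] = {}
    for unit in units:
        start = len(names)
        if unit in _CONTINUOUS_UNITS or unit.startswith("PCA_"):
            cols.append(data[unit].to_numpy(dtype=float))
            names.append(unit)
        elif unit == "cardiac_risk_factor":
            cols.append(data[unit].to_numpy(dtype=float))
            names.append("cardiac_risk_factor[yes]")
        elif unit in _INDICATOR_UNITS:
            src, levels = _INDICATOR_UNITS[unit]
            vals = data[src]
            known = CATEGORICAL_LEVELS[src]
            bad = ~vals.isin(known)
            if bad.any():
                raise ValueError(f"unknown level in column {src!r}")
            for lv in levels:
                cols.append((vals == lv).to_numpy(dtype=float))
                names.append(f"{unit}[{lv}]")
        else:
            raise KeyError(f"unknown candidate unit {unit!r}")
        term_map[unit] = list(range(start, len(names)))
    X = np.column_stack(cols) if cols else np.empty((len(data), 0))
    return SurvivalDesign(
        X=X,
        time=data["time"].to_numpy(dtype=float),
        event=data["event"].to_numpy(dtype=int),
        columns=names,
        term_map=term_map,
    )


# ---------------------------------------------------------------------------
# Efron partial likelihood
# ---------------------------------------------------------------------------

class PreparedSurvival:
    """Time-sorted survival data with precomputed tie structure.

    Caches everything that depends only on (time, event) so that repeated
    likelihood/fit calls on column subsets of the same data are cheap.
    """

    def __init__(self, X: np.ndarray, time: np.ndarray, event: np.ndarray):
        time = np.asarray(time, dtype=float)
        event = np.asarray(event, dtype=int)
        if event.sum() < 1:
            raise ValueError("no events in survival data")
        order = np.argsort(time, kind="stable")
        self.Xs = np.ascontiguousarray(np.asarray(X, dtype=float)[order])
        self.ts = time[order]
        self.ev = event[order]
        self.n = self.ts.size
        self.ev_idx = np.flatnonzero(self.ev == 1)
        et = self.ts[self.ev_idx]
        ut, starts, d = np.unique(et, return_index=True, return_counts=True)
        self.tie_starts = starts            # into ev_idx
        self.d = d                          # events per unique event time
        self.unique_event_times = ut
        # first index (in sorted order) of the risk set of each event time
        self.risk_start = np.searchsorted(self.ts, ut, side="left")
        # Efron fractions l/d for each individual event, grouped by tie set
        within = np.arange(et.size) - np.repeat(starts, d)
        self.frac = within / np.repeat(d, d)
        self.rep = np.repeat(np.arange(ut.size), d)

    @classmethod
    def from_design(cls, design: SurvivalDesign) -> "PreparedSurvival":
        return cls(design.X, design.time, design.event)

    def _terms(self, beta: np.ndarray, cols: np.ndarray | None, order: int):
        X = self.Xs if cols is None else self.Xs[:, cols]
        p = X.shape[1]
        eta = X @ beta if p else np.zeros(self.n)
        shift = eta.max() if p else 0.0
        w = np.exp(eta - shift)
        ev_idx = self.ev_idx
        # risk-set reverse cumulative sums
        R0 = np.cumsum(w[::-1])[::-1]
        s0 = np.add.reduceat(w[ev_idx], self.tie_starts)
        phi = R0[self.risk_start][self.rep] - self.frac * s0[self.rep]
        n_e = ev_idx.size
        loglik = float(eta[ev_idx].sum() - n_e * shift - np.log(phi).sum())
        if order == 0 or p == 0:
            if order == 0:
                return loglik
            z = np.zeros(p)
            return loglik, z, np.zeros((p, p))
        wX = w[:, None] * X
        R1 = np.cumsum(wX[::-1], axis=0)[::-1]
        s1 = np.add.reduceat(wX[ev_idx], self.tie_starts, axis=0)
        num1 = R1[self.risk_start][self.rep] - self.frac[:, None] * s1[self.rep]
        ratio1 = num1 / phi[:, None]
        grad = X[ev_idx].sum(axis=0) - ratio1.sum(axis=0)
        if order == 1:
            return loglik, grad
        wXX = wX[:, :, None] * X[:, None, :]
        R2 = np.cumsum(wXX[::-1], axis=0)[::-1]
        s2 = np.add.reduceat(wXX[ev_idx], self.tie_starts, axis=0)
        num2 = R2[self.risk_start][self.rep] - self.frac[:, None, None] * s2[self.rep]
        info = (
            num2 / phi[:, None, None]
            - ratio1[:, :, None] * ratio1[:, None, :]
        ).sum(axis=0)
        return loglik, grad, info

    def loglik(self, beta: np.ndarray, cols: np.ndarray | None = None) -> float:
        return self._terms(np.asarray(beta, dtype=float), cols, order=0)

    def fit(
        self,
        cols: np.ndarray | None = None,
        max_iter: int = 100,
        tol: float = 1e-7,
        beta0: np.ndarray | None = None,
    ) -> "CoxFit":
        p = self.Xs.shape[1] if cols is None else len(cols)
        beta = np.zeros(p) if beta0 is None else np.asarray(beta0, dtype=float).copy()
        null_ll = self.loglik(np.zeros(p), cols)
        ll, grad, info = self._terms(beta, cols, order=2)
        converged = False
        n_iter = 0
        for n_iter in range(1, max_iter + 1):
            if p == 0 or np.max(np.abs(grad)) < tol:
                converged = True
                break
            try:
                step = np.linalg.solve(info, grad)
            except np.linalg.LinAlgError:
                step, *_ = np.linalg.lstsq(info, grad, rcond=None)
            # step halving on likelihood decrease
            new_beta = beta + step
            new = self._terms(new_beta, cols, order=2)
            halvings = 0
            while new[0] < ll - 1e-12 and halvings < 30:
                step = step / 2.0
                new_beta = beta + step
                new = self._terms(new_beta, cols, order=2)
                halvings += 1
            beta, (ll, grad, info) = new_beta, new
            if np.max(np.abs(beta)) > 200:  # monotone likelihood / separation
                break
        else:
            n_iter = max_iter
        if p and np.max(np.abs(grad)) < tol:
            converged = True
        cov = np.full((p, p), np.nan)
        se = np.full(p, np.nan)
        if p:
            try:
                cov = np.linalg.inv(info)
                se = np.sqrt(np.clip(np.diag(cov), 0, None))
            except np.linalg.LinAlgError:
                converged = False
        names = None if cols is None else list(cols)
        return CoxFit(
            beta=beta, se=se, cov=cov, loglik=ll, null_loglik=null_ll,
            converged=bool(converged), n_events=int(self.ev.sum()),
            n_iter=n_iter, columns=names,
        )


@dataclass
class CoxFit:
    beta: np.ndarray
    se: np.ndarray
    cov: np.ndarray
    loglik: float
    null_loglik: float
    converged: bool
    n_events: int
    n_iter: int
    columns: list | None = None

    def to_dict(self) -> dict:
        return {
            "beta": self.beta.tolist(),
            "se": self.se.tolist(),
            "loglik": self.loglik,
            "null_loglik": self.null_loglik,
            "converged": self.converged,
            "n_events": self.n_events,
            "n_iter": self.n_iter,
        }


def log_partial_likelihood(design: SurvivalDesign, beta: np.ndarray) -> float:
    """Efron-approximation log partial likelihood at arbitrary coefficients;
    exact partial likelihood when event times are unique."""
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (design.X.shape[1],):
        raise ValueError(
            f"beta length {beta.size} does not match {design.X.shape[1]} columns"
        )
    return PreparedSurvival.from_design(design).loglik(beta)


def fit_cox(design: SurvivalDesign, max_iter: int = 100, tol: float = 1e-7) -> CoxFit:
    """Maximum partial likelihood via Newton iteration with step halving."""
    p = design.X.shape[1]
    if design.event.sum() < p:
        warnings.warn(
            f"only {int(design.event.sum())} events for {p} coefficients; "
            "fit may be unstable",
            stacklevel=2,
        )
    fit = PreparedSurvival.from_design(design).fit(max_iter=max_iter, tol=tol)
    fit.columns = list(design.columns)
    return fit


def linear_predictor(
    design: SurvivalDesign, beta: np.ndarray, center: bool = True
) -> np.ndarray:
    """X.beta per patient; centered by default (the centering constant is
    irrelevant to risk ranking and cancels against the baseline)."""
    lp = design.X @ np.asarray(beta, dtype=float)
    return lp - lp.mean() if center else lp


# ---------------------------------------------------------------------------
# Kaplan-Meier estimators (lifelines)
# ---------------------------------------------------------------------------

@dataclass
class KMCurve:
    times: np.ndarray
    survival: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray

    def evaluate(self, t) -> np.ndarray:
        """Right-continuous step evaluation S(t)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(self.times, t, side="right") - 1
        out = np.where(idx >= 0, self.survival[np.clip(idx, 0, None)], 1.0)
        return out

    @property
    def median(self) -> float:
        below = np.flatnonzero(self.survival <= 0.5)
        return float(self.times[below[0]]) if below.size else math.inf


def kaplan_meier(time, event, alpha: float = 0.05) -> KMCurve:
    """Product-limit survival estimate with Greenwood-based log-log CIs."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    kmf = KaplanMeierFitter(alpha=alpha)
    kmf.fit(time, event_observed=event)
    sf = kmf.survival_function_
    ci = kmf.confidence_interval_
    return KMCurve(
        times=sf.index.to_numpy(dtype=float),
        survival=sf.iloc[:, 0].to_numpy(dtype=float),
        ci_lower=ci.iloc[:, 0].to_numpy(dtype=float),
        ci_upper=ci.iloc[:, 1].to_numpy(dtype=float),
    )


def reverse_km_median_followup(time, event) -> float:
    """Median follow-up by the reverse Kaplan-Meier method (censoring
    indicator inverted).  Undefined (NaN, with a warning) when there are no
    censored observations."""
    event = np.asarray(event, dtype=int)
    if np.all(event == 1):
        warnings.warn(
            "no censored observations; reverse-KM follow-up undefined",
            stacklevel=2,
        )
        return math.nan
    kmf = KaplanMeierFitter()
    kmf.fit(np.asarray(time, dtype=float), event_observed=1 - event)
    return float(kmf.median_survival_time_)


# ---------------------------------------------------------------------------
# baseline hazard and survival prediction
# ---------------------------------------------------------------------------

def breslow_baseline(design: SurvivalDesign, beta: np.ndarray):
    """Breslow estimate of the baseline cumulative hazard H0 at the unique
    event times (uncentered linear predictor convention)."""
    prep = PreparedSurvival.from_design(design)
    eta = (prep.Xs @ np.asarray(beta, dtype=float)) if design.X.shape[1] else np.zeros(prep.n)
    shift = eta.max()
    w = np.exp(eta - shift)
    R0 = np.cumsum(w[::-1])[::-1]
    dh = prep.d / (R0[prep.risk_start] * np.exp(shift))
    return prep.unique_event_times, np.cumsum(dh)


def predicted_survival(
    design: SurvivalDesign, beta: np.ndarray, times: np.ndarray,
    baseline: tuple[np.ndarray, np.ndarray] | None = None,
) -> np.ndarray:
    """Per-patient predicted survival S_i(t) = exp(-H0(t) e^{x_i.beta}) on a
    time grid; returns an (n, len(times)) array."""
    if baseline is None:
        baseline = breslow_baseline(design, beta)
    bt, bh = baseline
    times = np.asarray(times, dtype=float)
    idx = np.searchsorted(bt, times, side="right") - 1
    H0 = np.where(idx >= 0, bh[np.clip(idx, 0, None)], 0.0)
    lp = design.X @ np.asarray(beta, dtype=float) if design.X.shape[1] else np.zeros(design.n)
    return np.exp(-np.outer(np.exp(lp), H0))
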