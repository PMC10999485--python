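"""Risk-group calibration and interpretation tables.

Patients are split into low/mid/high risk tertile groups at the 25th and
75th percentiles of the fitted linear predictor; within each group the
observed Kaplan-Meier curve is compared with the model-predicted survival
(Breslow baseline times exp(linear predictor), averaged over the group's
patients) and a percentile bootstrap band around the model curve.  The
module also builds the forest table (univariable and multivariable hazard
ratios, per unit and per score-SD) and the per-patient tumor-position /
hazard table (HR = exp(beta_k * score_k) for each dose-pattern component).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cox import (
    KMCurve,
    PreparedSurvival,
    SurvivalDesign,
    breslow_baseline,
    build_design,
    kaplan_meier,
    predicted_survival,
)

GROUP_ORDER = ("low", "mid", "high")


def assign_risk_groups(linear_predictors: np.ndarray) -> np.ndarray:
    """Label each patient low/mid/high by the 25th/75th percentiles of the
    linear predictor (linear-interpolation percentiles).  Values exactly on
    a threshold fall into the middle group, so a constant cohort is all mid."""
    lp = np.asarray(linear_predictors, dtype=float)
    if lp.size < 4:
        raise ValueError("risk grouping requires at least 4 patients")
    q25, q75 = np.percentile(lp, [25.0, 75.0])  # type-7 linear interpolation
    groups = np.full(lp.size, "mid", dtype=object)
    groups[lp < q25] = "low"
    groups[lp > q75] = "high"
    return groups


@dataclass
class CalibrationReport:
    groups: np.ndarray                  # per-patient labels
    time_grid: np.ndarray
    observed: dict[str, KMCurve]        # per-group Kaplan-Meier
    model: dict[str, np.ndarray]        # per-group mean predicted survival
    band_low: dict[str, np.ndarray]
    band_high: dict[str, np.ndarray]
    B: int

    @property
    def present_groups(self) -> tuple[str, ...]:
        return tuple(g for g in GROUP_ORDER if g in self.model)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g in self.present_groups:
            obs = self.observed[g].evaluate(self.time_grid)
            for i, t in enumerate(self.time_grid):
                rows.append({
                    "time": t, "group": g,
                    "observed_km": obs[i],
                    "model_survival": self.model[g][i],
                    "band_low": self.band_low[g][i],
                    "band_high": self.band_high[g][i],
                })
        return pd.DataFrame(rows)

    def within_band_fraction(self) -> dict[str, float]:
        """Fraction of grid times at which the observed KM lies inside the
        model band, per group."""
        out = {}
        for g in self.present_groups:
            obs = self.observed[g].evaluate(self.time_grid)
            inside = (obs >= self.band_low[g] - 1e-12) & (obs <= self.band_high[g] + 1e-12)
            out[g] = float(inside.mean())
        return out


def calibration(
    design: SurvivalDesign,
    beta: np.ndarray,
    B: int = 2000,
    seed: int = 0,
    time_grid: np.ndarray | None = None,
    groups: np.ndarray | None = None,
) -> CalibrationReport:
    """Risk-tertile calibration of a fitted Cox model.

    The group model curve is the mean of the patient-level predicted
    survival curves within the group.  The band is the 2.5th/97.5th
    percentile envelope over B bootstrap refits of the same model (selection
    held fixed), with the point prediction included in the envelope so the
    band always contains it.  `groups` overrides the default assignment
    (needed e.g. for a null model whose linear predictor is constant and
    would put everyone in the middle group).
    """
    beta = np.asarray(beta, dtype=float)
    lp = design.X @ beta if design.X.shape[1] else np.zeros(design.n)
    if groups is None:
        groups = assign_risk_groups(lp)
    if time_grid is None:
        tmax = float(design.time.max())
        time_grid = np.linspace(0.0, tmax, 61)
    masks = {g: groups == g for g in GROUP_ORDER if np.any(groups == g)}

    point = predicted_survival(design, beta, time_grid)
    model_curves = {g: point[m].mean(axis=0) for g, m in masks.items()}
    observed = {
        g: kaplan_meier(design.time[m], design.event[m]) for g, m in masks.items()
    }

    boot = {g: [model_curves[g]] for g in masks}
    for b in range(B):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 30, b]))
        idx = rng.integers(0, design.n, size=design.n)
        sub = design.take(idx)
        if sub.event.sum() == 0:
            continue
        fit = PreparedSurvival.from_design(sub).fit(beta0=beta)
        if not fit.converged:
            continue
        base = breslow_baseline(sub, fit.beta)
        curves = predicted_survival(design, fit.beta, time_grid, baseline=base)
        for g, m in masks.items():
            boot[g].append(curves[m].mean(axis=0))
    band_low, band_high = {}, {}
    for g in masks:
        arr = np.vstack(boot[g])
        band_low[g] = np.percentile(arr, 2.5, axis=0)
        band_high[g] = np.percentile(arr, 97.5, axis=0)
    return CalibrationReport(
        groups=groups, time_grid=time_grid, observed=observed,
        model=model_curves, band_low=band_low, band_high=band_high, B=B,
    )


def hr_position_table(
    scores: np.ndarray,
    geometry: pd.DataFrame,
    betas: dict[str, float],
) -> pd.DataFrame:
    """Per-patient tumor-position table with component scores and hazard
    ratios HR_k = exp(beta_k * score_k), long over components.

    `betas` maps component names ("PCA_1", ...) to their fitted per-unit
    log-hazard coefficients; a zero coefficient gives HR 1 for everyone.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    rows = []
    for name, beta in betas.items():
        k = int(name.split("_")[1]) - 1
        sc = scores[:, k]
        rows.append(pd.DataFrame({
            "x_lr": geometry["x_lr"].to_numpy(),
            "y_cc": geometry["y_cc"].to_numpy(),
            "gtv_volume": geometry["gtv_volume"].to_numpy(),
            "component": name,
            "score": sc,
            "hr": np.exp(beta * sc),
        }))
    return pd.concat(rows, ignore_index=True)


def forest_table(
    data: pd.DataFrame,
    units: list[str] | tuple[str, ...],
    selected: tuple[str, ...],
    sd_map: dict[str, float] | None = None,
    ci_overrides: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Long forest-plot table: per-term HR with 95% CI, univariable and
    multivariable, on the per-unit scale and (for dose-pattern components)
    per one cohort SD of the score.

    CIs are Wald (beta +- 1.96 se) unless `ci_overrides` (the bootstrap CI
    table for the multivariable model) provides percentile bounds per term.
    """
    sd_map = sd_map or {}
    rows: list[dict] = []

    def add_rows(fit_cols, beta, lo, hi, model_label):
        for name, b, l, h in zip(fit_cols, beta, lo, hi):
            unit = name.split("[")[0]
            rows.append({
                "term": name, "model": model_label, "scale": "per-unit",
                "hr": float(np.exp(b)),
                "ci_low": float(np.exp(l)), "ci_high": float(np.exp(h)),
            })
            if unit in sd_map:
                sd = sd_map[unit]
                rows.append({
                    "term": name, "model": model_label, "scale": "per-SD",
                    "hr": float(np.exp(b * sd)),
                    "ci_low": float(np.exp(min(l * sd, h * sd))),
                    "ci_high": float(np.exp(max(l * sd, h * sd))),
                })

    for unit in units:
        design = build_design(data, (unit,))
        fit = PreparedSurvival.from_design(design).fit()
        lo = fit.beta - 1.96 * fit.se
        hi = fit.beta + 1.96 * fit.se
        add_rows(design.columns, fit.beta, lo, hi, "univariable")

    if selected:
        design = build_design(data, tuple(selected))
        fit = PreparedSurvival.from_design(design).fit()
        lo = fit.beta - 1.96 * fit.se
        hi = fit.beta + 1.96 * fit.se
        if ci_overrides is not None:
            ci = ci_overrides.set_index("term")
            for i, name in enumerate(design.columns):
                if name in ci.index:
                    lo[i] = ci.loc[name, "beta_ci_low"]
                    hi[i] = ci.loc[name, "beta_ci_high"]
        add_rows(design.columns, fit.beta, lo, hi, "multivariable")
    return pd.DataFrame(rows)
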