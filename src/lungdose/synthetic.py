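"""Synthetic lung-cancer radiotherapy cohorts with known ground truth.

Emulates a national-registry cohort of locally advanced NSCLC patients
treated with definitive radiotherapy: clinical covariates, a scaled tumor
position inside a lung bounding box, per-structure cumulative DVHs driven by
that position, proportional-hazards overall survival whose linear predictor
uses the cohort's *own* dose-pattern PCA scores, right censoring tuned to a
target rate, and MCAR missingness in BMI and pack-years.

Dose model
----------
Each structure's cumulative DVH is a logistic curve in dose,
``V(d) = A / (1 + exp((d - D50) / k))``, which is smooth, monotone
non-increasing and bounded in [0, 1].  The plateau ``A`` and midpoint
``D50`` grow with the tumor's caudal proximity ``c = (200 - y_cc)/200``
(the heart sits caudally, so caudal tumors irradiate it more, for every
heart structure), and at heart level the lateral position shifts dose
between left-sided and right-sided chambers while leaving the whole-heart
curve untouched.  Multiplicative lognormal noise on the plateau and
additive noise on the midpoint give the strong inter-structure correlations
the dose-pattern PCA exploits.  This construction plants exactly two
dominant dose patterns — overall heart irradiation (craniocaudal) and
right/left chamber balance — with known survival effects, so downstream
selection and inference can be checked against ground truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import pca as _pca
from .dvh import (
    CHAMBER_STRUCTURES,
    CORONARY_STRUCTURES,
    DOSE_GRID,
    STRUCTURE_SETS,
    Cohort,
    StructureDVH,
    build_feature_matrix,
    eqd2,
)

logger = logging.getLogger(__name__)

#: Fields that may be blanked / imputed; survival and DVH data never are.
IMPUTABLE_FIELDS: tuple[str, ...] = ("bmi", "pack_years")

#: Default per-unit log-hazard coefficients used to generate survival.
#: Dose-pattern components are keyed PCA_1 / PCA_2 (scores on the cohort's
#: own fitted PCA); categorical variables enter generation through ordinal
#: codes (cacs_group 0-3; baseline_cardiac none=0, arrhythmia=1, other=2).
DEFAULT_TRUE_BETAS: dict[str, float] = {
    "age": 0.025,           # per year
    "sex": 0.35,            # male vs female
    "bmi": -0.025,          # per kg/m^2
    "ps": 0.45,             # PS >=2 vs 0-1
    "stage": 0.35,          # >=IIIA vs <=IIB
    "log_gtv": 0.30,        # per log(cm^3)
    "eqd2": -0.03,          # per Gy
    "pack_years": 0.004,    # per pack-year
    "cacs_group": 0.08,     # per category step
    "baseline_cardiac": 0.10,
    "cardiac_risk_factor": 0.10,
    "PCA_1": 0.131,         # per score unit: overall heart irradiation
    "PCA_2": -0.083,        # per score unit: right-minus-left balance
}


@dataclass
class CohortConfig:
    """Generator configuration; defaults emulate the 644-patient study cohort."""

    n_patients: int = 644
    seed: int = 0
    structure_set: str = "chambers"
    true_betas: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TRUE_BETAS)
    )
    baseline_shape: float = 1.1   # Weibull shape (months scale)
    baseline_scale: float = 36.0  # Weibull scale, months; median ~= 26 mo
    censor_rate_target: float = 0.30
    admin_horizon: float = 84.0   # months; emulates ~7 y median follow-up
    missing_counts: dict[str, int] = field(
        default_factory=lambda: {"bmi": 57, "pack_years": 49}
    )

    def validate(self) -> None:
        if self.n_patients < 10:
            raise ValueError(f"n_patients must be >= 10, got {self.n_patients}")
        if not (0 <= self.censor_rate_target < 1):
            raise ValueError(
                f"censor_rate_target must be in [0, 1), got {self.censor_rate_target}"
            )
        if self.structure_set not in STRUCTURE_SETS:
            raise ValueError(f"unknown structure_set {self.structure_set!r}")
        if self.baseline_shape <= 0 or self.baseline_scale <= 0:
            raise ValueError("baseline_shape and baseline_scale must be positive")
        for k, v in self.missing_counts.items():
            if k not in IMPUTABLE_FIELDS:
                raise ValueError(f"missing_counts: field {k!r} may not be blanked")
            if not (0 <= v < self.n_patients):
                raise ValueError(
                    f"missing_counts[{k!r}] must be in [0, n_patients), got {v}"
                )


@dataclass(frozen=True)
class TumorGeometry:
    """Scaled tumor position inside the lung bounding box.

    x_lr in [0, 250], 0 = most right, 250 = most left; y_cc in [0, 200],
    0 = most caudal, 200 = most cranial; gtv_volume in cm^3.
    """

    x_lr: float
    y_cc: float
    gtv_volume: float

    def validate(self) -> None:
        if not (0 <= self.x_lr <= 250):
            raise ValueError(f"x_lr must be in [0, 250], got {self.x_lr}")
        if not (0 <= self.y_cc <= 200):
            raise ValueError(f"y_cc must be in [0, 200], got {self.y_cc}")
        if self.gtv_volume <= 0:
            raise ValueError(f"gtv_volume must be > 0, got {self.gtv_volume}")


def _rng(seed: int, *path: int) -> np.random.Generator:
    """Named substream: independent generator per (seed, stage) path."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, path)]))


# ---------------------------------------------------------------------------
# DVH simulation
# ---------------------------------------------------------------------------
# Lateral weight: positive values boost left-sided structures for left-sided
# tumors (x_lr > 125) and vice versa; 0 leaves the structure symmetric.
_LATERAL_WEIGHT: dict[str, float] = {
    "Lung": 0.0, "Heart": 0.0,
    "AtriumLeft": 0.22, "AtriumRight": -0.55,
    "VentricleLeft": 0.55, "VentricleRight": -0.22,
    "LMCA": 0.22, "LAD": 0.55, "CX": 0.40, "RCA": -0.55,
}
_SIGMA_A = 0.20   # lognormal plateau noise (log scale)
_SIGMA_D50 = 2.0  # additive midpoint noise, Gy
_HEART_LEVEL_Y = 60.0   # craniocaudal center of the heart (scaled units)
_HEART_LEVEL_WIDTH = 55.0


def _dvh_params(x_lr, y_cc, structure: str):
    """Noise-free plateau A and midpoint D50 for one structure (vectorized)."""
    c = (200.0 - np.asarray(y_cc, dtype=float)) / 200.0   # caudal proximity
    lam = (np.asarray(x_lr, dtype=float) - 125.0) / 125.0  # -1 right .. +1 left
    heart_level = np.exp(-(((np.asarray(y_cc, dtype=float) - _HEART_LEVEL_Y)
                            / _HEART_LEVEL_WIDTH) ** 2))
    if structure == "Lung":
        A = 0.30 + 0.10 * c
        d50 = 10.0 + 5.0 * c
    elif structure == "Heart":
        A = 0.15 + 0.55 * c
        d50 = 5.0 + 20.0 * c
    else:
        side = _LATERAL_WEIGHT[structure]
        mult = 1.0 + side * lam * heart_level
        A = (0.12 + 0.50 * c) * mult
        d50 = 5.0 + 20.0 * c
    return A, d50


def _dvh_batch(
    x_lr: np.ndarray, y_cc: np.ndarray, structure_set: str, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Noisy cumulative DVHs for a whole cohort: structure -> (n, 35)."""
    structures = STRUCTURE_SETS[structure_set]
    n = np.asarray(x_lr).size
    out: dict[str, np.ndarray] = {}
    for s in structures:
        A, d50 = _dvh_params(x_lr, y_cc, s)
        A = A * np.exp(_SIGMA_A * rng.standard_normal(n))
        d50 = d50 + _SIGMA_D50 * rng.standard_normal(n)
        A = np.clip(A, 0.002, 0.98)
        k = 4.5
        out[s] = A[:, None] / (1.0 + np.exp((DOSE_GRID[None, :] - d50[:, None]) / k))
    return out


def dvh_from_geometry(
    geom: TumorGeometry,
    structure_set: str = "chambers",
    rng: np.random.Generator | int | None = None,
) -> dict[str, StructureDVH]:
    """Simulate the six structure DVHs for one tumor geometry.

    Passing the same seed (or an identically seeded generator) reproduces
    the noise exactly, so geometric contrasts can be tested noise-free.
    """
    geom.validate()
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    batch = _dvh_batch(
        np.array([geom.x_lr]), np.array([geom.y_cc]), structure_set, rng
    )
    return {s: StructureDVH(s, v[0]) for s, v in batch.items()}


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _clinical_table(n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Clinical covariates with marginals typical of an LA-NSCLC cohort."""
    age = np.clip(rng.normal(68.0, 9.0, n), 35, 92)
    sex = np.where(rng.random(n) < 0.55, "male", "female")
    bmi = np.clip(rng.normal(24.8, 4.5, n), 14, 45)
    ps = np.where(rng.random(n) < 0.16, ">=2", "0-1")
    stage = np.where(rng.random(n) < 0.78, ">=IIIA", "<=IIB")
    pack_years = np.round(np.clip(rng.gamma(3.0, 14.0, n), 0, 150), 1)
    cacs = rng.choice(["0", "1-99", "100-399", ">=400"], n,
                      p=[0.35, 0.25, 0.20, 0.20])
    cardiac = rng.choice(["none", "arrhythmia", "other"], n, p=[0.74, 0.10, 0.16])
    risk = (rng.random(n) < 0.45).astype(int)
    # prescription: 60-66 Gy in 2, 2.2, 2.5 or 2.75 Gy/fraction schedules
    schedules = [(66.0, 33), (60.0, 30), (66.0, 30), (60.0, 24), (55.0, 20)]
    probs = [0.45, 0.25, 0.12, 0.12, 0.06]
    idx = rng.choice(len(schedules), n, p=probs)
    dose = np.array([schedules[i][0] for i in idx])
    frac = np.array([schedules[i][1] for i in idx])
    eqd2_vals = np.array([eqd2(d, f) for d, f in zip(dose, frac)])
    return pd.DataFrame({
        "age": age, "sex": sex, "bmi": bmi, "performance_status": ps,
        "stage": stage, "pack_years": pack_years, "cacs_group": cacs,
        "baseline_cardiac": cardiac, "cardiac_risk_factor": risk,
        "eqd2": eqd2_vals,
    })


def _geometry_table(n: int, rng: np.random.Generator) -> pd.DataFrame:
    side = rng.random(n) < 0.5
    x = np.where(side, rng.normal(70.0, 32.0, n), rng.normal(180.0, 32.0, n))
    x = np.clip(x, 0.0, 250.0)
    y = rng.uniform(5.0, 195.0, n)
    gtv = np.exp(rng.normal(np.log(50.0), 0.9, n))
    return pd.DataFrame({"x_lr": x, "y_cc": y, "gtv_volume": gtv})


def _numeric_codes(clin: pd.DataFrame) -> pd.DataFrame:
    """Per-unit numeric encodings used in the generating linear predictor."""
    return pd.DataFrame({
        "age": clin["age"],
        "sex": (clin["sex"] == "male").astype(float),
        "bmi": clin["bmi"],
        "ps": (clin["performance_status"] == ">=2").astype(float),
        "stage": (clin["stage"] == ">=IIIA").astype(float),
        "pack_years": clin["pack_years"],
        "eqd2": clin["eqd2"],
        "cacs_group": clin["cacs_group"].map(
            {"0": 0.0, "1-99": 1.0, "100-399": 2.0, ">=400": 3.0}
        ),
        "baseline_cardiac": clin["baseline_cardiac"].map(
            {"none": 0.0, "arrhythmia": 1.0, "other": 2.0}
        ),
        "cardiac_risk_factor": clin["cardiac_risk_factor"].astype(float),
    })


def _tune_dropout(
    event_time: np.ndarray, u_drop: np.ndarray, horizon: float, target: float
) -> float:
    """Bisect the uniform-dropout width tau so that censoring by
    min(horizon, tau*U) hits the target fraction on this sample."""

    def frac(tau: float) -> float:
        c = np.minimum(horizon, tau * u_drop)
        return float(np.mean(c < event_time))

    if frac(np.inf) > target:  # administrative censoring alone overshoots
        logger.warning(
            "admin censoring alone (%.3f) exceeds target %.3f; no dropout added",
            frac(np.inf), target,
        )
        return np.inf
    lo, hi = 1e-6, 1e7
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if frac(mid) > target:
            lo = mid
        else:
            hi = mid
    return hi


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate a full synthetic cohort (clinical + DVH + geometry + outcome).

    Survival times follow a Weibull-baseline Cox model whose linear
    predictor combines the clinical covariates with the cohort's own
    dose-pattern PCA scores (fitted after DVH simulation), centered so the
    baseline describes the average patient.  Fully reproducible from the
    config seed.
    """
    config.validate()
    n = config.n_patients
    clin = _clinical_table(n, _rng(config.seed, 1))
    geom = _geometry_table(n, _rng(config.seed, 2))
    clin["log_gtv"] = np.log(geom["gtv_volume"].to_numpy())

    dvh_arrays = _dvh_batch(
        geom["x_lr"].to_numpy(), geom["y_cc"].to_numpy(),
        config.structure_set, _rng(config.seed, 3),
    )
    ids = np.array([f"P{i:04d}" for i in range(n)])
    frames = []
    for s, arr in dvh_arrays.items():
        frames.append(pd.DataFrame({
            "patient_id": np.repeat(ids, DOSE_GRID.size),
            "structure": s,
            "dose_gy": np.tile(DOSE_GRID, n),
            "volume_fraction": arr.ravel(),
        }))
    dvh_long = pd.concat(frames, ignore_index=True)

    # assemble the feature matrix directly from the simulated arrays (same
    # structure-major layout as build_feature_matrix, which tests cross-check)
    from .dvh import DoseFeatureMatrix, feature_columns

    raw = np.hstack([dvh_arrays[s] for s in STRUCTURE_SETS[config.structure_set]])
    features = DoseFeatureMatrix(
        structure_set=config.structure_set,
        columns=feature_columns(config.structure_set),
        patient_ids=ids, raw=raw, column_means=raw.mean(axis=0),
    )
    model = _pca.fit_pca(features)
    scores = model.scores

    codes = _numeric_codes(clin)
    codes["log_gtv"] = clin["log_gtv"]
    lp = np.zeros(n)
    for name, beta in config.true_betas.items():
        if name.startswith("PCA_"):
            k = int(name.split("_")[1]) - 1
            if k < scores.shape[1]:
                lp += beta * scores[:, k]
        elif name in codes:
            lp += beta * codes[name].to_numpy(dtype=float)
        else:
            raise KeyError(f"true_betas: unknown variable {name!r}")
    lp = lp - lp.mean()

    rng_surv = _rng(config.seed, 4)
    E = rng_surv.exponential(1.0, n)
    T = config.baseline_scale * (E / np.exp(lp)) ** (1.0 / config.baseline_shape)

    if config.censor_rate_target == 0:
        time, event = T, np.ones(n, dtype=int)
    else:
        u_drop = rng_surv.random(n)
        tau = _tune_dropout(T, u_drop, config.admin_horizon, config.censor_rate_target)
        C = np.minimum(config.admin_horizon, tau * u_drop)
        event = (T <= C).astype(int)
        time = np.minimum(T, C)

    patients = pd.concat([clin, geom], axis=1)
    patients["time"] = time
    patients["event"] = event
    patients.index = pd.Index(ids, name="patient_id")

    cohort = Cohort(
        patients=patients, dvh=dvh_long,
        structure_set=config.structure_set,
        truth={
            "config": asdict(config),
            "linear_predictor": lp,
            "event_time": T,
            "pca_scores": scores[:, : model.n_components].copy(),
            "pca_score_sd": _pca.score_sd(model)[: model.n_components].copy(),
            "complete_patients": patients.copy(),
        },
    )
    if config.missing_counts:
        cohort = inject_missingness(cohort, config.missing_counts, config.seed)
    return cohort


def inject_missingness(
    cohort: Cohort, missing_counts: dict[str, int], seed: int
) -> Cohort:
    """Blank exactly the requested number of values per variable (MCAR).

    Only BMI and pack-years may be blanked; survival, DVH and the remaining
    covariates are mandatory.
    """
    for k, v in missing_counts.items():
        if k not in IMPUTABLE_FIELDS:
            raise ValueError(f"field {k!r} is mandatory and may not be blanked")
        if not (0 <= v <= cohort.n_patients):
            raise ValueError(f"missing count for {k!r} out of range: {v}")
    patients = cohort.patients.copy()
    rng = _rng(seed, 5)
    for k in sorted(missing_counts):
        count = missing_counts[k]
        idx = rng.choice(cohort.n_patients, size=count, replace=False)
        patients.iloc[idx, patients.columns.get_loc(k)] = np.nan
    return Cohort(
        patients=patients, dvh=cohort.dvh,
        structure_set=cohort.structure_set, truth=cohort.truth,
    )
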