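"""Data model, validation and I/O for cumulative dose-volume histograms.

A cumulative DVH samples, for each dose level d, the fraction V_d of a
structure's volume receiving at least d Gy.  Every structure is sampled on a
fixed grid of 2,4,...,70 Gy (35 points), and a cohort's six structures are
flattened structure-major into a 210-column dose feature matrix whose column
order is a frozen contract (downstream PCA weights are indexed by it).

Volumes are stored as fractions in [0, 1], never percent: the PCA operates on
the raw (mean-centered, unstandardized) matrix and is therefore scale
sensitive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Dose grid in Gy: 2, 4, ..., 70 (35 points).
DOSE_GRID: np.ndarray = np.arange(2, 71, 2, dtype=float)
N_GRID: int = DOSE_GRID.size  # 35

#: Frozen structure orders.  "Lung" is the combined lungs; the heart-chamber
#: set carries the whole heart and its four chambers, the coronary set the
#: whole heart and the four coronary arteries.
CHAMBER_STRUCTURES: tuple[str, ...] = (
    "Lung", "Heart", "AtriumLeft", "AtriumRight", "VentricleRight", "VentricleLeft",
)
CORONARY_STRUCTURES: tuple[str, ...] = (
    "Lung", "Heart", "LMCA", "LAD", "CX", "RCA",
)
STRUCTURE_SETS: dict[str, tuple[str, ...]] = {
    "chambers": CHAMBER_STRUCTURES,
    "coronaries": CORONARY_STRUCTURES,
}
N_FEATURES: int = 6 * N_GRID  # 210

#: Clinical covariate columns of the patients table, with categorical levels.
CATEGORICAL_LEVELS: dict[str, tuple[str, ...]] = {
    "sex": ("female", "male"),
    "performance_status": ("0-1", ">=2"),
    "stage": ("<=IIB", ">=IIIA"),
    "cacs_group": ("0", "1-99", "100-399", ">=400"),
    "baseline_cardiac": ("none", "arrhythmia", "other"),
}
CONTINUOUS_COLUMNS: tuple[str, ...] = (
    "age", "bmi", "pack_years", "eqd2", "log_gtv",
)
CLINICAL_COLUMNS: tuple[str, ...] = (
    "age", "sex", "bmi", "performance_status", "stage", "pack_years",
    "cacs_group", "baseline_cardiac", "cardiac_risk_factor", "eqd2", "log_gtv",
)
OUTCOME_COLUMNS: tuple[str, ...] = ("time", "event")
GEOMETRY_COLUMNS: tuple[str, ...] = ("x_lr", "y_cc", "gtv_volume")


# ---------------------------------------------------------------------------
# core types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StructureDVH:
    """One structure's cumulative DVH on the common 2-70 Gy grid."""

    structure: str
    values: np.ndarray  # shape (35,), volume fractions

    @property
    def grid(self) -> np.ndarray:
        return DOSE_GRID

    def mean_dose(self) -> float:
        """Mean structure dose in Gy, the integral of the cumulative DVH."""
        return float(2.0 * np.sum(self.values))


@dataclass(frozen=True)
class DVHValidation:
    ok: bool
    reasons: tuple[str, ...] = ()


def validate_dvh(dvh: StructureDVH, tol: float = 1e-9) -> DVHValidation:
    """Check grid length, monotonicity and the [0, 1] range.

    Returns diagnostics rather than raising; `reasons` names every violation.
    """
    v = np.asarray(dvh.values, dtype=float)
    reasons: list[str] = []
    if v.ndim != 1 or v.size != N_GRID:
        reasons.append(f"grid length {v.size} != {N_GRID}")
        return DVHValidation(False, tuple(reasons))
    if not np.all(np.isfinite(v)):
        reasons.append("non-finite values")
    if np.any(v < -tol) or np.any(v > 1 + tol):
        reasons.append("values outside [0, 1]")
    rises = np.flatnonzero(np.diff(v) > tol)
    for i in rises:
        reasons.append(f"non-monotone at {int(DOSE_GRID[i + 1])} Gy")
    return DVHValidation(len(reasons) == 0, tuple(reasons))


@dataclass
class Cohort:
    """A cohort: clinical/outcome table plus long-format DVH table.

    `patients` is indexed by patient_id and holds the clinical covariates,
    outcome (time in months, event indicator) and, when available, the scaled
    tumor geometry columns (x_lr, y_cc, gtv_volume).  `dvh` is long format
    with columns patient_id, structure, dose_gy, volume_fraction.  `truth`
    carries synthetic ground truth (generator config, true coefficients,
    pre-missingness covariates) and is None for real data.
    """

    patients: pd.DataFrame
    dvh: pd.DataFrame
    structure_set: str = "chambers"
    truth: dict | None = None

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    @property
    def patient_ids(self) -> np.ndarray:
        return self.patients.index.to_numpy()

    def structure_dvhs(self, patient_id) -> dict[str, StructureDVH]:
        sub = self.dvh[self.dvh["patient_id"] == patient_id]
        out: dict[str, StructureDVH] = {}
        for structure, grp in sub.groupby("structure", sort=False):
            g = grp.sort_values("dose_gy")
            out[str(structure)] = StructureDVH(
                str(structure), g["volume_fraction"].to_numpy(dtype=float)
            )
        return out


# ---------------------------------------------------------------------------
# dose feature matrix
# ---------------------------------------------------------------------------

def feature_columns(structure_set: str = "chambers") -> list[str]:
    """Frozen 210-column order: structure-major, dose-ascending."""
    structures = STRUCTURE_SETS[structure_set]
    return [f"V{int(d)}_{s}" for s in structures for d in DOSE_GRID]


@dataclass
class DoseFeatureMatrix:
    """n x 210 DVH matrix with stored column means and the centered matrix."""

    structure_set: str
    columns: list[str]
    patient_ids: np.ndarray
    raw: np.ndarray            # (n, 210)
    column_means: np.ndarray   # (210,)

    @property
    def centered(self) -> np.ndarray:
        return self.raw - self.column_means

    @property
    def n(self) -> int:
        return self.raw.shape[0]


def build_feature_matrix(
    dvh: pd.DataFrame,
    structure_set: str = "chambers",
    patient_ids: Sequence | None = None,
) -> DoseFeatureMatrix:
    """Assemble the mean-centered dose feature matrix from a long DVH table.

    Every patient must contribute all six structures of `structure_set`,
    each on the full 35-point grid; a missing structure is an error naming
    the patient and structure.
    """
    structures = STRUCTURE_SETS[structure_set]
    wide = dvh.pivot_table(
        index="patient_id", columns=["structure", "dose_gy"],
        values="volume_fraction", aggfunc="first",
    )
    if patient_ids is None:
        patient_ids = wide.index.to_numpy()
    cols = pd.MultiIndex.from_tuples(
        [(s, float(d)) for s in structures for d in DOSE_GRID]
    )
    missing_struct = set(s for s, _ in cols) - set(wide.columns.get_level_values(0))
    if missing_struct:
        raise ValueError(
            f"structure(s) {sorted(missing_struct)} absent from DVH table "
            f"for structure set '{structure_set}'"
        )
    wide = wide.reindex(index=list(patient_ids), columns=cols)
    if wide.isna().any().any():
        bad = wide.isna().any(axis=1)
        pid = wide.index[bad][0]
        col = wide.columns[wide.loc[pid].isna()][0]
        raise ValueError(
            f"patient {pid!r} is missing structure {col[0]!r} at {col[1]:g} Gy"
        )
    raw = wide.to_numpy(dtype=float)
    means = raw.mean(axis=0)
    return DoseFeatureMatrix(
        structure_set=structure_set,
        columns=feature_columns(structure_set),
        patient_ids=np.asarray(patient_ids),
        raw=raw,
        column_means=means,
    )


# ---------------------------------------------------------------------------
# dose-unit conversion
# ---------------------------------------------------------------------------

def eqd2(total_dose: float, n_fractions: int, alpha_beta: float = 10.0) -> float:
    """Equivalent dose in 2 Gy fractions under the linear-quadratic model.

    EQD2 = D * (d + alpha/beta) / (2 + alpha/beta) with d = D / n the dose
    per fraction.  A schedule already delivered at 2 Gy/fraction maps to
    itself.  alpha/beta defaults to 10 Gy (tumor effect).
    """
    if n_fractions < 1:
        raise ValueError(f"n_fractions must be >= 1, got {n_fractions}")
    if total_dose < 0:
        raise ValueError(f"total_dose must be >= 0, got {total_dose}")
    if total_dose == 0:
        return 0.0
    d = total_dose / n_fractions
    return float(total_dose * (d + alpha_beta) / (2.0 + alpha_beta))


# ---------------------------------------------------------------------------
# cohort I/O
# ---------------------------------------------------------------------------
# CSV dialect: UTF-8, comma separated, header row, missing = empty string.
# Floats are written with 17 significant digits so a write/read round trip is
# exact to 1e-12 (in practice bit exact).

_FLOAT_FMT = "%.17g"


def write_cohort(cohort: Cohort, out_dir: str | Path) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    patients_path = out / "patients.csv"
    dvh_path = out / "dvh.csv"
    sidecar_path = out / "cohort.json"

    pat = cohort.patients.reset_index()
    pat.to_csv(patients_path, index=False, float_format=_FLOAT_FMT)
    cohort.dvh.to_csv(dvh_path, index=False, float_format=_FLOAT_FMT)

    sidecar = {"structure_set": cohort.structure_set}
    if cohort.truth is not None:
        sidecar["truth"] = _jsonable(cohort.truth)
    sidecar_path.write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return {"patients": patients_path, "dvh": dvh_path, "sidecar": sidecar_path}


def read_cohort(
    patients_path: str | Path,
    dvh_path: str | Path,
    structure_set: str | None = None,
) -> Cohort:
    patients_path = Path(patients_path)
    dvh_path = Path(dvh_path)
    pat = pd.read_csv(patients_path, dtype={"patient_id": str})
    if "patient_id" not in pat.columns:
        raise ValueError("patients table lacks a patient_id column")
    dup = pat["patient_id"].duplicated()
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0]) + 2  # header = line 1
        raise ValueError(f"duplicated patient_id at row {row} of {patients_path.name}")
    for col, levels in CATEGORICAL_LEVELS.items():
        if col in pat.columns:
            bad = ~(pat[col].isna() | pat[col].isin(levels))
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0]) + 2
                raise ValueError(f"invalid {col} value at row {row} of {patients_path.name}")
    pat = pat.set_index("patient_id")

    dvh = pd.read_csv(dvh_path, dtype={"patient_id": str})
    required = {"patient_id", "structure", "dose_gy", "volume_fraction"}
    if not required.issubset(dvh.columns):
        raise ValueError(f"DVH table must have columns {sorted(required)}")
    dvh["dose_gy"] = dvh["dose_gy"].astype(float)
    dvh["volume_fraction"] = dvh["volume_fraction"].astype(float)

    if structure_set is None:
        sidecar = patients_path.with_name("cohort.json")
        if sidecar.exists():
            structure_set = json.loads(sidecar.read_text()).get("structure_set", "chambers")
        else:
            present = set(dvh["structure"].unique())
            structure_set = "coronaries" if present & {"LAD", "RCA", "CX", "LMCA"} else "chambers"
    return Cohort(patients=pat, dvh=dvh, structure_set=structure_set)


def validate_cohort(cohort: Cohort) -> list[str]:
    """Validate every patient's DVH set; returns a list of problem strings."""
    problems: list[str] = []
    structures = STRUCTURE_SETS[cohort.structure_set]
    counts = cohort.dvh.groupby(["patient_id", "structure"]).size()
    for pid in cohort.patient_ids:
        for s in structures:
            if (pid, s) not in counts.index:
                problems.append(f"patient {pid}: structure {s} missing")
    for (pid, s), grp in cohort.dvh.groupby(["patient_id", "structure"], sort=False):
        vals = grp.sort_values("dose_gy")["volume_fraction"].to_numpy(dtype=float)
        res = validate_dvh(StructureDVH(str(s), vals))
        if not res.ok:
            problems.append(f"patient {pid}, {s}: " + "; ".join(res.reasons))
    if (cohort.patients["time"] < 0).any():
        problems.append("negative survival time")
    return problems


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, pd.DataFrame):
        return json.loads(obj.to_json(orient="split"))
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj
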