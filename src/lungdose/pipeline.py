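"""End-to-end pipeline: cohort -> validate -> PCA -> select -> report.

One `RunConfig` (loadable from YAML) drives a fully reproducible run: every
source of randomness derives from the single master seed via named
substreams, the manifest records a config hash and a SHA-256 checksum of
every output file, and re-running the same config into a clean directory
reproduces those checksums bit for bit.  A stage failure aborts the run
with the failing stage named; outputs written so far are moved under a
``failed/`` prefix.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cox import CLINICAL_UNITS, PreparedSurvival, build_design
from .dvh import Cohort, build_feature_matrix, read_cohort, validate_cohort, write_cohort
from .pca import PCAModel, fit_pca, score_sd
from .reporting import calibration, forest_table, hr_position_table
from .selection import best_subset_select, bootstrap_ci, impute
from .synthetic import CohortConfig, generate_cohort

logger = logging.getLogger(__name__)

STAGES = ("cohort", "validate", "pca", "select", "report")


@dataclass
class RunConfig:
    out_dir: str = "lungdose_run"
    seed: int = 0
    model_variant: str = "primary"          # primary: chambers, secondary: coronaries
    # either synthesize ...
    n_patients: int | None = 644
    synth_overrides: dict = field(default_factory=dict)
    # ... or load from CSV
    patients_csv: str | None = None
    dvh_csv: str | None = None
    # PCA retention rule
    variance_threshold: float = 0.95
    component_cap: int = 8
    # selection
    candidates: list[str] | None = None     # None = all clinical units + PCs
    B_select: int = 50
    B_ci: int = 2000
    calibration_B: int | None = None        # None = B_ci
    cv_method: str = "mean_oob"

    @property
    def structure_set(self) -> str:
        return {"primary": "chambers", "secondary": "coronaries"}[self.model_variant]

    def validate(self) -> None:
        if self.model_variant not in ("primary", "secondary"):
            raise ValueError(f"unknown model_variant {self.model_variant!r}")
        if (self.patients_csv is None) != (self.dvh_csv is None):
            raise ValueError("patients_csv and dvh_csv must be given together")
        if self.patients_csv is not None:
            for p in (self.patients_csv, self.dvh_csv):
                if not Path(p).exists():
                    raise FileNotFoundError(p)
        elif self.n_patients is None:
            raise ValueError("either n_patients (synthesis) or input CSVs required")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        obj = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**obj)

    def canonical_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run(config: RunConfig) -> dict:
    """Execute the full pipeline and return (and write) the run manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "config_hash": hashlib.sha256(config.canonical_json().encode()).hexdigest(),
        "versions": _versions(),
        "stages": [],
    }
    written: list[Path] = []

    def finish_stage(name: str, t0: float, files: list[Path]) -> None:
        written.extend(files)
        manifest["stages"].append({
            "name": name,
            "wall_time_s": round(_time.perf_counter() - t0, 3),
            "outputs": {f.name: _sha256(f) for f in files},
        })

    state: dict = {}
    try:
        for stage in STAGES:
            t0 = _time.perf_counter()
            files = _STAGE_FUNCS[stage](config, out, state)
            finish_stage(stage, t0, files)
    except Exception as exc:
        failed = out / "failed"
        failed.mkdir(exist_ok=True)
        for f in written:
            if f.exists():
                f.rename(failed / f.name)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _stage_cohort(config: RunConfig, out: Path, state: dict) -> list[Path]:
    if config.patients_csv is not None:
        cohort = read_cohort(config.patients_csv, config.dvh_csv)
    else:
        overrides = dict(config.synth_overrides)
        overrides.setdefault("n_patients", config.n_patients)
        overrides.setdefault("seed", config.seed)
        overrides.setdefault("structure_set", config.structure_set)
        cohort = generate_cohort(CohortConfig(**overrides))
    state["cohort"] = cohort
    paths = write_cohort(cohort, out)
    return list(paths.values())


def _stage_validate(config: RunConfig, out: Path, state: dict) -> list[Path]:
    problems = validate_cohort(state["cohort"])
    if problems:
        raise ValueError(f"{len(problems)} validation problems; first: {problems[0]}")
    path = out / "validation.json"
    path.write_text(json.dumps({"n_patients": state["cohort"].n_patients,
                                "problems": problems}, indent=2))
    return [path]


def _stage_pca(config: RunConfig, out: Path, state: dict) -> list[Path]:
    cohort: Cohort = state["cohort"]
    features = build_feature_matrix(
        cohort.dvh, cohort.structure_set, patient_ids=cohort.patient_ids
    )
    model = fit_pca(features, config.variance_threshold, config.component_cap)
    state["pca"] = model
    path = out / "pca_model.json"
    model.to_json(path)
    return [path]


def _stage_select(config: RunConfig, out: Path, state: dict) -> list[Path]:
    cohort: Cohort = state["cohort"]
    model: PCAModel = state["pca"]
    completed = impute(cohort, seed=config.seed)
    data = completed.patients.copy()
    for k in range(model.n_components):
        data[f"PCA_{k + 1}"] = model.scores[:, k]
    pc_units = [f"PCA_{k + 1}" for k in range(model.n_components)]
    candidates = (
        list(config.candidates) if config.candidates is not None
        else list(CLINICAL_UNITS) + pc_units
    )
    logger.info("best-subset selection over 2^%d subsets", len(candidates))
    result = best_subset_select(
        data, candidates, B=config.B_select, seed=config.seed,
        cv_method=config.cv_method,
    )
    ci = (
        bootstrap_ci(data, result.selected, B=config.B_ci, seed=config.seed)
        if result.selected else pd.DataFrame(
            columns=["term", "beta", "hr", "beta_ci_low", "beta_ci_high",
                     "hr_ci_low", "hr_ci_high"]
        )
    )
    state.update(data=data, selection=result, ci=ci)

    table_path = out / "selection_table.csv"
    result.score_table.to_csv(table_path, index=False, float_format="%.12g")
    model_path = out / "final_model.json"
    sds = score_sd(model)
    sd_map = {f"PCA_{k + 1}": float(sds[k]) for k in range(model.n_components)}
    model_path.write_text(json.dumps({
        "selected": list(result.selected),
        "cv_method": result.cv_method,
        "mean_cv_loglik": result.selected_score,
        "n_failed_fits": result.n_failed_fits,
        "terms": ci.drop(columns=[], errors="ignore").to_dict(orient="records"),
        "per_sd": {
            u: {"sd": sd_map[u]} for u in result.selected if u in sd_map
        },
        "final_fit": result.final_fit.to_dict(),
    }, indent=2, sort_keys=True))
    log_path = out / "selection_log.json"
    log_path.write_text(json.dumps({
        "B": config.B_select,
        "n_subsets": len(result.score_table),
        "splits": [
            {"n_in_unique": int(np.unique(i).size), "n_out": int(o.size)}
            for i, o in result.splits
        ],
    }, indent=2))
    return [table_path, model_path, log_path]


def _stage_report(config: RunConfig, out: Path, state: dict) -> list[Path]:
    cohort: Cohort = state["cohort"]
    model: PCAModel = state["pca"]
    data: pd.DataFrame = state["data"]
    result = state["selection"]

    files: list[Path] = []
    B_cal = config.calibration_B if config.calibration_B is not None else config.B_ci
    design = build_design(data, result.selected)
    beta = result.final_fit.beta
    report = calibration(design, beta, B=B_cal, seed=config.seed)
    cal_path = out / "calibration.csv"
    report.to_frame().to_csv(cal_path, index=False, float_format="%.12g")
    files.append(cal_path)

    sds = score_sd(model)
    sd_map = {f"PCA_{k + 1}": float(sds[k]) for k in range(model.n_components)}
    forest = forest_table(
        data, list(result.candidates), result.selected, sd_map=sd_map,
        ci_overrides=state["ci"] if len(state["ci"]) else None,
    )
    forest_path = out / "forest.csv"
    forest.to_csv(forest_path, index=False, float_format="%.12g")
    files.append(forest_path)

    geom_cols = {"x_lr", "y_cc", "gtv_volume"}
    if geom_cols.issubset(cohort.patients.columns):
        pca_betas = _pca_betas_for_map(data, result)
        if pca_betas:
            hr_map = hr_position_table(
                model.scores[:, : model.n_components],
                cohort.patients, pca_betas,
            )
            map_path = out / "hr_map.csv"
            hr_map.to_csv(map_path, index=False, float_format="%.12g")
            files.append(map_path)
    return files


def _pca_betas_for_map(data: pd.DataFrame, result) -> dict[str, float]:
    """Fitted per-unit betas for the dose-pattern components in the selected
    model; if none were selected, an adjusted fit adding the first two
    components to the selected clinical terms supplies them."""
    pc_selected = [u for u in result.selected if u.startswith("PCA_")]
    if pc_selected:
        fit = result.final_fit
        design_cols = fit.columns
        return {
            u: float(fit.beta[design_cols.index(u)]) for u in pc_selected
        }
    extra = [u for u in ("PCA_1", "PCA_2") if u in data.columns]
    if not extra:
        return {}
    units = tuple(result.selected) + tuple(extra)
    design = build_design(data, units)
    fit = PreparedSurvival.from_design(design).fit()
    return {u: float(fit.beta[design.columns.index(u)]) for u in extra}


_STAGE_FUNCS = {
    "cohort": _stage_cohort,
    "validate": _stage_validate,
    "pca": _stage_pca,
    "select": _stage_select,
    "report": _stage_report,
}


def _versions() -> dict[str, str]:
    import lifelines
    import sklearn

    return {
        "lungdose": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "lifelines": lifelines.__version__,
        "scikit-learn": sklearn.__version__,
    }
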