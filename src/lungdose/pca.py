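"""Principal component analysis of the centered dose feature matrix.

The PCA is run on the covariance (not correlation) of the raw
volume-fraction matrix after subtracting cohort column means, so a
component's weights are interpretable in raw volume units and a patient's
score measures deviation from the cohort-mean DVH pattern.  Component signs
are fixed by a deterministic convention so that "larger first component =
more whole-heart irradiation" holds regardless of linear-algebra backend:
each weight vector is flipped to make its whole-heart weight sum positive,
unless the right-minus-left structure weight contrast is larger in
magnitude (the left/right dose-balance component leaves the whole heart
nearly untouched, so its heart load is noise), in which case that contrast
is made positive — positive scores then correspond to right-sided
irradiation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .dvh import (
    DOSE_GRID,
    N_GRID,
    STRUCTURE_SETS,
    DoseFeatureMatrix,
    StructureDVH,
    feature_columns,
)

#: Structures entering the right-minus-left fallback sign contrast.
_RIGHT_LEFT_CONTRAST: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "chambers": (("AtriumRight", "VentricleRight"), ("AtriumLeft", "VentricleLeft")),
    "coronaries": (("RCA",), ("LMCA", "LAD", "CX")),
}


@dataclass
class PCAModel:
    structure_set: str
    columns: list[str]
    column_means: np.ndarray        # (210,)
    weights: np.ndarray             # (210, K_all), orthonormal columns
    eigenvalues: np.ndarray         # (K_all,), score variances (ddof=1)
    explained_fraction: np.ndarray  # (K_all,)
    scores: np.ndarray              # (n, K_all)
    n_components: int               # retained K (variance rule, capped)
    sign_convention: str = "heart-sum-positive/right-minus-left-fallback"

    @property
    def n(self) -> int:
        return self.scores.shape[0]

    def to_json(self, path: str | Path) -> None:
        obj = {
            "structure_set": self.structure_set,
            "columns": self.columns,
            "column_means": self.column_means.tolist(),
            "weights": self.weights.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "explained_fraction": self.explained_fraction.tolist(),
            "scores": self.scores.tolist(),
            "n_components": self.n_components,
            "sign_convention": self.sign_convention,
        }
        Path(path).write_text(json.dumps(obj))

    @classmethod
    def from_json(cls, path: str | Path) -> "PCAModel":
        obj = json.loads(Path(path).read_text())
        return cls(
            structure_set=obj["structure_set"],
            columns=list(obj["columns"]),
            column_means=np.asarray(obj["column_means"], dtype=float),
            weights=np.asarray(obj["weights"], dtype=float),
            eigenvalues=np.asarray(obj["eigenvalues"], dtype=float),
            explained_fraction=np.asarray(obj["explained_fraction"], dtype=float),
            scores=np.asarray(obj["scores"], dtype=float),
            n_components=int(obj["n_components"]),
            sign_convention=obj["sign_convention"],
        )


def _structure_slice(columns: list[str], structure: str) -> np.ndarray:
    return np.array([i for i, c in enumerate(columns) if c.endswith("_" + structure)])


def _fix_signs(weights: np.ndarray, columns: list[str], structure_set: str) -> np.ndarray:
    heart_idx = _structure_slice(columns, "Heart")
    right, left = _RIGHT_LEFT_CONTRAST[structure_set]
    right_idx = np.concatenate([_structure_slice(columns, s) for s in right])
    left_idx = np.concatenate([_structure_slice(columns, s) for s in left])
    w = weights.copy()
    for k in range(w.shape[1]):
        h = w[heart_idx, k].sum()
        contrast = w[right_idx, k].sum() - w[left_idx, k].sum()
        # orient by whichever signal dominates the component: whole-heart
        # load (heart-irradiation patterns) or the right-minus-left contrast
        # (balance patterns, whose heart load is noise)
        pivot = h if abs(h) >= abs(contrast) else contrast
        if pivot == 0:
            pivot = w[np.argmax(np.abs(w[:, k])), k] or 1.0
        if pivot < 0:
            w[:, k] = -w[:, k]
    return w


def fit_pca(
    features: DoseFeatureMatrix,
    variance_threshold: float = 0.95,
    cap: int = 8,
) -> PCAModel:
    """Fit the dose-pattern PCA on a mean-centered feature matrix.

    Keeps min(n - 1, 210) components (the full rank of a centered matrix),
    so reconstruction with all of them reproduces the input; the retained
    count `n_components` follows the cumulative-variance rule with a cap.
    """
    Xc = features.centered
    n, p = Xc.shape
    if n < 2:
        raise ValueError("PCA requires at least 2 patients")
    total_var = float(np.sum(Xc * Xc)) / (n - 1)
    if float(np.abs(Xc).max()) < 1e-12:  # constant matrix up to roundoff
        raise ValueError("feature matrix has zero variance; PCA undefined")
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    k_all = min(n - 1, p)
    s, vt = s[:k_all], vt[:k_all]
    weights = _fix_signs(vt.T, features.columns, features.structure_set)
    eig = s**2 / (n - 1)
    frac = eig / total_var
    scores = Xc @ weights
    k = select_n_components(frac, threshold=variance_threshold, cap=cap)
    return PCAModel(
        structure_set=features.structure_set,
        columns=list(features.columns),
        column_means=features.column_means.copy(),
        weights=weights,
        eigenvalues=eig,
        explained_fraction=frac,
        scores=scores,
        n_components=k,
    )


def select_n_components(
    explained_fraction: np.ndarray, threshold: float = 0.95, cap: int = 8
) -> int:
    """Smallest K whose cumulative explained fraction reaches the threshold,
    truncated to the cap (the cap bounds the 2^K best-subset cost downstream)."""
    frac = np.asarray(explained_fraction, dtype=float)
    if frac.size == 0 or np.any(frac < -1e-12):
        raise ValueError("invalid explained-variance fractions")
    cum = np.cumsum(frac)
    reached = np.flatnonzero(cum >= threshold - 1e-12)
    k = int(reached[0]) + 1 if reached.size else frac.size
    return min(k, cap)


def project(dvh_vector: np.ndarray, model: PCAModel) -> np.ndarray:
    """Scores of one raw 210-vector: (x - column_means) . weights."""
    x = np.asarray(dvh_vector, dtype=float)
    if x.shape != (len(model.columns),):
        raise ValueError(
            f"expected vector of length {len(model.columns)}, got shape {x.shape}"
        )
    return (x - model.column_means) @ model.weights[:, : model.n_components]


def reconstruct_dvh(
    scores: np.ndarray, model: PCAModel
) -> tuple[dict[str, StructureDVH], bool]:
    """Reconstruct the six structure DVHs for given component scores.

    The raw vector is column_means + sum_k score_k * weight_k; an all-zero
    score vector returns the cohort-mean DVHs exactly.  Values are clipped
    to [0, 1]; the second return flags whether clipping occurred.
    """
    sc = np.atleast_1d(np.asarray(scores, dtype=float))
    if sc.size > model.weights.shape[1]:
        raise ValueError("more scores than fitted components")
    vec = model.column_means + model.weights[:, : sc.size] @ sc
    clipped = bool(np.any(vec < 0) or np.any(vec > 1))
    vec = np.clip(vec, 0.0, 1.0)
    structures = STRUCTURE_SETS[model.structure_set]
    out = {
        s: StructureDVH(s, vec[i * N_GRID : (i + 1) * N_GRID])
        for i, s in enumerate(structures)
    }
    return out, clipped


def score_sd(model: PCAModel) -> np.ndarray:
    """Cohort standard deviation (ddof=1) of each component score.

    Hazard ratios for dose-pattern components are reported per one SD of the
    score within the cohort, which makes them invariant to the volume unit.
    """
    return model.scores.std(axis=0, ddof=1)
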