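"""The inner evaluation the optimizer minimizes.

One evaluation pre-processes a single sub-sampling subset with the candidate
(voxel size, FWHM) pair, trains a linear-kernel SVM (young/old
classification) or epsilon-SVR (age regression) and returns the mean
10-fold cross-validated error — classification error in [0, 1] or MAE in
years.  Lower is better for both tasks; that minimization contract is shared
with the optimizer.

SVM hyper-parameters are fixed at defaults (C = 1, linear kernel; SVR
epsilon = 0.1 × label sd) and features enter unscaled unless requested —
the search is over pre-processing only.
"""

from __future__ import annotations

import csv
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, SVR

from .errors import InputError
from .preprocess import PreprocParams, vectorize_dataset
from .volumes import SubjectRecord

__all__ = ["ObjectiveValue", "crossval_split", "evaluate_params", "make_estimator", "EvaluationLog"]

DEFAULT_C = 1.0
DEFAULT_EPSILON_FRACTION = 0.1  # SVR epsilon as a fraction of the label sd


@dataclass(frozen=True)
class ObjectiveValue:
    """One evaluated point: objective value (mean of per-fold scores),
    the parameters, which subset was consumed and the wall time."""

    value: float
    per_fold: tuple[float, ...]
    params: PreprocParams
    subset_id: int
    elapsed_s: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.per_fold and not self.degenerate:
            if abs(self.value - float(np.mean(self.per_fold))) > 1e-9:
                raise InputError("objective value must equal the mean of per-fold scores")


def crossval_split(
    y: Sequence, k: int, task: str, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """k-fold CV indices over one subset; classification folds are
    stratified by group label.  Fold sizes differ by at most one and every
    subject is tested exactly once."""
    y = np.asarray(y)
    if k < 2:
        raise InputError(f"k must be >= 2, got {k}")
    if k > y.size:
        raise InputError(f"k={k} exceeds subset size {y.size}")
    if task == "classification":
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        return [(tr, te) for tr, te in splitter.split(np.zeros((y.size, 1)), y)]
    if task == "regression":
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        return [(tr, te) for tr, te in splitter.split(np.zeros((y.size, 1)))]
    raise InputError(f"task must be classification or regression, got {task!r}")


def make_estimator(task: str, y_train: np.ndarray, precomputed: bool = False):
    """Default linear-kernel learner for a task (C = 1; SVR epsilon scaled
    to the training-label sd).  ``precomputed=True`` expects Gram-matrix
    inputs (same linear model, shared kernel computation)."""
    kernel = "precomputed" if precomputed else "linear"
    if task == "classification":
        return SVC(kernel=kernel, C=DEFAULT_C)
    sd = float(np.std(y_train))
    return SVR(kernel=kernel, C=DEFAULT_C, epsilon=DEFAULT_EPSILON_FRACTION * max(sd, 1e-12))


def evaluate_params(
    params: PreprocParams,
    subjects: Sequence[SubjectRecord],
    subset: Sequence[int],
    task: str,
    k: int = 10,
    seed: int = 0,
    subset_id: int = -1,
    scale_features: bool = False,
    resample_mode: str = "linear",
) -> ObjectiveValue:
    """Score one (voxel size, FWHM) candidate on one disjoint subset.

    Features are built from the subset only; each fold's model sees only its
    training rows (no leakage), so repeated calls with the same seed are
    bit-reproducible.  A degenerate feature matrix (zero retained voxels)
    yields the worst-case objective — 1.0 for classification, the subset's
    age-range width for regression — flagged rather than raised, so the
    surrogate treats failures as poor regions.
    """
    t0 = time.perf_counter()
    subset = np.asarray(subset, dtype=int)
    members = [subjects[i] for i in subset]
    if task == "classification":
        y = np.array([m.group for m in members])
        if any(g is None for g in y):
            raise InputError("classification requires group labels on every subject")
    elif task == "regression":
        y = np.array([m.age_years for m in members], dtype=float)
    else:
        raise InputError(f"task must be classification or regression, got {task!r}")

    features = vectorize_dataset(members, params, resample_mode=resample_mode)
    if features.n_features == 0:
        worst = 1.0 if task == "classification" else float(np.ptp(y))
        return ObjectiveValue(
            value=worst,
            per_fold=(),
            params=params,
            subset_id=subset_id,
            elapsed_s=time.perf_counter() - t0,
            degenerate=True,
        )

    X = features.values
    folds = crossval_split(y, k, task, seed)
    # linear kernel: precompute the Gram matrix once and slice per fold
    # (identical model, avoids re-doing the dominant X·Xᵀ work k times)
    gram = X @ X.T if not scale_features else None
    per_fold = []
    for tr, te in folds:
        if scale_features:
            scaler = StandardScaler().fit(X[tr])
            X_tr, X_te = scaler.transform(X[tr]), scaler.transform(X[te])
            model = make_estimator(task, y[tr])
            model.fit(X_tr, y[tr])
            pred = model.predict(X_te)
        else:
            model = make_estimator(task, y[tr], precomputed=True)
            model.fit(gram[np.ix_(tr, tr)], y[tr])
            pred = model.predict(gram[np.ix_(te, tr)])
        if task == "classification":
            per_fold.append(float(np.mean(pred != y[te])))
        else:
            per_fold.append(float(np.mean(np.abs(pred - y[te]))))
    return ObjectiveValue(
        value=float(np.mean(per_fold)),
        per_fold=tuple(per_fold),
        params=params,
        subset_id=subset_id,
        elapsed_s=time.perf_counter() - t0,
    )


class EvaluationLog:
    """Append-only CSV log of objective evaluations."""

    FIELDS = ["iteration", "voxel_mm", "fwhm_mm", "objective", "per_fold", "elapsed_s", "seed"]

    def __init__(self, path: Union[str, Path]):
        self.path = Path(path)
        if not self.path.exists():
            with open(self.path, "w", newline="") as fh:
                csv.writer(fh).writerow(self.FIELDS)

    def append(self, iteration: int, obs: ObjectiveValue, seed: int) -> None:
        with open(self.path, "a", newline="") as fh:
            csv.writer(fh).writerow(
                [
                    iteration,
                    f"{obs.params.voxel_size_mm:.6g}",
                    f"{obs.params.fwhm_mm:.6g}",
                    f"{obs.value:.8g}",
                    ";".join(f"{v:.6g}" for v in obs.per_fold),
                    f"{obs.elapsed_s:.4f}",
                    seed,
                ]
            )
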