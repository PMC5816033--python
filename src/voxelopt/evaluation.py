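"""Final-model training, reporting and statistical comparison.

Covers the downstream layer of the pipeline: hold-out accuracy / MAE /
Pearson r / R² reporting, the two paired comparisons (McNemar's chi-square
for classifiers, Steiger's z for dependent correlations), the stability
cross-correlation analysis of fitted objective surfaces, and the three-case
cross-dataset generalization protocol.

R² is reported as the square of the Pearson correlation between predicted
and true age (not 1 − SSE/SST); this is the convention the rest of the
package follows throughout.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError, ParameterError
from .objective import make_estimator
from .preprocess import PreprocParams, vectorize_dataset
from .subsampling import build_strata, make_plan
from .volumes import SubjectRecord
from . import bayesopt as bo

__all__ = [
    "ConfusionTable",
    "MetricsReport",
    "TestResult",
    "GeneralizationReport",
    "GeneralizationConfig",
    "accuracy_from_confusion",
    "mcnemar_test",
    "mcnemar_from_counts",
    "steiger_z",
    "regression_metrics",
    "split_holdout",
    "train_final_and_holdout",
    "stability_correlations",
    "generalization_cases",
]


@dataclass(frozen=True)
class ConfusionTable:
    """2×2 confusion counts, rows = predicted (old, young), columns =
    actual (old, young)."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        if counts.shape != (2, 2) or np.any(counts < 0):
            raise InputError("confusion table must be 2x2 with nonnegative counts")
        if counts.sum() == 0:
            raise InputError("confusion table must contain at least one subject")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class MetricsReport:
    """Prediction-quality summary for one evaluated model."""

    n: int
    mae_years: Optional[float] = None
    pearson_r: Optional[float] = None
    r_squared: Optional[float] = None
    accuracy: Optional[float] = None
    confusion: Optional[ConfusionTable] = None
    predictions: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        if self.pearson_r is not None and self.r_squared is not None:
            if abs(self.r_squared - self.pearson_r**2) > 1e-12:
                raise InputError("r_squared must equal pearson_r squared")


@dataclass(frozen=True)
class TestResult:
    """A paired-comparison test outcome."""

    statistic: float
    p_value: float
    method: str  # mcnemar | steiger
    degenerate: bool = False


@dataclass(frozen=True)
class GeneralizationReport:
    """One of the three cross-dataset validation cases.  ``audit`` records
    which subject ids each stage consumed (isolation check for case 2)."""

    case_id: int
    params_source: str
    model_source: str
    params: PreprocParams
    metrics: MetricsReport
    audit: Optional[dict] = None


def accuracy_from_confusion(table: ConfusionTable) -> float:
    """(correct old + correct young) / total."""
    c = table.counts
    return float((c[0, 0] + c[1, 1]) / c.sum())


def mcnemar_from_counts(b: int, c: int, correction: bool = False) -> TestResult:
    """McNemar's chi-square from the discordant counts b, c.

    chi2 = (|b − c| − corr)² / (b + c) with the continuity correction
    (corr = 1) off by default; p from the upper tail of chi-square with
    1 df.  b + c = 0 is degenerate: statistic 0, p = 1, flagged.
    """
    if b < 0 or c < 0:
        raise InputError("discordant counts must be nonnegative")
    if b + c == 0:
        return TestResult(0.0, 1.0, "mcnemar", degenerate=True)
    corr = 1.0 if correction else 0.0
    stat = (abs(b - c) - corr) ** 2 / (b + c)
    return TestResult(float(stat), float(stats.chi2.sf(stat, df=1)), "mcnemar")


def mcnemar_test(
    correct_a: Sequence[bool], correct_b: Sequence[bool], correction: bool = False
) -> TestResult:
    """Compare two classifiers on the same subjects via their discordant
    pairs (A right & B wrong vs A wrong & B right)."""
    a = np.asarray(correct_a, dtype=bool)
    bb = np.asarray(correct_b, dtype=bool)
    if a.shape != bb.shape:
        raise InputError("paired outcome vectors must have equal length")
    b = int(np.sum(a & ~bb))
    c = int(np.sum(~a & bb))
    return mcnemar_from_counts(b, c, correction=correction)


def steiger_z(r12: float, r13: float, r23: float, n: int) -> TestResult:
    """Steiger's z-test for two dependent correlations sharing variable 1.

    Tests H0: rho(1,2) = rho(1,3) given the dependence through r23, using
    Fisher-transformed correlations (Steiger's Z̄* with the Dunn-Clark
    covariance term).  Two-sided p from the normal tail.
    """
    for r in (r12, r13, r23):
        if not -1 < r < 1:
            raise InputError(f"correlations must lie strictly inside (-1, 1), got {r}")
    if n <= 3:
        raise InputError("need n > 3 for the Fisher-transform variance")
    z12, z13 = np.arctanh(r12), np.arctanh(r13)
    rm2 = (r12**2 + r13**2) / 2.0
    f = min((1.0 - r23) / (2.0 * (1.0 - rm2)), 1.0)
    h = (1.0 - f * rm2) / (1.0 - rm2)
    z = (z12 - z13) * np.sqrt((n - 3) / (2.0 * (1.0 - r23) * h))
    return TestResult(float(z), float(2.0 * stats.norm.sf(abs(z))), "steiger")


def regression_metrics(
    true_ages: Sequence[float], predicted_ages: Sequence[float]
) -> MetricsReport:
    """MAE (years), Pearson r and R² = r² for an age-prediction model."""
    y = np.asarray(true_ages, dtype=float)
    yhat = np.asarray(predicted_ages, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1:
        raise InputError("true and predicted ages must be equal-length vectors")
    if y.size < 3:
        raise InputError("need at least 3 pairs")
    if np.std(yhat) == 0 or np.std(y) == 0:
        raise InputError("zero-variance predictions or targets: correlation undefined")
    r = float(stats.pearsonr(y, yhat).statistic)
    return MetricsReport(
        n=int(y.size),
        mae_years=float(np.mean(np.abs(yhat - y))),
        pearson_r=r,
        r_squared=r**2,
    )


def _classification_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> MetricsReport:
    """Accuracy plus the (old, young)-ordered confusion table."""
    labels = ["old", "young"] if set(y_true) == {"old", "young"} else sorted(set(y_true))
    counts = np.zeros((2, 2), dtype=int)
    for i, pl in enumerate(labels):
        for j, al in enumerate(labels):
            counts[i, j] = int(np.sum((y_pred == pl) & (y_true == al)))
    table = ConfusionTable(counts)
    return MetricsReport(n=int(y_true.size), accuracy=accuracy_from_confusion(table), confusion=table)


def split_holdout(
    ages: Sequence[float],
    holdout_n: int,
    seed: int,
    groups: Optional[Sequence[Optional[str]]] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded age-stratified train/hold-out split.

    The cohort is cut into ``holdout_n`` contiguous age strata and one
    seeded draw per stratum forms the hold-out, so the hold-out tracks the
    cohort's age distribution.  With group labels, the draw is made per
    group (half the hold-out from each).  Returns (train_idx, holdout_idx).
    """
    ages = np.asarray(ages, dtype=float)
    if not 0 < holdout_n < ages.size:
        raise InputError(f"holdout_n must be in (0, {ages.size}), got {holdout_n}")
    rng = np.random.default_rng(seed)

    def pick(indices: np.ndarray, n_pick: int) -> list[int]:
        strata = build_strata(ages[indices], n_pick)
        return [int(indices[s[rng.integers(len(s))]]) for s in strata]

    if groups is not None and any(g for g in groups):
        groups = np.asarray([g if g else "" for g in groups])
        labels = [g for g in dict.fromkeys(groups) if g]
        holdout: list[int] = []
        share = holdout_n // len(labels)
        extra = holdout_n - share * len(labels)
        for i, lab in enumerate(labels):
            holdout.extend(pick(np.flatnonzero(groups == lab), share + (1 if i < extra else 0)))
    else:
        holdout = pick(np.arange(ages.size), holdout_n)
    holdout_idx = np.array(sorted(holdout), dtype=int)
    train_idx = np.setdiff1d(np.arange(ages.size), holdout_idx)
    return train_idx, holdout_idx


def train_final_and_holdout(
    subjects: Sequence[SubjectRecord],
    params: PreprocParams,
    task: str,
    holdout_n: int,
    seed: int,
    bounds: Optional[bo.Bounds] = None,
) -> MetricsReport:
    """Train the final model with the supplied pre-processing parameters and
    score it on an untouched, age-stratified hold-out.

    The model only ever sees the training portion; metrics come from the
    hold-out.  Re-running with the same seed reproduces the report exactly.
    """
    if bounds is not None and not bounds.contains(params):
        raise ParameterError(f"{params} outside the task bounds {bounds}")
    ages = np.array([s.age_years for s in subjects], dtype=float)
    groups = [s.group for s in subjects]
    train_idx, hold_idx = split_holdout(
        ages, holdout_n, seed, groups=groups if task == "classification" else None
    )
    features = vectorize_dataset(list(subjects), params)
    X = features.values
    if task == "classification":
        y = np.asarray([g if g is not None else "" for g in groups])
    else:
        y = ages
    model = make_estimator(task, y[train_idx])
    model.fit(X[train_idx], y[train_idx])
    pred = model.predict(X[hold_idx])

    ids = [subjects[i].id for i in hold_idx]
    if task == "classification":
        report = _classification_metrics(y[hold_idx], pred)
        pred_df = pd.DataFrame({"id": ids, "true": y[hold_idx], "predicted": pred})
    else:
        report = regression_metrics(y[hold_idx], pred)
        pred_df = pd.DataFrame({"id": ids, "age": y[hold_idx], "predicted_age": pred})
    return MetricsReport(
        n=report.n,
        mae_years=report.mae_years,
        pearson_r=report.pearson_r,
        r_squared=report.r_squared,
        accuracy=report.accuracy,
        confusion=report.confusion,
        predictions=pred_df,
    )


def stability_correlations(
    models: Sequence[bo.SurrogateModel],
    grid_shape: tuple[int, int] = (30, 30),
) -> np.ndarray:
    """Pairwise Pearson correlation of posterior-mean surfaces.

    All runs must share one search box; each surface is sampled on the same
    grid, flattened and correlated.  The matrix is symmetric with a unit
    diagonal — the heat-map input of the stability analysis.
    """
    if len(models) < 2:
        raise InputError("need at least two fitted runs to correlate")
    boxes = {(m.bounds.voxel_mm, m.bounds.fwhm_mm) for m in models}
    if len(boxes) != 1:
        raise InputError(f"runs must share one search box, found {boxes}")
    surfaces = [
        bo.posterior_surface(m, m.bounds, grid_shape)["mean"] for m in models
    ]
    corr = np.corrcoef(np.stack(surfaces))
    # enforce exact symmetry and unit diagonal (corrcoef can be off by 1 ulp)
    corr = 0.5 * (corr + corr.T)
    np.fill_diagonal(corr, 1.0)
    return corr


@dataclass(frozen=True)
class GeneralizationConfig:
    """Settings shared by the three cross-dataset cases."""

    n_per_iter: int = 40
    burn_in: int = 5
    acquisition: bo.AcquisitionSpec = field(default_factory=bo.AcquisitionSpec)
    seed: int = 0
    k: int = 10
    #: test fraction for the within-B split of cases 2-3 (≈ 60/648,
    #: mirroring a ~9.8:1 train:test ratio)
    test_fraction: float = 60.0 / 648.0


def generalization_cases(
    cohort_a: Sequence[SubjectRecord],
    cohort_b: Sequence[SubjectRecord],
    bounds: bo.Bounds,
    config: GeneralizationConfig = GeneralizationConfig(),
) -> list[GeneralizationReport]:
    """The three-case cross-dataset protocol for the regression task.

    Case 1: parameters optimized on A and the A-trained model, applied to
    all of B.  Case 2: the entire optimization framework re-run within B
    (train portion only), new model trained on B-train, scored on B-test.
    Case 3: A-derived parameters, but a fresh model trained/tested within B
    on the same split as case 2.
    """
    ids_a = {s.id for s in cohort_a}
    ids_b = {s.id for s in cohort_b}
    if ids_a & ids_b:
        raise InputError(f"cohorts share subject ids: {sorted(ids_a & ids_b)[:5]} ...")

    cfg = config
    # --- optimize on A
    plan_a = make_plan(list(cohort_a), cfg.n_per_iter, "regression", seed=cfg.seed)
    run_a = bo.run_loop(
        list(cohort_a), plan_a, "regression", bounds, cfg.acquisition,
        burn_in=cfg.burn_in, seed=cfg.seed, k=cfg.k,
    )
    params_a = run_a.estimated_optimum

    ages_b = np.array([s.age_years for s in cohort_b], dtype=float)
    n_test = max(3, int(round(cfg.test_fraction * len(cohort_b))))
    train_b, test_b = split_holdout(ages_b, n_test, seed=cfg.seed + 1)

    # --- case 1: A params + A model → all of B
    feats_a = vectorize_dataset(list(cohort_a), params_a)
    y_a = np.array([s.age_years for s in cohort_a], dtype=float)
    model_a = make_estimator("regression", y_a)
    model_a.fit(feats_a.values, y_a)
    feats_b_pa = vectorize_dataset(list(cohort_b), params_a, mask=None)
    # align columns: apply A's feature mask to B's resampled grid
    full_b = feats_b_pa
    if not np.array_equal(full_b.feature_index, feats_a.feature_index):
        # re-vectorize B keeping exactly A's retained voxels
        mask = np.zeros(int(np.prod(feats_a.grid_shape)), dtype=bool)
        mask[feats_a.feature_index] = True
        full_b = vectorize_dataset(
            list(cohort_b), params_a, mask=mask.reshape(feats_a.grid_shape)
        )
    pred_b = model_a.predict(full_b.values)
    m1 = dataclasses.replace(
        regression_metrics(ages_b, pred_b),
        predictions=pd.DataFrame(
            {"id": [s.id for s in cohort_b], "age": ages_b, "predicted_age": pred_b}
        ),
    )
    case1 = GeneralizationReport(
        1, "A", "A", params_a, m1,
        audit={"model_trained_on": sorted(s.id for s in cohort_a)},
    )

    # --- case 2: full re-optimization and re-training within B
    b_train_subjects = [cohort_b[i] for i in train_b]
    plan_b = make_plan(b_train_subjects, min(cfg.n_per_iter, max(2, len(train_b) // 2)),
                       "regression", seed=cfg.seed + 2)
    run_b = bo.run_loop(
        b_train_subjects, plan_b, "regression", bounds, cfg.acquisition,
        burn_in=min(cfg.burn_in, plan_b.n_subsets), seed=cfg.seed + 2, k=cfg.k,
    )
    params_b = run_b.estimated_optimum
    case2 = GeneralizationReport(
        2, "B", "B", params_b,
        _fit_and_score_regression(cohort_b, train_b, test_b, params_b),
        audit={
            "optimization_subsets": [
                [b_train_subjects[i].id for i in sub] for sub in plan_b.subsets
            ],
            "model_trained_on": sorted(cohort_b[i].id for i in train_b),
        },
    )

    # --- case 3: A params, B-trained model, same split as case 2
    case3 = GeneralizationReport(
        3, "A", "B", params_a,
        _fit_and_score_regression(cohort_b, train_b, test_b, params_a),
    )
    return [case1, case2, case3]


def _fit_and_score_regression(
    cohort: Sequence[SubjectRecord],
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    params: PreprocParams,
) -> MetricsReport:
    feats = vectorize_dataset(list(cohort), params)
    ages = np.array([s.age_years for s in cohort], dtype=float)
    model = make_estimator("regression", ages[train_idx])
    model.fit(feats.values[train_idx], ages[train_idx])
    pred = model.predict(feats.values[test_idx])
    base = regression_metrics(ages[test_idx], pred)
    pred_df = pd.DataFrame(
        {
            "id": [cohort[i].id for i in test_idx],
            "age": ages[test_idx],
            "predicted_age": pred,
        }
    )
    return dataclasses.replace(base, predictions=pred_df)
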