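"""The synthetic parameter-recovery benchmark.

A classification cohort with a planted 8 mm signal scale defines a ground
truth: an exhaustive grid evaluation of the objective over the search box
(the oracle, which the optimizer never sees) identifies where pre-processing
is genuinely best.  The benchmark then asks whether the 12-evaluation
optimization (5 burn-in + 7 guided) lands in the oracle's best region, and
whether guided sampling beats a pure-random search of the same budget on
paired subsets.

The search box is the 1-15 mm voxel × 1-10 mm FWHM stability-analysis box;
subsets hold 32 subjects (16 per group) so a 400-subject cohort yields the
12 disjoint evaluations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .bayesopt import AcquisitionSpec, Bounds, OptimizationResult, run_loop
from .objective import ObjectiveValue, evaluate_params
from .preprocess import PreprocParams
from .subsampling import SubsamplePlan, make_plan
from .volumes import CohortSpec, SubjectRecord, generate_cohort

__all__ = [
    "BENCH_BOUNDS",
    "BENCH_N_PER_ITER",
    "GridOracle",
    "make_benchmark_cohort",
    "exhaustive_grid_oracle",
    "run_benchmark_optimization",
    "random_search_best",
    "synthetic_error_surface",
    "run_synthetic_objective",
]

#: Search box of the benchmark (voxel mm, FWHM mm).
BENCH_BOUNDS = Bounds((1.0, 15.0), (1.0, 10.0))
#: Subjects per optimization iteration (16 young + 16 old).
BENCH_N_PER_ITER = 32


def make_benchmark_cohort(seed: int = 0) -> tuple[CohortSpec, list[SubjectRecord]]:
    """The default-scale classification cohort: 400 subjects, 32³ grid,
    young/old design, default signal and noise settings."""
    spec = CohortSpec(seed=seed)
    subjects, _ = generate_cohort(spec, design="two_group")
    return spec, subjects


@dataclass(frozen=True)
class GridOracle:
    """Exhaustive grid evaluation of the objective."""

    voxel_mm: np.ndarray      # grid axis, length nv
    fwhm_mm: np.ndarray       # grid axis, length nf
    values: np.ndarray        # (nv, nf) mean objective per cell
    top_decile: np.ndarray    # (nv, nf) boolean mask of the best 10% of cells

    def cell_of(self, params: PreprocParams) -> tuple[int, int]:
        """Nearest grid cell to a parameter point."""
        i = int(np.argmin(np.abs(self.voxel_mm - params.voxel_size_mm)))
        j = int(np.argmin(np.abs(self.fwhm_mm - params.fwhm_mm)))
        return i, j

    def in_top_decile(self, params: PreprocParams) -> bool:
        return bool(self.top_decile[self.cell_of(params)])


def exhaustive_grid_oracle(
    subjects: Sequence[SubjectRecord],
    bounds: Bounds = BENCH_BOUNDS,
    grid_shape: tuple[int, int] = (10, 10),
    subsets_per_cell: int = 3,
    n_per_iter: int = BENCH_N_PER_ITER,
    seed: int = 10_000,
    task: str = "classification",
    k: int = 10,
) -> GridOracle:
    """Evaluate every grid cell on ``subsets_per_cell`` disjoint subsets and
    average — the ground-truth surface the optimizer is judged against.

    The oracle uses its own sub-sampling plan (own seed), so it shares no
    evaluation data with any optimization run under test.
    """
    plan = make_plan(list(subjects), n_per_iter, task, seed=seed)
    if subsets_per_cell > plan.n_subsets:
        raise ValueError("not enough disjoint subsets for the requested averaging")
    gv = np.linspace(bounds.voxel_mm[0], bounds.voxel_mm[1], grid_shape[0])
    gf = np.linspace(bounds.fwhm_mm[0], bounds.fwhm_mm[1], grid_shape[1])
    values = np.empty(grid_shape)
    for i, v in enumerate(gv):
        for j, f in enumerate(gf):
            params = PreprocParams(float(v), float(f))
            scores = [
                evaluate_params(
                    params, subjects, plan.subsets[s], task, k=k, seed=seed + 71 * s
                ).value
                for s in range(subsets_per_cell)
            ]
            values[i, j] = float(np.mean(scores))
    n_top = max(1, int(round(0.1 * values.size)))
    cutoff = np.sort(values.ravel())[n_top - 1]
    return GridOracle(voxel_mm=gv, fwhm_mm=gf, values=values, top_decile=values <= cutoff)


def run_benchmark_optimization(
    subjects: Sequence[SubjectRecord],
    seed: int,
    spec: AcquisitionSpec = AcquisitionSpec(),
    bounds: Bounds = BENCH_BOUNDS,
    burn_in: int = 5,
    n_per_iter: int = BENCH_N_PER_ITER,
    task: str = "classification",
    k: int = 10,
) -> OptimizationResult:
    """One full optimization run: fresh plan and burn-in for this seed."""
    plan = make_plan(list(subjects), n_per_iter, task, seed=seed)
    return run_loop(subjects, plan, task, bounds, spec, burn_in=burn_in, seed=seed, k=k)


def synthetic_error_surface(voxel_mm, fwhm_mm):
    """A closed-form analogue of the classification-error landscape.

    Shaped like the cohort-based objective — a fine-voxel noise penalty, a
    signal-dilution cliff beyond ~10 mm voxels and a shallow smoothing bowl
    around 6 mm FWHM — but evaluable instantly and with controllable noise,
    so surface-stability analyses isolate the optimizer's reproducibility
    from the image pipeline's sampling noise.
    """
    v = np.asarray(voxel_mm, dtype=float)
    f = np.asarray(fwhm_mm, dtype=float)
    return (
        0.22
        + 0.30 / (1.0 + np.exp(-(v - 10.0) / 1.2))
        + 0.06 * np.exp(-(v - 1.0) / 1.5)
        + 0.04 * ((f - 6.0) / 5.0) ** 2
    )


def run_synthetic_objective(
    seed: int,
    spec: AcquisitionSpec = AcquisitionSpec(),
    bounds: Bounds = BENCH_BOUNDS,
    n_evaluations: int = 12,
    burn_in: int = 5,
    noise_sd: float = 0.05,
) -> OptimizationResult:
    """One optimization run on the analytic noisy objective.

    Mirrors the cohort protocol (12 evaluations, burn-in 5) but scores
    candidates on :func:`synthetic_error_surface` plus seeded Gaussian
    evaluation noise.
    """
    ages = np.linspace(20.0, 80.0, 10 * n_evaluations)
    plan = make_plan(ages, 10, "regression", seed=seed)
    rng = np.random.default_rng(seed + 5000)

    def evaluate(params: PreprocParams, it: int) -> ObjectiveValue:
        val = float(
            synthetic_error_surface(params.voxel_size_mm, params.fwhm_mm)
            + rng.normal(0.0, noise_sd)
        )
        return ObjectiveValue(
            value=val, per_fold=(val,), params=params, subset_id=it, elapsed_s=0.01
        )

    return run_loop(
        [], plan, "regression", bounds, spec, burn_in=burn_in, seed=seed, evaluate=evaluate
    )


def random_search_best(
    subjects: Sequence[SubjectRecord],
    seed: int,
    bounds: Bounds = BENCH_BOUNDS,
    n_evaluations: int = 12,
    n_per_iter: int = BENCH_N_PER_ITER,
    task: str = "classification",
    k: int = 10,
) -> float:
    """Best objective found by pure uniform-random sampling with the same
    evaluation budget and the same per-seed sub-sampling plan as the guided
    run — the paired baseline."""
    plan = make_plan(list(subjects), n_per_iter, task, seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    pts = rng.uniform(bounds.lows, bounds.highs, size=(n_evaluations, 2))
    ss = np.random.SeedSequence(seed)
    eval_seeds = [int(s) for s in ss.generate_state(n_evaluations) % (2**31)]
    best = np.inf
    for it in range(n_evaluations):
        params = PreprocParams(float(pts[it, 0]), float(pts[it, 1]))
        val = evaluate_params(
            params, subjects, plan.subsets[it], task, k=k, seed=eval_seeds[it]
        ).value
        best = min(best, val)
    return float(best)
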