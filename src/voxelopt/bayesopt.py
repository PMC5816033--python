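"""Gaussian-process Bayesian optimization over (voxel size, FWHM).

The optimizer maintains a GP surrogate of the objective over the 2-D
pre-processing search space, refined in a closed loop: a burn-in phase of
randomly sampled points seeds the surrogate, after which each iteration
maximizes an acquisition function to propose the next candidate, which is
scored on the next unused disjoint subject subset.  Six acquisition
functions are supported — expected improvement (EI), EI per second, EI+
(EI with an exploratory escape rule), EI per second +, lower confidence
bound and probability of improvement.  The EI+ escape triggers when the
posterior standard deviation at the incumbent falls below the noise
standard deviation times the exploration ratio, in which case the surrogate's
predictive variability is inflated for the next proposal so the search can
leave an over-exploited region.

Kernel machinery (anisotropic Matérn-5/2 + constant mean + Gaussian noise,
multi-start marginal-likelihood fitting) is delegated to scikit-learn;
inputs are affinely mapped to the unit square and objective values z-scored
before fitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.stats import norm, qmc
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel

from .errors import InputError, ParameterError
from .objective import ObjectiveValue, evaluate_params
from .preprocess import PreprocParams
from .subsampling import SubsamplePlan
from .volumes import SubjectRecord

__all__ = [
    "Bounds",
    "Observation",
    "AcquisitionSpec",
    "SurrogateModel",
    "OptimizationResult",
    "ACQUISITION_NAMES",
    "fit_surrogate",
    "posterior_predict",
    "acquisition_value",
    "eiplus_escape_check",
    "propose_next",
    "run_loop",
    "estimate_optimum",
    "posterior_surface",
    "fit_time_model",
]

ACQUISITION_NAMES = ("ei", "ei_per_second", "ei_plus", "ei_per_second_plus", "lcb", "pi")

#: Classification-task search box (mm): voxel 1-30, FWHM 1-20.
#: Regression uses the narrower 1-15 / 1-10 box (see Bounds.for_task).


@dataclass(frozen=True)
class Bounds:
    """The rectangular search box: (lo, hi) in mm for each dimension."""

    voxel_mm: tuple[float, float]
    fwhm_mm: tuple[float, float]

    def __post_init__(self) -> None:
        for lo, hi in (self.voxel_mm, self.fwhm_mm):
            if not (0 < lo < hi):
                raise ParameterError(f"bounds must satisfy 0 < lo < hi, got {(lo, hi)}")

    @classmethod
    def for_task(cls, task: str) -> "Bounds":
        """Default boxes: 1-30 × 1-20 mm for classification, 1-15 × 1-10 mm
        for regression (the narrower space keeps the costlier task cheap)."""
        if task == "classification":
            return cls((1.0, 30.0), (1.0, 20.0))
        if task == "regression":
            return cls((1.0, 15.0), (1.0, 10.0))
        raise ParameterError(f"unknown task {task!r}")

    @property
    def lows(self) -> np.ndarray:
        return np.array([self.voxel_mm[0], self.fwhm_mm[0]])

    @property
    def highs(self) -> np.ndarray:
        return np.array([self.voxel_mm[1], self.fwhm_mm[1]])

    def contains(self, params: PreprocParams, atol: float = 1e-9) -> bool:
        x = params.as_array()
        return bool(np.all(x >= self.lows - atol) and np.all(x <= self.highs + atol))

    def to_unit(self, x: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(x) - self.lows) / (self.highs - self.lows)

    def from_unit(self, u: np.ndarray) -> np.ndarray:
        return self.lows + np.atleast_2d(u) * (self.highs - self.lows)


@dataclass(frozen=True)
class Observation:
    """One evaluated point in the loop."""

    params: PreprocParams
    y: float
    elapsed_s: float = 0.0
    phase: str = "guided"  # burn_in | guided
    subset_id: int = -1


@dataclass(frozen=True)
class AcquisitionSpec:
    """Which acquisition to maximize and how exploratory to be.

    ``exploration_ratio`` is the exploration-exploitation ratio in (0, 1)
    (default 0.5).  It sets the EI+ escape threshold directly and maps to
    the LCB weight as kappa = 2 × ratio.  ``escape_inflation`` is the factor
    by which the posterior sd is inflated for one proposal after an EI+
    escape triggers.
    """

    name: str = "ei_plus"
    exploration_ratio: float = 0.5
    escape_inflation: float = 5.0

    def __post_init__(self) -> None:
        name = self.name.lower().replace("+", "_plus").replace(" ", "_")
        if name not in ACQUISITION_NAMES:
            raise ParameterError(f"acquisition must be one of {ACQUISITION_NAMES}, got {self.name!r}")
        object.__setattr__(self, "name", name)
        if not 0 < self.exploration_ratio < 1:
            raise ParameterError("exploration_ratio must lie in (0, 1)")

    @property
    def is_plus(self) -> bool:
        return self.name in ("ei_plus", "ei_per_second_plus")

    @property
    def per_second(self) -> bool:
        return self.name in ("ei_per_second", "ei_per_second_plus")


@dataclass(frozen=True)
class SurrogateModel:
    """Fitted GP posterior over the search box.

    Wraps a scikit-learn GP fitted on unit-square inputs and z-scored
    objective values; predictions are reported in original units for the
    noise-free latent objective (the fitted noise variance is subtracted
    from the predictive variance).
    """

    gpr: GaussianProcessRegressor
    bounds: Bounds
    y_mean: float
    y_sd: float
    noise_sd: float  # fitted noise level, original units
    observations: tuple[Observation, ...]
    sd_inflation: float = 1.0

    def predict(self, x_mm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Posterior mean and sd of the latent objective at points given in
        mm, shape (n, 2) or (2,)."""
        u = self.bounds.to_unit(np.atleast_2d(x_mm))
        mean_z, sd_z = self.gpr.predict(u, return_std=True)
        noise_z = self.noise_sd / self.y_sd
        latent_var = np.clip(sd_z**2 - noise_z**2, 0.0, None)
        mean = mean_z * self.y_sd + self.y_mean
        sd = np.sqrt(latent_var) * self.y_sd * self.sd_inflation
        return mean, sd

    def inflated(self, factor: float) -> "SurrogateModel":
        """A copy with predictive sd multiplied by ``factor`` (the EI+
        escape's exploratory surrogate)."""
        return replace(self, sd_inflation=self.sd_inflation * factor)

    @property
    def prior_mean(self) -> float:
        return self.y_mean

    @property
    def incumbent(self) -> Observation:
        """Best (lowest-objective) observation."""
        return min(self.observations, key=lambda o: o.y)

    def plugin_incumbent(self) -> tuple[Observation, float]:
        """The sampled point with the lowest *posterior mean*, and that mean.

        With noisy evaluations the raw best observation is biased low (it is
        the luckiest draw, not the best parameters), which deflates
        improvement-based acquisitions; the posterior-mean plug-in is the
        standard noisy-optimization incumbent.
        """
        X = np.stack([o.params.as_array() for o in self.observations])
        mean, _ = self.predict(X)
        i = int(np.argmin(mean))
        return self.observations[i], float(mean[i])


@dataclass(frozen=True)
class OptimizationResult:
    """Everything a finished run produces."""

    observations: tuple[Observation, ...]
    model: SurrogateModel
    best_observed: Observation
    estimated_optimum: PreprocParams
    estimated_min: float
    bounds: Bounds
    complete: bool = True


def _default_kernel(length_scale: Sequence[float] = (0.3, 0.3), noise_level: float = 1e-2):
    # length scales bounded to [0.1, 2] of the unit square: the objective is
    # smooth at the search-box scale, and unbounded ML on ~12 points
    # otherwise collapses to noise-interpolating spikes or to a surface flat
    # in one dimension (spurious likelihood modes)
    return (
        ConstantKernel(1.0, (1e-3, 1e3))
        * Matern(length_scale=list(length_scale), length_scale_bounds=(0.1, 2.0), nu=2.5)
        + WhiteKernel(noise_level=noise_level, noise_level_bounds=(1e-10, 1e1))
    )


def fit_surrogate(
    observations: Sequence[Observation],
    bounds: Bounds,
    seed: int = 0,
    n_restarts: int = 4,
    optimize_hyperparams: bool = True,
    length_scale: Sequence[float] = (0.3, 0.3),
    noise_level: float = 1e-2,
) -> SurrogateModel:
    """Fit the GP surrogate to the evaluated points.

    Kernel hyper-parameters maximize the marginal likelihood from
    ``n_restarts`` extra random starts; the white-noise term absorbs
    duplicate inputs without singular kernel matrices.  With
    ``optimize_hyperparams=False`` the kernel is used as initialized
    (useful for controlled analyses of the posterior itself).
    """
    if len(observations) < 1:
        raise InputError("need at least one observation to fit a surrogate")
    X = np.stack([o.params.as_array() for o in observations])
    y = np.array([o.y for o in observations], dtype=float)
    y_mean = float(y.mean())
    y_sd = float(y.std())
    if y_sd < 1e-12:
        y_sd = 1.0
    y_z = (y - y_mean) / y_sd

    gpr = GaussianProcessRegressor(
        kernel=_default_kernel(length_scale, noise_level),
        alpha=1e-10,
        normalize_y=False,
        optimizer="fmin_l_bfgs_b" if optimize_hyperparams else None,
        n_restarts_optimizer=n_restarts if optimize_hyperparams else 0,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=ConvergenceWarning)
        gpr.fit(bounds.to_unit(X), y_z)
    noise_level = float(gpr.kernel_.k2.noise_level)
    return SurrogateModel(
        gpr=gpr,
        bounds=bounds,
        y_mean=y_mean,
        y_sd=y_sd,
        noise_sd=float(np.sqrt(noise_level)) * y_sd,
        observations=tuple(observations),
    )


def posterior_predict(model: SurrogateModel, params: PreprocParams) -> tuple[float, float]:
    """Posterior (mean, sd) of the latent objective at one in-bounds point."""
    if not model.bounds.contains(params):
        raise ParameterError(f"{params} lies outside the search box {model.bounds}")
    mean, sd = model.predict(params.as_array())
    return float(mean[0]), float(sd[0])


def _ei(mean: np.ndarray, sd: np.ndarray, best_y: float) -> np.ndarray:
    """Closed-form expected improvement for minimization."""
    imp = best_y - mean
    out = np.maximum(imp, 0.0)
    pos = sd > 0
    z = np.where(pos, imp / np.where(pos, sd, 1.0), 0.0)
    out = np.where(pos, imp * norm.cdf(z) + sd * norm.pdf(z), out)
    return np.maximum(out, 0.0)


def acquisition_value(
    model: SurrogateModel,
    params,
    spec: AcquisitionSpec,
    best_y: float,
    predicted_time: Optional[np.ndarray] = None,
):
    """Evaluate the acquisition at one or many points (higher = better).

    EI = E[max(0, best_y − Y)], PI = P(Y < best_y); LCB variants rank by
    mean − kappa·sd with kappa = 2 × exploration_ratio (returned negated so
    that maximization applies uniformly); per-second variants divide EI by
    the predicted evaluation time.
    """
    x = params.as_array() if isinstance(params, PreprocParams) else np.asarray(params, float)
    scalar = x.ndim == 1
    mean, sd = model.predict(x)

    if spec.name in ("ei", "ei_plus", "ei_per_second", "ei_per_second_plus"):
        val = _ei(mean, sd, best_y)
        if spec.per_second:
            if predicted_time is None:
                raise ParameterError("per-second acquisitions need a predicted evaluation time")
            t = np.broadcast_to(np.asarray(predicted_time, float), mean.shape)
            if np.any(t <= 0):
                raise ParameterError("predicted evaluation time must be positive")
            val = val / t
    elif spec.name == "pi":
        with np.errstate(divide="ignore"):
            z = np.where(sd > 0, (best_y - mean) / np.where(sd > 0, sd, 1.0), np.inf)
        val = np.where(sd > 0, norm.cdf(z), (mean < best_y).astype(float))
    else:  # lcb
        kappa = 2.0 * spec.exploration_ratio
        val = -(mean - kappa * sd)
    return float(val[0]) if scalar else val


def eiplus_escape_check(
    model: SurrogateModel, incumbent_region_sd: float, spec: AcquisitionSpec
) -> bool:
    """The EI+ escape rule: trigger exploratory behavior exactly when the
    posterior sd at the incumbent drops below the fitted noise sd times the
    exploration ratio (the region is considered over-exploited)."""
    return bool(incumbent_region_sd < model.noise_sd * spec.exploration_ratio)


def _candidates(bounds: Bounds, rng: np.random.Generator, n: int) -> np.ndarray:
    """Seeded quasi-random (Sobol) candidate set in mm, shape (n, 2)."""
    sampler = qmc.Sobol(d=2, scramble=True, seed=rng)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=UserWarning)
        u = sampler.random(n)
    return bounds.from_unit(u)


def propose_next(
    model: SurrogateModel,
    spec: AcquisitionSpec,
    bounds: Bounds,
    rng: np.random.Generator,
    n_candidates: int = 2048,
    time_model: Optional[Callable[[np.ndarray], np.ndarray]] = None,
    polish: bool = True,
) -> PreprocParams:
    """Approximate argmax of the acquisition over the search box.

    A seeded quasi-random candidate set is scored in bulk (ties broken by
    candidate order), then the best candidate is polished with a bounded
    local search.  The improvement target is the posterior-mean plug-in
    incumbent (robust to noisy evaluations).  For EI+ variants the escape
    rule is checked at the incumbent first and, when triggered, the
    surrogate's predictive sd is inflated for this proposal.
    """
    inc_obs, best_y = model.plugin_incumbent()
    if spec.is_plus:
        _, inc_sd = model.predict(inc_obs.params.as_array())
        if eiplus_escape_check(model, float(inc_sd[0]), spec):
            model = model.inflated(spec.escape_inflation)

    cand = _candidates(bounds, rng, n_candidates)
    times = time_model(cand) if (spec.per_second and time_model is not None) else None
    if spec.per_second and times is None:
        times = np.ones(len(cand))
    vals = acquisition_value(model, cand, spec, best_y, predicted_time=times)
    i_best = int(np.argmax(vals))
    x0, v0 = cand[i_best], vals[i_best]

    if polish and len(cand) > 1:
        def neg_acq(x: np.ndarray) -> float:
            t = time_model(x[None, :]) if (spec.per_second and time_model is not None) else (
                np.ones(1) if spec.per_second else None
            )
            return -float(np.atleast_1d(acquisition_value(model, x[None, :], spec, best_y, t))[0])

        res = minimize(
            neg_acq,
            x0,
            method="L-BFGS-B",
            bounds=list(zip(bounds.lows, bounds.highs)),
        )
        if res.success and -res.fun > v0:
            x0 = np.clip(res.x, bounds.lows, bounds.highs)
    return PreprocParams(float(x0[0]), float(x0[1]))


def fit_time_model(
    observations: Sequence[Observation], bounds: Bounds, seed: int = 0
) -> Callable[[np.ndarray], np.ndarray]:
    """Second GP over log evaluation time, for the per-second acquisitions.

    Returns a callable mapping (n, 2) parameter arrays to predicted seconds.
    """
    usable = [o for o in observations if o.elapsed_s > 0]
    if len(usable) < 2:
        return lambda x: np.ones(np.atleast_2d(x).shape[0])
    log_obs = [replace(o, y=float(np.log(o.elapsed_s))) for o in usable]
    tm = fit_surrogate(log_obs, bounds, seed=seed, n_restarts=1)

    def predict_seconds(x: np.ndarray) -> np.ndarray:
        mean, _ = tm.predict(np.atleast_2d(x))
        return np.exp(mean)

    return predict_seconds


def estimate_optimum(
    model: SurrogateModel, bounds: Bounds, grid_shape: tuple[int, int] = (60, 60)
) -> tuple[PreprocParams, float]:
    """Minimizer of the posterior-mean surface over the box.

    A dense grid scan locates the basin, then a bounded local search
    refines it; the returned minimum never exceeds the posterior mean at
    any grid point.
    """
    gv = np.linspace(bounds.voxel_mm[0], bounds.voxel_mm[1], grid_shape[0])
    gf = np.linspace(bounds.fwhm_mm[0], bounds.fwhm_mm[1], grid_shape[1])
    gx, gy = np.meshgrid(gv, gf, indexing="ij")
    # observed points join the candidate set and win ties (a flat posterior,
    # e.g. from a single observation, then returns the best sampled point)
    obs_pts = np.stack([o.params.as_array() for o in model.observations])
    pts = np.vstack([obs_pts, np.column_stack([gx.ravel(), gy.ravel()])])
    mean, _ = model.predict(pts)
    ties = np.nonzero(mean <= mean.min() + 1e-12)[0]
    i = int(ties[0])
    x0, m0 = pts[i], float(mean[i])

    def post_mean(x: np.ndarray) -> float:
        return float(model.predict(x[None, :])[0][0])

    res = minimize(post_mean, x0, method="L-BFGS-B", bounds=list(zip(bounds.lows, bounds.highs)))
    if res.success and res.fun < m0:
        x0, m0 = np.clip(res.x, bounds.lows, bounds.highs), float(res.fun)
    return PreprocParams(float(x0[0]), float(x0[1])), m0


def posterior_surface(
    model: SurrogateModel, bounds: Bounds, grid_shape: tuple[int, int] = (50, 50)
) -> dict[str, np.ndarray]:
    """Posterior mean/sd sampled on a regular grid — the objective-surface
    artifact behind the run's surface plots and the stability analysis."""
    gv = np.linspace(bounds.voxel_mm[0], bounds.voxel_mm[1], grid_shape[0])
    gf = np.linspace(bounds.fwhm_mm[0], bounds.fwhm_mm[1], grid_shape[1])
    gx, gy = np.meshgrid(gv, gf, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    mean, sd = model.predict(pts)
    return {
        "voxel_mm": pts[:, 0],
        "fwhm_mm": pts[:, 1],
        "mean": mean,
        "sd": sd,
        "grid_shape": np.array(grid_shape),
    }


def run_loop(
    subjects: Sequence[SubjectRecord],
    plan: SubsamplePlan,
    task: str,
    bounds: Bounds,
    spec: AcquisitionSpec = AcquisitionSpec(),
    burn_in: int = 5,
    seed: int = 0,
    k: int = 10,
    time_model: Optional[Callable[[np.ndarray], np.ndarray]] = None,
    log=None,
    evaluate=None,
) -> OptimizationResult:
    """Run the full optimization: burn-in then guided sampling.

    One disjoint subset is consumed per evaluation, so the number of
    evaluations equals the number of subsets in the plan.  The first
    ``burn_in`` points are seeded uniform draws over the box, independent of
    any objective value; each subsequent point maximizes the acquisition on
    the surrogate refitted to all previous observations.  Fully
    deterministic for a fixed seed and configuration.

    ``evaluate`` may override the inner objective (signature
    ``(params, subset_index) -> ObjectiveValue``), e.g. for synthetic
    benchmark objectives; ``time_model`` overrides the fitted time GP for
    the per-second acquisitions.
    """
    if burn_in < 1:
        raise ParameterError("burn_in must be >= 1")
    if burn_in > plan.n_subsets:
        raise ParameterError(
            f"burn_in {burn_in} exceeds the {plan.n_subsets} subsets available"
        )
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    eval_seeds = [int(s) for s in ss.generate_state(plan.n_subsets) % (2**31)]

    # seeded scrambled-Sobol burn-in: uniformly distributed and independent
    # of any objective value, but space-filling, so every run covers the box
    # (iid draws can leave whole regions unsampled at burn_in = 5)
    burn_pts = _candidates(bounds, rng, burn_in)

    observations: list[Observation] = []
    for it in range(plan.n_subsets):
        if it < burn_in:
            params = PreprocParams(float(burn_pts[it, 0]), float(burn_pts[it, 1]))
            phase = "burn_in"
        else:
            model = fit_surrogate(observations, bounds, seed=eval_seeds[it])
            tmodel = time_model
            if spec.per_second and tmodel is None:
                tmodel = fit_time_model(observations, bounds, seed=eval_seeds[it])
            params = propose_next(model, spec, bounds, rng, time_model=tmodel)
            phase = "guided"
        if evaluate is not None:
            obs_val = evaluate(params, it)
        else:
            obs_val = evaluate_params(
                params, subjects, plan.subsets[it], task, k=k, seed=eval_seeds[it], subset_id=it
            )
        observations.append(
            Observation(
                params=params,
                y=obs_val.value,
                elapsed_s=obs_val.elapsed_s,
                phase=phase,
                subset_id=it,
            )
        )
        if log is not None:
            log.append(it, obs_val, seed)

    model = fit_surrogate(observations, bounds, seed=seed)
    best = min(observations, key=lambda o: o.y)
    opt_params, opt_min = estimate_optimum(model, bounds)
    return OptimizationResult(
        observations=tuple(observations),
        model=model,
        best_observed=best,
        estimated_optimum=opt_params,
        estimated_min=opt_min,
        bounds=bounds,
    )
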