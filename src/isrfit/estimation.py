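"""Multi-start bounded nonlinear least-squares inference of secretion parameters.

For one species (insulin or c-peptide) the unknowns are the degradation
time(s) and the three secretion-sigmoid parameters.  The cost is the sum of
squared residuals between measured concentrations z(k) and the model plasma
output y(theta, t_k), simulated from the fasting steady state under the
interpolated glucose input.

Because the problem is nonconvex, the estimate and its uncertainty come
from an ensemble of local fits started at many random parameter draws
within physiological bounds; runs whose optimum sticks to a bound are
excluded, and the surviving solutions supply mean +/- SD parameters and
trajectories (a bootstrap over initializations).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
from scipy.optimize import least_squares

from . import models
from .models import ModelParams, SecretionParams, secretion_rate
from .preprocessing import GlucoseInput, OGTTRecord, interpolate_glucose

__all__ = [
    "ParamBounds",
    "FitConfig",
    "FitResult",
    "FitEnsemble",
    "EstimationError",
    "objective",
    "fit_single_start",
    "fit_ensemble",
    "fit_subject",
]


class EstimationError(RuntimeError):
    """Raised when an ensemble yields no accepted (interior, converged) solution."""


_UNIT_SCALE = {"mg/L": 1.0, "mg/dl": 0.1}  # glucose-unit scaling relative to mg/L


@dataclass(frozen=True)
class ParamBounds:
    """Box bounds for the random starts and for the constrained solver.

    Defaults are the physiologically plausible ranges in mg/L glucose
    units: tau in [10, 180] min, K_m in [1, 350] rate units, C_0 in
    [200, 1500] mg/L, alpha in [0.015, 0.045] per mg/L.  ``for_unit``
    rescales the glucose-linked bounds (C_0, alpha) to a record's unit.
    ``tau_i`` defaults to the ``tau_p`` range.
    """

    tau_p: Tuple[float, float] = (10.0, 180.0)
    km: Tuple[float, float] = (1.0, 350.0)
    c0: Tuple[float, float] = (200.0, 1500.0)
    alpha: Tuple[float, float] = (0.015, 0.045)
    tau_i: Optional[Tuple[float, float]] = None

    def __post_init__(self) -> None:
        for name in ("tau_p", "km", "c0", "alpha", "tau_i"):
            pair = getattr(self, name)
            if pair is None:
                continue
            lo, hi = pair
            if not lo < hi:
                raise ValueError(f"bounds for {name} must satisfy lower < upper, got {pair}")

    def for_unit(self, glucose_unit: str) -> "ParamBounds":
        s = _UNIT_SCALE[glucose_unit]
        return replace(
            self,
            c0=(self.c0[0] * s, self.c0[1] * s),
            alpha=(self.alpha[0] / s, self.alpha[1] / s),
        )

    def arrays(self, kind: str) -> Tuple[np.ndarray, np.ndarray, Tuple[str, ...]]:
        names = _param_names(kind)
        tau_i = self.tau_i if self.tau_i is not None else self.tau_p
        table = {"tau_p": self.tau_p, "tau_i": tau_i, "km": self.km, "c0": self.c0, "alpha": self.alpha}
        lb = np.array([table[n][0] for n in names])
        ub = np.array([table[n][1] for n in names])
        return lb, ub, names


def _param_names(kind: str) -> Tuple[str, ...]:
    if kind == "single":
        return ("tau_p", "km", "c0", "alpha")
    if kind == "two_compartment":
        return ("tau_p", "tau_i", "km", "c0", "alpha")
    raise ValueError(f"unknown model kind {kind!r}")


def _vector_to_params(vec: np.ndarray, kind: str) -> ModelParams:
    if kind == "single":
        tau_p, km, c0, alpha = vec
        tau_i = None
    else:
        tau_p, tau_i, km, c0, alpha = vec
    return ModelParams(
        kind=kind,
        secretion=SecretionParams(km=float(km), c0=float(c0), alpha=float(alpha)),
        tau_p=float(tau_p),
        tau_i=None if tau_i is None else float(tau_i),
    )


def _params_to_vector(mp: ModelParams) -> np.ndarray:
    s = mp.secretion
    if mp.kind == "single":
        return np.array([mp.tau_p, s.km, s.c0, s.alpha])
    return np.array([mp.tau_p, mp.tau_i, s.km, s.c0, s.alpha])


@dataclass(frozen=True)
class FitConfig:
    """Estimation settings shared by the fitting and screening front-ends."""

    model_kind: str = "single"
    n_starts: int = 1000
    seed: int = 0
    ts: float = models.TS_DEFAULT
    interp_step: float = 1.0
    bounds: Optional[ParamBounds] = None
    #: optional separate bounds for the c-peptide fit (its K_m is in ng/ml/min,
    #: roughly the molar constant times the insulin scale); defaults to ``bounds``.
    cpeptide_bounds: Optional[ParamBounds] = None
    ftol: float = 1e-10
    xtol: float = 1e-10
    boundary_rtol: float = 1e-6
    #: a converged interior solution is accepted only if its cost is within
    #: (1 + cost_rtol) of the best interior cost: stray local minima far
    #: above the global basin would otherwise contaminate the ensemble mean.
    cost_rtol: float = 1.0

    def bounds_for(self, species: str) -> Optional[ParamBounds]:
        if species == "cpeptide" and self.cpeptide_bounds is not None:
            return self.cpeptide_bounds
        return self.bounds

    def to_file(self, path) -> None:
        lines = []
        for key in ("model_kind", "n_starts", "seed", "ts", "interp_step", "ftol", "xtol", "boundary_rtol"):
            lines.append(f"{key} = {getattr(self, key)}")
        for prefix, bounds in (("bounds", self.bounds), ("cpeptide_bounds", self.cpeptide_bounds)):
            if bounds is None:
                continue
            for name in ("tau_p", "km", "c0", "alpha", "tau_i"):
                pair = getattr(bounds, name)
                if pair is not None:
                    lines.append(f"{prefix}.{name} = {pair[0]} {pair[1]}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path) -> "FitConfig":
        kwargs = {}
        bound_kwargs: dict = {"bounds": {}, "cpeptide_bounds": {}}
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key.startswith("cpeptide_bounds."):
                lo, hi = value.split()
                bound_kwargs["cpeptide_bounds"][key.split(".", 1)[1]] = (float(lo), float(hi))
            elif key.startswith("bounds."):
                lo, hi = value.split()
                bound_kwargs["bounds"][key.split(".", 1)[1]] = (float(lo), float(hi))
            elif key in ("n_starts", "seed"):
                kwargs[key] = int(value)
            elif key == "model_kind":
                kwargs[key] = value
            else:
                kwargs[key] = float(value)
        for field_name, pairs in bound_kwargs.items():
            if pairs:
                kwargs[field_name] = ParamBounds(**pairs)
        return cls(**kwargs)


@dataclass(frozen=True)
class FitResult:
    """Outcome of one local optimization start."""

    theta: ModelParams
    cost: float
    converged: bool
    at_boundary: bool
    start_index: int = -1

    def __post_init__(self) -> None:
        if self.cost < 0:
            raise ValueError("cost must be >= 0")


class _FitContext:
    """Precomputed quantities shared by every residual evaluation of one fit."""

    def __init__(self, rec: OGTTRecord, ginput: GlucoseInput, species: str, ts: float):
        t0, t1 = ginput.span
        n = int(math.ceil((t1 - t0) / ts - 1e-9))
        self.ts = ts
        self.grid = t0 + ts * np.arange(n + 1)
        self.g_grid = ginput(self.grid)
        meas_times, z = rec.species_values(species)
        self.meas_idx = np.clip(np.rint((meas_times - t0) / ts).astype(int), 0, n)
        self.z = z
        self.g0 = float(self.g_grid[0])
        self.species = species

    def output_at_measurements(self, mp: ModelParams) -> np.ndarray:
        y = models.propagate(mp, self.g_grid, ts=self.ts)
        return y[self.meas_idx]

    def residuals(self, vec: np.ndarray, kind: str) -> np.ndarray:
        return self.output_at_measurements(_vector_to_params(vec, kind)) - self.z


def _check_enough_measurements(n_meas: int, kind: str) -> None:
    n_params = len(_param_names(kind))
    if n_meas <= n_params:
        raise ValueError(
            f"need more measurements ({n_meas}) than free parameters ({n_params}) for species fit"
        )


def objective(
    theta: ModelParams,
    rec: OGTTRecord,
    ginput: GlucoseInput,
    species: str,
    ts: float = models.TS_DEFAULT,
) -> float:
    """Sum of squared residuals J(theta) over the available measurements."""
    ctx = _FitContext(rec, ginput, species, ts)
    _check_enough_measurements(ctx.z.size, theta.kind)
    r = ctx.residuals(_params_to_vector(theta), theta.kind)
    return float(np.dot(r, r))


def _solve_one(
    ctx: _FitContext,
    kind: str,
    vec0: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
    config: FitConfig,
    start_index: int = -1,
) -> FitResult:
    res = least_squares(
        ctx.residuals,
        vec0,
        args=(kind,),
        bounds=(lb, ub),
        method="trf",
        ftol=config.ftol,
        xtol=config.xtol,
        x_scale=ub - lb,
    )
    tol = config.boundary_rtol * (ub - lb)
    at_boundary = bool(np.any(res.x - lb <= tol) or np.any(ub - res.x <= tol))
    return FitResult(
        theta=_vector_to_params(res.x, kind),
        cost=float(2.0 * res.cost),  # least_squares reports 0.5 * sum of squares
        converged=bool(res.status > 0),
        at_boundary=at_boundary,
        start_index=start_index,
    )


def fit_single_start(
    rec: OGTTRecord,
    ginput: GlucoseInput,
    species: str,
    theta0: ModelParams,
    bounds: Optional[ParamBounds] = None,
    config: Optional[FitConfig] = None,
) -> FitResult:
    """One bounded local minimization of J from a given starting parameter set.

    Non-convergence is reported in the result flags, never raised; a
    solution within relative tolerance of any bound is flagged
    ``at_boundary`` (such runs are excluded from ensembles).
    """
    config = config or FitConfig(model_kind=theta0.kind)
    bounds = (bounds or config.bounds or ParamBounds().for_unit(rec.glucose_unit))
    lb, ub, _ = bounds.arrays(theta0.kind)
    vec0 = _params_to_vector(theta0)
    if np.any(vec0 < lb) or np.any(vec0 > ub):
        raise ValueError("theta0 must lie within the bounds")
    ctx = _FitContext(rec, ginput, species, config.ts)
    _check_enough_measurements(ctx.z.size, theta0.kind)
    return _solve_one(ctx, theta0.kind, vec0, lb, ub, config)


@dataclass(frozen=True)
class FitEnsemble:
    """Accepted multi-start solutions for one species with summary statistics.

    Trajectory statistics (plasma output and secretion rate, mean +/- SD
    over accepted solutions) are tabulated on the interpolation grid and at
    the record's sample times; parameter summaries use the sample SD and a
    normal 95% interval (mean +/- 1.96 SD).
    """

    species: str
    model_kind: str
    accepted: Tuple[FitResult, ...]
    n_starts: int
    seed: Optional[int]
    param_names: Tuple[str, ...]
    params: np.ndarray  # (n_accepted, n_params)
    param_mean: np.ndarray
    param_sd: np.ndarray
    grid_times: np.ndarray
    output_mean: np.ndarray
    output_sd: np.ndarray
    secretion_mean: np.ndarray
    secretion_sd: np.ndarray
    sample_times: np.ndarray
    output_at_times_mean: np.ndarray
    output_at_times_sd: np.ndarray
    secretion_at_times_mean: np.ndarray
    secretion_at_times_sd: np.ndarray
    max_measured_glucose: float

    @property
    def n_accepted(self) -> int:
        return len(self.accepted)

    @property
    def theta_hat(self) -> ModelParams:
        """Ensemble-mean parameter set."""
        return _vector_to_params(self.param_mean, self.model_kind)

    @property
    def param_ci95(self) -> Tuple[np.ndarray, np.ndarray]:
        half = 1.96 * self.param_sd
        return self.param_mean - half, self.param_mean + half

    def param_dict(self) -> dict:
        return {
            name: {"mean": float(m), "sd": float(s)}
            for name, m, s in zip(self.param_names, self.param_mean, self.param_sd)
        }

    def secretion_samples(self, g) -> np.ndarray:
        """Secretion rate at glucose ``g`` for every accepted solution; shape (n_accepted, ...)."""
        return np.array([secretion_rate(g, r.theta.secretion) for r in self.accepted])


def _sd(values: np.ndarray, axis=0) -> np.ndarray:
    if values.shape[axis] < 2:
        return np.zeros_like(np.mean(values, axis=axis))
    return np.std(values, axis=axis, ddof=1)


def fit_ensemble(
    rec: OGTTRecord,
    species: str,
    config: Optional[FitConfig] = None,
    ginput: Optional[GlucoseInput] = None,
    **overrides,
) -> FitEnsemble:
    """Bootstrap-over-starts estimation of one species' parameters.

    Draws ``config.n_starts`` starting points uniformly within the bounds
    from a generator seeded with ``config.seed``, runs a bounded local fit
    from each, discards non-converged solutions, solutions stuck at a
    bound, and stray local minima whose cost exceeds the best interior
    cost by more than ``config.cost_rtol`` (relative), and summarizes the
    rest.  Fully deterministic for a fixed seed.
    """
    config = replace(config or FitConfig(), **overrides) if overrides else (config or FitConfig())
    if not rec.has_species(species):
        raise ValueError(f"record has no {species} measurements")
    species_bounds = config.bounds_for(species)
    bounds = species_bounds if species_bounds is not None else ParamBounds().for_unit(rec.glucose_unit)
    lb, ub, names = bounds.arrays(config.model_kind)
    if ginput is None:
        ginput = interpolate_glucose(rec, step=config.interp_step)
    ctx = _FitContext(rec, ginput, species, config.ts)
    _check_enough_measurements(ctx.z.size, config.model_kind)

    rng = np.random.default_rng(config.seed)
    starts = rng.uniform(lb, ub, size=(config.n_starts, lb.size))
    interior: List[FitResult] = []
    for i in range(config.n_starts):
        result = _solve_one(ctx, config.model_kind, starts[i], lb, ub, config, start_index=i)
        if result.converged and not result.at_boundary:
            interior.append(result)
    if not interior:
        raise EstimationError(
            f"no accepted solution for {species} out of {config.n_starts} starts; "
            "review the parameter bounds (all optima hit a bound or failed to converge)"
        )
    # drop stray local minima far above the best interior basin
    best = min(r.cost for r in interior)
    cost_cap = (1.0 + config.cost_rtol) * best + 1e-12 * float(ctx.z @ ctx.z)
    accepted = [r for r in interior if r.cost <= cost_cap]

    params = np.array([_params_to_vector(r.theta) for r in accepted])
    # trajectory statistics on the interpolation grid (1 min by default)
    grid_times = ginput.grid_times
    g_on_grid = ginput.values
    outputs = np.empty((len(accepted), grid_times.size))
    secretions = np.empty_like(outputs)
    stride_idx = np.clip(
        np.rint((grid_times - ctx.grid[0]) / config.ts).astype(int), 0, ctx.grid.size - 1
    )
    times_idx = np.clip(
        np.rint((rec.times - ctx.grid[0]) / config.ts).astype(int), 0, ctx.grid.size - 1
    )
    out_at_times = np.empty((len(accepted), rec.times.size))
    sec_at_times = np.empty_like(out_at_times)
    g_at_times = ctx.g_grid[times_idx]
    for j, r in enumerate(accepted):
        y = models.propagate(r.theta, ctx.g_grid, ts=config.ts)
        outputs[j] = y[stride_idx]
        secretions[j] = secretion_rate(g_on_grid, r.theta.secretion)
        out_at_times[j] = y[times_idx]
        sec_at_times[j] = secretion_rate(g_at_times, r.theta.secretion)

    return FitEnsemble(
        species=species,
        model_kind=config.model_kind,
        accepted=tuple(accepted),
        n_starts=config.n_starts,
        seed=config.seed,
        param_names=names,
        params=params,
        param_mean=params.mean(axis=0),
        param_sd=_sd(params),
        grid_times=grid_times,
        output_mean=outputs.mean(axis=0),
        output_sd=_sd(outputs),
        secretion_mean=secretions.mean(axis=0),
        secretion_sd=_sd(secretions),
        sample_times=rec.times,
        output_at_times_mean=out_at_times.mean(axis=0),
        output_at_times_sd=_sd(out_at_times),
        secretion_at_times_mean=sec_at_times.mean(axis=0),
        secretion_at_times_sd=_sd(sec_at_times),
        max_measured_glucose=float(np.max(rec.glucose)),
    )


def fit_subject(
    rec: OGTTRecord,
    config: Optional[FitConfig] = None,
) -> Tuple[Optional[FitEnsemble], Optional[FitEnsemble]]:
    """Fit insulin and c-peptide independently, sharing one glucose interpolant.

    Returns ``(insulin_ensemble, cpeptide_ensemble)``; a species without
    measurements yields ``None`` in its slot.  Raises if neither species is
    measured.
    """
    config = config or FitConfig()
    if not (rec.has_species("insulin") or rec.has_species("cpeptide")):
        raise ValueError("record has neither insulin nor c-peptide measurements")
    ginput = interpolate_glucose(rec, step=config.interp_step)
    out = []
    for species in ("insulin", "cpeptide"):
        if rec.has_species(species):
            out.append(fit_ensemble(rec, species, config=config, ginput=ginput))
        else:
            out.append(None)
    return out[0], out[1]
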