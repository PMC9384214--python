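"""Compartmental plasma-kinetics models for insulin and c-peptide.

Plasma insulin (or c-peptide) is modelled as linear first-order clearance
driven by a glucose-dependent sigmoidal secretion input

    u(g) = K_m / (1 + exp(alpha * (C_0 - g)))

either as a single plasma compartment

    dx_p/dt = u(g(t)) - x_p / tau_p

or as a plasma + interstitial two-compartment system with mass transport
rates q1 (plasma -> interstitial) and q2 (interstitial -> plasma) and
separate degradation times tau_p, tau_i.  Both are expressed as a linear
state-space model  dx/dt = A x + B u,  y = C x  and propagated exactly on a
fine time grid by zero-order-hold discretization

    Phi = exp(A * Ts),   Gamma = A^{-1} (Phi - I) B.

The propagation is exact for piecewise-constant secretion input; the only
approximation is holding u constant over each Ts = 0.1 min substep.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import signal
from scipy.linalg import expm

__all__ = [
    "SecretionParams",
    "ModelParams",
    "StateSpace",
    "DiscreteSystem",
    "Trajectory",
    "secretion_rate",
    "build_state_space",
    "discretize",
    "propagate",
    "simulate",
    "steady_state_init",
    "convert_glucose",
    "Q1_DEFAULT",
    "Q2_DEFAULT",
    "TS_DEFAULT",
]

#: inter-compartment transport rates (1/min), fixed constants of the
#: two-compartment variant.
Q1_DEFAULT = 0.0473
Q2_DEFAULT = 0.0348

#: default propagation step (min).
TS_DEFAULT = 0.1

_UNIT_FACTORS = {"mg/dl": 1.0, "mg/L": 10.0}  # relative to mg/dl


def convert_glucose(value, from_unit: str, to_unit: str):
    """Convert a glucose concentration between mg/dl and mg/L (1 mg/dl = 10 mg/L)."""
    try:
        factor = _UNIT_FACTORS[to_unit] / _UNIT_FACTORS[from_unit]
    except KeyError as exc:
        raise ValueError(f"unknown glucose unit: {exc.args[0]!r}") from None
    return np.asarray(value) * factor if np.ndim(value) else float(value) * factor


@dataclass(frozen=True)
class SecretionParams:
    """Parameters of the sigmoidal secretion functional u(g).

    Attributes
    ----------
    km : float
        Maximal secretion rate (uU/ml/min for insulin, ng/ml/min for
        c-peptide).
    c0 : float
        Glucose midpoint, in the glucose unit of the record driving the
        model (u(c0) = km / 2).
    alpha : float
        Inverse sigmoid width, in the reciprocal of the glucose unit.
    """

    km: float
    c0: float
    alpha: float

    def __post_init__(self) -> None:
        for name in ("km", "c0", "alpha"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"SecretionParams.{name} must be finite and > 0, got {v}")

    def to_unit(self, from_unit: str, to_unit: str) -> "SecretionParams":
        """Re-express c0 and alpha for a different glucose unit."""
        f = _UNIT_FACTORS[to_unit] / _UNIT_FACTORS[from_unit]
        return SecretionParams(km=self.km, c0=self.c0 * f, alpha=self.alpha / f)


@dataclass(frozen=True)
class ModelParams:
    """Full parameter vector of one species' compartment model.

    ``kind`` is ``"single"`` (plasma only; parameters tau_p plus the
    secretion triple) or ``"two_compartment"`` (adds the interstitial
    degradation time tau_i; q1 and q2 are fixed transport constants).
    """

    kind: str
    secretion: SecretionParams
    tau_p: float
    tau_i: Optional[float] = None
    q1: float = Q1_DEFAULT
    q2: float = Q2_DEFAULT

    def __post_init__(self) -> None:
        if self.kind not in ("single", "two_compartment"):
            raise ValueError(f"unknown model kind: {self.kind!r}")
        if not (np.isfinite(self.tau_p) and self.tau_p > 0):
            raise ValueError(f"tau_p must be finite and > 0, got {self.tau_p}")
        if self.kind == "two_compartment":
            if self.tau_i is None or not (np.isfinite(self.tau_i) and self.tau_i > 0):
                raise ValueError("two_compartment model requires tau_i > 0")
            if not (self.q1 >= 0 and self.q2 >= 0):
                raise ValueError("transport rates q1, q2 must be >= 0")

    @property
    def n_states(self) -> int:
        return 1 if self.kind == "single" else 2


@dataclass(frozen=True)
class StateSpace:
    """Continuous-time linear system dx/dt = A x + B u, y = C x."""

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray

    def __post_init__(self) -> None:
        eig = np.linalg.eigvals(self.A)
        if not np.all(eig.real < 0):
            raise ValueError("state matrix must be stable (all eigenvalues in the left half-plane)")


@dataclass(frozen=True)
class DiscreteSystem:
    """One-step propagation x_{k+1} = Phi x_k + Gamma u_k at step Ts (min)."""

    phi: np.ndarray
    gamma: np.ndarray
    ts: float

    def __post_init__(self) -> None:
        if not self.ts > 0:
            raise ValueError("Ts must be > 0")
        if np.max(np.abs(np.linalg.eigvals(self.phi))) >= 1.0:
            raise ValueError("discrete transition matrix must have spectral radius < 1")


@dataclass(frozen=True)
class Trajectory:
    """Uniform or measurement-time series of one signal (concentration or rate)."""

    times: np.ndarray
    values: np.ndarray
    species: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if times.shape != values.shape:
            raise ValueError("times and values must have matching shapes")
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(values)):
            raise ValueError("trajectory values must be finite")


def secretion_rate(g, p: SecretionParams):
    """Glucose-dependent secretion rate u(g) = km / (1 + exp(alpha (c0 - g))).

    Strictly increasing in g, bounded in (0, km), with u(c0) = km / 2.
    Accepts scalars or arrays; any finite real glucose value is valid.
    """
    g_arr = np.asarray(g, dtype=float)
    if not np.all(np.isfinite(g_arr)):
        raise ValueError("glucose values must be finite")
    with np.errstate(over="ignore"):
        u = p.km / (1.0 + np.exp(p.alpha * (p.c0 - g_arr)))
    return u if g_arr.ndim else float(u)


def build_state_space(mp: ModelParams) -> StateSpace:
    """Assemble the (A, B, C) matrices for a parameter set.

    Single compartment: A = [-1/tau_p], B = [1], C = [1].  Two-compartment:
    plasma row -(q1 + 1/tau_p), q2; interstitial row q1, -(q2 + 1/tau_i);
    secretion enters the plasma state and the plasma state is observed.
    """
    if mp.kind == "single":
        A = np.array([[-1.0 / mp.tau_p]])
        B = np.array([1.0])
        C = np.array([1.0])
    else:
        A = np.array(
            [
                [-(mp.q1 + 1.0 / mp.tau_p), mp.q2],
                [mp.q1, -(mp.q2 + 1.0 / mp.tau_i)],
            ]
        )
        B = np.array([1.0, 0.0])
        C = np.array([1.0, 0.0])
    return StateSpace(A=A, B=B, C=C)


def discretize(ss: StateSpace, ts: float = TS_DEFAULT) -> DiscreteSystem:
    """Zero-order-hold discretization: Phi = e^{A Ts}, Gamma = A^{-1}(Phi - I)B.

    The scalar case uses the closed form; larger systems use the dense
    matrix exponential.  Gamma is the integral of e^{As}B over one step,
    evaluated exactly (A is invertible by the stability invariant).
    """
    if not ts > 0:
        raise ValueError("Ts must be > 0")
    A = ss.A
    if A.shape == (1, 1):
        a = A[0, 0]
        phi = np.array([[math.exp(a * ts)]])
        gamma = np.array([(phi[0, 0] - 1.0) / a]) * ss.B
    else:
        phi = expm(A * ts)
        gamma = np.linalg.solve(A, (phi - np.eye(A.shape[0])) @ ss.B)
    return DiscreteSystem(phi=phi, gamma=gamma, ts=ts)


def _filter_first_order(phi: float, gamma: float, u: np.ndarray, x0: float) -> np.ndarray:
    """Solve x[k+1] = phi x[k] + gamma u[k] for k = 0..n-1, returning x[0..n]."""
    n = u.shape[0]
    out = np.empty(n + 1, dtype=np.result_type(u.dtype, type(x0), float))
    out[0] = x0
    if n == 0:
        return out
    # forced response as an IIR filter; free response via powers of phi
    forced = signal.lfilter([gamma], [1.0, -phi], u)
    out[1:] = np.cumprod(np.full(n, phi)) * x0 + forced
    return out


def _propagate_states(mp: ModelParams, u: np.ndarray, ts: float, x0: np.ndarray) -> np.ndarray:
    """All compartment states over the grid; shape (n_states, len(u) + 1)."""
    ss = build_state_space(mp)
    if mp.kind == "single":
        phi = math.exp(-ts / mp.tau_p)
        gamma = (1.0 - phi) * mp.tau_p
        return _filter_first_order(phi, gamma, u, float(x0[0]))[None, :]

    A = ss.A
    lam, V = np.linalg.eig(A)
    # A is similar to a symmetric matrix whenever q1*q2 > 0, so its
    # eigenvalues are real; fall back to stepwise propagation if the
    # decomposition is degenerate.
    if np.max(np.abs(lam.imag)) > 1e-12 * np.max(np.abs(lam.real)) or abs(
        lam[0] - lam[1]
    ) < 1e-12 * np.max(np.abs(lam)):
        dsys = discretize(ss, ts)
        x = np.empty((2, u.shape[0] + 1))
        x[:, 0] = x0
        for k in range(u.shape[0]):
            x[:, k + 1] = dsys.phi @ x[:, k] + dsys.gamma * u[k]
        return x

    lam = lam.real
    V = V.real
    z0 = np.linalg.solve(V, x0)
    b_modal = np.linalg.solve(V, ss.B)
    z = np.empty((2, u.shape[0] + 1))
    for i in range(2):
        phi_i = math.exp(lam[i] * ts)
        gamma_i = (phi_i - 1.0) / lam[i] * b_modal[i]
        z[i] = _filter_first_order(phi_i, gamma_i, u, z0[i])
    return V @ z


def propagate(
    mp: ModelParams,
    glucose: np.ndarray,
    ts: float = TS_DEFAULT,
    x0: Optional[np.ndarray] = None,
    return_states: bool = False,
) -> np.ndarray:
    """Propagate the discrete model over a uniform glucose grid.

    ``glucose`` holds the interpolated glucose at grid nodes t0, t0+ts, ...;
    over each substep the secretion input is held constant at the average
    of its two node values (trapezoidal sampling, second-order accurate in
    ts).  Returns the plasma output at every grid node (or the full state
    matrix when ``return_states``).  ``x0`` defaults to the steady state at
    the first glucose value.
    """
    g = np.asarray(glucose, dtype=float)
    if g.ndim != 1 or g.size < 2:
        raise ValueError("glucose grid must be a 1-d array with at least 2 nodes")
    if x0 is None:
        x0 = steady_state_init(mp, float(g[0]))
    x0 = np.atleast_1d(np.asarray(x0, dtype=float))
    if x0.shape != (mp.n_states,):
        raise ValueError(f"x0 must have shape ({mp.n_states},) for kind={mp.kind!r}")
    u_nodes = secretion_rate(g, mp.secretion)
    u = 0.5 * (u_nodes[:-1] + u_nodes[1:])
    states = _propagate_states(mp, u, ts, x0)
    if np.all(x0 >= 0):
        # the model is positive (Metzler A, nonnegative input); clamp the
        # eigen-recomposition roundoff so outputs stay >= 0
        np.clip(states, 0.0, None, out=states)
    return states if return_states else states[0]


def simulate(
    mp: ModelParams,
    ginput,
    x0: Optional[np.ndarray] = None,
    out_times: Optional[np.ndarray] = None,
    ts: float = TS_DEFAULT,
) -> Trajectory:
    """Simulate the plasma output under an interpolated glucose input.

    ``ginput`` is a callable (typically a :class:`~isrfit.preprocessing.
    GlucoseInput`) with a ``span`` attribute giving the valid time range.
    The model is propagated at step ``ts`` over the full span and sampled
    at ``out_times`` by nearest-grid-node lookup (grid is 0.1 min by
    default, so the sampling offset is at most 0.05 min).
    """
    t0, t1 = ginput.span
    n = int(math.ceil((t1 - t0) / ts - 1e-9))
    grid = t0 + ts * np.arange(n + 1)
    if out_times is None:
        out_times = grid
    out_times = np.asarray(out_times, dtype=float)
    if np.any(out_times < t0 - 1e-9) or np.any(out_times > t1 + 1e-9):
        raise ValueError("out_times must lie within the span of the glucose input")
    g = ginput(grid)
    y = propagate(mp, g, ts=ts, x0=x0)
    idx = np.clip(np.rint((out_times - t0) / ts).astype(int), 0, n)
    return Trajectory(times=out_times, values=y[idx], species="plasma_output")


def steady_state_init(mp: ModelParams, g0: float) -> np.ndarray:
    """Equilibrium state at constant glucose g0: the solution of A x + B u(g0) = 0."""
    if not np.isfinite(g0):
        raise ValueError("baseline glucose must be finite")
    u0 = secretion_rate(g0, mp.secretion)
    if mp.kind == "single":
        return np.array([u0 * mp.tau_p])
    ss = build_state_space(mp)
    return np.linalg.solve(-ss.A, ss.B * u0)
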