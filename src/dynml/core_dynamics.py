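"""Heterogeneous chaotic ODE ensembles used as the reservoir core.

The reservoir is a *multiplexed* ensemble: N independent (non-interacting)
3-D chaotic units — Lorenz units for time-series work, Rössler units for
classification — whose states are concatenated into one 3N-dimensional
vector. The state layout is unit-major throughout the package:

    [x_1, y_1, z_1, x_2, y_2, z_2, ..., x_N, y_N, z_N]

so that row 3*i + c of a projection matrix addresses coordinate c of unit i.

Each unit i carries its own parameters and a timescale tau_i; the vector
field of unit i is the canonical field divided by tau_i, so larger tau_i
means slower evolution. The ensemble is integrated from a projected initial
condition over a fixed horizon; the final state is the feature embedding.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
from scipy.integrate import solve_ivp

from ._kernels import rk4_lorenz_final, rk4_lorenz_traj, rk4_rossler_final

__all__ = [
    "LorenzEnsembleParams",
    "RosslerEnsembleParams",
    "IntegratorConfig",
    "NumericalDivergenceError",
    "LORENZ_SIGMA_RANGE",
    "LORENZ_RHO_RANGE",
    "LORENZ_BETA_RANGE",
    "DEFAULT_TAU_RANGE",
    "lorenz_rhs",
    "rossler_rhs",
    "sample_lorenz_params",
    "sample_rossler_params",
    "evolve_ensemble",
    "save_params",
    "load_params",
]

# Narrow chaotic sampling windows around the canonical Lorenz regime.
LORENZ_SIGMA_RANGE = (9.9, 10.1)
LORENZ_RHO_RANGE = (27.9, 28.1)
LORENZ_BETA_RANGE = (2.65, 2.70)

# Unit timescales, log-uniform. The horizon is 30 time units, so tau in
# [20, 200] realizes 0.15-1.5 intrinsic time units per unit: long enough for
# nonlinear transients, short enough that chaotic mixing does not erase the
# initial condition (the feature map must stay informative about the input).
DEFAULT_TAU_RANGE = (20.0, 200.0)

ROSSLER_CANONICAL = (0.2, 0.2, 5.7)


class NumericalDivergenceError(RuntimeError):
    """Raised when an integration produces non-finite state components."""


@dataclass(frozen=True)
class LorenzEnsembleParams:
    """Per-unit Lorenz parameters (sigma_i, rho_i, beta_i) and timescales tau_i."""

    sigma: np.ndarray
    rho: np.ndarray
    beta: np.ndarray
    tau: np.ndarray

    def __post_init__(self):
        for name in ("sigma", "rho", "beta", "tau"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        n = self.sigma.shape[0]
        if not (self.rho.shape == self.beta.shape == self.tau.shape == (n,)):
            raise ValueError("sigma, rho, beta, tau must be equal-length 1-D vectors")
        if n < 1:
            raise ValueError("ensemble must contain at least one unit")
        if np.any(self.tau <= 0):
            raise ValueError("tau must be strictly positive")

    @property
    def N(self) -> int:
        return self.sigma.shape[0]

    kind = "lorenz"


@dataclass(frozen=True)
class RosslerEnsembleParams:
    """Per-unit Rössler parameters (a_i, b_i, c_i) and timescales tau_i."""

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    tau: np.ndarray

    def __post_init__(self):
        for name in ("a", "b", "c", "tau"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        n = self.a.shape[0]
        if not (self.b.shape == self.c.shape == self.tau.shape == (n,)):
            raise ValueError("a, b, c, tau must be equal-length 1-D vectors")
        if n < 1:
            raise ValueError("ensemble must contain at least one unit")
        if np.any(self.tau <= 0):
            raise ValueError("tau must be strictly positive")

    @property
    def N(self) -> int:
        return self.a.shape[0]

    kind = "rossler"


@dataclass(frozen=True)
class IntegratorConfig:
    """How to integrate the reservoir ensemble.

    method
        "rk4" — fixed-step classical Runge-Kutta with step ``dt`` (default;
        fully vectorized and bitwise reproducible), or "rk45" — adaptive
        Dormand-Prince via scipy, integrated per sample.
    horizon
        Total evolution time (default 30 time units).
    n_save
        Number of saved states *in addition to* the initial one when a
        trajectory is requested; saved states are equidistant in time and
        include both endpoints, so a trajectory has n_save + 1 rows. For the
        fixed-step method ``horizon/dt`` must be a multiple of n_save.
    """

    method: Literal["rk4", "rk45"] = "rk4"
    horizon: float = 30.0
    dt: float = 0.01
    rtol: float = 1e-6
    atol: float = 1e-9
    n_save: int = 3000

    def __post_init__(self):
        if self.horizon <= 0:
            raise ValueError("horizon must be positive")
        if self.dt <= 0 or self.rtol <= 0 or self.atol <= 0:
            raise ValueError("dt, rtol, atol must be positive")
        if self.n_save < 1:
            raise ValueError("n_save must be >= 1")
        if self.method not in ("rk4", "rk45"):
            raise ValueError(f"unknown integration method {self.method!r}")

    @property
    def n_steps(self) -> int:
        n = int(round(self.horizon / self.dt))
        if abs(n * self.dt - self.horizon) > 1e-9 * max(1.0, self.horizon):
            raise ValueError("horizon must be an integer multiple of dt")
        return n


def _check_state(state: np.ndarray, N: int) -> np.ndarray:
    state = np.asarray(state, dtype=float)
    if state.shape[-1] != 3 * N:
        raise ValueError(
            f"state has {state.shape[-1]} components, expected 3N = {3 * N}"
        )
    return state


def lorenz_rhs(state: np.ndarray, params: LorenzEnsembleParams) -> np.ndarray:
    """Concatenated per-unit Lorenz derivatives, each scaled by 1/tau_i.

    Unit i evolves as
        dx/dt = sigma_i (y - x) / tau_i
        dy/dt = (x (rho_i - z) - y) / tau_i
        dz/dt = (x y - beta_i z) / tau_i
    """
    state = _check_state(state, params.N)
    u = state.reshape(*state.shape[:-1], params.N, 3)
    x, y, z = u[..., 0], u[..., 1], u[..., 2]
    out = np.empty_like(u)
    out[..., 0] = params.sigma * (y - x)
    out[..., 1] = x * (params.rho - z) - y
    out[..., 2] = x * y - params.beta * z
    out /= params.tau[:, None]
    return out.reshape(state.shape)


def rossler_rhs(state: np.ndarray, params: RosslerEnsembleParams) -> np.ndarray:
    """Concatenated per-unit Rössler derivatives, each scaled by 1/tau_i.

    Unit i evolves as
        dx/dt = (-y - z) / tau_i
        dy/dt = (x + a_i y) / tau_i
        dz/dt = (b_i + z (x - c_i)) / tau_i
    """
    state = _check_state(state, params.N)
    u = state.reshape(*state.shape[:-1], params.N, 3)
    x, y, z = u[..., 0], u[..., 1], u[..., 2]
    out = np.empty_like(u)
    out[..., 0] = -y - z
    out[..., 1] = x + params.a * y
    out[..., 2] = params.b + z * (x - params.c)
    out /= params.tau[:, None]
    return out.reshape(state.shape)


def _sample_interval(rng: np.random.Generator, lo: float, hi: float, n: int,
                     log: bool = False) -> np.ndarray:
    if hi < lo:
        raise ValueError(f"invalid interval [{lo}, {hi}]")
    if log:
        if lo <= 0:
            raise ValueError("log-uniform interval requires positive bounds")
        return np.exp(rng.uniform(np.log(lo), np.log(hi), n))
    return rng.uniform(lo, hi, n)


def sample_lorenz_params(
    N: int,
    rng: np.random.Generator,
    sigma_range: tuple[float, float] = LORENZ_SIGMA_RANGE,
    rho_range: tuple[float, float] = LORENZ_RHO_RANGE,
    beta_range: tuple[float, float] = LORENZ_BETA_RANGE,
    tau_range: tuple[float, float] = DEFAULT_TAU_RANGE,
) -> LorenzEnsembleParams:
    """Sample a heterogeneous Lorenz ensemble.

    (sigma, rho, beta) are uniform on narrow windows around the canonical
    chaotic point (10, 28, 8/3); tau is log-uniform on ``tau_range`` so unit
    speeds spread evenly over an order of magnitude.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    return LorenzEnsembleParams(
        sigma=_sample_interval(rng, *sigma_range, N),
        rho=_sample_interval(rng, *rho_range, N),
        beta=_sample_interval(rng, *beta_range, N),
        tau=_sample_interval(rng, *tau_range, N, log=True),
    )


def sample_rossler_params(
    N: int,
    rng: np.random.Generator,
    jitter: float = 0.05,
    tau_range: tuple[float, float] = DEFAULT_TAU_RANGE,
) -> RosslerEnsembleParams:
    """Sample a Rössler ensemble with +/- ``jitter`` uniform spread around
    the canonical (a, b, c) = (0.2, 0.2, 5.7)."""
    if N < 1:
        raise ValueError("N must be >= 1")
    if not 0 <= jitter < 1:
        raise ValueError("jitter must be in [0, 1)")
    a0, b0, c0 = ROSSLER_CANONICAL
    return RosslerEnsembleParams(
        a=_sample_interval(rng, a0 * (1 - jitter), a0 * (1 + jitter), N),
        b=_sample_interval(rng, b0 * (1 - jitter), b0 * (1 + jitter), N),
        c=_sample_interval(rng, c0 * (1 - jitter), c0 * (1 + jitter), N),
        tau=_sample_interval(rng, *tau_range, N, log=True),
    )


def _raise_if_nonfinite(arr: np.ndarray, what: str) -> None:
    flat = arr.reshape(arr.shape[0], -1) if arr.ndim > 1 else arr[None]
    bad = ~np.isfinite(flat).all(axis=1)
    if bad.any():
        idx = int(np.argmax(bad))
        raise NumericalDivergenceError(
            f"non-finite reservoir state in {what}, first bad sample index {idx}"
        )


def evolve_ensemble(
    x0: np.ndarray,
    params: LorenzEnsembleParams | RosslerEnsembleParams,
    integ: IntegratorConfig | None = None,
    want_trajectory: bool = False,
):
    """Integrate the ensemble from x0 over the configured horizon.

    Parameters
    ----------
    x0
        Initial state, shape (3N,) for a single sample or (D, 3N) for a
        batch. Every sample is evolved with the *same* parameters.
    want_trajectory
        If True, also return ``integ.n_save + 1`` equidistant saved states
        (including both endpoints), shape (T, 3N) or (D, T, 3N).

    Returns
    -------
    final state with the same leading shape as ``x0``; or a tuple
    ``(final, trajectory)`` when ``want_trajectory``.
    """
    integ = integ or IntegratorConfig()
    single = np.asarray(x0).ndim == 1
    state = _check_state(np.atleast_2d(np.asarray(x0, dtype=float)), params.N)
    if not np.isfinite(state).all():
        raise ValueError("initial states must be finite")
    D, N = state.shape[0], params.N
    if integ.method == "rk4":
        n_steps = integ.n_steps
        x0b = np.ascontiguousarray(state.reshape(D, N, 3))
        inv_tau = 1.0 / params.tau
        if want_trajectory:
            if params.kind != "lorenz":
                raise NotImplementedError(
                    "trajectory saving is implemented for Lorenz ensembles"
                )
            if n_steps % integ.n_save != 0:
                raise ValueError("n_steps must be a multiple of n_save")
            every = n_steps // integ.n_save
            traj = rk4_lorenz_traj(
                x0b, params.sigma, params.rho, params.beta, inv_tau,
                integ.dt, n_steps, every,
            )
            traj = traj.reshape(D, integ.n_save + 1, 3 * N)
            final = traj[:, -1, :].copy()
            _raise_if_nonfinite(final, "rk4 evolution")
            if single:
                return final[0], traj[0]
            return final, traj
        if params.kind == "lorenz":
            out = rk4_lorenz_final(
                x0b, params.sigma, params.rho, params.beta, inv_tau,
                integ.dt, n_steps,
            )
        else:
            out = rk4_rossler_final(
                x0b, params.a, params.b, params.c, inv_tau, integ.dt, n_steps,
            )
        final = out.reshape(D, 3 * N)
        _raise_if_nonfinite(final, "rk4 evolution")
        return final[0] if single else final

    # Adaptive path: per-sample solve_ivp keeps batch results identical to
    # single-sample calls (a joint system would share step-size control).
    rhs = lorenz_rhs if params.kind == "lorenz" else rossler_rhs
    t_save = np.linspace(0.0, integ.horizon, integ.n_save + 1)
    finals = np.empty_like(state)
    trajs = np.empty((D, integ.n_save + 1, 3 * N)) if want_trajectory else None
    for d in range(D):
        sol = solve_ivp(
            lambda t, s: rhs(s, params),
            (0.0, integ.horizon),
            state[d],
            method="RK45",
            t_eval=t_save if want_trajectory else [integ.horizon],
            rtol=integ.rtol,
            atol=integ.atol,
        )
        if not sol.success:
            raise NumericalDivergenceError(
                f"adaptive integration failed for sample {d}: {sol.message}"
            )
        finals[d] = sol.y[:, -1]
        if want_trajectory:
            trajs[d] = sol.y.T
    _raise_if_nonfinite(finals, "rk45 evolution")
    if want_trajectory:
        if single:
            return finals[0], trajs[0]
        return finals, trajs
    return finals[0] if single else finals


def save_params(path: str | Path, params, seed: int | None = None) -> None:
    """Serialize ensemble parameters to JSON."""
    if params.kind == "lorenz":
        payload = {
            "kind": "lorenz",
            "sigma": params.sigma.tolist(),
            "rho": params.rho.tolist(),
            "beta": params.beta.tolist(),
            "tau": params.tau.tolist(),
        }
    else:
        payload = {
            "kind": "rossler",
            "a": params.a.tolist(),
            "b": params.b.tolist(),
            "c": params.c.tolist(),
            "tau": params.tau.tolist(),
        }
    if seed is not None:
        payload["seed"] = int(seed)
    Path(path).write_text(json.dumps(payload))


def load_params(path: str | Path):
    """Load ensemble parameters from JSON written by :func:`save_params`."""
    payload = json.loads(Path(path).read_text())
    kind = payload.get("kind")
    if kind == "lorenz":
        return LorenzEnsembleParams(
            sigma=payload["sigma"], rho=payload["rho"],
            beta=payload["beta"], tau=payload["tau"],
        )
    if kind == "rossler":
        return RosslerEnsembleParams(
            a=payload["a"], b=payload["b"], c=payload["c"], tau=payload["tau"],
        )
    raise ValueError(f"unknown ensemble kind {kind!r}")
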