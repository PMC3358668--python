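"""Euler–Maruyama simulation of SDEs under drift-perturbed probability measures.

A model ``dX = b(t, X) dt + v(t, X) dW`` is integrated on a fixed grid by the
difference scheme ``X_{k+1} = X_k + b(t_k, X_k) dt + v(t_k, X_k) ΔŴ_k``.  The
increments ``ΔŴ_k = ΔW_k + θ dt`` are those of a Brownian motion carrying a
constant drift shift ``θ``: by Girsanov's theorem, simulating with shifted
increments is equivalent to simulating the original model under an equivalent
probability measure whose Radon–Nikodym derivative is the exponential
martingale ``Z_T = exp(−θ·W_T − ‖θ‖² T / 2)``.  Every simulated trajectory
records ``log Z_T`` so that the bias applied to it is accounted for.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from math import ceil
from typing import Callable, Sequence

import numpy as np

from .bltl import Trace

__all__ = [
    "SDEModel",
    "SimulationGrid",
    "Perturbation",
    "TrajectoryRecord",
    "SimulationError",
    "simulate",
    "simulate_batch",
    "girsanov_log_weight",
    "to_trace",
    "write_trajectory_csv",
]


class SimulationError(RuntimeError):
    """Raised when integration produces a non-finite state."""


@dataclass(frozen=True)
class SDEModel:
    """An Itō SDE ``dX = drift dt + diffusion dW`` with independent noise.

    Parameters
    ----------
    dim_state
        Number of state variables.
    dim_noise
        Number of independent driving Brownian motions.
    drift
        ``drift(t, x)`` with ``x`` of shape ``(batch, dim_state)``; must
        return an array broadcastable to the same shape.
    diffusion
        ``diffusion(t, x)`` returning shape ``(batch, dim_state, dim_noise)``
        (or ``(dim_state, dim_noise)`` for state-independent noise).
    initial_state
        Starting point, shape ``(dim_state,)``.
    variable_names
        One identifier per state variable; these are the atoms available to
        temporal-logic formulas.
    clamp_nonnegative
        If true, every state component is clamped at zero after each Euler
        step (population models); clamping events are counted on the record.
    """

    dim_state: int
    dim_noise: int
    drift: Callable[[float, np.ndarray], np.ndarray]
    diffusion: Callable[[float, np.ndarray], np.ndarray]
    initial_state: np.ndarray
    variable_names: tuple[str, ...]
    clamp_nonnegative: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "initial_state", np.asarray(self.initial_state, dtype=float)
        )
        object.__setattr__(self, "variable_names", tuple(self.variable_names))
        if self.dim_state < 1 or self.dim_noise < 1:
            raise ValueError("dim_state and dim_noise must be positive")
        if self.initial_state.shape != (self.dim_state,):
            raise ValueError(
                f"initial_state has shape {self.initial_state.shape}, "
                f"expected ({self.dim_state},)"
            )
        if len(self.variable_names) != self.dim_state:
            raise ValueError("need one variable name per state dimension")
        if len(set(self.variable_names)) != self.dim_state:
            raise ValueError("variable names must be unique")


@dataclass(frozen=True)
class SimulationGrid:
    """Fixed time grid ``0, dt, 2 dt, …, n_steps · dt`` covering ``[0, t_end]``."""

    t_end: float
    dt: float

    def __post_init__(self) -> None:
        if self.t_end <= 0 or self.dt <= 0:
            raise ValueError("t_end and dt must be positive")
        if self.dt > self.t_end:
            raise ValueError("dt must not exceed t_end")

    @property
    def n_steps(self) -> int:
        return ceil(round(self.t_end / self.dt, 9))

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_steps + 1) * self.dt


@dataclass(frozen=True)
class Perturbation:
    """Constant drift shift applied to the Brownian motion of one trajectory.

    ``theta = 0`` is the natural (unbiased) measure.  Constant shifts satisfy
    the Novikov condition trivially, so the Girsanov weight is available in
    closed form.
    """

    theta: np.ndarray
    theta_max: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "theta", np.atleast_1d(np.asarray(self.theta, float)))
        if self.theta_max < 0:
            raise ValueError("theta_max must be non-negative")
        if np.max(np.abs(self.theta), initial=0.0) > self.theta_max + 1e-12:
            raise ValueError("|theta| exceeds theta_max")

    @classmethod
    def null(cls, dim_noise: int) -> "Perturbation":
        return cls(theta=np.zeros(dim_noise), theta_max=0.0)

    @property
    def is_null(self) -> bool:
        return not np.any(self.theta)


@dataclass
class TrajectoryRecord:
    """One simulated path together with its change-of-measure bookkeeping.

    ``brownian_increments`` are the increments of the *perturbed* Brownian
    motion actually fed to the Euler scheme (``ΔŴ_k = ΔW_k + θ dt``); the
    natural-measure increments are recovered by subtracting ``θ dt``.
    """

    times: np.ndarray
    states: np.ndarray
    brownian_increments: np.ndarray
    log_weight: float
    perturbation: Perturbation
    n_clamped: int = 0

    @property
    def final_state(self) -> np.ndarray:
        return self.states[-1]


def girsanov_log_weight(
    perturbation: Perturbation, brownian_increments: np.ndarray, dt: float
) -> float:
    """Log Radon–Nikodym derivative ``log Z_T`` for a constant drift shift.

    ``brownian_increments`` must be the NATURAL-measure increments ``ΔW_k``
    (shape ``(n_steps, dim_noise)``).  For constant ``θ``,

        log Z_T = −θ · W_T − ‖θ‖² T / 2,   W_T = Σ_k ΔW_k,  T = n_steps · dt.

    Returns exactly 0.0 when ``θ = 0``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    theta = perturbation.theta
    if perturbation.is_null:
        return 0.0
    inc = np.asarray(brownian_increments, dtype=float)
    if inc.ndim == 1:
        inc = inc[:, None]
    horizon = inc.shape[0] * dt
    w_final = inc.sum(axis=0)
    return float(-theta @ w_final - 0.5 * (theta @ theta) * horizon)


def _eval_diffusion(model: SDEModel, t: float, x: np.ndarray) -> np.ndarray:
    v = np.asarray(model.diffusion(t, x), dtype=float)
    if v.ndim == 2:
        if v.shape != (model.dim_state, model.dim_noise):
            raise ValueError(
                f"diffusion returned shape {v.shape}, expected "
                f"({model.dim_state}, {model.dim_noise}) or batched"
            )
        v = np.broadcast_to(v, (x.shape[0],) + v.shape)
    return v


def simulate_batch(
    model: SDEModel,
    grid: SimulationGrid,
    thetas: np.ndarray,
    rng: np.random.Generator,
    return_states: bool = True,
):
    """Integrate a batch of independent trajectories, one drift shift per path.

    Parameters
    ----------
    thetas
        Shape ``(n_paths, dim_noise)``; row ``i`` is the constant drift shift
        for path ``i`` (all-zero rows simulate under the natural measure).
    rng
        Source of the raw Normal(0, dt) increments for the whole batch.
    return_states
        If false, only initial/final states are kept (memory saver for
        probability estimation that does not need intermediate states is NOT
        possible here since the monitor needs full paths; this flag exists
        for weight-only computations).

    Returns
    -------
    states : ndarray ``(n_paths, n_steps+1, dim_state)`` (or final states
        ``(n_paths, dim_state)`` when ``return_states`` is false)
    log_weights : ndarray ``(n_paths,)``
    n_clamped : int, total clamping events across the batch
    """
    thetas = np.atleast_2d(np.asarray(thetas, dtype=float))
    n_paths = thetas.shape[0]
    if thetas.shape[1] != model.dim_noise:
        raise ValueError("thetas second dimension must equal dim_noise")
    dt = grid.dt
    n_steps = grid.n_steps
    sqrt_dt = np.sqrt(dt)

    x = np.broadcast_to(model.initial_state, (n_paths, model.dim_state)).copy()
    if return_states:
        states = np.empty((n_paths, n_steps + 1, model.dim_state))
        states[:, 0] = x
    # log Z_T accumulates −θ·ΔW per step; the −‖θ‖²T/2 term is added at the end.
    log_w = np.zeros(n_paths)
    n_clamped = 0

    for k in range(n_steps):
        t = k * dt
        raw = rng.standard_normal((n_paths, model.dim_noise)) * sqrt_dt
        dw_hat = raw + thetas * dt
        b = np.asarray(model.drift(t, x), dtype=float)
        v = _eval_diffusion(model, t, x)
        x = x + b * dt + np.einsum("pij,pj->pi", v, dw_hat)
        if model.clamp_nonnegative:
            neg = x < 0
            n_clamped += int(np.count_nonzero(neg))
            np.clip(x, 0.0, None, out=x)
        if not np.all(np.isfinite(x)):
            bad = int(np.argwhere(~np.isfinite(x))[0, 0])
            raise SimulationError(
                f"non-finite state at step {k + 1} (t = {t + dt:g}), path {bad}"
            )
        log_w -= (raw * thetas).sum(axis=1)
        if return_states:
            states[:, k + 1] = x

    log_w -= 0.5 * (thetas**2).sum(axis=1) * (n_steps * dt)
    return (states if return_states else x), log_w, n_clamped


def simulate(
    model: SDEModel,
    grid: SimulationGrid,
    perturbation: Perturbation | None = None,
    seed: int = 0,
) -> TrajectoryRecord:
    """Simulate a single trajectory; deterministic given (model, grid, perturbation, seed)."""
    if perturbation is None:
        perturbation = Perturbation.null(model.dim_noise)
    if perturbation.theta.shape != (model.dim_noise,):
        raise ValueError("perturbation dimension must equal dim_noise")
    rng = np.random.default_rng(np.random.SeedSequence(abs(int(seed))))

    thetas = perturbation.theta[None, :]
    n_steps = grid.n_steps
    sqrt_dt = np.sqrt(grid.dt)
    raw = rng.standard_normal((n_steps, model.dim_noise)) * sqrt_dt

    x = model.initial_state.copy()[None, :]
    states = np.empty((n_steps + 1, model.dim_state))
    states[0] = x[0]
    n_clamped = 0
    for k in range(n_steps):
        t = k * grid.dt
        dw_hat = raw[k : k + 1] + thetas * grid.dt
        b = np.asarray(model.drift(t, x), dtype=float)
        v = _eval_diffusion(model, t, x)
        x = x + b * grid.dt + np.einsum("pij,pj->pi", v, dw_hat)
        if model.clamp_nonnegative:
            neg = x < 0
            n_clamped += int(np.count_nonzero(neg))
            np.clip(x, 0.0, None, out=x)
        if not np.all(np.isfinite(x)):
            raise SimulationError(
                f"non-finite state at step {k + 1} (t = {t + grid.dt:g})"
            )
        states[k + 1] = x[0]

    log_weight = girsanov_log_weight(perturbation, raw, grid.dt)
    return TrajectoryRecord(
        times=grid.times,
        states=states,
        brownian_increments=raw + perturbation.theta * grid.dt,
        log_weight=log_weight,
        perturbation=perturbation,
        n_clamped=n_clamped,
    )


def to_trace(record: TrajectoryRecord, variable_names: Sequence[str]) -> Trace:
    """Adapt a trajectory to the timed-trace form consumed by the monitor.

    Each state carries the integration step as its duration; the final state
    carries duration 0.
    """
    n = record.states.shape[0]
    durations = np.diff(record.times, append=record.times[-1])
    return Trace(
        states=record.states,
        durations=durations[:n],
        variable_names=tuple(variable_names),
    )


def write_trajectory_csv(
    record: TrajectoryRecord, variable_names: Sequence[str], path
) -> None:
    """Export ``time,<var1>,…,log_weight``; log_weight only on the final row."""
    names = list(variable_names)
    buf = io.StringIO()
    buf.write("time," + ",".join(names) + ",log_weight\n")
    last = record.states.shape[0] - 1
    for i, t in enumerate(record.times):
        vals = ",".join(repr(v) for v in record.states[i])
        lw = repr(record.log_weight) if i == last else ""
        buf.write(f"{t!r},{vals},{lw}\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())
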