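"""Continuous-time rate-network dynamics.

The model is a recurrent network of ``N`` units whose activations ``x``
evolve in continuous time with time constant ``tau`` and communicate
through firing rates ``H(x) = tanh(x)``.  Three variants of the dynamics
appear throughout the package:

task-performing network
    ``tau dx/dt = -x + J H(x) + u_in f_in(t)``
    The final product of training.  Its output is the linear readout
    ``z = w^T H(x)``.

output-feedback (FORCE) network
    ``tau dx/dt = -x + J H(x) + u_in f_in(t) + u z(t)``
    The readout is fed back through fixed random weights ``u``; the
    effective recurrence is ``J + u w^T``.

driven (target-generating) network
    ``tau dx^D/dt = -x^D + J^D H(x^D) + u f_out(t) + u_in f_in(t)
    + u_hint f_hint(t)``
    A fixed random network that receives the target output (and an
    optional hint) as input.  Strong time-varying input suppresses the
    chaos a ``g > 1`` random network would otherwise exhibit, making the
    driven activity a reproducible source of per-unit learning targets.

All stepping here is forward Euler at step ``dt`` (default 1 ms against
``tau = 10`` ms).  These functions are the reference implementation;
production training and long simulations go through the compiled loops in
:mod:`fullforce._kernels`, which tests pin against this module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NumericalError",
    "NetworkParams",
    "WeightSet",
    "StateTrace",
    "init_random_weights",
    "step_task_network",
    "step_force_network",
    "step_driven_network",
    "readout",
    "simulate",
]


class NumericalError(RuntimeError):
    """Network state became NaN/Inf during integration."""


@dataclass(frozen=True)
class NetworkParams:
    """Fixed architecture and integration constants.

    Parameters
    ----------
    n_units
        Network size ``N``.
    tau
        Unit time constant in ms.
    dt
        Euler integration step in ms.  Must satisfy ``dt <= tau / 5``.
    g
        Gain of the random recurrence; entries of ``J^D`` have variance
        ``g**2 / N``.  ``g > 1`` puts the undriven network in the chaotic
        regime.
    nonlinearity
        ``"tanh"`` for the shipped model; ``"identity"`` exists so tests
        can check against linear closed forms.
    """

    n_units: int
    tau: float = 10.0
    dt: float = 1.0
    g: float = 1.5
    nonlinearity: str = "tanh"

    def __post_init__(self) -> None:
        if self.n_units < 1:
            raise ValueError(f"n_units must be a positive integer, got {self.n_units}")
        if not (0.0 < self.dt <= self.tau / 5.0):
            raise ValueError(
                f"dt must satisfy 0 < dt <= tau/5 (= {self.tau / 5.0}), got {self.dt}"
            )
        if self.g < 0.0:
            raise ValueError(f"g must be non-negative, got {self.g}")
        if self.nonlinearity not in ("tanh", "identity"):
            raise ValueError(f"unknown nonlinearity {self.nonlinearity!r}")

    def nonlin(self, x: np.ndarray) -> np.ndarray:
        """Apply the rate nonlinearity ``H`` to activations."""
        if self.nonlinearity == "tanh":
            return np.tanh(x)
        return np.asarray(x, dtype=float)


@dataclass
class WeightSet:
    """All connection vectors/matrices of one network.

    ``J`` is the ``N x N`` recurrence (the learned matrix of a trained
    task network, or the fixed random ``J^D`` of a driven network),
    ``u_in``/``u``/``u_hint`` are input, output-feedback and hint input
    weights, and ``w`` is the linear readout.
    """

    J: np.ndarray
    u_in: np.ndarray
    u: np.ndarray
    u_hint: np.ndarray
    w: np.ndarray

    @property
    def n_units(self) -> int:
        return self.J.shape[0]

    def __post_init__(self) -> None:
        n = self.J.shape[0]
        if self.J.shape != (n, n):
            raise ValueError(f"J must be square, got shape {self.J.shape}")
        for name in ("u_in", "u", "u_hint", "w"):
            v = getattr(self, name)
            if v.shape != (n,):
                raise ValueError(
                    f"{name} must have shape ({n},), got {v.shape}"
                )

    def copy(self) -> "WeightSet":
        return WeightSet(
            J=self.J.copy(),
            u_in=self.u_in.copy(),
            u=self.u.copy(),
            u_hint=self.u_hint.copy(),
            w=self.w.copy(),
        )


@dataclass
class StateTrace:
    """Time-gridded record of a simulation.

    ``x`` and ``rates`` may be ``None`` when only the readout was stored
    (long closed-loop runs); when present, ``rates = tanh(x)`` row-wise.
    """

    times: np.ndarray
    z: np.ndarray
    x: np.ndarray | None = None
    rates: np.ndarray | None = None
    store_every: int = 1
    meta: dict = field(default_factory=dict)


def init_random_weights(params: NetworkParams, seed) -> WeightSet:
    """Draw the standard random weight set.

    ``J`` entries are i.i.d. ``Normal(0, g**2 / N)``; ``u_in``, ``u`` and
    ``u_hint`` entries are i.i.d. ``Uniform(-1, 1)``; the readout ``w``
    starts at zero.  ``seed`` may be an int or a ``numpy.random.Generator``.
    """
    rng = np.random.default_rng(seed)
    n = params.n_units
    J = rng.normal(0.0, params.g / np.sqrt(n), size=(n, n))
    u_in = rng.uniform(-1.0, 1.0, size=n)
    u = rng.uniform(-1.0, 1.0, size=n)
    u_hint = rng.uniform(-1.0, 1.0, size=n)
    w = np.zeros(n)
    return WeightSet(J=J, u_in=u_in, u=u, u_hint=u_hint, w=w)


def _check_finite(x: np.ndarray, step: int | None) -> None:
    if not np.all(np.isfinite(x)):
        where = "" if step is None else f" at step {step}"
        raise NumericalError(f"non-finite network state{where}")


def step_task_network(
    x: np.ndarray,
    weights: WeightSet,
    f_in: float,
    noise: np.ndarray | None,
    params: NetworkParams,
    step: int | None = None,
) -> np.ndarray:
    """One Euler step of the task-performing dynamics.

    ``noise`` is an additive increment to ``x`` (already scaled by
    ``sqrt(2 D dt)`` for white-noise input); pass ``None`` for a clean
    step.
    """
    r = params.nonlin(x)
    dx = (params.dt / params.tau) * (-x + weights.J @ r + weights.u_in * f_in)
    x_new = x + dx
    if noise is not None:
        x_new = x_new + noise
    _check_finite(x_new, step)
    return x_new


def step_force_network(
    x: np.ndarray,
    weights: WeightSet,
    f_in: float,
    z: float,
    noise: np.ndarray | None,
    params: NetworkParams,
    step: int | None = None,
) -> np.ndarray:
    """One Euler step with output feedback ``u * z``.

    ``z`` is the readout computed from the current state, or the teacher
    value ``f_out(t)`` under teacher forcing.
    """
    r = params.nonlin(x)
    dx = (params.dt / params.tau) * (
        -x + weights.J @ r + weights.u_in * f_in + weights.u * z
    )
    x_new = x + dx
    if noise is not None:
        x_new = x_new + noise
    _check_finite(x_new, step)
    return x_new


def step_driven_network(
    xD: np.ndarray,
    weightsD: WeightSet,
    f_in: float,
    f_out: float,
    f_hint: float,
    params: NetworkParams,
    noise: np.ndarray | None = None,
    step: int | None = None,
) -> np.ndarray:
    """One Euler step of the driven (target-generating) dynamics.

    With ``f_hint = 0`` this is the plain driven network; the hint term
    ``u_hint * f_hint`` is only ever used during training.
    """
    r = params.nonlin(xD)
    dx = (params.dt / params.tau) * (
        -xD
        + weightsD.J @ r
        + weightsD.u * f_out
        + weightsD.u_in * f_in
        + weightsD.u_hint * f_hint
    )
    x_new = xD + dx
    if noise is not None:
        x_new = x_new + noise
    _check_finite(x_new, step)
    return x_new


def readout(x: np.ndarray, w: np.ndarray, nonlinearity: str = "tanh") -> float:
    """Linear readout ``z = w^T H(x)``."""
    x = np.asarray(x, dtype=float)
    w = np.asarray(w, dtype=float)
    if x.shape != w.shape:
        raise ValueError(f"shape mismatch: x {x.shape} vs w {w.shape}")
    r = np.tanh(x) if nonlinearity == "tanh" else x
    return float(w @ r)


def simulate(
    params: NetworkParams,
    weights: WeightSet,
    f_in: np.ndarray,
    *,
    mode: str = "task",
    f_out: np.ndarray | None = None,
    f_hint: np.ndarray | None = None,
    noise: np.ndarray | None = None,
    x0: np.ndarray | None = None,
    teacher_force: bool = False,
) -> StateTrace:
    """Reference (pure-Python) simulation loop, storing the full state.

    Modes: ``"task"`` (no feedback), ``"force"`` (readout fed back
    through ``u``; with ``teacher_force=True`` the feedback is
    ``f_out(t)`` instead of ``z``), ``"driven"`` (``weights.J`` is
    ``J^D``; requires ``f_out``, optional ``f_hint``).

    Intended for tests and small problems; long runs use the compiled
    kernels via :func:`fullforce.training.run_trained`.
    """
    if mode not in ("task", "force", "driven"):
        raise ValueError(f"unknown mode {mode!r}")
    T = len(f_in)
    n = params.n_units
    if f_hint is None:
        f_hint = np.zeros(T)
    if mode in ("force", "driven") and teacher_force and f_out is None:
        raise ValueError("teacher forcing requires f_out")
    if mode == "driven" and f_out is None:
        raise ValueError("driven mode requires f_out")
    x = np.zeros(n) if x0 is None else np.asarray(x0, dtype=float).copy()
    X = np.empty((T, n))
    z = np.empty(T)
    for t in range(T):
        X[t] = x
        z[t] = readout(x, weights.w, params.nonlinearity)
        eta = None if noise is None else noise[t]
        if mode == "task":
            x = step_task_network(x, weights, f_in[t], eta, params, step=t)
        elif mode == "force":
            fb = f_out[t] if teacher_force else z[t]
            x = step_force_network(x, weights, f_in[t], fb, eta, params, step=t)
        else:
            x = step_driven_network(
                x, weights, f_in[t], f_out[t], f_hint[t], params, noise=eta, step=t
            )
    rates = params.nonlin(X)
    times = np.arange(T) * params.dt
    return StateTrace(times=times, z=z, x=X, rates=rates)
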