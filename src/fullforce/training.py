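"""End-to-end trainers: full-FORCE, the FORCE baseline, and helpers.

full-FORCE trains the entire recurrent matrix ``J`` of a task-performing
network (starting from ``J = 0``) so that its internal drive
``J H(x)`` matches the combined internal-plus-external drive
``J^D H(x^D) + u f_out (+ u_hint f_hint)`` of a driven target-generating
network integrated concurrently on the same input stream.  The readout
``w`` is trained toward ``f_out`` with the same RLS machinery (shared
``P``), by default concurrently with ``J``.

FORCE keeps the random recurrence ``J^D`` fixed, runs closed-loop with
output feedback ``u z(t)``, and learns only ``w``; the effective
connectivity is the rank-one update ``J^D + u w^T``.

Hints (``f_hint``) are fed to the target-generating network only and
only during training; the trained task-performing network has no hint
channel at all.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import _kernels
from .dynamics import NetworkParams, NumericalError, StateTrace, WeightSet, init_random_weights
from .rls import batch_ridge_solve, update_mask
from .tasks import (
    Trial,
    make_comparison_stream,
    make_interval_stream,
    make_oscillation_stream,
)

__all__ = [
    "TrainingConfig",
    "TrainedModel",
    "make_batch_stream",
    "train_full_force",
    "train_force",
    "train",
    "run_trained",
    "driven_rates",
    "fit_driven_readout",
    "save_model",
    "load_model",
]

TASKS = ("oscillation", "interval", "comparison")
ALGORITHMS = ("full-force", "force")


@dataclass
class TrainingConfig:
    """Everything needed to reproduce one training run.

    ``periods_per_batch`` applies to the oscillation task and
    ``trials_per_batch`` to the pulse tasks; ``noise_2D`` is the
    white-noise diffusion coefficient ``2D`` in 1/ms applied to the
    task-performing network during training (and, by the evaluation
    protocols, during testing); ``output_offset`` is the constant
    baseline added to pulse-task targets.
    """

    algorithm: str = "full-force"
    task: str = "oscillation"
    n_batches: int = 10
    periods_per_batch: int = 100
    trials_per_batch: int = 30
    alpha: float = 1.0
    mean_update_interval: float = 2.0
    noise_2D: float = 0.0
    hint_enabled: bool = False
    seed: int = 0
    train_w: str = "concurrent"  # "concurrent" | "sequential"
    output_offset: float = 0.25
    task_kwargs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}")
        if self.n_batches < 0:
            raise ValueError("n_batches must be >= 0")
        if self.noise_2D < 0:
            raise ValueError("noise_2D must be >= 0")
        if self.train_w not in ("concurrent", "sequential"):
            raise ValueError(f"unknown train_w mode {self.train_w!r}")


@dataclass
class TrainedModel:
    """A trained task-performing network with full provenance.

    ``weights`` holds the learned ``J`` and ``w`` (for FORCE, ``J`` is
    the fixed random ``J^D``; inference then uses feedback ``u z``).
    ``driven_weights`` retains the target-generating network for
    spectrum analyses and reproducibility.
    """

    params: NetworkParams
    weights: WeightSet
    driven_weights: WeightSet
    config: TrainingConfig
    training_error_trace: np.ndarray
    final_x: np.ndarray | None = None
    final_xD: np.ndarray | None = None

    @property
    def algorithm(self) -> str:
        return self.config.algorithm


def make_batch_stream(
    task: str,
    config: TrainingConfig,
    dt: float,
    rng,
    *,
    n_units_of_work: int | None = None,
    hint: bool | None = None,
) -> Trial:
    """Generate one batch (or test block) of the named task stream."""
    hint = config.hint_enabled if hint is None else hint
    if task == "oscillation":
        n = n_units_of_work or config.periods_per_batch
        return make_oscillation_stream(n, dt, seed=rng, **config.task_kwargs)
    n = n_units_of_work or config.trials_per_batch
    if task == "interval":
        return make_interval_stream(
            n, dt, hint, seed=rng, offset=config.output_offset,
            **config.task_kwargs,
        )
    if task == "comparison":
        return make_comparison_stream(
            n, dt, hint, seed=rng, offset=config.output_offset,
            **config.task_kwargs,
        )
    raise ValueError(f"unknown task {task!r}")


def _noise_increment_std(noise_2D: float, params: NetworkParams) -> float:
    """Per-step state increment produced by white-noise *input*.

    The noise enters the dynamics like any other input, inside the
    tau dx/dt bracket: tau dx/dt = -x + ... + eta(t) with
    <eta(t) eta(t')> = 2D delta(t - t').  One Euler step therefore adds
    (dt/tau) eta_t with Var(eta_t) = 2D/dt, i.e. an increment of
    standard deviation sqrt(2D dt)/tau.
    """
    return float(np.sqrt(noise_2D * params.dt) / params.tau)


def _norm_err(z: np.ndarray, f: np.ndarray) -> float:
    v = float(np.var(f))
    if v == 0.0:
        return float("nan")
    return float(np.mean((z - f) ** 2) / v)


def train_full_force(
    params: NetworkParams,
    config: TrainingConfig,
    stream_factory=None,
    *,
    progress: bool = False,
) -> TrainedModel:
    """Train a task-performing network with full-FORCE.

    ``stream_factory(batch_index, rng) -> Trial`` overrides the default
    task generator (used by tests); the default draws fresh random
    batches of ``config.task``.  With ``progress=True`` a line per batch
    reports simulated time and batch error.
    """
    if config.algorithm != "full-force":
        raise ValueError("config.algorithm must be 'full-force'")
    rng = np.random.default_rng(config.seed)
    wD = init_random_weights(params, rng)
    n = params.n_units
    J = np.zeros((n, n))
    w = np.zeros(n)
    P = np.eye(n) / config.alpha
    x = rng.uniform(-0.1, 0.1, n)
    xD = rng.uniform(-0.1, 0.1, n)
    noise_std = _noise_increment_std(config.noise_2D, params)
    if stream_factory is None:
        stream_factory = lambda b, r: make_batch_stream(config.task, config, params.dt, r)

    errors = []
    simulated_ms = 0.0
    concurrent_w = config.train_w == "concurrent"
    for b in range(config.n_batches):
        trial = stream_factory(b, rng)
        mask = update_mask(trial.n_steps, config.mean_update_interval, params.dt, rng)
        nseed = int(rng.integers(2**31))
        try:
            z = _kernels.train_full_force_kernel(
                wD.J, wD.u, wD.u_in, wD.u_hint, J, w, P, x, xD,
                trial.f_in, trial.f_out, trial.f_hint, mask,
                noise_std, params.dt / params.tau, nseed,
                True, concurrent_w,
            )
        except FloatingPointError as err:
            raise NumericalError(f"{err} (batch {b})") from err
        errors.append(_norm_err(z, trial.f_out))
        simulated_ms += trial.n_steps * params.dt
        if progress:
            print(f"[full-force] batch {b + 1}/{config.n_batches}: "
                  f"{simulated_ms / 1000.0:.0f} s simulated, "
                  f"batch error {errors[-1]:.3g}", flush=True)

    if not concurrent_w and config.n_batches > 0:
        # Second pass: J frozen, readout trained on the closed-loop network.
        P = np.eye(n) / config.alpha
        for b in range(config.n_batches):
            trial = stream_factory(config.n_batches + b, rng)
            mask = update_mask(trial.n_steps, config.mean_update_interval, params.dt, rng)
            nseed = int(rng.integers(2**31))
            try:
                z = _kernels.train_full_force_kernel(
                    wD.J, wD.u, wD.u_in, wD.u_hint, J, w, P, x, xD,
                    trial.f_in, trial.f_out, trial.f_hint, mask,
                    noise_std, params.dt / params.tau, nseed,
                    False, True,
                )
            except FloatingPointError as err:
                raise NumericalError(f"{err} (readout batch {b})") from err
            errors.append(_norm_err(z, trial.f_out))

    weights = WeightSet(
        J=J, u_in=wD.u_in.copy(), u=wD.u.copy(), u_hint=np.zeros(n), w=w
    )
    return TrainedModel(params, weights, wD, config, np.asarray(errors),
                        final_x=x, final_xD=xD)


def train_force(
    params: NetworkParams,
    config: TrainingConfig,
    stream_factory=None,
    *,
    progress: bool = False,
) -> TrainedModel:
    """Train only the readout of a fixed random network (FORCE).

    The random recurrence is drawn exactly as the driven network of
    :func:`train_full_force` under the same seed, so paired comparisons
    between the algorithms share ``J^D``, ``u`` and ``u_in``.
    """
    if config.algorithm != "force":
        raise ValueError("config.algorithm must be 'force'")
    rng = np.random.default_rng(config.seed)
    wD = init_random_weights(params, rng)
    n = params.n_units
    simulated_ms = 0.0
    w = np.zeros(n)
    P = np.eye(n) / config.alpha
    x = rng.uniform(-0.1, 0.1, n)
    rng.uniform(-0.1, 0.1, n)  # keep the stream aligned with full-FORCE
    noise_std = _noise_increment_std(config.noise_2D, params)
    if stream_factory is None:
        stream_factory = lambda b, r: make_batch_stream(
            config.task, config, params.dt, r, hint=False
        )

    errors = []
    for b in range(config.n_batches):
        trial = stream_factory(b, rng)
        mask = update_mask(trial.n_steps, config.mean_update_interval, params.dt, rng)
        nseed = int(rng.integers(2**31))
        try:
            z = _kernels.train_force_kernel(
                wD.J, wD.u, wD.u_in, w, P, x,
                trial.f_in, trial.f_out, mask,
                noise_std, params.dt / params.tau, nseed, True,
            )
        except FloatingPointError as err:
            raise NumericalError(f"{err} (batch {b})") from err
        errors.append(_norm_err(z, trial.f_out))
        simulated_ms += trial.n_steps * params.dt
        if progress:
            print(f"[force] batch {b + 1}/{config.n_batches}: "
                  f"{simulated_ms / 1000.0:.0f} s simulated, "
                  f"batch error {errors[-1]:.3g}", flush=True)

    weights = WeightSet(
        J=wD.J.copy(), u_in=wD.u_in.copy(), u=wD.u.copy(),
        u_hint=np.zeros(n), w=w,
    )
    return TrainedModel(params, weights, wD, config, np.asarray(errors),
                        final_x=x)


def train(params: NetworkParams, config: TrainingConfig, stream_factory=None,
          *, progress: bool = False) -> TrainedModel:
    """Dispatch on ``config.algorithm``."""
    if config.algorithm == "full-force":
        return train_full_force(params, config, stream_factory, progress=progress)
    return train_force(params, config, stream_factory, progress=progress)


def run_trained(
    model: TrainedModel,
    trial: Trial,
    noise_2D: float = 0.0,
    seed: int = 0,
    *,
    x0=None,
    store_state: bool = False,
    store_every: int = 1,
    use_hint: bool = False,
) -> StateTrace:
    """Closed-loop simulation of a trained (or untrained) model.

    For a full-FORCE model the only external signal is ``f_in``; FORCE
    models additionally feed their own output back through ``u``.  The
    hint channel does not exist at inference: requesting it raises.

    ``x0=None`` (default) continues from the network state at the end of
    training, matching the continuous-stream protocol in which test
    trials follow training trials without a reset; ``x0="random"`` draws
    a fresh Uniform(-0.1, 0.1) state from ``seed``; an array gives an
    explicit state.
    """
    if use_hint:
        raise ValueError(
            "hint inputs are training-only; the task-performing network "
            "has no hint channel"
        )
    params = model.params
    rng = np.random.default_rng(seed)
    if x0 is None and model.final_x is not None:
        x = model.final_x.copy()
    elif x0 is None or (isinstance(x0, str) and x0 == "random"):
        x = rng.uniform(-0.1, 0.1, params.n_units)
    else:
        x = np.asarray(x0, float).copy()
    noise_std = _noise_increment_std(noise_2D, params)
    nseed = int(rng.integers(2**31))
    se = store_every if store_state else 0
    try:
        if model.algorithm == "full-force":
            z, X = _kernels.sim_task_kernel(
                model.weights.J, model.weights.u_in, model.weights.w, x,
                trial.f_in, noise_std, params.dt / params.tau, nseed, se,
            )
        else:
            z, X = _kernels.sim_force_kernel(
                model.weights.J, model.weights.u, model.weights.u_in,
                model.weights.w, x,
                trial.f_in, noise_std, params.dt / params.tau, nseed, se,
            )
    except FloatingPointError as err:
        raise NumericalError(str(err)) from err
    if store_state:
        times = trial.times[::store_every][: len(X)]
        return StateTrace(times=times, z=z, x=X, rates=np.tanh(X),
                          store_every=store_every)
    return StateTrace(times=trial.times, z=z)


def driven_rates(
    params: NetworkParams,
    weightsD: WeightSet,
    trial: Trial,
    *,
    store_every: int = 2,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate the driven network on a task stream and return
    ``(step_indices, rates)`` subsampled every ``store_every`` steps."""
    rng = np.random.default_rng(seed)
    xD = rng.uniform(-0.1, 0.1, params.n_units)
    idx, R = _kernels.sim_driven_kernel(
        weightsD.J, weightsD.u, weightsD.u_in, weightsD.u_hint, xD,
        trial.f_in, trial.f_out, trial.f_hint,
        params.dt / params.tau, store_every,
    )
    return idx, R


def fit_driven_readout(
    rates: np.ndarray,
    f_out: np.ndarray,
    alpha: float = 1.0,
) -> tuple[np.ndarray, float]:
    """Auto-encoder check: fit ``w^D`` so ``(w^D)^T H(x^D) ~ f_out``.

    ``rates`` is a ``(T, N)`` array of driven-network rates (or a
    :class:`~fullforce.dynamics.StateTrace`, whose ``rates`` are used)
    and ``f_out`` the target sampled at the same steps.  Returns
    ``(w_D, normalized error)``.  A target with zero variance is only accepted when it is
    identically zero (then ``w^D = 0`` and the error is 0 by convention).
    """
    if isinstance(rates, StateTrace):
        rates = rates.rates
    rates = np.asarray(rates, dtype=float)
    f_out = np.asarray(f_out, dtype=float)
    if rates is None or rates.size == 0:
        raise ValueError("empty rate trace")
    if rates.shape[0] != f_out.shape[0]:
        raise ValueError("rates and f_out must have the same number of samples")
    v = float(np.var(f_out))
    if v == 0.0:
        if np.all(f_out == 0.0):
            return np.zeros(rates.shape[1]), 0.0
        raise ValueError("constant nonzero target has no normalized error")
    wD = batch_ridge_solve(rates, f_out, alpha)
    zD = rates @ wD
    return wD, float(np.mean((zD - f_out) ** 2) / v)


def save_model(model: TrainedModel, path) -> None:
    """Write a model archive (NPZ: weight arrays + JSON metadata)."""
    meta = {
        "params": asdict(model.params),
        "config": asdict(model.config),
        "format_version": 1,
    }
    np.savez(
        path,
        J=model.weights.J,
        w=model.weights.w,
        u_in=model.weights.u_in,
        u=model.weights.u,
        u_hint=model.weights.u_hint,
        JD=model.driven_weights.J,
        uD=model.driven_weights.u,
        u_inD=model.driven_weights.u_in,
        u_hintD=model.driven_weights.u_hint,
        training_error_trace=model.training_error_trace,
        final_x=model.final_x if model.final_x is not None else np.empty(0),
        final_xD=model.final_xD if model.final_xD is not None else np.empty(0),
        meta=np.array(json.dumps(meta)),
    )


def load_model(path) -> TrainedModel:
    with np.load(path, allow_pickle=False) as archive:
        meta = json.loads(str(archive["meta"]))
        params = NetworkParams(**meta["params"])
        config = TrainingConfig(**meta["config"])
        n = params.n_units
        weights = WeightSet(
            J=archive["J"], u_in=archive["u_in"], u=archive["u"],
            u_hint=archive["u_hint"], w=archive["w"],
        )
        driven = WeightSet(
            J=archive["JD"], u_in=archive["u_inD"], u=archive["uD"],
            u_hint=archive["u_hintD"], w=np.zeros(n),
        )
        trace = archive["training_error_trace"]
        final_x = archive["final_x"] if archive["final_x"].size else None
        final_xD = archive["final_xD"] if archive["final_xD"].size else None
    return TrainedModel(params, weights, driven, config, trace,
                        final_x=final_x, final_xD=final_xD)
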