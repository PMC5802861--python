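"""Scoring, trial classification, sweeps, and spectrum analysis.

The central score is the normalized test error: the mean squared
difference between network output and target divided by the target's
variance, so 0 is perfect and ~1 is output-stuck-at-the-mean.  Pulse
tasks are additionally scored per trial: a trial is "correct" when the
output matches the target bump with normalized error below 0.25 (for the
interval task, within a +-250 ms timing window around the nominal
response time); comparison trials that instead match the opposite-class
bump are "incorrect", and trials matching neither are "undetermined" and
excluded from percent correct.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .config import derive_seed
from .dynamics import NetworkParams
from .tasks import (
    TrialEvents,
    make_comparison_stream,
    make_interval_stream,
    make_oscillation_stream,
    response_bump,
)
from .training import TrainedModel, TrainingConfig, run_trained, train

__all__ = [
    "EvalReport",
    "normalized_error",
    "classify_interval_trial",
    "classify_comparison_trial",
    "evaluate_oscillation",
    "evaluate_interval",
    "evaluate_comparison",
    "evaluate",
    "SpectrumReport",
    "spectrum_analysis",
    "run_size_sweep",
    "run_noise_sweep",
    "success_onset",
    "force_anomaly_sizes",
]


@dataclass
class EvalReport:
    """Evaluation summary plus (for pulse tasks) per-trial records."""

    normalized_error: float
    n_correct: int = 0
    n_incorrect: int = 0
    n_undetermined: int = 0
    pct_correct: float = float("nan")
    trials: pd.DataFrame | None = None
    extras: dict = field(default_factory=dict)


def normalized_error(z_stream: np.ndarray, f_out_stream: np.ndarray) -> float:
    """Mean squared error of z against f_out, divided by Var(f_out)."""
    z = np.asarray(z_stream, dtype=float)
    f = np.asarray(f_out_stream, dtype=float)
    if z.shape != f.shape:
        raise ValueError(f"stream length mismatch: {z.shape} vs {f.shape}")
    v = float(np.var(f))
    if v == 0.0:
        raise ValueError("f_out is constant; normalized error is undefined")
    return float(np.mean((z - f) ** 2) / v)


def _bump_template(ev: TrialEvents, dt: float, offset: float) -> np.ndarray:
    nb = int(round((ev.t_bump_off - ev.t_bump_on) / dt))
    sign = -1.0 if ev.trial_class == "-" else 1.0
    return offset + sign * response_bump(nb)


def classify_interval_trial(
    z_stream: np.ndarray,
    ev: TrialEvents,
    *,
    dt: float = 1.0,
    threshold: float = 0.25,
    window: float = 250.0,
    offset: float = 0.25,
    strict_center: bool = False,
) -> dict:
    """Score one interval-matching trial.

    The comparison window may be centered anywhere within ``window`` ms
    of the nominal response time (timing slack); the trial is correct if
    the best-aligned normalized error against the target bump falls
    below ``threshold``.  With ``strict_center=True`` only the nominal
    alignment is scored.  Returns verdict, best error/shift, and the
    time of the output peak.
    """
    z = np.asarray(z_stream, dtype=float)
    template = _bump_template(ev, dt, offset)
    nb = len(template)
    var_t = float(np.var(template))
    i_on = int(round(ev.t_bump_on / dt))
    w_steps = 0 if strict_center else int(round(window / dt))

    best_err = np.inf
    best_shift = 0
    truncated = False
    for shift in range(-w_steps, w_steps + 1):
        a = i_on + shift
        b = a + nb
        if a < 0 or b > len(z):
            truncated = True
            continue
        err = float(np.mean((z[a:b] - template) ** 2) / var_t)
        if err < best_err:
            best_err = err
            best_shift = shift
    if truncated:
        warnings.warn("classification window truncated at stream bounds")
    if not np.isfinite(best_err):
        return {"correct": False, "error": np.inf, "shift_ms": np.nan,
                "peak_time": np.nan}

    a = max(0, i_on - w_steps)
    b = min(len(z), i_on + nb + w_steps)
    i_peak = a + int(np.argmax(z[a:b] - offset))
    return {
        "correct": best_err < threshold,
        "error": best_err,
        "shift_ms": best_shift * dt,
        "peak_time": i_peak * dt,
    }


def classify_comparison_trial(
    z_stream: np.ndarray,
    ev: TrialEvents,
    *,
    dt: float = 1.0,
    threshold: float = 0.25,
    offset: float = 0.25,
) -> dict:
    """Three-way verdict for one delayed-comparison trial.

    Correct if the output matches the trial's own target bump with
    normalized error below ``threshold``; incorrect if it matches the
    opposite-class bump instead; undetermined otherwise.
    """
    z = np.asarray(z_stream, dtype=float)
    target = _bump_template(ev, dt, offset)
    opposite = 2.0 * offset - target  # class-flipped bump on the same baseline
    nb = len(target)
    i_on = int(round(ev.t_bump_on / dt))
    a, b = i_on, i_on + nb
    if a < 0 or b > len(z):
        warnings.warn("classification window truncated at stream bounds")
        return {"verdict": "undetermined", "error_target": np.inf,
                "error_opposite": np.inf}
    var_t = float(np.var(target))
    err_t = float(np.mean((z[a:b] - target) ** 2) / var_t)
    err_o = float(np.mean((z[a:b] - opposite) ** 2) / var_t)
    if err_t < threshold and err_t <= err_o:
        verdict = "correct"
    elif err_o < threshold:
        verdict = "incorrect"
    else:
        verdict = "undetermined"
    return {"verdict": verdict, "error_target": err_t, "error_opposite": err_o}


def evaluate_oscillation(
    model: TrainedModel,
    n_periods: int = 50,
    *,
    warmup_periods: int = 2,
    noise_2D: float = 0.0,
    seed: int = 0,
) -> EvalReport:
    """Test protocol for the oscillation task: run ``warmup_periods``
    unscored periods to wash out the initial condition, then score
    ``n_periods`` of closed-loop output."""
    trial = make_oscillation_stream(n_periods + warmup_periods, model.params.dt)
    trace = run_trained(model, trial, noise_2D=noise_2D, seed=seed)
    skip = int(round(warmup_periods * 2000.0 / model.params.dt))
    err = normalized_error(trace.z[skip:], trial.f_out[skip:])
    return EvalReport(normalized_error=err,
                      extras={"n_periods": n_periods, "noise_2D": noise_2D})


def evaluate_interval(
    model: TrainedModel,
    n_trials: int = 100,
    *,
    noise_2D: float = 0.0,
    seed: int = 0,
    threshold: float = 0.25,
    window: float = 250.0,
    stream_kwargs: dict | None = None,
) -> EvalReport:
    """Test protocol for the interval task.

    Percent correct uses all trials (there is no undetermined category
    for this task).  ``stream_kwargs`` is forwarded to the generator
    (e.g. a shortened ``interval_range``).
    """
    kw = dict(stream_kwargs or {})
    offset = kw.setdefault("offset", model.config.output_offset)
    trial = make_interval_stream(n_trials, model.params.dt, False, seed=seed, **kw)
    trace = run_trained(model, trial, noise_2D=noise_2D, seed=seed + 1)
    records = []
    for ev in trial.events:
        res = classify_interval_trial(
            trace.z, ev, dt=model.params.dt, threshold=threshold,
            window=window, offset=offset,
        )
        records.append({
            "trial_id": ev.trial_id, "interval": ev.interval,
            "expected_peak": ev.t_response_peak, **res,
        })
    df = pd.DataFrame(records)
    n_correct = int(df["correct"].sum())
    return EvalReport(
        normalized_error=normalized_error(trace.z, trial.f_out),
        n_correct=n_correct,
        n_incorrect=int(len(df) - n_correct),
        n_undetermined=0,
        pct_correct=100.0 * n_correct / len(df),
        trials=df,
        extras={"noise_2D": noise_2D},
    )


def evaluate_comparison(
    model: TrainedModel,
    n_trials: int = 100,
    *,
    noise_2D: float = 0.0,
    seed: int = 0,
    threshold: float = 0.25,
    stream_kwargs: dict | None = None,
) -> EvalReport:
    """Test protocol for the delayed-comparison task.

    Percent correct is computed over determined trials only, as the
    classification rule prescribes.
    """
    kw = dict(stream_kwargs or {})
    offset = kw.setdefault("offset", model.config.output_offset)
    trial = make_comparison_stream(n_trials, model.params.dt, False, seed=seed, **kw)
    trace = run_trained(model, trial, noise_2D=noise_2D, seed=seed + 1)
    records = []
    for ev in trial.events:
        res = classify_comparison_trial(
            trace.z, ev, dt=model.params.dt, threshold=threshold, offset=offset,
        )
        records.append({
            "trial_id": ev.trial_id, "delay": ev.interval,
            "amp_difference": ev.amplitudes[0] - ev.amplitudes[1],
            "trial_class": ev.trial_class, **res,
        })
    df = pd.DataFrame(records)
    n_c = int((df["verdict"] == "correct").sum())
    n_i = int((df["verdict"] == "incorrect").sum())
    n_u = int((df["verdict"] == "undetermined").sum())
    determined = n_c + n_i
    return EvalReport(
        normalized_error=normalized_error(trace.z, trial.f_out),
        n_correct=n_c,
        n_incorrect=n_i,
        n_undetermined=n_u,
        pct_correct=100.0 * n_c / determined if determined else float("nan"),
        trials=df,
        extras={"noise_2D": noise_2D},
    )


def evaluate(model: TrainedModel, **kwargs) -> EvalReport:
    """Dispatch on the model's task."""
    task = model.config.task
    if task == "oscillation":
        return evaluate_oscillation(model, **kwargs)
    if task == "interval":
        return evaluate_interval(model, **kwargs)
    return evaluate_comparison(model, **kwargs)


@dataclass
class SpectrumReport:
    """Eigenvalues of the task recurrence, the random ``J^D``, and the
    rank-one FORCE-effective matrix ``J^D + u w^T``."""

    eigs_task: np.ndarray
    eigs_driven: np.ndarray
    eigs_effective: np.ndarray
    summary: dict


def _eig_summary(eigs: np.ndarray) -> dict:
    mod = np.abs(eigs)
    return {
        "max_modulus": float(mod.max()),
        "frac_modulus_gt1": float(np.mean(mod > 1.0)),
        "frac_real_gt1": float(np.mean(eigs.real > 1.0)),
    }


def spectrum_analysis(model: TrainedModel) -> SpectrumReport:
    """Connectivity spectra after learning.

    ``eigs_task`` is the spectrum of the matrix that actually governs
    inference recurrence: the learned ``J`` for full-FORCE, or
    ``J^D + u w^T`` for FORCE (feedback folded in).  ``eigs_effective``
    is always ``J^D + u w^T`` built from the model's own ``u`` and ``w``.
    """
    JD = model.driven_weights.J
    effective = JD + np.outer(model.weights.u, model.weights.w)
    task_matrix = model.weights.J if model.algorithm == "full-force" else effective
    eigs_task = np.linalg.eigvals(task_matrix)
    eigs_driven = np.linalg.eigvals(JD)
    eigs_effective = (
        eigs_task if model.algorithm == "force" else np.linalg.eigvals(effective)
    )
    summary = {
        "task": _eig_summary(eigs_task),
        "driven": _eig_summary(eigs_driven),
        "effective": _eig_summary(eigs_effective),
    }
    return SpectrumReport(eigs_task, eigs_driven, eigs_effective, summary)


# ---------------------------------------------------------------------------
# Sweeps


def _eval_kwargs_for(task: str, eval_kwargs: dict | None) -> dict:
    kw = {"n_periods": 50} if task == "oscillation" else {"n_trials": 100}
    kw.update(eval_kwargs or {})
    return kw


def _run_cell(
    task: str,
    algorithm: str,
    n_units: int,
    noise_2D: float,
    seed_idx: int,
    config: TrainingConfig,
    master_seed: int,
    base_params: dict,
    eval_kwargs: dict | None,
) -> dict:
    cell_seed = derive_seed(master_seed, algorithm, task, n_units, seed_idx,
                            int(round(1e9 * noise_2D)))
    params = NetworkParams(n_units=n_units, **base_params)
    cfg = replace(config, algorithm=algorithm, task=task, seed=cell_seed,
                  noise_2D=noise_2D)
    model = train(params, cfg)
    kw = _eval_kwargs_for(task, eval_kwargs)
    report = evaluate(model, noise_2D=noise_2D, seed=cell_seed + 1, **kw)
    return {
        "algorithm": algorithm,
        "task": task,
        "N": n_units,
        "noise_2D": noise_2D,
        "seed_idx": seed_idx,
        "seed": cell_seed,
        "normalized_error": report.normalized_error,
        "pct_correct": report.pct_correct,
    }


_SWEEP_COLUMNS = ["algorithm", "task", "N", "noise_2D", "seed_idx", "seed",
                  "normalized_error", "pct_correct"]
_CELL_KEY = ["algorithm", "task", "N", "noise_2D", "seed_idx"]


def _sweep(
    task, algorithm, sizes, noise_levels, n_seeds, config, master_seed,
    base_params, eval_kwargs, out_csv, progress,
) -> pd.DataFrame:
    base_params = base_params or {}
    done = pd.DataFrame(columns=_SWEEP_COLUMNS)
    if out_csv is not None:
        try:
            done = pd.read_csv(out_csv)
        except (FileNotFoundError, pd.errors.EmptyDataError):
            pass
    rows = [] if done.empty else [done]
    seen = set(map(tuple, done[_CELL_KEY].itertuples(index=False))) if not done.empty else set()
    for level in noise_levels:
        for n_units in sizes:
            for s in range(n_seeds):
                key = (algorithm, task, n_units, level, s)
                if key in seen:
                    continue
                row = _run_cell(task, algorithm, n_units, level, s, config,
                                master_seed, base_params, eval_kwargs)
                if progress:
                    print(
                        f"[sweep] {algorithm} {task} N={n_units} 2D={level:g} "
                        f"seed {s}: err={row['normalized_error']:.3g}",
                        flush=True,
                    )
                row_df = pd.DataFrame([row], columns=_SWEEP_COLUMNS)
                rows.append(row_df)
                if out_csv is not None:
                    header = not (len(rows) > 1 or not done.empty)
                    row_df.to_csv(out_csv, mode="a", header=header, index=False)
    if not rows:
        return done
    return pd.concat(rows, ignore_index=True)


def run_size_sweep(
    task: str,
    algorithm: str,
    sizes,
    n_seeds: int,
    config: TrainingConfig,
    *,
    master_seed: int = 0,
    base_params: dict | None = None,
    eval_kwargs: dict | None = None,
    out_csv=None,
    progress: bool = False,
) -> pd.DataFrame:
    """Train/evaluate over network sizes, ``n_seeds`` random draws each.

    Cell seeds derive deterministically from ``master_seed`` and the cell
    coordinates, so sweeps are order-independent and resumable: with
    ``out_csv`` set, completed cells found in the file are skipped and
    new rows appended as they finish.
    """
    if len(list(sizes)) == 0:
        raise ValueError("sizes must be non-empty")
    return _sweep(task, algorithm, list(sizes), [config.noise_2D], n_seeds,
                  config, master_seed, base_params, eval_kwargs, out_csv, progress)


def run_noise_sweep(
    task: str,
    algorithm: str,
    sizes,
    noise_levels,
    n_seeds: int,
    config: TrainingConfig,
    *,
    master_seed: int = 0,
    base_params: dict | None = None,
    eval_kwargs: dict | None = None,
    out_csv=None,
    progress: bool = False,
) -> pd.DataFrame:
    """Grid sweep over sizes and white-noise levels (``2D`` in 1/ms),
    training and testing at the same noise level."""
    if len(list(sizes)) == 0 or len(list(noise_levels)) == 0:
        raise ValueError("sizes and noise_levels must be non-empty")
    return _sweep(task, algorithm, list(sizes), list(noise_levels), n_seeds,
                  config, master_seed, base_params, eval_kwargs, out_csv, progress)


def success_onset(
    df: pd.DataFrame,
    threshold: float = 0.05,
    *,
    noise_2D: float | None = None,
) -> int | None:
    """Smallest network size whose median normalized error over seeds is
    below ``threshold`` (the documented "reliably solves" criterion)."""
    sub = df if noise_2D is None else df[df["noise_2D"] == noise_2D]
    medians = sub.groupby("N")["normalized_error"].median().sort_index()
    passing = medians[medians < threshold]
    return int(passing.index[0]) if len(passing) else None


def force_anomaly_sizes(df: pd.DataFrame) -> pd.DataFrame:
    """Flag the (noise level, N) cells where the median error *increases*
    with N relative to the next-smaller size — the partial-learning
    noise-sensitivity anomaly of readout-only training."""
    out = []
    for level, sub in df.groupby("noise_2D"):
        med = sub.groupby("N")["normalized_error"].median().sort_index()
        inc = med.diff() > 0
        for n_units in med.index[inc.fillna(False)]:
            out.append({"noise_2D": level, "N": int(n_units),
                        "median_error": float(med[n_units])})
    return pd.DataFrame(out, columns=["noise_2D", "N", "median_error"])
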