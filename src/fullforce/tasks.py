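"""Benchmark task generators.

Three task streams, each a continuous time series on the integration
grid rather than padded isolated trials (state is carried across trials
during training and testing):

oscillation
    A 2-s periodic frequency-modulated oscillation,
    ``f_out(t) = sin(omega(t) t)`` with ``omega`` rising linearly from
    ``2*pi`` to ``6*pi`` rad/s over the first half of the period and the
    signal reflected in time about the period midpoint.  A brief input
    pulse at the start of each period pins the phase so the trained
    (autonomous) network cannot drift slowly against the target.

interval matching
    Two 50-ms input pulses of amplitude 1 separated by a random interval
    (onset to onset, uniform 0.1-2.1 s); the network must emit a smooth
    response bump at a delay after the second pulse equal to that
    interval.  The optional hint is a symmetric timing ramp peaking at
    the second pulse.

delayed comparison
    Two 50-ms pulses of random amplitude (uniform 0.125-1.875) separated
    by a random silent gap; the response bump is positive if the first
    pulse was larger, negative otherwise.  The optional hint holds the
    first amplitude throughout the gap, building a memory fixed point.

Pulse-task target outputs ride on a small constant baseline (default
+0.25) that shifts the target away from zero; the constant drive helps
suppress residual chaotic activity during long silent periods.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist

__all__ = [
    "TrialEvents",
    "Trial",
    "response_bump",
    "make_oscillation_stream",
    "make_interval_stream",
    "make_comparison_stream",
    "white_noise",
    "stream_to_frame",
    "export_stream_csv",
]


@dataclass
class TrialEvents:
    """Event metadata for one trial of a pulse task (or one period of the
    oscillation, in which case only the pulse fields are meaningful)."""

    trial_id: int
    t_start: float
    t_end: float
    t_pulse1_on: float
    t_pulse1_off: float
    t_pulse2_on: float = np.nan
    t_pulse2_off: float = np.nan
    interval: float = np.nan
    t_bump_on: float = np.nan
    t_bump_off: float = np.nan
    t_response_peak: float = np.nan
    trial_class: str | None = None
    amplitudes: tuple[float, float] | None = None


@dataclass
class Trial:
    """A task stream: shared time grid, input/target/hint signals, and
    per-trial event metadata."""

    times: np.ndarray
    f_in: np.ndarray
    f_out: np.ndarray
    f_hint: np.ndarray
    events: list[TrialEvents]
    dt: float
    offset: float = 0.0
    task: str = ""

    @property
    def n_steps(self) -> int:
        return len(self.times)


def response_bump(n_steps: int, peak: float = 1.5) -> np.ndarray:
    """Smooth response-pulse profile: a Beta(4, 4) density over the bump
    support, rescaled to the requested peak amplitude."""
    s = (np.arange(n_steps) + 0.5) / n_steps
    return peak * beta_dist.pdf(s, 4, 4) / beta_dist.pdf(0.5, 4, 4)


def make_oscillation_stream(
    n_periods: int,
    dt: float = 1.0,
    seed=None,
    *,
    period: float = 2000.0,
    pulse_amplitude: float = 1.0,
    pulse_duration: float = 50.0,
) -> Trial:
    """Periodic frequency-modulated oscillation with a phase-pinning pulse.

    The stream is deterministic; ``seed`` is accepted for interface
    uniformity and ignored.
    """
    if n_periods < 1:
        raise ValueError("n_periods must be >= 1")
    steps_pp = int(round(period / dt))
    t = np.arange(steps_pp) * dt
    half_s = period / 2000.0  # half-period in seconds
    ts = t / 1000.0
    s = np.where(ts <= half_s, ts, 2.0 * half_s - ts)
    omega = 2.0 * np.pi + 4.0 * np.pi * (s / half_s)
    f_out_pp = np.sin(omega * s)
    f_in_pp = np.where(t < pulse_duration, pulse_amplitude, 0.0)

    f_out = np.tile(f_out_pp, n_periods)
    f_in = np.tile(f_in_pp, n_periods)
    T = steps_pp * n_periods
    events = [
        TrialEvents(
            trial_id=k,
            t_start=k * period,
            t_end=(k + 1) * period,
            t_pulse1_on=k * period,
            t_pulse1_off=k * period + pulse_duration,
        )
        for k in range(n_periods)
    ]
    return Trial(
        times=np.arange(T) * dt,
        f_in=f_in,
        f_out=f_out,
        f_hint=np.zeros(T),
        events=events,
        dt=dt,
        offset=0.0,
        task="oscillation",
    )


def _grid(t_ms: float, dt: float) -> int:
    return int(round(t_ms / dt))


def make_interval_stream(
    n_trials: int,
    dt: float = 1.0,
    hint_enabled: bool = True,
    seed=None,
    *,
    interval_range: tuple[float, float] = (100.0, 2100.0),
    iti_mean: float = 2400.0,
    pulse_amplitude: float = 1.0,
    pulse_duration: float = 50.0,
    bump_duration: float = 500.0,
    bump_peak: float = 1.5,
    offset: float = 0.25,
    hint_slope: float = 1.0e-3,
    tail: float = 300.0,
) -> Trial:
    """Interval-matching ("ready-set-go" style) task stream.

    Conventions (times in ms): the interval is the onset-to-onset spacing
    of the two pulses; the response bump starts at second-pulse *offset*
    + interval, so its peak sits half a bump duration later.  The hint
    ramps linearly (``hint_slope`` per ms, default 1 unit/s) from the
    first pulse onset, peaks at the second pulse onset, and falls back to
    zero at the same rate — its second zero crossing marks second-pulse
    onset + interval.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if interval_range[0] < pulse_duration:
        raise ValueError("minimum interval must be at least the pulse duration")
    rng = np.random.default_rng(seed)

    itis = rng.exponential(iti_mean, size=n_trials)
    intervals = rng.uniform(interval_range[0], interval_range[1], size=n_trials)

    events: list[TrialEvents] = []
    cursor = 0.0
    for k in range(n_trials):
        t1_on = (cursor + itis[k]) // dt * dt
        interval = intervals[k] // dt * dt
        t1_off = t1_on + pulse_duration
        t2_on = t1_on + interval
        t2_off = t2_on + pulse_duration
        bump_on = t2_off + interval
        bump_off = bump_on + bump_duration
        events.append(
            TrialEvents(
                trial_id=k,
                t_start=t1_on,
                t_end=bump_off + tail,
                t_pulse1_on=t1_on,
                t_pulse1_off=t1_off,
                t_pulse2_on=t2_on,
                t_pulse2_off=t2_off,
                interval=interval,
                t_bump_on=bump_on,
                t_bump_off=bump_off,
                t_response_peak=bump_on + bump_duration / 2.0,
            )
        )
        cursor = bump_off + tail

    T = _grid(cursor, dt) + 1
    f_in = np.zeros(T)
    f_out = np.full(T, offset)
    f_hint = np.zeros(T)
    nb = _grid(bump_duration, dt)
    bump = response_bump(nb, bump_peak)
    for ev in events:
        for on, off in (
            (ev.t_pulse1_on, ev.t_pulse1_off),
            (ev.t_pulse2_on, ev.t_pulse2_off),
        ):
            f_in[_grid(on, dt): _grid(off, dt)] = pulse_amplitude
        i_b = _grid(ev.t_bump_on, dt)
        f_out[i_b: i_b + nb] += bump
        if hint_enabled:
            i1 = _grid(ev.t_pulse1_on, dt)
            i2 = _grid(ev.t_pulse2_on, dt)
            i3 = _grid(ev.t_pulse2_on + ev.interval, dt)
            up = (np.arange(i2 - i1) * dt) * hint_slope
            down = (ev.interval - np.arange(i3 - i2) * dt) * hint_slope
            f_hint[i1:i2] = up
            f_hint[i2:i3] = down
    return Trial(
        times=np.arange(T) * dt,
        f_in=f_in,
        f_out=f_out,
        f_hint=f_hint,
        events=events,
        dt=dt,
        offset=offset,
        task="interval",
    )


def make_comparison_stream(
    n_trials: int,
    dt: float = 1.0,
    hint_enabled: bool = True,
    seed=None,
    *,
    delay_range: tuple[float, float] = (100.0, 1000.0),
    amp_range: tuple[float, float] = (0.125, 1.875),
    iti_mean: float = 2400.0,
    pulse_duration: float = 50.0,
    bump_duration: float = 500.0,
    bump_peak: float = 1.5,
    offset: float = 0.25,
    tail: float = 300.0,
) -> Trial:
    """Delayed-comparison task stream.

    The delay is the silent gap between first-pulse offset and
    second-pulse onset (it may be shorter than the pulses themselves, as
    in the 20-ms extrapolation regime).  Trial class is "+" when the
    first amplitude exceeds the second, "-" otherwise; the response bump
    (starting right after the second pulse) is added to or subtracted
    from the baseline accordingly.  The hint holds the first-pulse
    amplitude during the entire gap.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if delay_range[0] < 0:
        raise ValueError("delays must be non-negative")
    rng = np.random.default_rng(seed)

    events: list[TrialEvents] = []
    cursor = 0.0
    for k in range(n_trials):
        t1_on = (cursor + rng.exponential(iti_mean)) // dt * dt
        delay = rng.uniform(delay_range[0], delay_range[1]) // dt * dt
        a1, a2 = rng.uniform(amp_range[0], amp_range[1], size=2)
        while a1 == a2:  # probability-zero guard
            a2 = rng.uniform(amp_range[0], amp_range[1])
        t1_off = t1_on + pulse_duration
        t2_on = t1_off + delay
        t2_off = t2_on + pulse_duration
        bump_on = t2_off
        bump_off = bump_on + bump_duration
        events.append(
            TrialEvents(
                trial_id=k,
                t_start=t1_on,
                t_end=bump_off + tail,
                t_pulse1_on=t1_on,
                t_pulse1_off=t1_off,
                t_pulse2_on=t2_on,
                t_pulse2_off=t2_off,
                interval=delay,
                t_bump_on=bump_on,
                t_bump_off=bump_off,
                t_response_peak=bump_on + bump_duration / 2.0,
                trial_class="+" if a1 > a2 else "-",
                amplitudes=(float(a1), float(a2)),
            )
        )
        cursor = bump_off + tail

    T = _grid(cursor, dt) + 1
    f_in = np.zeros(T)
    f_out = np.full(T, offset)
    f_hint = np.zeros(T)
    nb = _grid(bump_duration, dt)
    bump = response_bump(nb, bump_peak)
    for ev in events:
        a1, a2 = ev.amplitudes
        f_in[_grid(ev.t_pulse1_on, dt): _grid(ev.t_pulse1_off, dt)] = a1
        f_in[_grid(ev.t_pulse2_on, dt): _grid(ev.t_pulse2_off, dt)] = a2
        sign = 1.0 if ev.trial_class == "+" else -1.0
        i_b = _grid(ev.t_bump_on, dt)
        f_out[i_b: i_b + nb] += sign * bump
        if hint_enabled:
            f_hint[_grid(ev.t_pulse1_off, dt): _grid(ev.t_pulse2_on, dt)] = a1
    return Trial(
        times=np.arange(T) * dt,
        f_in=f_in,
        f_out=f_out,
        f_hint=f_hint,
        events=events,
        dt=dt,
        offset=offset,
        task="comparison",
    )


def white_noise(
    n_steps: int,
    n_units: int,
    two_D: float,
    dt: float = 1.0,
    seed=None,
) -> np.ndarray:
    """Per-step additive white-noise increments.

    A diffusion coefficient ``2D`` (per ms) discretizes to i.i.d.
    ``Normal(0, 2D * dt)`` increments per unit per step.
    """
    if two_D < 0:
        raise ValueError(f"two_D must be non-negative, got {two_D}")
    if two_D == 0:
        return np.zeros((n_steps, n_units))
    rng = np.random.default_rng(seed)
    return rng.normal(0.0, np.sqrt(two_D * dt), size=(n_steps, n_units))


def stream_to_frame(trial: Trial) -> pd.DataFrame:
    """Flatten a task stream to a table (time_ms, f_in, f_out, f_hint,
    trial_id, class); steps outside any trial span get trial_id -1."""
    trial_id = np.full(trial.n_steps, -1, dtype=int)
    klass = np.full(trial.n_steps, "", dtype=object)
    for ev in trial.events:
        i0, i1 = _grid(ev.t_start, trial.dt), _grid(ev.t_end, trial.dt)
        trial_id[i0:i1] = ev.trial_id
        if ev.trial_class is not None:
            klass[i0:i1] = ev.trial_class
    return pd.DataFrame(
        {
            "time_ms": trial.times,
            "f_in": trial.f_in,
            "f_out": trial.f_out,
            "f_hint": trial.f_hint,
            "trial_id": trial_id,
            "class": klass,
        }
    )


def export_stream_csv(trial: Trial, path) -> None:
    stream_to_frame(trial).to_csv(path, index=False)
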