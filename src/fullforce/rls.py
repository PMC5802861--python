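"""Recursive least-squares (RLS) learning and its batch oracle.

RLS maintains a running estimate ``P`` of the inverse rate-correlation
matrix ``(alpha I + sum_k r_k r_k^T)^{-1}`` and uses it to update weights
online.  With ``P`` updated *before* the weight update at each sample and
weights starting from zero, the RLS endpoint equals the batch ridge
(L2-regularized least-squares) solution on the same samples exactly; the
regularizer ``alpha`` doubles as an effective learning rate.

A single ``P`` serves every row of the recurrent matrix ``J`` as well as
the readout ``w`` because all rows regress onto the same rate vector
``r = H(x)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

__all__ = [
    "RLSState",
    "init_rls",
    "rls_update_P",
    "rls_update_J",
    "rls_update_w",
    "batch_ridge_solve",
    "draw_update_times",
    "update_mask",
]


@dataclass
class RLSState:
    """Inverse-correlation estimate ``P`` plus its regularization scale."""

    P: np.ndarray
    alpha: float
    last_update_time: float = 0.0


def init_rls(n_units: int, alpha: float = 1.0) -> RLSState:
    """Fresh RLS state with ``P(0) = I / alpha``."""
    if alpha <= 0.0:
        raise ValueError(f"alpha must be positive, got {alpha}")
    return RLSState(P=np.eye(n_units) / alpha, alpha=alpha)


def rls_update_P(state: RLSState, r: np.ndarray) -> RLSState:
    """Rank-one downdate of the inverse correlation matrix.

    ``P <- P - (P r r^T P) / (1 + r^T P r)``, followed by an explicit
    symmetrization to suppress floating-point drift.  Equivalent, by the
    Sherman-Morrison identity, to ``P^{-1} <- P^{-1} + r r^T``.
    """
    r = np.asarray(r, dtype=float)
    if not np.all(np.isfinite(r)):
        raise ValueError("non-finite rate vector in RLS update")
    Pr = state.P @ r
    c = 1.0 + float(r @ Pr)
    P = state.P - np.outer(Pr, Pr) / c
    P = 0.5 * (P + P.T)
    return RLSState(P=P, alpha=state.alpha, last_update_time=state.last_update_time)


def rls_update_J(
    J: np.ndarray,
    state: RLSState,
    r: np.ndarray,
    target_drive: np.ndarray,
) -> np.ndarray:
    """One RLS step on the full recurrent matrix.

    ``state.P`` must already be post-update for this sample.  The error
    is ``e = J r - target_drive`` (for full-FORCE training,
    ``target_drive = J^D H(x^D) + u f_out + u_hint f_hint``) and every
    row is corrected along the shared gain ``P r``:

        ``J <- J - e (P r)^T``
    """
    r = np.asarray(r, dtype=float)
    target_drive = np.asarray(target_drive, dtype=float)
    n = J.shape[0]
    if r.shape != (n,) or target_drive.shape != (n,):
        raise ValueError(
            f"shape mismatch: J {J.shape}, r {r.shape}, target {target_drive.shape}"
        )
    e = J @ r - target_drive
    k = state.P @ r
    return J - np.outer(e, k)


def rls_update_w(
    w: np.ndarray,
    state: RLSState,
    r: np.ndarray,
    f_out: float,
) -> np.ndarray:
    """RLS step on the readout: ``w <- w - (w^T r - f_out) P r``."""
    r = np.asarray(r, dtype=float)
    if w.shape != r.shape:
        raise ValueError(f"shape mismatch: w {w.shape} vs r {r.shape}")
    e_z = float(w @ r) - f_out
    return w - e_z * (state.P @ r)


def batch_ridge_solve(
    rates: np.ndarray,
    targets: np.ndarray,
    alpha: float,
) -> np.ndarray:
    """Closed-form ridge regression, the batch oracle for RLS.

    Solves ``W = targets^T rates (alpha I + rates^T rates)^{-1}`` for
    ``rates`` of shape ``(T, N)`` and ``targets`` of shape ``(T, M)`` (or
    ``(T,)``), returning ``W`` of shape ``(M, N)`` (or ``(N,)``).
    """
    if alpha <= 0.0:
        raise ValueError(f"alpha must be positive, got {alpha}")
    rates = np.atleast_2d(np.asarray(rates, dtype=float))
    targets = np.asarray(targets, dtype=float)
    squeeze = targets.ndim == 1
    targets = targets.reshape(targets.shape[0], -1)
    if rates.shape[0] != targets.shape[0]:
        raise ValueError(
            f"rates has {rates.shape[0]} samples but targets has {targets.shape[0]}"
        )
    n = rates.shape[1]
    G = alpha * np.eye(n) + rates.T @ rates
    B = rates.T @ targets  # (N, M)
    W = scipy.linalg.solve(G, B, assume_a="pos").T
    return W[0] if squeeze else W


def draw_update_times(
    horizon: float,
    mean_interval: float,
    dt: float,
    seed,
) -> np.ndarray:
    """Random RLS update times on the integration grid.

    Inter-update gaps are geometric in units of ``dt`` with the requested
    mean, so updates stay irregular (avoiding redundant sampling of
    periodic tasks) while landing on grid points.  Times are strictly
    increasing and lie in ``(0, horizon]``.
    """
    if mean_interval < dt:
        raise ValueError(
            f"mean_interval ({mean_interval}) must be at least dt ({dt})"
        )
    if horizon <= 0:
        return np.empty(0)
    rng = np.random.default_rng(seed)
    n_steps = int(np.floor(horizon / dt))
    p = dt / mean_interval
    # Draw in blocks until the horizon is exceeded.
    gaps: list[np.ndarray] = []
    total = 0
    while total < n_steps:
        block = rng.geometric(p, size=max(16, int(1.5 * (n_steps - total) * p) + 16))
        gaps.append(block)
        total += int(block.sum())
    steps = np.cumsum(np.concatenate(gaps))
    steps = steps[steps <= n_steps]
    return steps * dt


def update_mask(
    n_steps: int,
    mean_interval: float,
    dt: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Boolean per-step mask form of :func:`draw_update_times`.

    Same geometric-gap scheme, but drawn directly from an existing
    generator for use inside training loops.
    """
    if mean_interval < dt:
        raise ValueError(
            f"mean_interval ({mean_interval}) must be at least dt ({dt})"
        )
    mask = np.zeros(n_steps, dtype=np.bool_)
    p = dt / mean_interval
    pos = -1
    while True:
        pos += int(rng.geometric(p))
        if pos >= n_steps:
            break
        mask[pos] = True
    return mask
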