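"""Numba-compiled inner loops for training and long simulations.

These loops implement exactly the same mathematics as the reference
functions in :mod:`fullforce.dynamics` and :mod:`fullforce.rls`; unit
tests pin them against that reference on small problems.  The ``P``
downdate subtracts a term-by-term symmetric outer product, so ``P``
stays symmetric to rounding without an explicit symmetrization pass.

Noise is generated internally from ``numpy.random.seed`` (the legacy
global stream, which numba supports inside jitted code); callers derive
the per-call seed from their own generator so all randomness is
reproducible.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "train_full_force_kernel",
    "train_force_kernel",
    "sim_task_kernel",
    "sim_force_kernel",
    "sim_driven_kernel",
]


@njit(cache=True, fastmath=True)
def _tanh_into(x, r):
    for i in range(x.shape[0]):
        r[i] = np.tanh(x[i])


@njit(cache=True, fastmath=True)
def _p_downdate(P, r):
    """P <- P - (P r r^T P) / (1 + r^T P r); returns k = P_new @ r.

    The subtracted outer product is symmetric term-by-term, so P stays
    symmetric to rounding without an explicit symmetrization pass.
    """
    Pr = P @ r
    c = 1.0 + np.dot(r, Pr)
    n = r.shape[0]
    for i in range(n):
        pri = Pr[i] / c
        for j in range(n):
            P[i, j] -= pri * Pr[j]
    return Pr / c


@njit(cache=True, fastmath=True)
def train_full_force_kernel(
    JD, u, u_in, u_hint, J, w, P, x, xD,
    f_in, f_out, f_hint, update_mask,
    noise_std, dt_over_tau, noise_seed, learn_J, learn_w,
):
    """One batch of full-FORCE training; mutates J, w, P, x, xD in place.

    The driven and task-performing networks are integrated concurrently
    on the same input stream.  At each flagged step the inverse
    correlation P is downdated first, then every row of J is corrected
    toward the driven drive J^D H(x^D) + u f_out + u_hint f_hint, and
    (optionally) w toward f_out.  Only the task-performing network
    receives noise.  Returns the readout trace z(t).
    """
    T = f_in.shape[0]
    N = x.shape[0]
    z = np.empty(T)
    r = np.empty(N)
    rD = np.empty(N)
    np.random.seed(noise_seed)
    for t in range(T):
        _tanh_into(x, r)
        _tanh_into(xD, rD)
        drive_D = JD @ rD
        for i in range(N):
            drive_D[i] += u[i] * f_out[t] + u_hint[i] * f_hint[t]
        Jr = J @ r
        if update_mask[t]:
            k = _p_downdate(P, r)
            if learn_J:
                kr = np.dot(k, r)
                for i in range(N):
                    ei = Jr[i] - drive_D[i]
                    for j in range(N):
                        J[i, j] -= ei * k[j]
                    Jr[i] -= ei * kr
            if learn_w:
                ez = np.dot(w, r) - f_out[t]
                for i in range(N):
                    w[i] -= ez * k[i]
        z[t] = np.dot(w, r)
        if noise_std > 0.0:
            for i in range(N):
                xD[i] += dt_over_tau * (-xD[i] + drive_D[i] + u_in[i] * f_in[t])
                x[i] += dt_over_tau * (-x[i] + Jr[i] + u_in[i] * f_in[t]) \
                    + noise_std * np.random.normal(0.0, 1.0)
        else:
            for i in range(N):
                xD[i] += dt_over_tau * (-xD[i] + drive_D[i] + u_in[i] * f_in[t])
                x[i] += dt_over_tau * (-x[i] + Jr[i] + u_in[i] * f_in[t])
        if t % 200 == 0 and not np.isfinite(x[0] + xD[0]):
            raise FloatingPointError("non-finite network state during training")
    s = 0.0
    for i in range(N):
        s += x[i] + xD[i]
    if not np.isfinite(s):
        raise FloatingPointError("non-finite network state during training")
    return z


@njit(cache=True, fastmath=True)
def train_force_kernel(
    JD, u, u_in, w, P, x,
    f_in, f_out, update_mask,
    noise_std, dt_over_tau, noise_seed, learn_w,
):
    """One batch of FORCE training; mutates w, P, x in place.

    The network runs closed-loop with output feedback u * z; only the
    readout w is learned.  Feedback uses the readout recomputed after
    the weight update at update steps.  Returns the readout trace.
    """
    T = f_in.shape[0]
    N = x.shape[0]
    z = np.empty(T)
    r = np.empty(N)
    np.random.seed(noise_seed)
    for t in range(T):
        _tanh_into(x, r)
        zt = np.dot(w, r)
        if update_mask[t] and learn_w:
            k = _p_downdate(P, r)
            ez = zt - f_out[t]
            for i in range(N):
                w[i] -= ez * k[i]
            zt -= ez * np.dot(k, r)
        z[t] = zt
        JDr = JD @ r
        if noise_std > 0.0:
            for i in range(N):
                x[i] += dt_over_tau * (
                    -x[i] + JDr[i] + u_in[i] * f_in[t] + u[i] * zt
                ) + noise_std * np.random.normal(0.0, 1.0)
        else:
            for i in range(N):
                x[i] += dt_over_tau * (
                    -x[i] + JDr[i] + u_in[i] * f_in[t] + u[i] * zt
                )
        if t % 200 == 0 and not np.isfinite(x[0]):
            raise FloatingPointError("non-finite network state during training")
    s = 0.0
    for i in range(N):
        s += x[i]
    if not np.isfinite(s):
        raise FloatingPointError("non-finite network state during training")
    return z


@njit(cache=True, fastmath=True)
def sim_task_kernel(J, u_in, w, x, f_in, noise_std, dt_over_tau, noise_seed,
                    store_every):
    """Closed-loop task-performing simulation (input only, no feedback).

    Returns (z, X) where X holds the state every ``store_every`` steps
    (empty when store_every == 0).  Mutates x in place.
    """
    T = f_in.shape[0]
    N = x.shape[0]
    z = np.empty(T)
    r = np.empty(N)
    n_store = T // store_every + 1 if store_every > 0 else 0
    X = np.empty((n_store, N))
    ns = 0
    np.random.seed(noise_seed)
    for t in range(T):
        if store_every > 0 and t % store_every == 0:
            X[ns] = x
            ns += 1
        _tanh_into(x, r)
        z[t] = np.dot(w, r)
        Jr = J @ r
        if noise_std > 0.0:
            for i in range(N):
                x[i] += dt_over_tau * (-x[i] + Jr[i] + u_in[i] * f_in[t]) \
                    + noise_std * np.random.normal(0.0, 1.0)
        else:
            for i in range(N):
                x[i] += dt_over_tau * (-x[i] + Jr[i] + u_in[i] * f_in[t])
        if t % 200 == 0 and not np.isfinite(x[0]):
            raise FloatingPointError("non-finite network state during simulation")
    return z, X[:ns]


@njit(cache=True, fastmath=True)
def sim_force_kernel(JD, u, u_in, w, x, f_in, noise_std, dt_over_tau,
                     noise_seed, store_every):
    """Closed-loop FORCE simulation with output feedback u * z."""
    T = f_in.shape[0]
    N = x.shape[0]
    z = np.empty(T)
    r = np.empty(N)
    n_store = T // store_every + 1 if store_every > 0 else 0
    X = np.empty((n_store, N))
    ns = 0
    np.random.seed(noise_seed)
    for t in range(T):
        if store_every > 0 and t % store_every == 0:
            X[ns] = x
            ns += 1
        _tanh_into(x, r)
        zt = np.dot(w, r)
        z[t] = zt
        JDr = JD @ r
        if noise_std > 0.0:
            for i in range(N):
                x[i] += dt_over_tau * (
                    -x[i] + JDr[i] + u_in[i] * f_in[t] + u[i] * zt
                ) + noise_std * np.random.normal(0.0, 1.0)
        else:
            for i in range(N):
                x[i] += dt_over_tau * (
                    -x[i] + JDr[i] + u_in[i] * f_in[t] + u[i] * zt
                )
        if t % 200 == 0 and not np.isfinite(x[0]):
            raise FloatingPointError("non-finite network state during simulation")
    return z, X[:ns]


@njit(cache=True, fastmath=True)
def sim_driven_kernel(JD, u, u_in, u_hint, xD, f_in, f_out, f_hint,
                      dt_over_tau, store_every):
    """Driven (target-generating) simulation, storing rates every
    ``store_every`` steps.  Returns (step_indices, rates)."""
    T = f_in.shape[0]
    N = xD.shape[0]
    rD = np.empty(N)
    n_store = T // store_every + 1
    R = np.empty((n_store, N))
    idx = np.empty(n_store, dtype=np.int64)
    ns = 0
    for t in range(T):
        _tanh_into(xD, rD)
        if t % store_every == 0:
            R[ns] = rD
            idx[ns] = t
            ns += 1
        drive = JD @ rD
        for i in range(N):
            xD[i] += dt_over_tau * (
                -xD[i] + drive[i] + u[i] * f_out[t]
                + u_in[i] * f_in[t] + u_hint[i] * f_hint[t]
            )
        if t % 200 == 0 and not np.isfinite(xD[0]):
            raise FloatingPointError("non-finite network state during simulation")
    return idx[:ns], R[:ns]
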