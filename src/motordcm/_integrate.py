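"""Fixed-step RK4 integration kernels for the neural + hemodynamic model.

The kernels are batched over parameter sets so that a finite-difference
Jacobian (one perturbed parameter vector per batch entry) costs a single
call.  Inputs are held piecewise-constant per microtime bin.

State layout per region: z (neural), s (vasodilatory signal), f (inflow),
v (venous volume), q (deoxyhemoglobin).  Baseline is z = s = 0,
f = v = q = 1.  BOLD observation:

    y = V0 * (k1 (1 - q) + k2 (1 - q / v) + k3 (1 - v))

with k1 = 7 E0, k2 = 2, k3 = 2 E0 - 0.2.
"""

from __future__ import annotations

import numpy as np
from numba import njit

N_STATES = 5


@njit(cache=True)
def _deriv(M, cu, X, out, kappa, gamma, tau, alpha, E0):
    """Time derivative of the stacked states.

    M : (nb, R, R) effective coupling A + sum_j u_j B_j
    cu : (nb, R) driving input C @ u
    X, out : (nb, 5, R)
    tau : (nb, R); kappa, gamma, alpha, E0 scalars
    """
    nb, _, R = X.shape
    ooa = 1.0 / alpha
    for b in range(nb):
        for i in range(R):
            z = X[b, 0, i]
            s = X[b, 1, i]
            f = X[b, 2, i]
            v = X[b, 3, i]
            q = X[b, 4, i]
            dz = cu[b, i]
            for k in range(R):
                dz += M[b, i, k] * X[b, 0, k]
            out[b, 0, i] = dz
            out[b, 1, i] = z - kappa * s - gamma * (f - 1.0)
            out[b, 2, i] = s
            fv = f - v ** ooa
            out[b, 3, i] = fv / tau[b, i]
            ef = 1.0 - (1.0 - E0) ** (1.0 / f)
            out[b, 4, i] = (f * ef / E0 - (v ** ooa) * q / v) / tau[b, i]


@njit(cache=True)
def _observe(X, E0, V0, y, b, p):
    R = X.shape[2]
    k1 = 7.0 * E0
    k2 = 2.0
    k3 = 2.0 * E0 - 0.2
    for i in range(R):
        v = X[b, 3, i]
        q = X[b, 4, i]
        y[b, p, i] = V0 * (k1 * (1.0 - q) + k2 * (1.0 - q / v) + k3 * (1.0 - v))


@njit(cache=True)
def rk4_bold(A, B, C, U, dt, kappa, gamma, tau, alpha, E0, V0, sample_idx):
    """Integrate and sample BOLD at the given microtime bin indices.

    Returns (y, status): y (nb, n_samples, R); status 0 on success, else the
    1-based step index at which a hemodynamic state became non-positive.
    Samples are the state at time ``sample_idx * dt`` (before stepping).
    """
    nb, R, _ = A.shape
    J = C.shape[2]
    T = U.shape[0]
    S = sample_idx.shape[0]
    y = np.zeros((nb, S, R))
    X = np.zeros((nb, N_STATES, R))
    X[:, 2, :] = 1.0
    X[:, 3, :] = 1.0
    X[:, 4, :] = 1.0
    M = np.empty((nb, R, R))
    cu = np.empty((nb, R))
    k1 = np.empty_like(X)
    k2 = np.empty_like(X)
    k3 = np.empty_like(X)
    k4 = np.empty_like(X)
    Xt = np.empty_like(X)
    ptr = 0
    for t in range(T + 1):
        while ptr < S and sample_idx[ptr] == t:
            for b in range(nb):
                _observe(X, E0, V0, y, b, ptr)
            ptr += 1
        if t == T:
            break
        # effective coupling and drive for this bin
        for b in range(nb):
            for i in range(R):
                ci = 0.0
                for j in range(J):
                    ci += C[b, i, j] * U[t, j]
                cu[b, i] = ci
                for k in range(R):
                    m = A[b, i, k]
                    for j in range(J):
                        m += U[t, j] * B[b, j, i, k]
                    M[b, i, k] = m
        _deriv(M, cu, X, k1, kappa, gamma, tau, alpha, E0)
        Xt[:] = X + 0.5 * dt * k1
        _deriv(M, cu, Xt, k2, kappa, gamma, tau, alpha, E0)
        Xt[:] = X + 0.5 * dt * k2
        _deriv(M, cu, Xt, k3, kappa, gamma, tau, alpha, E0)
        Xt[:] = X + dt * k3
        _deriv(M, cu, Xt, k4, kappa, gamma, tau, alpha, E0)
        X += (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        for b in range(nb):
            for i in range(R):
                if X[b, 2, i] <= 0.0 or X[b, 3, i] <= 0.0 or X[b, 4, i] <= 0.0:
                    return y, t + 1
    return y, 0


@njit(cache=True)
def rk4_states(A, B, C, U, dt, kappa, gamma, tau, alpha, E0):
    """Integrate and return the full state trajectory (nb, T+1, 5, R).

    Same dynamics as :func:`rk4_bold`; intended for small batches where the
    trajectory itself is wanted.
    """
    nb, R, _ = A.shape
    J = C.shape[2]
    T = U.shape[0]
    out = np.zeros((nb, T + 1, N_STATES, R))
    X = np.zeros((nb, N_STATES, R))
    X[:, 2, :] = 1.0
    X[:, 3, :] = 1.0
    X[:, 4, :] = 1.0
    M = np.empty((nb, R, R))
    cu = np.empty((nb, R))
    k1 = np.empty_like(X)
    k2 = np.empty_like(X)
    k3 = np.empty_like(X)
    k4 = np.empty_like(X)
    Xt = np.empty_like(X)
    out[:, 0] = X
    status = 0
    for t in range(T):
        for b in range(nb):
            for i in range(R):
                ci = 0.0
                for j in range(J):
                    ci += C[b, i, j] * U[t, j]
                cu[b, i] = ci
                for k in range(R):
                    m = A[b, i, k]
                    for j in range(J):
                        m += U[t, j] * B[b, j, i, k]
                    M[b, i, k] = m
        _deriv(M, cu, X, k1, kappa, gamma, tau, alpha, E0)
        Xt[:] = X + 0.5 * dt * k1
        _deriv(M, cu, Xt, k2, kappa, gamma, tau, alpha, E0)
        Xt[:] = X + 0.5 * dt * k2
        _deriv(M, cu, Xt, k3, kappa, gamma, tau, alpha, E0)
        Xt[:] = X + dt * k3
        _deriv(M, cu, Xt, k4, kappa, gamma, tau, alpha, E0)
        X += (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        out[:, t + 1] = X
        for b in range(nb):
            for i in range(R):
                if X[b, 2, i] <= 0.0 or X[b, 3, i] <= 0.0 or X[b, 4, i] <= 0.0:
                    return out, t + 1
    return out, status


def bold_from_states(X: np.ndarray, E0: float, V0: float) -> np.ndarray:
    """BOLD observation from stacked states (..., 5, R) -> (..., R)."""
    v = X[..., 3, :]
    q = X[..., 4, :]
    k1 = 7.0 * E0
    k2 = 2.0
    k3 = 2.0 * E0 - 0.2
    return V0 * (k1 * (1.0 - q) + k2 * (1.0 - q / v) + k3 * (1.0 - v))
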