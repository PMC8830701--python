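"""Compiled numerical kernels: mass-action RHS, Jacobians, and fixed-step
RK4 integration with forward sensitivities.

All kernels take the library as two float64 matrices:
  R : (D, N) reactant multiplicities (0, 1 or 2) -> rate basis f_d = prod X^R[d]
  S : (D, N) net stoichiometric change

The fixed-step classical Runge-Kutta scheme is used during inference so that
the log-density and its gradient come from exactly the same discretization
(the gradient is the exact derivative of the discrete solution).  `nsub`
sub-steps are taken between consecutive output times.
"""

import numpy as np
from numba import njit

__all__ = [
    "propensities",
    "rhs_vec",
    "rk4_trajectory",
    "rk4_with_sensitivities",
]


@njit(cache=True)
def propensities(R, y):
    D, N = R.shape
    f = np.ones(D)
    for d in range(D):
        v = 1.0
        for n in range(N):
            m = R[d, n]
            if m == 1.0:
                v *= y[n]
            elif m == 2.0:
                v *= y[n] * y[n]
        f[d] = v
    return f


@njit(cache=True)
def rhs_vec(R, S, k, y):
    """dy/dt = S.T @ (k * f(y))."""
    D, N = R.shape
    f = propensities(R, y)
    out = np.zeros(N)
    for d in range(D):
        kf = k[d] * f[d]
        if kf != 0.0:
            for n in range(N):
                out[n] += S[d, n] * kf
    return out


@njit(cache=True)
def _rhs_and_jacobians(R, S, k, y, dy, J, B):
    """Fill dy (N), J = d(rhs)/dy (N,N), B = d(rhs)/dk (N,D) in place."""
    D, N = R.shape
    dy[:] = 0.0
    J[:, :] = 0.0
    for d in range(D):
        # f_d and its gradient wrt y
        f = 1.0
        for n in range(N):
            m = R[d, n]
            if m == 1.0:
                f *= y[n]
            elif m == 2.0:
                f *= y[n] * y[n]
        for n in range(N):
            B[n, d] = S[d, n] * f
            dy[n] += k[d] * S[d, n] * f
        if k[d] != 0.0:
            for m_idx in range(N):
                mm = R[d, m_idx]
                if mm == 0.0:
                    continue
                # d f_d / d y_m
                g = 1.0
                for n in range(N):
                    m2 = R[d, n]
                    if n == m_idx:
                        if m2 == 1.0:
                            g *= 1.0
                        else:  # m2 == 2
                            g *= 2.0 * y[n]
                    else:
                        if m2 == 1.0:
                            g *= y[n]
                        elif m2 == 2.0:
                            g *= y[n] * y[n]
                kg = k[d] * g
                for n in range(N):
                    J[n, m_idx] += S[d, n] * kg


@njit(cache=True)
def rk4_trajectory(R, S, k, y0, times, nsub):
    """Classical RK4 on the reaction-rate ODE, output at `times`.

    Returns (traj (T,N), ok flag).  ok=False if the state went non-finite
    or exploded (abs > 1e12), in which case the trajectory is invalid.
    """
    T = times.shape[0]
    N = y0.shape[0]
    traj = np.empty((T, N))
    y = y0.copy()
    traj[0] = y
    for j in range(T - 1):
        h = (times[j + 1] - times[j]) / nsub
        for _ in range(nsub):
            k1 = rhs_vec(R, S, k, y)
            k2 = rhs_vec(R, S, k, y + 0.5 * h * k1)
            k3 = rhs_vec(R, S, k, y + 0.5 * h * k2)
            k4 = rhs_vec(R, S, k, y + h * k3)
            y = y + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        for n in range(N):
            if not np.isfinite(y[n]) or abs(y[n]) > 1e12:
                return traj, False
        traj[j + 1] = y
    return traj, True


@njit(cache=True)
def _aug_rhs(R, S, k, y, Sy, S0, with_s0, dy, dSy, dS0, J, B):
    """Augmented RHS: state + sensitivities wrt k (and optionally y0).

    dSy/dt = J @ Sy + B with the accumulation ordered so the inner loop
    runs over the contiguous reaction axis (vectorizable).
    """
    N, D = Sy.shape
    _rhs_and_jacobians(R, S, k, y, dy, J, B)
    for n in range(N):
        for d in range(D):
            dSy[n, d] = B[n, d]
        for m in range(N):
            jm = J[n, m]
            if jm != 0.0:
                for d in range(D):
                    dSy[n, d] += jm * Sy[m, d]
    if with_s0:
        for n in range(N):
            for m0 in range(N):
                acc = 0.0
                for m in range(N):
                    acc += J[n, m] * S0[m, m0]
                dS0[n, m0] = acc


@njit(cache=True)
def rk4_with_sensitivities(R, S, k, y0, times, nsub, with_s0):
    """RK4 on the ODE augmented with forward sensitivities.

    Returns (traj (T,N), sens_k (T,N,D), sens_y0 (T,N,N), ok).
    sens_k[j] = dZ(t_j)/dk; sens_y0[j] = dZ(t_j)/dy0 (identity at t_0,
    only filled when with_s0).  All stage work uses preallocated buffers:
    this routine sits inside every leapfrog step of the sampler.
    """
    T = times.shape[0]
    D, N = R.shape
    traj = np.empty((T, N))
    sens_k = np.zeros((T, N, D))
    sens_y0 = np.zeros((T, N, N))
    y = y0.copy()
    Sy = np.zeros((N, D))
    S0 = np.eye(N)
    traj[0] = y
    if with_s0:
        sens_y0[0] = S0

    dy = np.empty(N)
    dSy = np.empty((N, D))
    dS0 = np.empty((N, N))
    J = np.empty((N, N))
    B = np.empty((N, D))
    # RK4 stage buffers and stage-evaluation points
    ky = np.empty((4, N))
    kS = np.empty((4, N, D))
    k0 = np.empty((4, N, N))
    yt = np.empty(N)
    St = np.empty((N, D))
    S0t = np.empty((N, N))

    for j in range(T - 1):
        h = (times[j + 1] - times[j]) / nsub
        for _ in range(nsub):
            for stage in range(4):
                if stage == 0:
                    a = 0.0
                elif stage == 3:
                    a = h
                else:
                    a = 0.5 * h
                if stage == 0:
                    for n in range(N):
                        yt[n] = y[n]
                        for d in range(D):
                            St[n, d] = Sy[n, d]
                        if with_s0:
                            for n2 in range(N):
                                S0t[n, n2] = S0[n, n2]
                else:
                    for n in range(N):
                        yt[n] = y[n] + a * ky[stage - 1, n]
                        for d in range(D):
                            St[n, d] = Sy[n, d] + a * kS[stage - 1, n, d]
                        if with_s0:
                            for n2 in range(N):
                                S0t[n, n2] = S0[n, n2] + a * k0[stage - 1, n, n2]
                _aug_rhs(R, S, k, yt, St, S0t, with_s0, dy, dSy, dS0, J, B)
                for n in range(N):
                    ky[stage, n] = dy[n]
                    for d in range(D):
                        kS[stage, n, d] = dSy[n, d]
                    if with_s0:
                        for n2 in range(N):
                            k0[stage, n, n2] = dS0[n, n2]
            h6 = h / 6.0
            for n in range(N):
                y[n] += h6 * (ky[0, n] + 2.0 * ky[1, n] + 2.0 * ky[2, n] + ky[3, n])
                for d in range(D):
                    Sy[n, d] += h6 * (kS[0, n, d] + 2.0 * kS[1, n, d]
                                      + 2.0 * kS[2, n, d] + kS[3, n, d])
                if with_s0:
                    for n2 in range(N):
                        S0[n, n2] += h6 * (k0[0, n, n2] + 2.0 * k0[1, n, n2]
                                           + 2.0 * k0[2, n, n2] + k0[3, n, n2])
        ok = True
        for n in range(N):
            if not np.isfinite(y[n]) or abs(y[n]) > 1e12:
                ok = False
        if not ok:
            return traj, sens_k, sens_y0, False
        traj[j + 1] = y
        sens_k[j + 1] = Sy
        if with_s0:
            sens_y0[j + 1] = S0
    return traj, sens_k, sens_y0, True
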