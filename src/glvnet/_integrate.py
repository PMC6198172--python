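"""Low-level ODE integration kernels for the generalized Lotka-Volterra system.

The community model is integrated in carrying-capacity units (y = x/K), so the
state lives on [0, ~1] regardless of whether K is 2e10 CFU/g or 1e11 cells/g.
The workhorse is a Dormand-Prince 5(4) adaptive stepper compiled with numba:
model selection evaluates tens of thousands of candidate trajectories, and a
Python-callback solver is the bottleneck otherwise.  Stiff parameter sets that
defeat the explicit stepper are retried with LSODA (see ``dynamics.simulate``).
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["glv_rhs_scaled", "integrate_scaled", "OK", "FAILED"]

OK = 0
FAILED = 1

# Dormand-Prince 5(4) tableau
_C2, _C3, _C4, _C5 = 1.0 / 5.0, 3.0 / 10.0, 4.0 / 5.0, 8.0 / 9.0
_A21 = 1.0 / 5.0
_A31, _A32 = 3.0 / 40.0, 9.0 / 40.0
_A41, _A42, _A43 = 44.0 / 45.0, -56.0 / 15.0, 32.0 / 9.0
_A51, _A52, _A53, _A54 = 19372.0 / 6561.0, -25360.0 / 2187.0, 64448.0 / 6561.0, -212.0 / 729.0
_A61, _A62, _A63, _A64, _A65 = (
    9017.0 / 3168.0,
    -355.0 / 33.0,
    46732.0 / 5247.0,
    49.0 / 176.0,
    -5103.0 / 18656.0,
)
_B1, _B3, _B4, _B5, _B6 = 35.0 / 384.0, 500.0 / 1113.0, 125.0 / 192.0, -2187.0 / 6784.0, 11.0 / 84.0
# embedded 4th-order error weights (b5 - b4)
_E1, _E3, _E4, _E5, _E6, _E7 = (
    71.0 / 57600.0,
    -71.0 / 16695.0,
    71.0 / 1920.0,
    -17253.0 / 339200.0,
    22.0 / 525.0,
    -1.0 / 40.0,
)


@njit(cache=True)
def glv_rhs_scaled(y, r, A):
    """dy/dt for the gLV system in carrying-capacity units (K = 1).

    dy_i/dt = y_i * (r_i + sum_j A[i, j] * y_j / N) * (1 - N),  N = sum(y).
    A zero community (N = 0) is absorbing: the derivative is identically zero.
    """
    n = y.shape[0]
    dy = np.zeros(n)
    N = 0.0
    for i in range(n):
        N += y[i]
    if N <= 0.0:
        return dy
    sat = 1.0 - N
    for i in range(n):
        s = r[i]
        for j in range(n):
            s += A[i, j] * y[j] / N
        dy[i] = y[i] * s * sat
    return dy


@njit(cache=True)
def integrate_scaled(r, A, y0, times, rtol, atol, max_steps):
    """Integrate the scaled gLV system across ``times`` (strictly increasing).

    Returns (Y, status) with Y of shape (len(times), n); Y[0] = clip(y0, 0).
    Negative excursions are clamped to zero after every accepted step (the
    model preserves non-negativity analytically, so they are pure solver
    error).  status is FAILED on step-size underflow, non-finite state, or
    step-count exhaustion; rows computed so far are left in Y.
    """
    n = y0.shape[0]
    T = times.shape[0]
    Y = np.empty((T, n))
    y = y0.copy()
    for i in range(n):
        if y[i] < 0.0:
            y[i] = 0.0
    Y[0] = y
    t = times[0]
    span = times[T - 1] - times[0]
    if span <= 0.0:
        return Y, FAILED
    hmin = 1e-12 * span

    k1 = glv_rhs_scaled(y, r, A)
    # initial step: conservative fraction of the span, limited by the rate scale
    rate = 0.0
    for i in range(n):
        a = abs(k1[i])
        if a > rate:
            rate = a
    h = 0.01 * span
    if rate > 0.0 and 0.1 / rate < h:
        h = 0.1 / rate

    nsteps = 0
    for kout in range(1, T):
        t_end = times[kout]
        while t < t_end:
            nsteps += 1
            if nsteps > max_steps:
                return Y, FAILED
            if h > t_end - t:
                h_use = t_end - t
            else:
                h_use = h
            if h_use < hmin:
                return Y, FAILED

            y2 = y + h_use * (_A21 * k1)
            k2 = glv_rhs_scaled(y2, r, A)
            y3 = y + h_use * (_A31 * k1 + _A32 * k2)
            k3 = glv_rhs_scaled(y3, r, A)
            y4 = y + h_use * (_A41 * k1 + _A42 * k2 + _A43 * k3)
            k4 = glv_rhs_scaled(y4, r, A)
            y5 = y + h_use * (_A51 * k1 + _A52 * k2 + _A53 * k3 + _A54 * k4)
            k5 = glv_rhs_scaled(y5, r, A)
            y6 = y + h_use * (_A61 * k1 + _A62 * k2 + _A63 * k3 + _A64 * k4 + _A65 * k5)
            k6 = glv_rhs_scaled(y6, r, A)
            ynew = y + h_use * (_B1 * k1 + _B3 * k3 + _B4 * k4 + _B5 * k5 + _B6 * k6)
            k7 = glv_rhs_scaled(ynew, r, A)

            # weighted RMS error of the embedded 4th-order estimate
            errnorm = 0.0
            ok = True
            for i in range(n):
                e = h_use * (
                    _E1 * k1[i] + _E3 * k3[i] + _E4 * k4[i] + _E5 * k5[i] + _E6 * k6[i] + _E7 * k7[i]
                )
                yi = abs(y[i])
                yn = abs(ynew[i])
                sc = atol + rtol * (yi if yi > yn else yn)
                q = e / sc
                errnorm += q * q
                if not np.isfinite(ynew[i]):
                    ok = False
            errnorm = np.sqrt(errnorm / n)

            if ok and errnorm <= 1.0:
                t = t + h_use
                for i in range(n):
                    if ynew[i] < 0.0:
                        ynew[i] = 0.0
                y = ynew
                k1 = glv_rhs_scaled(y, r, A)  # clamp invalidates FSAL reuse
                if errnorm > 1e-12:
                    fac = 0.9 * errnorm ** (-0.2)
                    if fac > 5.0:
                        fac = 5.0
                    h = h_use * fac
                else:
                    h = h_use * 5.0
            else:
                if not ok:
                    h = h_use * 0.1
                else:
                    fac = 0.9 * errnorm ** (-0.2)
                    if fac < 0.1:
                        fac = 0.1
                    h = h_use * fac
                if h < hmin:
                    return Y, FAILED
        Y[kout] = y
    return Y, OK
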