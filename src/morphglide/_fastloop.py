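"""Compiled inner loop for the stitched extension integration.

The scheduling loop advances a 4-state system through thousands of 5 ms
steps, each with its own frozen trim/derivative set; doing this with tiny
numpy arrays in interpreted code dominates the simulation cost.  This
module JIT-compiles the Dormand-Prince 5(4) stepping over the whole
extension.  ``morphglide.sim`` falls back to the interpreted loop when
numba is unavailable.

Per-step parameter rows (shape (n, 15)):
  0-8: Xu/m, Xw/m, Xq/m, Zu/m, Zw/m, Zq/m, Mu/Iyy, Mw/Iyy, Mq/Iyy
  9-11: U0, W0, Q0
  12-14: g*sin(Theta0), g*cos(Theta0), g
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn

        return wrap if not (args and callable(args[0])) else args[0]


_SPEED_LIMIT = 200.0
_PITCH_RATE_LIMIT = 100.0
_MAX_STEP_ATTEMPTS = 10_000


@njit(cache=True)
def _rhs(y, p, out):
    U, W, Q, Th = y[0], y[1], y[2], y[3]
    u = U - p[9]
    w = W - p[10]
    q = Q - p[11]
    out[0] = -Q * W + p[0] * u + p[1] * w + p[2] * q + p[12] - p[14] * np.sin(Th)
    out[1] = Q * U + p[3] * u + p[4] * w + p[5] * q - p[13] + p[14] * np.cos(Th)
    out[2] = p[6] * u + p[7] * w + p[8] * q
    out[3] = Q


@njit(cache=True)
def _dp45_interval(y, p, dt, rtol, atol):
    """Adaptive DP5(4) from 0 to dt in place; returns 0 on success."""
    t = 0.0
    h = dt
    k = np.empty((7, 4))
    yt = np.empty(4)
    y5 = np.empty(4)
    y4 = np.empty(4)
    A = np.array(
        [
            [0.0, 0.0, 0.0, 0.0, 0.0, 0.0],
            [1.0 / 5.0, 0.0, 0.0, 0.0, 0.0, 0.0],
            [3.0 / 40.0, 9.0 / 40.0, 0.0, 0.0, 0.0, 0.0],
            [44.0 / 45.0, -56.0 / 15.0, 32.0 / 9.0, 0.0, 0.0, 0.0],
            [
                19372.0 / 6561.0,
                -25360.0 / 2187.0,
                64448.0 / 6561.0,
                -212.0 / 729.0,
                0.0,
                0.0,
            ],
            [
                9017.0 / 3168.0,
                -355.0 / 33.0,
                46732.0 / 5247.0,
                49.0 / 176.0,
                -5103.0 / 18656.0,
                0.0,
            ],
            [
                35.0 / 384.0,
                0.0,
                500.0 / 1113.0,
                125.0 / 192.0,
                -2187.0 / 6784.0,
                11.0 / 84.0,
            ],
        ]
    )
    C = np.array([0.0, 0.2, 0.3, 0.8, 8.0 / 9.0, 1.0, 1.0])
    B4 = np.array(
        [
            5179.0 / 57600.0,
            0.0,
            7571.0 / 16695.0,
            393.0 / 640.0,
            -92097.0 / 339200.0,
            187.0 / 2100.0,
            1.0 / 40.0,
        ]
    )
    attempts = 0
    while t < dt - 1e-16:
        attempts += 1
        if attempts > _MAX_STEP_ATTEMPTS:
            return 1
        if h > dt - t:
            h = dt - t
        _rhs(y, p, k[0])
        for i in range(1, 7):
            for j in range(4):
                acc = 0.0
                for m in range(i):
                    acc += A[i][m] * k[m][j]
                yt[j] = y[j] + h * acc
            _rhs(yt, p, k[i])
        # stage 7 coefficients equal row 6 of A (FSAL pair): yt holds y5
        for j in range(4):
            y5[j] = yt[j]
        err = 0.0
        for j in range(4):
            acc4 = 0.0
            for m in range(7):
                acc4 += B4[m] * k[m][j]
            y4[j] = y[j] + h * acc4
            sc = atol + rtol * max(abs(y[j]), abs(y5[j]))
            e = (y5[j] - y4[j]) / sc
            err += e * e
        err = np.sqrt(err / 4.0)
        if err <= 1.0 or h <= 1e-12 * dt:
            t += h
            for j in range(4):
                y[j] = y5[j]
            if not np.isfinite(y[0] + y[1] + y[2] + y[3]):
                return 1
        if err > 0.0:
            fac = 0.9 * err ** -0.2
            if fac < 0.2:
                fac = 0.2
            elif fac > 5.0:
                fac = 5.0
            h *= fac
        else:
            h *= 5.0
    return 0


@njit(cache=True)
def _run_extension(y0, params, dt, rtol, atol, advance_last):
    """Integrate through all extension steps.

    Returns (states (n, 4), y_final (4,), status, fail_step); status 0 means
    success, 1 divergence at step ``fail_step``.  When ``advance_last`` is 0
    the state is not propagated past the final recorded sample.
    """
    n = params.shape[0]
    states = np.empty((n, 4))
    y = y0.copy()
    for k_step in range(n):
        for j in range(4):
            states[k_step, j] = y[j]
        if k_step == n - 1 and advance_last == 0:
            break
        bad = _dp45_interval(y, params[k_step], dt, rtol, atol)
        if bad != 0:
            return states, y, 1, k_step + 1
        if y[0] <= 0.0:
            return states, y, 1, k_step + 1
        if (
            np.hypot(y[0], y[1]) > _SPEED_LIMIT
            or abs(y[2]) > _PITCH_RATE_LIMIT
        ):
            return states, y, 1, k_step + 1
    return states, y, 0, n
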