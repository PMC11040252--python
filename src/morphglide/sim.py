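"""Stitched LPV integration of the longitudinal equations of motion.

The glider's longitudinal state X = (U, W, Q, Theta) is advanced along a
scheduled elbow/wrist trajectory.  Each scheduling step (dt = 0.005 s by
default) freezes the current configuration's trim state, stability
derivatives and pitch inertia; the aerodynamic perturbation forces are the
frozen derivative matrix times the perturbation state (u, w, q), while
gravity and the kinematic couplings (-QW, QU) enter nonlinearly:

    Udot = -Q W + (dFx + m g sin(Theta0) - m g sin(Theta)) / m
    Wdot =  Q U + (dFz - m g cos(Theta0) + m g cos(Theta)) / m
    Qdot =  dMy / Iyy
    Thetadot = Q

The gravity-offset terms cancel identically at trim, so every trim state is
an exact fixed point of its own frozen-configuration dynamics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import _fastloop
from .errors import SimulationDivergedError
from .model import (
    AeroModel,
    BirdParameters,
    JointConfig,
    StabilityDerivatives,
    TrimState,
    schedule_aero,
)

__all__ = [
    "BodyState",
    "PerturbationState",
    "PerturbationForces",
    "SimSettings",
    "SimResult",
    "perturbation_forces",
    "eom_rhs",
    "step",
    "simulate",
    "linearize",
]


@dataclass(frozen=True)
class BodyState:
    """Instantaneous longitudinal state in body axes.

    U: body-x speed, m/s (positive out of the beak); W: body-z speed, m/s
    (positive down); Q: pitch rate, rad/s; Theta: pitch angle, rad.
    """

    U: float
    W: float
    Q: float
    Theta: float

    def as_array(self) -> np.ndarray:
        return np.array([self.U, self.W, self.Q, self.Theta])

    @classmethod
    def from_array(cls, y) -> "BodyState":
        return cls(float(y[0]), float(y[1]), float(y[2]), float(y[3]))

    @classmethod
    def from_trim(cls, trim: TrimState) -> "BodyState":
        return cls(trim.U0, trim.W0, trim.Q0, trim.Theta0)


@dataclass(frozen=True)
class PerturbationState:
    """State minus the current configuration's trim (u, w, q).

    Theta does not appear: pitch-angle effects enter through the nonlinear
    gravity terms, not through the aerodynamic derivative matrix.
    """

    u: float
    w: float
    q: float


@dataclass(frozen=True)
class PerturbationForces:
    """Aerodynamic perturbation force/moment (dFx, dFz N; dMy N m)."""

    dFx: float
    dFz: float
    dMy: float


def perturbation_forces(
    delta: PerturbationState, derivs: StabilityDerivatives
) -> PerturbationForces:
    """A_aero times the perturbation state vector."""
    d = derivs
    return PerturbationForces(
        dFx=d.Xu * delta.u + d.Xw * delta.w + d.Xq * delta.q,
        dFz=d.Zu * delta.u + d.Zw * delta.w + d.Zq * delta.q,
        dMy=d.Mu * delta.u + d.Mw * delta.w + d.Mq * delta.q,
    )


def eom_rhs(
    state: BodyState,
    trim: TrimState,
    forces: PerturbationForces,
    params: BirdParameters,
    Iyy: float,
) -> np.ndarray:
    """Time derivative (Udot, Wdot, Qdot, Thetadot) of the body state."""
    if Iyy <= 0:
        raise ValueError("Iyy must be positive")
    m, g = params.mass_kg, params.gravity_m_s2
    sin0, cos0 = math.sin(trim.Theta0), math.cos(trim.Theta0)
    sin_t, cos_t = math.sin(state.Theta), math.cos(state.Theta)
    return np.array(
        [
            -state.Q * state.W + (forces.dFx + m * g * sin0 - m * g * sin_t) / m,
            state.Q * state.U + (forces.dFz - m * g * cos0 + m * g * cos_t) / m,
            forces.dMy / Iyy,
            state.Q,
        ]
    )


@dataclass
class SimSettings:
    """Integration settings.

    dt: scheduling step, s.  rtol/atol: adaptive-integrator tolerances.
    settle_horizon: time held at the final configuration after the
    extension ends, s (long enough for all response metrics to resolve with
    the default synthetic glider).
    """

    dt: float = 0.005
    rtol: float = 1e-8
    atol: float = 1e-10
    settle_horizon: float = 60.0

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.settle_horizon < 0:
            raise ValueError("settle_horizon must be non-negative")


# ---------------------------------------------------------------------------
# Adaptive Dormand-Prince 5(4) integrator
#
# A small embedded Runge-Kutta pair is used for the per-step stitched
# integration; with dt = 0.005 s and smooth dynamics a single accepted step
# almost always suffices, which keeps the scheduling loop cheap.
# ---------------------------------------------------------------------------

_A = (
    (),
    (1 / 5,),
    (3 / 40, 9 / 40),
    (44 / 45, -56 / 15, 32 / 9),
    (19372 / 6561, -25360 / 2187, 64448 / 6561, -212 / 729),
    (9017 / 3168, -355 / 33, 46732 / 5247, 49 / 176, -5103 / 18656),
    (35 / 384, 0.0, 500 / 1113, 125 / 192, -2187 / 6784, 11 / 84),
)
_B5 = (35 / 384, 0.0, 500 / 1113, 125 / 192, -2187 / 6784, 11 / 84, 0.0)
_B4 = (
    5179 / 57600,
    0.0,
    7571 / 16695,
    393 / 640,
    -92097 / 339200,
    187 / 2100,
    1 / 40,
)
_C = (0.0, 1 / 5, 3 / 10, 4 / 5, 8 / 9, 1.0, 1.0)


_MAX_STEP_ATTEMPTS = 10_000

# Divergence guards: a 1 kg glider never sustains these magnitudes; beyond
# them the trajectory is treated as having broken the dynamics model.
_SPEED_LIMIT = 200.0  # m/s airspeed
_PITCH_RATE_LIMIT = 100.0  # rad/s


def _integrate(f, t0: float, y0: np.ndarray, t1: float, rtol: float, atol: float):
    """Adaptive RK45 from t0 to t1; returns y(t1)."""
    t, y = t0, y0
    h = t1 - t0
    span = t1 - t0
    attempts = 0
    while t < t1 - 1e-14 * max(1.0, abs(t1)):
        attempts += 1
        if attempts > _MAX_STEP_ATTEMPTS:
            raise SimulationDivergedError(
                "integrator failed to make progress", t
            )
        h = min(h, t1 - t)
        k0 = f(t, y)
        k1 = f(t + _C[1] * h, y + h * (_A[1][0] * k0))
        k2 = f(t + _C[2] * h, y + h * (_A[2][0] * k0 + _A[2][1] * k1))
        k3 = f(
            t + _C[3] * h,
            y + h * (_A[3][0] * k0 + _A[3][1] * k1 + _A[3][2] * k2),
        )
        k4 = f(
            t + _C[4] * h,
            y
            + h
            * (
                _A[4][0] * k0
                + _A[4][1] * k1
                + _A[4][2] * k2
                + _A[4][3] * k3
            ),
        )
        k5 = f(
            t + h,
            y
            + h
            * (
                _A[5][0] * k0
                + _A[5][1] * k1
                + _A[5][2] * k2
                + _A[5][3] * k3
                + _A[5][4] * k4
            ),
        )
        y5 = y + h * (
            _B5[0] * k0 + _B5[2] * k2 + _B5[3] * k3 + _B5[4] * k4 + _B5[5] * k5
        )
        k6 = f(t + h, y5)
        y4 = y + h * (
            _B4[0] * k0
            + _B4[2] * k2
            + _B4[3] * k3
            + _B4[4] * k4
            + _B4[5] * k5
            + _B4[6] * k6
        )
        scale = atol + rtol * np.maximum(np.abs(y), np.abs(y5))
        err = math.sqrt(float(np.mean(((y5 - y4) / scale) ** 2)))
        if err <= 1.0 or h <= 1e-12 * span:
            t += h
            y = y5
            if not np.all(np.isfinite(y)):
                raise SimulationDivergedError("non-finite state", t)
        factor = 0.9 * (err ** -0.2) if err > 0 else 5.0
        h *= min(5.0, max(0.2, factor))
    return y


def _frozen_rhs(trim, derivs, Iyy, params):
    """RHS closure for one frozen configuration (plain-float hot path).

    ``trim`` is (U0, W0, Q0, Theta0); ``derivs`` is the flattened
    (Xu, Xw, Xq, Zu, Zw, Zq, Mu, Mw, Mq).
    """
    m, g = params.mass_kg, params.gravity_m_s2
    Xu, Xw, Xq = derivs[0] / m, derivs[1] / m, derivs[2] / m
    Zu, Zw, Zq = derivs[3] / m, derivs[4] / m, derivs[5] / m
    Mu, Mw, Mq = derivs[6] / Iyy, derivs[7] / Iyy, derivs[8] / Iyy
    U0, W0, Q0, Theta0 = trim[0], trim[1], trim[2], trim[3]
    gsin0, gcos0 = g * math.sin(Theta0), g * math.cos(Theta0)
    sin, cos = math.sin, math.cos

    def rhs(t, y):
        U, W, Q, Th = y[0], y[1], y[2], y[3]
        u, w, q = U - U0, W - W0, Q - Q0
        return np.array(
            [
                -Q * W + Xu * u + Xw * w + Xq * q + gsin0 - g * sin(Th),
                Q * U + Zu * u + Zw * w + Zq * q - gcos0 + g * cos(Th),
                Mu * u + Mw * w + Mq * q,
                Q,
            ]
        )

    return rhs


def step(
    state: BodyState,
    config: JointConfig,
    model: AeroModel,
    settings: SimSettings | None = None,
) -> BodyState:
    """Advance the state by one scheduling step at a frozen configuration."""
    settings = settings or SimSettings()
    trim, derivs, Iyy = model.frozen_point(config)
    rhs = _frozen_rhs(
        trim.as_array(), derivs.as_matrix().ravel(), Iyy, model.parameters
    )
    y = _integrate(
        rhs, 0.0, state.as_array(), settings.dt, settings.rtol, settings.atol
    )
    out = BodyState.from_array(y)
    if out.U <= 0:
        raise SimulationDivergedError("body-x speed became non-positive", settings.dt)
    return out


@dataclass
class SimResult:
    """Uniform-dt time series of state, scheduled configuration and trim."""

    t: np.ndarray  # (N,)
    states: np.ndarray  # (N, 4): U, W, Q, Theta
    configs: np.ndarray  # (N, 2): elbow_deg, wrist_deg
    trims: np.ndarray  # (N, 4): U0, W0, Q0, Theta0
    dt: float
    extension_steps: int  # number of samples covering the extension phase

    def to_frame(self) -> pd.DataFrame:
        """Tabular export; Theta/Theta0 in degrees, elbow/wrist in degrees,
        SI units elsewhere."""
        return pd.DataFrame(
            {
                "t": self.t,
                "U": self.states[:, 0],
                "W": self.states[:, 1],
                "Q": self.states[:, 2],
                "Theta": np.degrees(self.states[:, 3]),
                "elbow": self.configs[:, 0],
                "wrist": self.configs[:, 1],
                "U0": self.trims[:, 0],
                "W0": self.trims[:, 1],
                "Q0": self.trims[:, 2],
                "Theta0": np.degrees(self.trims[:, 3]),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @property
    def final_trim(self) -> TrimState:
        r = self.trims[-1]
        return TrimState(float(r[0]), float(r[1]), float(r[2]), float(r[3]))


def simulate(
    schedule,
    initial: BodyState | str | None,
    model: AeroModel,
    settings: SimSettings | None = None,
) -> SimResult:
    """Integrate the stitched LPV dynamics along a morphing schedule.

    ``schedule`` provides per-step configurations on a uniform dt grid
    (``MorphSchedule``); after the extension the final configuration is held
    for ``settings.settle_horizon`` seconds.  ``initial`` defaults to the
    trim of the first configuration (the extension starts from a trimmed
    glide).  The hold phase is time-invariant, so it is integrated in one
    adaptive pass sampled on the same dt grid.
    """
    settings = settings or SimSettings()
    configs = np.asarray(schedule.configs, dtype=float)
    if configs.ndim != 2 or configs.shape[1] != 2:
        raise ValueError("schedule.configs must be (N, 2)")
    n_ext = configs.shape[0]
    dt = settings.dt
    if hasattr(schedule, "dt") and not math.isclose(schedule.dt, dt):
        raise ValueError(
            f"schedule dt {schedule.dt} does not match settings dt {dt}"
        )

    n_hold = int(round(settings.settle_horizon / dt))
    n_total = n_ext + n_hold
    t = np.arange(n_total) * dt
    states = np.empty((n_total, 4))
    all_configs = np.empty((n_total, 2))
    trims = np.empty((n_total, 4))

    # Frozen per-step quantities for the whole extension, evaluated in one
    # vectorized pass (identical arithmetic to the scalar trim/derivative
    # path).
    trims_ext, derivs_ext, Iyy_ext = schedule_aero(
        model, configs[:, 0], configs[:, 1]
    )

    if initial is None or (isinstance(initial, str) and initial == "trim"):
        state = BodyState.from_array(trims_ext[0])
    elif isinstance(initial, BodyState):
        state = initial
    else:
        raise ValueError("initial must be a BodyState, 'trim' or None")

    y = state.as_array()
    all_configs[:n_ext] = configs
    trims[:n_ext] = trims_ext
    # Extension phase: per-step frozen trim/derivatives (the LPV stitching).
    if _fastloop.HAVE_NUMBA:
        p = model.parameters
        m, g = p.mass_kg, p.gravity_m_s2
        par = np.empty((n_ext, 15))
        par[:, 0:6] = derivs_ext[:, 0:6] / m
        par[:, 6:9] = derivs_ext[:, 6:9] / Iyy_ext[:, None]
        par[:, 9:12] = trims_ext[:, 0:3]
        par[:, 12] = g * np.sin(trims_ext[:, 3])
        par[:, 13] = g * np.cos(trims_ext[:, 3])
        par[:, 14] = g
        ext_states, y, status, fail_step = _fastloop._run_extension(
            y, par, dt, settings.rtol, settings.atol,
            0 if n_hold == 0 else 1,
        )
        states[:n_ext] = ext_states
        if status != 0:
            raise SimulationDivergedError(
                "extension-phase integration diverged", fail_step * dt
            )
    else:  # pragma: no cover - interpreted fallback
        for k in range(n_ext):
            states[k] = y
            if k == n_ext - 1 and n_hold == 0:
                break
            rhs = _frozen_rhs(
                trims_ext[k], derivs_ext[k], Iyy_ext[k], model.parameters
            )
            y = _integrate(rhs, 0.0, y, dt, settings.rtol, settings.atol)
            if y[0] <= 0:
                raise SimulationDivergedError(
                    "body-x speed became non-positive", (k + 1) * dt
                )
            if (
                np.hypot(y[0], y[1]) > _SPEED_LIMIT
                or abs(y[2]) > _PITCH_RATE_LIMIT
            ):
                raise SimulationDivergedError(
                    "state left the physically plausible envelope",
                    (k + 1) * dt,
                )

    # Hold phase: configuration frozen at the schedule end.  The loop above
    # left ``y`` at time n_ext * dt, which is the first hold sample.
    if n_hold > 0:
        trim, derivs, Iyy = trims_ext[-1], derivs_ext[-1], Iyy_ext[-1]
        all_configs[n_ext:] = configs[-1]
        trims[n_ext:] = trim
        states[n_ext] = y
        if n_hold > 1:
            rhs = _frozen_rhs(trim, derivs, Iyy, model.parameters)
            t_hold = np.arange(1, n_hold) * dt

            def diverged(t, yv):
                if yv[0] <= 0:
                    return 0.0
                if math.hypot(yv[0], yv[1]) > _SPEED_LIMIT:
                    return 0.0
                if abs(yv[2]) > _PITCH_RATE_LIMIT:
                    return 0.0
                return 1.0

            diverged.terminal = True
            # LSODA: the short-period mode is much faster than the phugoid
            # (small pitch inertia), so a stiff-switching method takes far
            # larger steps once that mode has decayed.
            sol = solve_ivp(
                rhs,
                (0.0, float(t_hold[-1])),
                y,
                t_eval=t_hold,
                rtol=settings.rtol,
                atol=settings.atol,
                method="LSODA",
                events=diverged,
            )
            if (
                not sol.success
                or sol.status == 1  # terminated by the divergence event
                or sol.t.size != t_hold.size
                or not np.all(np.isfinite(sol.y))
            ):
                raise SimulationDivergedError(
                    "hold-phase integration diverged",
                    n_ext * dt + float(sol.t[-1] if len(sol.t) else 0.0),
                )
            if np.any(sol.y[0] <= 0):
                bad = int(np.argmax(sol.y[0] <= 0))
                raise SimulationDivergedError(
                    "body-x speed became non-positive",
                    n_ext * dt + float(t_hold[bad]),
                )
            states[n_ext + 1 :] = sol.y.T

    return SimResult(
        t=t,
        states=states,
        configs=all_configs,
        trims=trims,
        dt=dt,
        extension_steps=n_ext,
    )


def linearize(config: JointConfig, model: AeroModel) -> np.ndarray:
    """4x4 Jacobian of the frozen-configuration dynamics about trim.

    Rows are (Udot, Wdot, Qdot, Thetadot) with respect to (U, W, Q, Theta):
    the derivative matrix divided by mass (or Iyy), the kinematic couplings
    evaluated at trim (Q0 = 0 leaves -W0, +U0 in the Q column), and the
    gravity column (-g cos(Theta0), -g sin(Theta0), 0, 0).
    """
    trim, d, Iyy = model.frozen_point(config)
    m = model.parameters.mass_kg
    g = model.parameters.gravity_m_s2
    return np.array(
        [
            [d.Xu / m, d.Xw / m, d.Xq / m - trim.W0, -g * math.cos(trim.Theta0)],
            [d.Zu / m, d.Zw / m, d.Zq / m + trim.U0, -g * math.sin(trim.Theta0)],
            [d.Mu / Iyy, d.Mw / Iyy, d.Mq / Iyy, 0.0],
            [0.0, 0.0, 1.0, 0.0],
        ]
    )
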