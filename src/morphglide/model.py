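"""Quasi-steady aerodynamic model of a morphing-wing glider.

The glider's longitudinal aerodynamics are described by eight coefficient
surfaces (lift, drag, pitching moment and their angle-of-attack / pitch-rate
sensitivities) defined as low-degree bivariate polynomials over elbow-wrist
joint space, plus a pitch moment of inertia surface.  From these the module
computes, for any joint configuration:

* body-axis aerodynamic forces/moment (X, Z, M) for an arbitrary state,
* the steady-glide trim state (U0, W0, Q0 = 0, Theta0),
* the nine dimensional stability derivatives about that trim.

A synthetic "gull" preset is provided whose trim speed is calibrated to
decrease from 33 m/s at the folded start configuration (elbow 120.7 deg,
wrist 105.3 deg) to 17 m/s at the extended end configuration (elbow
155.8 deg, wrist 167.7 deg), emulating the smooth derivative/trim surfaces
of a gliding gull.  Models can also be loaded from a JSON coefficient-table
file (format ``morphglide-aero-1``).

Angles are degrees at every public interface; angle of attack and pitch
angles are radians internally.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
from numpy.polynomial import polynomial as npoly

from .errors import (
    DomainError,
    GeneratorError,
    InvalidStateError,
    ModelFormatError,
    NoGlideTrimError,
    TrimOutOfBandError,
)

__all__ = [
    "JointConfig",
    "BirdParameters",
    "Poly2D",
    "CoefficientSurfaces",
    "InertiaSurfaces",
    "TrimState",
    "StabilityDerivatives",
    "AeroModel",
    "aero_forces",
    "solve_trim",
    "stability_derivatives",
    "make_synthetic_model",
    "load_model",
    "save_model",
]

MODEL_FORMAT = "morphglide-aero-1"

#: Default anchor configurations: folded start and extended end of the wing
#: extension, in (elbow_deg, wrist_deg).
START_CONFIG = (120.7, 105.3)
END_CONFIG = (155.8, 167.7)

_COEFF_NAMES = ("CL0", "CLa", "Cm0", "Cma", "CD0", "k_ind", "CLq", "Cmq")


@dataclass(frozen=True)
class JointConfig:
    """An elbow/wrist angle pair: the scheduled parameter of the LPV model."""

    elbow_deg: float
    wrist_deg: float

    def as_tuple(self) -> tuple[float, float]:
        return (self.elbow_deg, self.wrist_deg)


@dataclass(frozen=True)
class BirdParameters:
    """Scalar physical parameters of the glider (SI units)."""

    mass_kg: float = 1.015
    gravity_m_s2: float = 9.81
    ref_area_m2: float = 0.268
    ref_chord_m: float = 0.286
    air_density_kg_m3: float = 1.225

    def __post_init__(self):
        for name in (
            "mass_kg",
            "gravity_m_s2",
            "ref_area_m2",
            "ref_chord_m",
            "air_density_kg_m3",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


class Poly2D:
    """Bivariate polynomial in (elbow_deg, wrist_deg).

    Wraps a coefficient matrix ``c`` with ``c[i, j]`` multiplying
    ``elbow**i * wrist**j`` (degree <= 2 in each variable by default).
    """

    def __init__(self, coeffs):
        c = np.atleast_2d(np.asarray(coeffs, dtype=float))
        if c.ndim != 2:
            raise ValueError("coefficient array must be 2-D")
        self.coeffs = c

    def __call__(self, elbow_deg, wrist_deg):
        return npoly.polyval2d(elbow_deg, wrist_deg, self.coeffs)

    @classmethod
    def constant(cls, value: float) -> "Poly2D":
        return cls([[float(value)]])

    def to_monomials(self) -> dict[str, float]:
        """Serialize to a ``{"e^i w^j": coeff}`` map (nonzero terms only)."""
        out = {}
        for i in range(self.coeffs.shape[0]):
            for j in range(self.coeffs.shape[1]):
                if self.coeffs[i, j] != 0.0:
                    out[f"e^{i} w^{j}"] = float(self.coeffs[i, j])
        if not out:
            out["e^0 w^0"] = 0.0
        return out

    _KEY_RE = re.compile(r"^e\^(\d+) w\^(\d+)$")

    @classmethod
    def from_monomials(cls, mono: Mapping[str, float]) -> "Poly2D":
        terms = {}
        for key, val in mono.items():
            m = cls._KEY_RE.match(key)
            if m is None:
                raise ModelFormatError(f"bad monomial key {key!r}")
            terms[(int(m.group(1)), int(m.group(2)))] = float(val)
        deg_e = max(i for i, _ in terms)
        deg_w = max(j for _, j in terms)
        c = np.zeros((deg_e + 1, deg_w + 1))
        for (i, j), val in terms.items():
            c[i, j] = val
        return cls(c)

    def __eq__(self, other):
        if not isinstance(other, Poly2D):
            return NotImplemented
        a, b = self.coeffs, other.coeffs
        shape = (max(a.shape[0], b.shape[0]), max(a.shape[1], b.shape[1]))
        pa = np.zeros(shape)
        pa[: a.shape[0], : a.shape[1]] = a
        pb = np.zeros(shape)
        pb[: b.shape[0], : b.shape[1]] = b
        return bool(np.array_equal(pa, pb))


@dataclass
class CoefficientSurfaces:
    """The eight aerodynamic coefficient surfaces over joint space.

    ``CLa``/``Cma`` are per radian of angle of attack; ``CLq``/``Cmq`` are
    per unit of nondimensional pitch rate Q*c/(2V).
    """

    CL0: Poly2D
    CLa: Poly2D
    Cm0: Poly2D
    Cma: Poly2D
    CD0: Poly2D
    k_ind: Poly2D
    CLq: Poly2D
    Cmq: Poly2D

    def evaluate(self, elbow_deg, wrist_deg) -> dict[str, np.ndarray]:
        return {
            name: getattr(self, name)(elbow_deg, wrist_deg)
            for name in _COEFF_NAMES
        }


@dataclass
class InertiaSurfaces:
    """Pitch moment of inertia (kg m^2) and optional CG offsets (m)."""

    Iyy: Poly2D
    cg_x: Poly2D | None = None
    cg_z: Poly2D | None = None


@dataclass(frozen=True)
class TrimState:
    """Steady-glide equilibrium state for one joint configuration."""

    U0: float
    W0: float
    Q0: float
    Theta0: float

    def as_array(self) -> np.ndarray:
        return np.array([self.U0, self.W0, self.Q0, self.Theta0])

    @property
    def airspeed(self) -> float:
        return math.hypot(self.U0, self.W0)


@dataclass(frozen=True)
class StabilityDerivatives:
    """The nine dimensional force/moment derivatives about trim.

    X*, Z* in N per (m/s) or N per (rad/s); M* in N m per (m/s) or
    N m per (rad/s).
    """

    Xu: float
    Xw: float
    Xq: float
    Zu: float
    Zw: float
    Zq: float
    Mu: float
    Mw: float
    Mq: float

    def as_matrix(self) -> np.ndarray:
        return np.array(
            [
                [self.Xu, self.Xw, self.Xq],
                [self.Zu, self.Zw, self.Zq],
                [self.Mu, self.Mw, self.Mq],
            ]
        )


@dataclass
class AeroModel:
    """Container tying parameters, coefficient surfaces, inertia and the
    joint-angle validity region together."""

    parameters: BirdParameters
    surfaces: CoefficientSurfaces
    inertia: InertiaSurfaces
    elbow_range: tuple[float, float] = (105.0, 160.0)
    wrist_range: tuple[float, float] = (105.0, 179.0)
    alpha_band_deg: float = 15.0
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def in_validity(self, config: JointConfig) -> bool:
        e, w = config.elbow_deg, config.wrist_deg
        return (
            self.elbow_range[0] <= e <= self.elbow_range[1]
            and self.wrist_range[0] <= w <= self.wrist_range[1]
        )

    def require_valid(self, config: JointConfig) -> None:
        if not self.in_validity(config):
            raise DomainError(
                f"configuration (elbow {config.elbow_deg:.2f} deg, wrist "
                f"{config.wrist_deg:.2f} deg) outside validity region "
                f"elbow {self.elbow_range}, wrist {self.wrist_range}"
            )

    def Iyy(self, config: JointConfig) -> float:
        return float(self.inertia.Iyy(config.elbow_deg, config.wrist_deg))

    # -- cached per-configuration trim/derivative/inertia bundle ----------
    def frozen_point(self, config: JointConfig):
        """(TrimState, StabilityDerivatives, Iyy) for ``config``, memoized.

        The LPV simulation freezes these quantities for one scheduling step;
        caching makes holding a configuration essentially free.
        """
        key = (config.elbow_deg, config.wrist_deg)
        hit = self._cache.get(key)
        if hit is None:
            trim = solve_trim(config, self)
            derivs = stability_derivatives(config, self, trim=trim)
            if len(self._cache) > 200_000:
                self._cache.clear()
            hit = (trim, derivs, self.Iyy(config))
            self._cache[key] = hit
        return hit


# ---------------------------------------------------------------------------
# Force model
# ---------------------------------------------------------------------------


def _forces_from_coeffs(c: Mapping[str, float], U, W, Q, p: BirdParameters):
    """Body-axis (X, Z, M) from already-evaluated coefficients.

    Vectorized over the state arguments.
    """
    alpha = np.arctan2(W, U)
    V = np.hypot(U, W)
    qbar_S = 0.5 * p.air_density_kg_m3 * V**2 * p.ref_area_m2
    qhat = Q * p.ref_chord_m / (2.0 * V)
    CL = c["CL0"] + c["CLa"] * alpha + c["CLq"] * qhat
    CD = c["CD0"] + c["k_ind"] * CL**2
    Cm = c["Cm0"] + c["Cma"] * alpha + c["Cmq"] * qhat
    sa, ca = np.sin(alpha), np.cos(alpha)
    X = qbar_S * (CL * sa - CD * ca)
    Z = -qbar_S * (CL * ca + CD * sa)
    M = qbar_S * p.ref_chord_m * Cm
    return X, Z, M


def aero_forces(state, config: JointConfig, model: AeroModel):
    """Body-axis aerodynamic force/moment triple (X, Z, M) in N / N m.

    ``state`` is anything exposing U, W, Q (m/s, m/s, rad/s); lift and drag
    act in wind axes and are rotated into body axes through the angle of
    attack alpha = atan2(W, U).
    """
    U, W, Q = state.U, state.W, state.Q
    if not np.all(np.asarray(U) > 0):
        raise InvalidStateError("body-x speed U must be positive")
    model.require_valid(config)
    c = model.surfaces.evaluate(config.elbow_deg, config.wrist_deg)
    return _forces_from_coeffs(c, U, W, Q, model.parameters)


# ---------------------------------------------------------------------------
# Trim
# ---------------------------------------------------------------------------


def _trim_from_coeffs(c: Mapping[str, float], p: BirdParameters):
    """Vectorized steady-glide trim from evaluated coefficients.

    Returns (U0, W0, Q0, Theta0, alpha, gamma, CL, CD) arrays.  With the
    quasi-steady coefficient model the zero-moment condition
    Cm0 + Cma * alpha = 0 is linear in alpha, so the trim angle of attack
    is available in closed form; speed follows from the wind-axis force
    balance L = m g cos(gamma), D = -m g sin(gamma).
    """
    alpha = -np.asarray(c["Cm0"]) / np.asarray(c["Cma"])
    CL = c["CL0"] + c["CLa"] * alpha
    CD = c["CD0"] + c["k_ind"] * CL**2
    gamma = np.arctan2(-CD, CL)
    cosg = np.cos(gamma)
    V2 = (
        2.0
        * p.mass_kg
        * p.gravity_m_s2
        * cosg
        / (p.air_density_kg_m3 * p.ref_area_m2 * np.where(CL > 0, CL, np.nan))
    )
    V = np.sqrt(V2)
    U0 = V * np.cos(alpha)
    W0 = V * np.sin(alpha)
    Theta0 = alpha + gamma
    return U0, W0, np.zeros_like(U0), Theta0, alpha, gamma, CL, CD


def solve_trim(config: JointConfig, model: AeroModel) -> TrimState:
    """Steady-glide equilibrium (zero pitch rate) for a joint configuration.

    The glide-path angle gamma satisfies tan(gamma) = -CD/CL (negative:
    descending), the pitch angle is Theta0 = alpha + gamma, and the speed
    comes from weight support, V = sqrt(2 m g cos(gamma) / (rho S CL)).

    Raises
    ------
    NoGlideTrimError
        if the trim lift coefficient is non-positive.
    TrimOutOfBandError
        if the trim angle of attack leaves the linear-aerodynamics band
        (``model.alpha_band_deg``, default +/-15 deg).
    """
    model.require_valid(config)
    c = model.surfaces.evaluate(config.elbow_deg, config.wrist_deg)
    U0, W0, Q0, Theta0, alpha, gamma, CL, _ = _trim_from_coeffs(
        c, model.parameters
    )
    alpha = float(alpha)
    if abs(alpha) > math.radians(model.alpha_band_deg):
        raise TrimOutOfBandError(
            f"trim alpha {math.degrees(alpha):.2f} deg outside "
            f"+/-{model.alpha_band_deg} deg band"
        )
    if not (CL > 0):
        raise NoGlideTrimError(
            f"trim lift coefficient {float(CL):.4f} <= 0: no gliding "
            "equilibrium"
        )
    return TrimState(float(U0), float(W0), float(Q0), float(Theta0))


def trim_residual(trim: TrimState, config: JointConfig, model: AeroModel):
    """Residual of the full nonlinear EOM at a candidate trim state.

    Returns (Udot, Wdot, Qdot, Thetadot) from the absolute force balance;
    a genuine trim gives magnitudes at numerical round-off.
    """
    from types import SimpleNamespace

    p = model.parameters
    state = SimpleNamespace(U=trim.U0, W=trim.W0, Q=trim.Q0)
    X, Z, M = aero_forces(state, config, model)
    g, m = p.gravity_m_s2, p.mass_kg
    Udot = -trim.Q0 * trim.W0 + (X - m * g * math.sin(trim.Theta0)) / m
    Wdot = trim.Q0 * trim.U0 + (Z + m * g * math.cos(trim.Theta0)) / m
    Qdot = M / model.Iyy(config)
    return np.array([Udot, Wdot, Qdot, trim.Q0])


# ---------------------------------------------------------------------------
# Stability derivatives
# ---------------------------------------------------------------------------


def stability_derivatives(
    config: JointConfig, model: AeroModel, trim: TrimState | None = None
) -> StabilityDerivatives:
    """Nine body-axis force/moment derivatives about the configuration trim.

    Central finite differences of the force model with respect to the u, w
    and q perturbations, step ``1e-6 * max(1, |U0|)``.
    """
    if trim is None:
        trim = solve_trim(config, model)
    model.require_valid(config)
    c = model.surfaces.evaluate(config.elbow_deg, config.wrist_deg)
    p = model.parameters
    h = 1e-6 * max(1.0, abs(trim.U0))
    U0, W0, Q0 = trim.U0, trim.W0, trim.Q0

    def fd(dU=0.0, dW=0.0, dQ=0.0):
        Xp, Zp, Mp = _forces_from_coeffs(c, U0 + dU, W0 + dW, Q0 + dQ, p)
        Xm, Zm, Mm = _forces_from_coeffs(c, U0 - dU, W0 - dW, Q0 - dQ, p)
        return (Xp - Xm) / (2 * h), (Zp - Zm) / (2 * h), (Mp - Mm) / (2 * h)

    Xu, Zu, Mu = fd(dU=h)
    Xw, Zw, Mw = fd(dW=h)
    Xq, Zq, Mq = fd(dQ=h)
    out = StabilityDerivatives(
        float(Xu), float(Xw), float(Xq),
        float(Zu), float(Zw), float(Zq),
        float(Mu), float(Mw), float(Mq),
    )
    if not np.all(np.isfinite(out.as_matrix())):
        raise InvalidStateError("non-finite stability derivative")
    return out


def schedule_aero(model: AeroModel, elbow_deg, wrist_deg):
    """Vectorized trim / derivative / inertia evaluation for a whole
    schedule of configurations.

    Returns ``(trims (N, 4), derivs (N, 9), Iyy (N,))`` with the same
    arithmetic as :func:`solve_trim` and :func:`stability_derivatives`
    applied elementwise; the simulation uses this to precompute the frozen
    per-step quantities cheaply.

    Raises the same errors as the scalar path if any configuration lies
    outside the validity region, loses trim, or leaves the alpha band.
    """
    e = np.asarray(elbow_deg, dtype=float)
    w = np.asarray(wrist_deg, dtype=float)
    if (
        np.any(e < model.elbow_range[0])
        or np.any(e > model.elbow_range[1])
        or np.any(w < model.wrist_range[0])
        or np.any(w > model.wrist_range[1])
    ):
        raise DomainError("schedule leaves the model validity region")
    c = model.surfaces.evaluate(e, w)
    p = model.parameters
    U0, W0, Q0, Theta0, alpha, _, CL, _ = _trim_from_coeffs(c, p)
    if np.any(np.abs(alpha) > math.radians(model.alpha_band_deg)):
        raise TrimOutOfBandError("trim alpha leaves the linear band")
    if not np.all(CL > 0):
        raise NoGlideTrimError("non-positive trim lift along the schedule")
    trims = np.stack([U0, W0, Q0, Theta0], axis=-1)

    h = 1e-6 * np.maximum(1.0, np.abs(U0))
    cols = []
    for dU, dW, dQ in ((h, 0.0, 0.0), (0.0, h, 0.0), (0.0, 0.0, h)):
        Xp, Zp, Mp = _forces_from_coeffs(c, U0 + dU, W0 + dW, Q0 + dQ, p)
        Xm, Zm, Mm = _forces_from_coeffs(c, U0 - dU, W0 - dW, Q0 - dQ, p)
        cols.append(((Xp - Xm), (Zp - Zm), (Mp - Mm)))
    inv = 1.0 / (2.0 * h)
    derivs = np.stack(
        [
            cols[0][0] * inv, cols[1][0] * inv, cols[2][0] * inv,
            cols[0][1] * inv, cols[1][1] * inv, cols[2][1] * inv,
            cols[0][2] * inv, cols[1][2] * inv, cols[2][2] * inv,
        ],
        axis=-1,
    )
    Iyy = np.broadcast_to(
        np.asarray(model.inertia.Iyy(e, w), dtype=float), U0.shape
    )
    if not (np.all(np.isfinite(trims)) and np.all(np.isfinite(derivs))):
        raise InvalidStateError("non-finite trim or derivative in schedule")
    return trims, derivs, np.asarray(Iyy)


# ---------------------------------------------------------------------------
# Synthetic model generator
# ---------------------------------------------------------------------------

PRESETS = ("gull",)


def _extension_coordinate(start, end):
    """Poly2D for the normalized projection onto the start-to-end chord.

    t = 0 at the start anchor, t = 1 at the end anchor, linear in (e, w).
    """
    e0, w0 = start
    de = end[0] - e0
    dw = end[1] - w0
    L2 = de * de + dw * dw
    c = np.zeros((2, 2))
    c[0, 0] = (-e0 * de - w0 * dw) / L2
    c[1, 0] = de / L2
    c[0, 1] = dw / L2
    return Poly2D(c)


def make_synthetic_model(
    seed: int = 0,
    preset: str = "gull",
    trim_speed_targets: tuple[float, float] = (33.0, 17.0),
    anchors: tuple[tuple[float, float], tuple[float, float]] = (
        START_CONFIG,
        END_CONFIG,
    ),
    parameters: BirdParameters | None = None,
) -> AeroModel:
    """Build a calibrated synthetic quasi-steady glider model.

    The preset defines smooth, statically stable coefficient surfaces whose
    trim speed decreases monotonically along the extension from
    ``trim_speed_targets[0]`` at the first anchor configuration to
    ``trim_speed_targets[1]`` at the second (each within 1e-3 m/s after
    calibration).  The pitch moment of inertia spans 0.0047-0.0086 kg m^2
    across the validity region.  ``seed`` applies small deterministic
    perturbations to the non-calibrated coefficients, so distinct seeds give
    distinct but equally well-behaved gliders.

    Raises ``GeneratorError`` if the trim-speed calibration cannot converge.
    """
    if preset not in PRESETS:
        raise GeneratorError(
            f"unknown preset {preset!r}; available: {PRESETS}"
        )
    p = parameters or BirdParameters()
    rng = np.random.default_rng(seed)
    j = rng.uniform(-1.0, 1.0, size=8)

    start, end = anchors
    t_surf = _extension_coordinate(start, end)
    t_c = t_surf.coeffs  # (2, 2) linear coefficient matrix

    # Base (seed-perturbed) aerodynamic constants.  Values are chosen to
    # give a statically and dynamically stable glider: positive lift slope,
    # negative moment slope, pitch damping, and enough profile drag that the
    # phugoid decays within the post-extension hold.
    CLa = 5.0 * (1.0 + 0.05 * j[0])
    Cma = -0.5 * (1.0 + 0.10 * j[1])
    k_ind = 0.050 * (1.0 + 0.10 * j[3])
    CLq = 3.0 * (1.0 + 0.10 * j[4])
    Cmq = -12.0 * (1.0 + 0.10 * j[5])
    # Profile drag grows with extension: the folded high-speed dive is
    # clean (else a 33 m/s steady glide would demand a near-vertical dive),
    # while the extended wing is draggy, which damps the phugoid strongly
    # at the slow-glide end where the response settles.
    CD0_start = 0.030 * (1.0 + 0.10 * j[2])
    CD0_end = 0.110 * (1.0 + 0.10 * j[2])
    CD0_c = (CD0_end - CD0_start) * t_c
    CD0_c[0, 0] += CD0_start

    # Trim angle of attack varies linearly along the extension coordinate,
    # ~1 deg in the fast dive to ~3 deg in the slow glide.
    a_start = math.radians(1.0 * (1.0 + 0.10 * j[6]))
    a_end = math.radians(3.0 * (1.0 + 0.10 * j[7]))
    alpha_c = np.zeros((2, 2))
    alpha_c[0, 0] = a_start
    alpha_c += (a_end - a_start) * t_c
    # Cm0 = -Cma * alpha_trim enforces Cm(alpha_trim) = 0 exactly.
    Cm0_c = -Cma * alpha_c

    def build(CL_s: float, CL_e: float) -> AeroModel:
        # CL at trim interpolates linearly in the extension coordinate;
        # CL0 absorbs the alpha contribution: CL0 = CL_trim - CLa * alpha.
        CLt_c = (CL_e - CL_s) * t_c
        CLt_c[0, 0] += CL_s
        CL0_c = CLt_c - CLa * alpha_c
        surfaces = CoefficientSurfaces(
            CL0=Poly2D(CL0_c),
            CLa=Poly2D.constant(CLa),
            Cm0=Poly2D(Cm0_c),
            Cma=Poly2D.constant(Cma),
            CD0=Poly2D(CD0_c),
            k_ind=Poly2D.constant(k_ind),
            CLq=Poly2D.constant(CLq),
            Cmq=Poly2D.constant(Cmq),
        )
        # Iyy spans the printed gull range across the validity region.
        iyy_c = np.zeros((2, 2))
        iyy_c[0, 0] = 0.0047 + 0.0039 * (-105.0 / 55.0 - 105.0 / 74.0) / 2.0
        iyy_c[1, 0] = 0.0039 / (2.0 * 55.0)
        iyy_c[0, 1] = 0.0039 / (2.0 * 74.0)
        inertia = InertiaSurfaces(
            Iyy=Poly2D(iyy_c),
            cg_x=Poly2D([[0.0, 0.0], [0.0, 0.0], [0.0, 0.0]]),
            cg_z=Poly2D.constant(0.0),
        )
        return AeroModel(parameters=p, surfaces=surfaces, inertia=inertia)

    # Fixed-point calibration of the anchor trim lift coefficients: the
    # glide-path angle couples weakly into speed, so CL <- CL (V/V*)^2
    # converges in a handful of iterations.
    V_s_target, V_e_target = trim_speed_targets
    q = p.air_density_kg_m3 * p.ref_area_m2
    CL_s = 2 * p.mass_kg * p.gravity_m_s2 / (q * V_s_target**2)
    CL_e = 2 * p.mass_kg * p.gravity_m_s2 / (q * V_e_target**2)
    model = build(CL_s, CL_e)
    for _ in range(50):
        try:
            V_s = solve_trim(JointConfig(*start), model).airspeed
            V_e = solve_trim(JointConfig(*end), model).airspeed
        except MorphGlideTrimErrors as exc:  # pragma: no cover - defensive
            raise GeneratorError(f"calibration hit invalid trim: {exc}")
        if abs(V_s - V_s_target) < 1e-6 and abs(V_e - V_e_target) < 1e-6:
            break
        CL_s *= (V_s / V_s_target) ** 2
        CL_e *= (V_e / V_e_target) ** 2
        if CL_s <= 0 or CL_e <= 0:
            raise GeneratorError("calibration drove trim lift non-positive")
        model = build(CL_s, CL_e)
    else:
        raise GeneratorError(
            "trim-speed calibration did not converge for targets "
            f"{trim_speed_targets}"
        )
    return model


MorphGlideTrimErrors = (NoGlideTrimError, TrimOutOfBandError, DomainError)


# ---------------------------------------------------------------------------
# Serialization (morphglide-aero-1 JSON)
# ---------------------------------------------------------------------------


def _model_to_dict(model: AeroModel) -> dict:
    p = model.parameters
    d = {
        "format": MODEL_FORMAT,
        "parameters": {
            "mass_kg": p.mass_kg,
            "gravity_m_s2": p.gravity_m_s2,
            "ref_area_m2": p.ref_area_m2,
            "ref_chord_m": p.ref_chord_m,
            "air_density_kg_m3": p.air_density_kg_m3,
        },
        "surfaces": {
            name: getattr(model.surfaces, name).to_monomials()
            for name in _COEFF_NAMES
        },
        "inertia": {"Iyy": model.inertia.Iyy.to_monomials()},
        "validity": {
            "elbow_deg": list(model.elbow_range),
            "wrist_deg": list(model.wrist_range),
            "alpha_band_deg": model.alpha_band_deg,
        },
    }
    if model.inertia.cg_x is not None:
        d["inertia"]["cg_x"] = model.inertia.cg_x.to_monomials()
    if model.inertia.cg_z is not None:
        d["inertia"]["cg_z"] = model.inertia.cg_z.to_monomials()
    return d


def save_model(model: AeroModel, path) -> None:
    """Write a model to a ``morphglide-aero-1`` JSON file.

    Keys are sorted, so identical models serialize byte-identically.
    """
    Path(path).write_text(
        json.dumps(_model_to_dict(model), sort_keys=True, indent=1) + "\n"
    )


def load_model(path) -> AeroModel:
    """Load a model from a ``morphglide-aero-1`` JSON file."""
    try:
        raw = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ModelFormatError(f"not valid JSON: {exc}") from exc
    if not isinstance(raw, dict):
        raise ModelFormatError("top level must be a JSON object")
    if raw.get("format") != MODEL_FORMAT:
        raise ModelFormatError(
            f"field 'format' must be {MODEL_FORMAT!r}, got "
            f"{raw.get('format')!r}"
        )
    for block in ("parameters", "surfaces", "inertia", "validity"):
        if block not in raw:
            raise ModelFormatError(f"missing block {block!r}")
    try:
        params = BirdParameters(**raw["parameters"])
    except (TypeError, ValueError) as exc:
        raise ModelFormatError(f"bad 'parameters' block: {exc}") from exc
    surf_kwargs = {}
    for name in _COEFF_NAMES:
        if name not in raw["surfaces"]:
            raise ModelFormatError(f"missing surface {name!r}")
        surf_kwargs[name] = Poly2D.from_monomials(raw["surfaces"][name])
    if "Iyy" not in raw["inertia"]:
        raise ModelFormatError("missing inertia surface 'Iyy'")
    inertia = InertiaSurfaces(
        Iyy=Poly2D.from_monomials(raw["inertia"]["Iyy"]),
        cg_x=(
            Poly2D.from_monomials(raw["inertia"]["cg_x"])
            if "cg_x" in raw["inertia"]
            else None
        ),
        cg_z=(
            Poly2D.from_monomials(raw["inertia"]["cg_z"])
            if "cg_z" in raw["inertia"]
            else None
        ),
    )
    validity = raw["validity"]
    try:
        elbow_range = tuple(float(x) for x in validity["elbow_deg"])
        wrist_range = tuple(float(x) for x in validity["wrist_deg"])
    except (KeyError, TypeError, ValueError) as exc:
        raise ModelFormatError(f"bad 'validity' block: {exc}") from exc
    return AeroModel(
        parameters=params,
        surfaces=CoefficientSurfaces(**surf_kwargs),
        inertia=inertia,
        elbow_range=elbow_range,
        wrist_range=wrist_range,
        alpha_band_deg=float(validity.get("alpha_band_deg", 15.0)),
    )
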