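"""Extension trajectories in elbow-wrist joint space and their scheduling.

A trajectory maps elbow angle to wrist angle, either as a cubic
``w(e) = c0 + c1 e + c2 e^2 + c3 e^3`` with fixed endpoints or as a
tabulated point list.  ``arc_length_schedule`` converts a trajectory into a
constant-speed time schedule: the joint-space arc length (Euclidean in
degrees, sqrt(d_elbow^2 + d_wrist^2)) grows at exactly the extension rate.
``reduced_frequency`` evaluates the quasi-steady check for one complete
extend-and-fold cycle.

All angles are degrees.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.interpolate import PchipInterpolator

from .errors import DegenerateEndpointsError, ParameterError
from .model import END_CONFIG, START_CONFIG, JointConfig

__all__ = [
    "CubicTrajectory",
    "TabulatedTrajectory",
    "MorphSchedule",
    "solve_endpoint_coeffs",
    "arc_length_schedule",
    "reduced_frequency",
    "default_trajectories",
    "load_trajectory",
    "save_trajectory",
]

#: Number of elbow samples used to discretize a path for arc-length
#: computations; chosen so the per-step schedule speed error stays below 1%.
ARC_SAMPLES = 2000


@dataclass(frozen=True)
class CubicTrajectory:
    """Wrist-vs-elbow cubic over a monotone elbow interval."""

    c0: float
    c1: float
    c2: float
    c3: float
    elbow_start: float
    elbow_end: float

    def __post_init__(self):
        if not self.elbow_start < self.elbow_end:
            raise DegenerateEndpointsError(
                "elbow_start must be strictly less than elbow_end"
            )

    @property
    def coefficients(self) -> tuple[float, float, float, float]:
        return (self.c0, self.c1, self.c2, self.c3)

    def wrist(self, elbow_deg):
        e = np.asarray(elbow_deg, dtype=float)
        out = self.c0 + e * (self.c1 + e * (self.c2 + e * self.c3))
        return out if out.ndim else float(out)

    @property
    def start(self) -> JointConfig:
        return JointConfig(self.elbow_start, self.wrist(self.elbow_start))

    @property
    def end(self) -> JointConfig:
        return JointConfig(self.elbow_end, self.wrist(self.elbow_end))


@dataclass(frozen=True)
class TabulatedTrajectory:
    """Ordered (elbow, wrist) samples with strictly increasing elbow.

    Wrist is interpolated piecewise-linearly between samples.
    """

    points: np.ndarray  # (n, 2)

    def __post_init__(self):
        pts = np.atleast_2d(np.asarray(self.points, dtype=float))
        if pts.shape[0] < 2 or pts.shape[1] != 2:
            raise ParameterError("need at least 2 (elbow, wrist) points")
        if not np.all(np.diff(pts[:, 0]) > 0):
            raise ParameterError("elbow angles must be strictly increasing")
        object.__setattr__(self, "points", pts)

    def wrist(self, elbow_deg):
        out = np.interp(elbow_deg, self.points[:, 0], self.points[:, 1])
        return out if np.ndim(out) else float(out)

    @property
    def elbow_start(self) -> float:
        return float(self.points[0, 0])

    @property
    def elbow_end(self) -> float:
        return float(self.points[-1, 0])

    @property
    def start(self) -> JointConfig:
        return JointConfig(*self.points[0])

    @property
    def end(self) -> JointConfig:
        return JointConfig(*self.points[-1])


@dataclass
class MorphSchedule:
    """Constant-speed time schedule of joint configurations.

    ``configs[k]`` is the (elbow, wrist) pair at time ``k * dt``.  The
    joint-space speed between consecutive samples equals ``rate`` to within
    1%, except for the final partial step, which lands exactly on the
    trajectory end point.
    """

    configs: np.ndarray  # (M, 2)
    dt: float
    rate: float  # deg/s along the path
    path_length: float  # deg

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.configs.shape[0]) * self.dt

    @property
    def duration(self) -> float:
        """Exact extension duration path_length / rate (s)."""
        return self.path_length / self.rate

    def __len__(self) -> int:
        return self.configs.shape[0]


def solve_endpoint_coeffs(
    c2: float,
    c3: float,
    start: JointConfig = JointConfig(*START_CONFIG),
    end: JointConfig = JointConfig(*END_CONFIG),
) -> tuple[float, float]:
    """(c0, c1) making the cubic pass exactly through both endpoints.

    With c2 and c3 given, the endpoint conditions are a 2x2 linear system
    in (c0, c1):

        c0 + c1 e_s = w_s - c2 e_s^2 - c3 e_s^3
        c0 + c1 e_e = w_e - c2 e_e^2 - c3 e_e^3
    """
    es, ee = start.elbow_deg, end.elbow_deg
    if es == ee:
        raise DegenerateEndpointsError("endpoints share the same elbow angle")
    rs = start.wrist_deg - c2 * es**2 - c3 * es**3
    re = end.wrist_deg - c2 * ee**2 - c3 * ee**3
    c1 = (re - rs) / (ee - es)
    c0 = rs - c1 * es
    # One compensated polish: with large |c2|, |c3| the monomial evaluation
    # at the endpoints loses ~1e-9 deg to cancellation; correcting (c0, c1)
    # by the floating-point endpoint residuals restores it.
    fa = c0 + es * (c1 + es * (c2 + es * c3))
    fb = c0 + ee * (c1 + ee * (c2 + ee * c3))
    dc1 = ((end.wrist_deg - fb) - (start.wrist_deg - fa)) / (ee - es)
    dc0 = (start.wrist_deg - fa) - dc1 * es
    return (c0 + dc0, c1 + dc1)


def _path_samples(traj, n: int = ARC_SAMPLES, refine: int = 4):
    """Dense (elbow, wrist) samples and cumulative arc length along a path.

    The chord-length accumulation runs on a grid ``refine`` times finer
    than the ``n`` nominal stations, keeping the discretization error of
    the total length well below 1e-6 deg for smooth cubics.  Tabulated
    break points are merged into the grid so piecewise linear paths are
    represented exactly.
    """
    e = np.linspace(traj.elbow_start, traj.elbow_end, (n - 1) * refine + 1)
    if isinstance(traj, TabulatedTrajectory):
        e = np.union1d(e, traj.points[:, 0])
    w = np.asarray(traj.wrist(e), dtype=float)
    seg = np.hypot(np.diff(e), np.diff(w))
    s = np.concatenate([[0.0], np.cumsum(seg)])
    return e, w, s


def arc_length_schedule(
    traj, rate: float, dt: float = 0.005, n_samples: int = ARC_SAMPLES
) -> MorphSchedule:
    """Discretize a trajectory into a constant-speed schedule.

    The path is sampled at ``n_samples`` elbow stations, the cumulative
    chord length is accumulated, and the mapping is inverted by monotone
    (PCHIP) interpolation so that arc length grows at exactly ``rate * t``.
    The final sample is clamped to the end configuration even when the last
    step is shorter than ``rate * dt``.
    """
    if rate <= 0:
        raise ParameterError("extension rate must be positive")
    if dt <= 0:
        raise ParameterError("dt must be positive")
    e_dense, _, s_dense = _path_samples(traj, n_samples)
    length = float(s_dense[-1])
    elbow_of_s = PchipInterpolator(s_dense, e_dense)
    duration = length / rate
    n_steps = max(1, math.ceil(duration / dt - 1e-9))
    t = np.arange(n_steps + 1) * dt
    s = np.minimum(rate * t, length)
    e = np.asarray(elbow_of_s(s), dtype=float)
    w = np.asarray(traj.wrist(e), dtype=float)
    configs = np.column_stack([e, w])
    configs[0] = [traj.elbow_start, traj.start.wrist_deg]
    configs[-1] = [traj.elbow_end, traj.end.wrist_deg]
    return MorphSchedule(configs=configs, dt=dt, rate=rate, path_length=length)


def reduced_frequency(
    path_length: float, rate: float, c_max: float, U_min: float
) -> float:
    """Quasi-steady reduced frequency of one extend-and-fold cycle.

    One-way time is ``path_length / rate``; a full cycle is twice that, so
    the cycle frequency is f = rate / (2 * path_length) and

        k = f * c_max / (2 * U_min).

    Values well below ~7.5e-4 justify the quasi-steady aerodynamics.
    """
    for name, val in (
        ("path_length", path_length),
        ("rate", rate),
        ("c_max", c_max),
        ("U_min", U_min),
    ):
        if val <= 0:
            raise ParameterError(f"{name} must be positive")
    one_way = path_length / rate
    f = 1.0 / (2.0 * one_way)
    return f * c_max / (2.0 * U_min)


#: Curvature coefficients of the skeletal-linkage extension path.  The
#: packaged linkage trajectory is a synthetic reconstruction: these two
#: shape coefficients with (c0, c1) re-solved so the path passes exactly
#: through the start/end configurations.
_LINKAGE_C2 = 0.222
_LINKAGE_C3 = -0.0005


def default_trajectories(
    start: JointConfig = JointConfig(*START_CONFIG),
    end: JointConfig = JointConfig(*END_CONFIG),
    n_linkage_points: int = 41,
) -> dict:
    """The two named baseline trajectories.

    ``linear``: the straight joint-space segment between the start and end
    configurations (c2 = c3 = 0).

    ``linkage``: a synthetic reconstruction of the coupled elbow-wrist path
    traced when the wing skeletal linkage is driven at the wrist alone,
    tabulated at ``n_linkage_points`` stations.  The published curvature
    shape is retained while the endpoints are enforced exactly; it deviates
    from the linear path by a few degrees of wrist angle at mid-extension.
    """
    c0, c1 = solve_endpoint_coeffs(0.0, 0.0, start, end)
    linear = CubicTrajectory(c0, c1, 0.0, 0.0, start.elbow_deg, end.elbow_deg)
    lc0, lc1 = solve_endpoint_coeffs(_LINKAGE_C2, _LINKAGE_C3, start, end)
    linkage_cubic = CubicTrajectory(
        lc0, lc1, _LINKAGE_C2, _LINKAGE_C3, start.elbow_deg, end.elbow_deg
    )
    e = np.linspace(start.elbow_deg, end.elbow_deg, n_linkage_points)
    pts = np.column_stack([e, linkage_cubic.wrist(e)])
    pts[0, 1] = start.wrist_deg
    pts[-1, 1] = end.wrist_deg
    return {"linear": linear, "linkage": TabulatedTrajectory(pts)}


# ---------------------------------------------------------------------------
# File I/O: CSV for tabulated paths, JSON for cubics
# ---------------------------------------------------------------------------


def save_trajectory(traj, path) -> None:
    path = Path(path)
    if isinstance(traj, CubicTrajectory):
        path.write_text(
            json.dumps(
                {
                    "c": list(traj.coefficients),
                    "elbow_range": [traj.elbow_start, traj.elbow_end],
                },
                sort_keys=True,
            )
            + "\n"
        )
    elif isinstance(traj, TabulatedTrajectory):
        lines = ["elbow_deg,wrist_deg"]
        lines += [f"{float(e)!r},{float(w)!r}" for e, w in traj.points]
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ParameterError(f"cannot save trajectory of type {type(traj)}")


def load_trajectory(path):
    """Load a trajectory file: ``.json`` cubic or ``.csv`` tabulated."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        raw = json.loads(path.read_text())
        c = raw["c"]
        a, b = raw["elbow_range"]
        return CubicTrajectory(c[0], c[1], c[2], c[3], float(a), float(b))
    rows = [
        line.split(",")
        for line in path.read_text().strip().splitlines()
        if line.strip()
    ]
    if rows and not _is_number(rows[0][0]):
        rows = rows[1:]
    pts = np.array([[float(r[0]), float(r[1])] for r in rows])
    return TabulatedTrajectory(pts)


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False
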