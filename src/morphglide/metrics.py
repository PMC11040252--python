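"""Step-response metrics of the morphing transition.

Four quantities summarize how the glider settles into the end
configuration's trim after a wing extension: speed overshoot and pitch
angle overshoot (percent of the final settled value), speed rise time and
pitch angle settling time (seconds).  The settled value is the end
configuration's trim (the end configuration is stable, so its trim is the
asymptote of the response), and the tolerance band is 2% of that value.

Overshoot is the maximum excursion of the signal past the settled value in
the direction of approach (the transition is a large commanded change, so
the raw series maximum is dominated by the initial condition, not by the
overshoot).  Rise time is the first entry into the 2% band.  Settling time
is the time of the first oscillation peak after which every subsequent peak
stays within the band; non-oscillatory signals fall back to the last exit
from the band.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import UndefinedMetricError

__all__ = [
    "MetricSettings",
    "MetricReport",
    "overshoot",
    "rise_time",
    "settling_time",
    "report",
]


@dataclass(frozen=True)
class MetricSettings:
    """tolerance_fraction: half-width of the settling band as a fraction of
    the settled value (default 0.02).  speed_signal: which component is
    "speed" — body-x ``"U"`` (default) or total ``"airspeed"``."""

    tolerance_fraction: float = 0.02
    speed_signal: str = "U"

    def __post_init__(self):
        if not 0 < self.tolerance_fraction < 1:
            raise ValueError("tolerance_fraction must be in (0, 1)")
        if self.speed_signal not in ("U", "airspeed"):
            raise ValueError("speed_signal must be 'U' or 'airspeed'")


@dataclass
class MetricReport:
    """The four response metrics plus resolution flags.

    A metric whose defining event never occurs inside the simulated horizon
    is flagged unresolved and reported as ``None``, never fabricated.
    """

    speed_overshoot_pct: float
    pitch_overshoot_pct: float
    speed_rise_time_s: float | None
    pitch_settling_time_s: float | None
    unresolved: list = field(default_factory=list)
    settings: MetricSettings = field(default_factory=MetricSettings)

    @property
    def all_resolved(self) -> bool:
        return not self.unresolved

    def value(self, objective: str):
        return getattr(self, _OBJECTIVE_FIELDS[objective])

    def to_dict(self) -> dict:
        return {
            "speed_overshoot_pct": self.speed_overshoot_pct,
            "pitch_overshoot_pct": self.pitch_overshoot_pct,
            "speed_rise_time_s": self.speed_rise_time_s,
            "pitch_settling_time_s": self.pitch_settling_time_s,
            "unresolved": list(self.unresolved),
            "settings": {
                "tolerance_fraction": self.settings.tolerance_fraction,
                "speed_signal": self.settings.speed_signal,
            },
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1) + "\n")


_OBJECTIVE_FIELDS = {
    "speed_overshoot": "speed_overshoot_pct",
    "pitch_overshoot": "pitch_overshoot_pct",
    "speed_rise_time": "speed_rise_time_s",
    "pitch_settling_time": "pitch_settling_time_s",
}

OBJECTIVES = tuple(_OBJECTIVE_FIELDS)


def _check_final(final: float) -> None:
    if final == 0:
        raise UndefinedMetricError(
            "settled value is zero; relative metrics undefined"
        )


def overshoot(t, y, final: float) -> float:
    """Percent excursion past the settled value in the approach direction.

    Zero if the series never crosses the settled value.
    """
    _check_final(final)
    y = np.asarray(y, dtype=float)
    d = y - final
    nz = d[d != 0]
    if nz.size == 0:
        return 0.0
    # Direction of approach: from the initial side toward the final value.
    sign = -np.sign(nz[0])
    exc = float(np.max(sign * d))
    return 100.0 * exc / abs(final) if exc > 0 else 0.0


def rise_time(
    t, y, final: float, settings: MetricSettings = MetricSettings()
) -> float | None:
    """Earliest time with |y - final| inside the tolerance band, else None."""
    _check_final(final)
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    band = settings.tolerance_fraction * abs(final)
    inside = np.abs(y - final) < band
    if not inside.any():
        return None
    return float(t[int(np.argmax(inside))])


def _extrema_indices(y: np.ndarray) -> np.ndarray:
    """Indices of interior local extrema by discrete-derivative sign change.

    Zero slopes (plateaus) inherit the preceding nonzero sign, so a plateau
    counts as a single extremum at its leading edge when the slope reverses
    across it.
    """
    d = np.diff(y)
    s = np.sign(d)
    last = 0.0
    for i in range(s.size):  # forward-fill zero signs (plateau guard)
        if s[i] == 0.0:
            s[i] = last
        else:
            last = s[i]
    turns = np.nonzero(s[1:] * s[:-1] < 0)[0] + 1
    return turns


def settling_time(
    t, y, final: float, settings: MetricSettings = MetricSettings()
) -> float | None:
    """Time of the first oscillation peak after which all later peaks stay
    within the tolerance band.

    For signals without interior extrema the definition degenerates to the
    last exit from the band.  Returns None (unresolved) when the signal is
    still outside the band at the end of the series.
    """
    _check_final(final)
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    band = settings.tolerance_fraction * abs(final)
    dev = np.abs(y - final)
    ext = _extrema_indices(y)
    if ext.size:
        ext_dev = dev[ext]
        # First index j such that every extremum from j on is within band.
        bad = np.nonzero(ext_dev > band)[0]
        if bad.size == 0:
            j = 0
        elif bad[-1] == ext.size - 1:
            # The last detected extremum still violates the band: either
            # unresolved, or the signal decays monotonically afterwards and
            # the band entry after that extremum is the settling event.
            tail = dev[ext[-1] :]
            inside = tail < band
            if not inside.any():
                return None
            entry = int(np.argmax(inside))
            if np.any(tail[entry:] >= band):
                # re-exits the band before the series ends: not settled
                return None
            return float(t[ext[-1] + entry])
        else:
            j = bad[-1] + 1
        if dev[-1] >= band:
            return None
        return float(t[ext[j]])
    # Non-oscillatory: last exit from the band.
    outside = np.nonzero(dev >= band)[0]
    if outside.size == 0:
        return 0.0
    if outside[-1] == y.size - 1:
        return None
    return float(t[outside[-1] + 1])


def report(sim, model, settings: MetricSettings = MetricSettings()) -> MetricReport:
    """Compute all four metrics from a simulation result.

    Settled values are the end configuration's trim: U0 (or trim airspeed)
    for the speed metrics, Theta0 for the pitch metrics.
    """
    final_trim = sim.final_trim
    if settings.speed_signal == "U":
        speed = sim.states[:, 0]
        speed_final = final_trim.U0
    else:
        speed = np.hypot(sim.states[:, 0], sim.states[:, 1])
        speed_final = final_trim.airspeed
    pitch = sim.states[:, 3]
    pitch_final = final_trim.Theta0

    unresolved = []
    so = overshoot(sim.t, speed, speed_final)
    po = overshoot(sim.t, pitch, pitch_final)
    rt = rise_time(sim.t, speed, speed_final, settings)
    if rt is None:
        unresolved.append("speed_rise_time")
    st = settling_time(sim.t, pitch, pitch_final, settings)
    if st is None:
        unresolved.append("pitch_settling_time")
    return MetricReport(
        speed_overshoot_pct=so,
        pitch_overshoot_pct=po,
        speed_rise_time_s=rt,
        pitch_settling_time_s=st,
        unresolved=unresolved,
        settings=settings,
    )
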