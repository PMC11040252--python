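"""Exception hierarchy for morphglide."""


class MorphGlideError(Exception):
    """Base class for all morphglide errors."""


class InvalidStateError(MorphGlideError):
    """Body state violates a physical precondition (e.g. U <= 0)."""


class DomainError(MorphGlideError):
    """Joint configuration lies outside the model validity region."""


class NoGlideTrimError(MorphGlideError):
    """No gliding equilibrium exists (non-positive trim lift)."""


class TrimOutOfBandError(MorphGlideError):
    """Trim angle of attack falls outside the linear-aerodynamics band."""


class GeneratorError(MorphGlideError):
    """Synthetic model generation / calibration failed."""


class ModelFormatError(MorphGlideError):
    """Model file violates the morphglide-aero-1 schema."""


class SimulationDivergedError(MorphGlideError):
    """Time integration produced a non-finite or unphysical state.

    Carries the simulation time at which the failure occurred.
    """

    def __init__(self, message: str, time: float):
        super().__init__(f"{message} (t = {time:.4f} s)")
        self.time = time


class ParameterError(MorphGlideError):
    """A scalar parameter is out of its admissible range."""


class DegenerateEndpointsError(MorphGlideError):
    """Trajectory endpoints share the same elbow angle."""


class UndefinedMetricError(MorphGlideError):
    """A response metric is undefined (zero settled value)."""
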