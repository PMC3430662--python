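"""Exception types raised across the tahill pipeline."""


class TahillError(Exception):
    """Base class for all tahill-specific errors."""


class InvalidGeometryError(TahillError):
    """Rest geometry violates a physical constraint (nonpositive length, bad angle)."""


class InconsistentGeometryError(TahillError):
    """Derived muscle-tendon geometry is impossible (e.g. nonpositive aponeurosis length)."""


class DegenerateTrialError(TahillError):
    """A trial signal cannot be normalized or processed (e.g. nonpositive peak moment)."""


class RankDeficiencyError(TahillError):
    """Force-strain samples do not constrain the quadratic fit."""


class MonotoneViolationError(TahillError):
    """A fitted force-strain curve is not strictly increasing on its valid range."""


class TrackLostError(TahillError):
    """The tracking window left the image; carries the last valid frame index."""

    def __init__(self, message: str, last_valid_frame: int):
        super().__init__(message)
        self.last_valid_frame = last_valid_frame


class DegenerateTemplateError(TahillError):
    """Template window has zero intensity variance; correlation is undefined."""


class GeometryError(TahillError):
    """Landmark lines are degenerate (e.g. fascicle parallel to an aponeurosis)."""


class EquilibriumError(TahillError):
    """Fibre/SEE force balance has no root in the admissible fibre-length bracket."""

    def __init__(self, message: str, step: int | None = None,
                 bracket: tuple[float, float] | None = None):
        super().__init__(message)
        self.step = step
        self.bracket = bracket


class CalibrationError(TahillError):
    """All calibration starts failed to produce a usable model."""


class UndefinedMetricError(TahillError):
    """A goodness-of-fit metric is undefined for the given series (constant reference)."""
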