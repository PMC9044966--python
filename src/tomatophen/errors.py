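"""Exception hierarchy.

Every failure mode the pipeline can hit deliberately (bad scene spec, missing
calibration, degenerate geometry) raises a distinct subclass of
:class:`TomatophenError` so callers can isolate per-image failures without
string matching.
"""


class TomatophenError(Exception):
    """Base class for all tomatophen errors."""


class InvalidSpecError(TomatophenError):
    """A synthetic scene specification violates its invariants."""


class CalibrationError(TomatophenError):
    """Pixel scale could not be derived, or a measurement was attempted without one."""


class AnnotationError(TomatophenError):
    """An annotation file is missing, malformed, or inconsistent."""


class DegenerateContourError(TomatophenError):
    """A contour is too short or collapsed for geometric analysis."""


class NoNavelError(TomatophenError):
    """No concave landmark candidate exists on a vertical-cut contour."""


class UndefinedMetricError(TomatophenError):
    """A requested quantity is mathematically undefined for the given input."""


class InputError(TomatophenError):
    """Inputs violate a documented precondition (mismatched lengths, duplicate ids...)."""
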