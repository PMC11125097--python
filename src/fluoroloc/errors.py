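"""Exception hierarchy.

Every failure path in the localization chain raises a typed error so callers
(and the evaluation harness) can record the reason instead of receiving a
fabricated plant center.
"""


class FluorolocError(Exception):
    """Base class for all package errors."""


class SingularGeometryError(FluorolocError):
    """A forward-projection denominator is (numerically) zero."""


class DegenerateObservationError(FluorolocError):
    """Observations carry no usable signal (e.g. zero parallax)."""


class ConfigurationError(FluorolocError):
    """A rig or pipeline parameter is invalid (e.g. sin(theta) = 0)."""


class ParallelLinesError(FluorolocError):
    """Two construction lines are parallel within the angular epsilon."""


class MissingSecondFrameError(FluorolocError):
    """A single-mirror case was dispatched without a second frame."""


class InvalidLayoutError(FluorolocError):
    """Region polygons overlap, leave gaps, or are degenerate."""


class EmptyMaskError(FluorolocError):
    """Intensity statistics requested over an empty mask."""


class KeyMismatchError(FluorolocError):
    """Results and ground truths are not keyed consistently."""


class InputFormatError(FluorolocError):
    """An image file is not 8-bit single-channel grayscale."""
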