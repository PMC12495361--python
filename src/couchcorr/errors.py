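"""Exception hierarchy.

The CLI maps these onto exit codes: usage errors are handled by click
(exit 2), :class:`ValidationError` subtypes exit 3, and
:class:`UndefinedMetricError` exits 4.
"""


class CouchCorrError(Exception):
    """Base class for all couchcorr errors."""


class ValidationError(CouchCorrError):
    """Input data violates a documented invariant."""


class InvalidRotationError(ValidationError):
    """Rotation sub-matrix is not a proper rotation within tolerance."""


class ParseError(ValidationError):
    """A file could not be parsed; message names the offending line."""


class EmptyOverlapError(ValidationError):
    """Two streams share no overlapping time range."""


class AlignmentError(ValidationError):
    """A trace lacks the X-ray-on transition needed for alignment."""


class ConfigError(ValidationError):
    """Simulation or feedback configuration is invalid."""


class UndefinedMetricError(CouchCorrError):
    """A metric's preconditions are not met (e.g. <2 end-expiration minima)."""


class DegenerateFitError(UndefinedMetricError):
    """A regression cannot be fitted (e.g. all timestamps equal)."""


class DegenerateTestError(UndefinedMetricError):
    """A statistical test is degenerate (e.g. zero-variance differences)."""
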