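"""Exception hierarchy for tubeval.

Every error raised on a user-facing path derives from :class:`TubevalError`
so callers (and the CLI) can distinguish validation problems from bugs.
"""


class TubevalError(Exception):
    """Base class for all tubeval errors."""


class FormatError(TubevalError):
    """A file or table does not conform to the documented format."""


class GridMismatchError(TubevalError):
    """Two masks do not share a geometric frame (shape/spacing/origin)."""


class EmptyInputError(TubevalError):
    """An operation that requires a non-empty mask or centerline got none."""


class UndefinedMetricError(TubevalError):
    """A ratio metric has a zero denominator and no defined convention."""


class InsufficientDataError(TubevalError):
    """Too few defined values to run a statistical comparison."""


class DegenerateDataError(TubevalError):
    """Zero-variance input where a correlation or test needs spread."""


class GenerationError(TubevalError):
    """Phantom geometry could not be generated under the given spec."""


class ValidationError(TubevalError):
    """A parameter or record violates its documented invariants."""
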