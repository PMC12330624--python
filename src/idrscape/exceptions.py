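"""Exception hierarchy shared across the package."""


class IdrscapeError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(IdrscapeError, ValueError):
    """An input value violates a documented precondition (non-finite score,
    empty sample, overlapping intervals, ...)."""


class ShapeError(IdrscapeError, ValueError):
    """An array or string has the wrong length/shape."""


class FormatError(IdrscapeError, ValueError):
    """A file does not conform to its documented on-disk format."""


class AlignmentMismatchError(IdrscapeError, ValueError):
    """Per-residue tracks that must describe the same protein disagree in
    length or identity."""


class IntervalError(IdrscapeError, ValueError):
    """An interval lies outside the coordinate range it is applied to."""


class GenerationError(IdrscapeError, RuntimeError):
    """The synthetic generator cannot satisfy the requested configuration
    (e.g. planted-motif demand exceeds disordered capacity)."""


class ReconciliationError(IdrscapeError, ValueError):
    """Protein identifiers are inconsistent across pipeline inputs."""
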