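"""Typed exceptions.

Degenerate inputs raise errors instead of returning NaN so that pipeline
stages can skip a gene pair and log it, rather than silently ranking a
meaningless score.
"""


class AssocnetError(Exception):
    """Base class for all package errors."""


class DegenerateInputError(AssocnetError):
    """Input carries no usable variation (constant vector, all ties, ...)."""


class SampleSizeError(AssocnetError):
    """Too few samples for the requested estimator."""


class ParameterError(AssocnetError):
    """A measure parameter is out of its admissible range."""


class CombinatorialExplosionError(AssocnetError):
    """A subset enumeration would exceed the configured guard."""


class CollinearityError(AssocnetError):
    """Conditioning variable is (numerically) collinear with an argument."""


class FormatError(AssocnetError):
    """An on-disk artifact violates its format contract."""


class UniverseMismatchError(AssocnetError):
    """Gene identifiers do not match between two artifacts."""


class UndefinedMetricError(AssocnetError):
    """A metric is undefined for the given labels (e.g. single-class AUC)."""
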