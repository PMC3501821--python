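"""Exception hierarchy for spikeface.

All package errors derive from :class:`SpikeFaceError` so callers can catch
one base type; the subclasses mirror the failure modes of each stage
(bad files, bad parameters, shape mismatches, rank deficiency, ...).
"""


class SpikeFaceError(Exception):
    """Base class for all spikeface errors."""


class InputError(SpikeFaceError):
    """A file could not be read or decoded."""


class SizeError(SpikeFaceError):
    """An image or kernel violates a size constraint."""


class ParameterError(SpikeFaceError, ValueError):
    """A parameter value is outside its documented domain."""


class DimensionError(SpikeFaceError):
    """Array shapes do not conform."""


class DataError(SpikeFaceError):
    """A dataset is empty, too small, or structurally invalid."""


class RankError(SpikeFaceError):
    """A matrix is rank deficient where full rank is required."""


class NumericalError(SpikeFaceError):
    """An optimisation or linear-algebra step produced non-finite values."""


class StateError(SpikeFaceError):
    """An operation was called on an unfitted or untrained object."""


class FormatError(SpikeFaceError):
    """A serialized artifact has an unknown or corrupt format."""
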