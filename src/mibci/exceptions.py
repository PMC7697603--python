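"""Exception hierarchy for mibci.

Every error raised by the library derives from :class:`MibciError` so callers
can catch library failures with a single except clause. Subclasses also derive
from the closest builtin (``ValueError``/``KeyError``) so code written against
generic exceptions keeps working.
"""


class MibciError(Exception):
    """Base class for all mibci errors."""


class ParameterError(MibciError, ValueError):
    """An argument violates a documented precondition."""


class FormatError(MibciError, ValueError):
    """A file could not be parsed in the expected on-disk format."""


class SchemaError(MibciError, ValueError):
    """A parsed file is structurally inconsistent (e.g. label/row mismatch)."""


class UnsupportedTaskError(MibciError, ValueError):
    """More than two task classes were found; the pipeline is binary."""


class RegistryError(MibciError, KeyError):
    """An unknown channel-set name was requested."""


class ChannelNotFoundError(MibciError, KeyError):
    """A requested channel label is absent from the recording."""


class DegenerateDataError(MibciError, ValueError):
    """Input data make the requested statistic undefined.

    Covers constant channels (zero standard deviation), all-zero energy
    distributions, zero-variance derivatives, and zero absolute-mean
    sub-bands used as ratio denominators.
    """


class EmptyInputError(MibciError, ValueError):
    """An operation received an empty sample vector."""


class OutOfRangeError(MibciError, ValueError):
    """An epoch window extends past the recording bounds for some markers."""


class DecompositionDepthError(MibciError, ValueError):
    """Signal too short for the requested wavelet-packet level."""


class AlignmentError(MibciError, ValueError):
    """Feature blocks with incompatible trial counts cannot be fused."""


class NoSignalError(MibciError, ValueError):
    """All candidate features are constant; selection is impossible."""


class DegenerateFoldError(MibciError, ValueError):
    """A training fold contains a single class."""


class StratificationError(MibciError, ValueError):
    """Stratified folds cannot be built for the requested split."""


class UndefinedMetricError(MibciError, ValueError):
    """A performance metric has a zero denominator or a single class."""
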