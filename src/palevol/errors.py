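"""Exception types shared across the package."""


class PalevolError(Exception):
    """Base class for all package errors."""


class AlphabetError(PalevolError):
    """A sequence contains a residue outside the declared alphabet."""


class EmptyInputError(PalevolError):
    """An input file or collection contained no usable records."""


class MalformedIntervalError(PalevolError):
    """An interval is inconsistent (start >= end, negative coordinate, ...)."""


class NoDataError(PalevolError):
    """A statistic was requested on zero comparable sites/codons."""


class ParameterError(PalevolError):
    """A parameter value is outside its documented domain."""
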