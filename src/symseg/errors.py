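"""Exception hierarchy."""


class SymsegError(Exception):
    """Base class for all package errors."""


class ParameterError(SymsegError, ValueError):
    """Invalid argument: bad shape, out-of-range value, malformed spec."""


class UnsupportedFormatError(SymsegError):
    """Readable file in a format the package does not handle (color,
    multi-frame DICOM, non-MONOCHROME2 photometric interpretation)."""


class NumericalError(SymsegError, ArithmeticError):
    """Non-finite values produced during level-set evolution."""
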