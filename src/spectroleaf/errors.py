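"""Exception hierarchy shared across the package."""


class SpectroleafError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(SpectroleafError, ValueError):
    """An argument violates an operation's stated precondition."""


class DegenerateInputError(SpectroleafError, ValueError):
    """Input is structurally valid but carries no usable signal (flat spectrum, zero-variance response, ...)."""


class ContractError(SpectroleafError, ValueError):
    """Two artifacts that must agree (band lists, vector lengths) do not."""


class EnviFormatError(SpectroleafError, ValueError):
    """An ENVI header is missing required fields or uses an unsupported dialect."""


class EnviIOError(SpectroleafError, IOError):
    """The ENVI binary does not match its header (size mismatch, missing file)."""
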