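"""Exception types shared across the package."""


class DegenerateSignalError(ValueError):
    """A time series has zero variance where a correlation is required."""


class NumericalInstabilityError(FloatingPointError):
    """An integration produced a non-finite value; the message names the step."""


class UndefinedPeakError(ValueError):
    """A spectrum has no well-defined peak (e.g. constant input)."""


class FormatVersionError(ValueError):
    """A serialized archive carries an unsupported format version."""
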