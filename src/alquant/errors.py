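"""Exception hierarchy shared across the pipeline."""


class AlquantError(Exception):
    """Base class for all package errors."""


class FormatError(AlquantError):
    """A file does not conform to the expected dialect (bad header, missing field)."""


class DataError(AlquantError):
    """Well-formed input whose content violates a data invariant."""


class ParameterError(AlquantError, ValueError):
    """Invalid parameter combination passed to a generator or analysis op."""
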