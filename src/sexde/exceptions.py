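"""Exception types shared across the pipeline."""


class SexDEError(Exception):
    """Base class for all package-specific errors."""


class FormatError(SexDEError, ValueError):
    """An input file violates its format contract (raised with location info)."""


class ParameterError(SexDEError, ValueError):
    """An argument or configuration value violates a precondition."""
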