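"""Exception hierarchy shared across the model stages."""


class SSBStrokeError(Exception):
    """Base class for all package errors."""


class ValidationError(SSBStrokeError, ValueError):
    """An input value violates a declared invariant (wrong magnitude/sign)."""


class StructuralError(SSBStrokeError, ValueError):
    """An input is structurally malformed (missing table, column or stratum,
    non-contiguous age bands)."""


class NumericalError(SSBStrokeError, ArithmeticError):
    """A numerical routine failed to converge or produced an invalid state."""
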