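"""Exception types shared across the package."""


class GenerationError(RuntimeError):
    """Raised when a synthetic recording cannot satisfy its placement constraints."""


class QuantizationError(ValueError):
    """Raised when a coefficient or weight does not fit the requested integer format."""


class PreconditionError(ValueError):
    """Raised when an input violates an operation's stated precondition."""


class SchemaError(ValueError):
    """Raised when a serialized artifact is malformed or missing required fields."""


class TrainingDivergedError(RuntimeError):
    """Raised when the training loss becomes non-finite."""
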