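"""Exception types shared across the package."""


class VenusError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(VenusError, ValueError):
    """An input value violates a documented invariant."""


class SchemaError(VenusError, ValueError):
    """A tabular or sequence input does not match the expected schema."""


class ReferenceMismatchError(VenusError, ValueError):
    """A variant annotation disagrees with the supplied reference sequence."""


class MissingPredictionError(VenusError, ValueError):
    """A required MHC-I prediction is absent from the prediction table."""
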