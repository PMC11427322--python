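"""Exception and warning types shared across the package."""


class RestoviewError(Exception):
    """Base class for restoview errors."""


class DimensionError(RestoviewError):
    """An image or array does not meet a size precondition."""


class DegenerateInputError(RestoviewError):
    """The input admits no meaningful estimate (e.g. empty mask, flat spectrum)."""


class ValidationError(RestoviewError):
    """A record violates the data contract (range, completeness, identifiers)."""


class DegenerateInputWarning(UserWarning):
    """A degenerate input was mapped to its documented fallback value."""
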