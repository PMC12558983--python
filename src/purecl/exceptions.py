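"""Package-level exception types."""


class ConfigError(ValueError):
    """A configuration or specification field is invalid."""


class ShapeError(ValueError):
    """Array shapes are incompatible with the requested operation."""


class DataError(ValueError):
    """A dataset violates a precondition (missing class, unseen label, ...)."""


class DegenerateInputError(ValueError):
    """A numerically degenerate input (e.g. normalizing a zero vector)."""
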