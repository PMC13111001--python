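"""Exception taxonomy shared across the package."""


class DimensionError(ValueError):
    """Array shapes are mutually incompatible (both shapes are named)."""


class ConfigurationError(ValueError):
    """A structural configuration constraint is violated (e.g. channels not
    divisible by 8 where an attention block is attached)."""


class InputError(ValueError):
    """Invalid user-supplied data (labels, masks, file contents, ranges)."""


class NumericError(ArithmeticError):
    """Non-finite values where finite ones are required."""
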