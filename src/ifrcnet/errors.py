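"""Exception types shared across the package."""


class ParameterError(ValueError):
    """An argument is outside its valid range (e.g. shape outside the frame)."""


class FormatError(ValueError):
    """An on-disk dataset violates the expected layout or value contract."""


class ShapeError(ValueError):
    """Array shapes are incompatible with the requested operation."""


class ConfigError(ValueError):
    """Network/fusion/training configurations are mutually inconsistent."""


class SizeError(ValueError):
    """A dataset is too small for the requested split or operation."""
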