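"""Exception hierarchy for netquant."""


class NetquantError(Exception):
    """Base class for all netquant errors."""


class ParameterError(NetquantError, ValueError):
    """A parameter value is outside its valid domain."""


class ConfigError(NetquantError, ValueError):
    """A configuration file or class definition is inconsistent."""


class StructuralError(NetquantError, ValueError):
    """An input object violates a structural invariant (empty image,
    out-of-bounds ROI, degenerate bounding box, ...)."""


class InputError(NetquantError, ValueError):
    """An input file is missing, unreadable, or lacks a required channel."""


class UsageError(NetquantError, ValueError):
    """The caller invoked an operation with unusable arguments
    (empty batch, unknown preset name, ...)."""
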