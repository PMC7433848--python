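"""Exception hierarchy shared across the package."""


class IronstripError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(IronstripError, ValueError):
    """A design, spec or config object violates its invariants.

    The message always names the offending field.
    """


class ComputationError(IronstripError, RuntimeError):
    """A numerical procedure failed (singular fit, failed integration, ...)."""
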