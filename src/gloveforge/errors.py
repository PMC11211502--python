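"""Exception types shared across the toolkit."""


class GloveForgeError(Exception):
    """Base class for all toolkit errors."""


class ConfigurationError(GloveForgeError, ValueError):
    """Unknown joint/site/marker name or an inconsistent model definition."""


class ValidationError(GloveForgeError, ValueError):
    """Invalid numeric input (non-positive length, empty sequence, ...)."""


class AlignmentError(GloveForgeError, ValueError):
    """Degenerate point set for which a rigid alignment is not defined."""
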