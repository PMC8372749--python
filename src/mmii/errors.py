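"""Exception hierarchy shared across the toolkit."""


class MMIIError(Exception):
    """Base class for all toolkit errors."""


class FormatError(MMIIError):
    """Unreadable or inconsistent image/point-set file."""


class ValidationError(MMIIError):
    """Input violates a documented precondition or invariant."""


class GeometryError(MMIIError):
    """Degenerate geometric configuration (e.g. collinear landmarks)."""


class RegistrationError(MMIIError):
    """Registration cannot be initialized or has no field-of-view overlap."""


class DegenerateInputError(MMIIError):
    """Numerically degenerate input (e.g. zero-variance difference image)."""
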