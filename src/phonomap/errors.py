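"""Exception hierarchy."""


class PhonomapError(Exception):
    """Base class for all package-specific errors."""


class DegenerateInputError(PhonomapError, ValueError):
    """Input has no usable variation (constant ensemble, zero range, ...)."""


class RegistrationError(PhonomapError, ValueError):
    """Marker extraction or landmark registration failed."""
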