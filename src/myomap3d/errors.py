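"""Exception types shared across the package."""


class Myomap3dError(Exception):
    """Base class for all package errors."""


class InputError(Myomap3dError):
    """A required input (file, mask, ROI) is missing or unreadable."""


class FormatError(Myomap3dError):
    """A file exists but does not conform to the expected format."""


class ValidationError(Myomap3dError):
    """An argument or derived quantity violates a documented precondition."""


class GenerationError(Myomap3dError):
    """A phantom generator could not satisfy its constraints."""
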