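"""Exception types shared across the package."""


class DensitexError(Exception):
    """Base class for all package errors."""


class InvalidSpecError(DensitexError):
    """A generator or model specification violates its invariants."""


class InvalidConfigError(DensitexError):
    """A descriptor configuration violates its invariants."""


class InvalidInputError(DensitexError):
    """An input array/mask/label set violates an operation's precondition."""


class FormatError(DensitexError):
    """A file could not be read as a supported grayscale image."""


class SegmentationError(DensitexError):
    """Breast-region segmentation found no foreground."""
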