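"""Exception hierarchy shared by all pipeline stages."""


class IdcgradeError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(IdcgradeError, ValueError):
    """An input violates a documented precondition or invariant."""


class ManifestError(ValidationError):
    """A cohort manifest row is malformed or inconsistent."""


class ImageFormatError(IdcgradeError, ValueError):
    """An image file is unreadable or not single-channel grayscale."""


class ConfigurationError(IdcgradeError, ValueError):
    """A configuration value (wavelet name, kernel family, ...) is unknown."""


class SegmentationError(IdcgradeError, RuntimeError):
    """Tumor segmentation produced no usable mask.

    Carries diagnostic counts (cluster sizes, selected cluster) so the
    failure can be inspected rather than silently propagated.
    """

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = dict(diagnostics or {})
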