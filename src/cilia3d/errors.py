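"""Exception hierarchy shared across the package."""


class Cilia3DError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(Cilia3DError, ValueError):
    """Invalid argument or inconsistent metadata (spacing, shapes, bounds)."""


class StackFormatError(Cilia3DError, ValueError):
    """Unsupported TIFF layout (RGB/multichannel, exotic dtype)."""


class EstimationError(Cilia3DError, RuntimeError):
    """A fit or iterative estimate failed; carries diagnostics for inspection."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class ThresholdError(Cilia3DError, RuntimeError):
    """Binarization produced an empty foreground."""

    def __init__(self, message: str, threshold: float | None = None):
        super().__init__(message)
        self.threshold = threshold
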