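"""Exception hierarchy for the synkey package."""


class SynkeyError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(SynkeyError, ValueError):
    """An input violates a documented precondition."""


class NoMovementError(InvalidInputError):
    """A recording contains no movement (all-zero velocity)."""


class OverlongTrialError(InvalidInputError):
    """A segmented trial exceeds the configured fixed length."""


class TrialParseError(SynkeyError, ValueError):
    """A trial file is malformed (bad header, column count, or cell)."""


class ShapeError(InvalidInputError):
    """Array shapes are inconsistent with the operation's contract."""


class SegmentationError(SynkeyError):
    """Image segmentation found no usable hand component."""


class FingerDetectionError(SynkeyError):
    """Fewer than five finger peaks were detected in a radial profile."""

    def __init__(self, count: int, message: str | None = None):
        self.count = count
        super().__init__(message or f"detected {count} finger peaks, need 5")


class DegenerateSynergyError(SynkeyError):
    """A synergy admits no compliant gain (for example, zero integral)."""


class ConfigurationError(SynkeyError, ValueError):
    """A population or run configuration is inconsistent."""
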