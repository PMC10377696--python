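"""Exception hierarchy for the bnctcam package."""


class BnctcamError(Exception):
    """Base class for all package-specific errors."""


class GeometryError(BnctcamError):
    """Inconsistent or physically impossible geometry (source outside phantom,
    structuring element larger than the image, ...)."""


class KinematicsError(BnctcamError):
    """Energy split incompatible with Compton kinematics (|cos theta| > 1)."""


class CsvParseError(BnctcamError):
    """Malformed CSV input. Carries the 1-based line number when known."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class EmptyInputError(BnctcamError):
    """An operation that requires at least one event/sample got none."""


class DegenerateImageError(BnctcamError):
    """All-zero or otherwise degenerate image where intensity structure is required."""


class FitError(BnctcamError):
    """Non-convergent or ill-posed curve fit."""


class UndefinedScoreError(BnctcamError):
    """Confusion-matrix score undefined (empty prediction or empty truth)."""
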