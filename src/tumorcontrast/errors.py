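"""Exception hierarchy.

Each error carries a distinct ``exit_code`` so the command-line layer can
report machine-readable failure categories.
"""


class TumorContrastError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ValidationError(TumorContrastError):
    """A domain object violates one of its invariants."""

    exit_code = 2


class ShapeError(TumorContrastError):
    """Images or masks do not share a common pixel grid."""

    exit_code = 3


class ScaleError(TumorContrastError):
    """Images carry incompatible intensity scales (e.g. uint8 vs analog)."""

    exit_code = 4


class FileFormatError(TumorContrastError):
    """An image or mask file is unreadable or has an unsupported bit depth."""

    exit_code = 5


class ContainmentError(ValidationError):
    """The tumor ellipse is not fully contained in the tissue ellipse."""

    exit_code = 6


class UndefinedContrastError(TumorContrastError):
    """Tissue signal is zero, so the tumor-contrast ratio is undefined.

    Typically signals a degenerate subtraction where the two weightings
    carry identical tissue signal.
    """

    exit_code = 7
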