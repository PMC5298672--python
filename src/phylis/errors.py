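"""Exception and warning types shared across the package."""


class PhylisError(Exception):
    """Base class for all package-specific errors."""


class NoRegionFound(PhylisError):
    """No pixel region above the brightness threshold was found in the image."""


class AmbiguousRegion(PhylisError):
    """Two candidate bright regions are too similar in area to choose between."""


class EmptyBand(PhylisError):
    """The spectrum band box has zero area."""


class TooFewColumns(PhylisError):
    """Fewer than two source columns; a 1000-point scale cannot be defined."""


class AllGaps(PhylisError):
    """A raw spectrum with no occupied positions cannot be gap-filled."""


class OutOfRange(PhylisError):
    """Position outside the 1..1000 scale."""


class TooFewGroups(PhylisError):
    """Fewer sample-location groups than requested cross-validation folds."""


class NonFiniteLoss(PhylisError):
    """Neural-network training diverged to a non-finite loss."""


class DegenerateInput(PhylisError):
    """Input too small or degenerate for the requested operation."""


class DegenerateMatrix(PhylisError):
    """Confusion matrix whose expected agreement is 1; kappa undefined."""


class MalformedFile(PhylisError):
    """A spectrum or dataset file violates the expected format."""


class SchemaError(PhylisError):
    """A dataset file is missing a required column."""


class ZeroSpectrumWarning(UserWarning):
    """Normalisation was asked for an all-zero series; zeros returned."""
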