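"""Exception hierarchy for the pipeline.

Every failure mode that a caller may want to branch on has its own class;
all inherit from :class:`EmbryoQuantError` so ``except EmbryoQuantError``
catches any pipeline-level failure without masking programming errors.
"""


class EmbryoQuantError(Exception):
    """Base class for all pipeline errors."""


class ParameterError(EmbryoQuantError, ValueError):
    """Invalid parameter combination (geometry, sigmas, config)."""


class DegenerateHistogram(EmbryoQuantError, ValueError):
    """Histogram has fewer than two occupied bins; no threshold exists."""


class SegmentationFailure(EmbryoQuantError):
    """Embryo could not be located or split in a frame."""


class BackgroundUnavailable(EmbryoQuantError):
    """No pixels outside the embryo mask to estimate background from."""


class MeasurementError(EmbryoQuantError):
    """A required measurement region is empty."""


class RatioUndefined(EmbryoQuantError):
    """P1/AB ratio undefined (non-positive AB signal after correction)."""


class NormalizationError(EmbryoQuantError):
    """Normalization reference missing or non-positive."""


class NoNEBDetected(EmbryoQuantError):
    """Nucleus never disappears for the required persistence."""


class DegenerateInput(EmbryoQuantError, ValueError):
    """Statistical input with zero variance where variance is required."""
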