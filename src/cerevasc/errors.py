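"""Exception hierarchy for cerevasc.

All package errors derive from :class:`CerevascError`, itself a ``ValueError``
so that callers who validate inputs generically still catch them.
"""


class CerevascError(ValueError):
    """Base class for all cerevasc errors."""


class DegenerateFitError(CerevascError):
    """Regression input has fewer than two distinct abscissae."""


class EmptyROIError(CerevascError):
    """ROI contains no pixel centers within the image support."""


class OutOfBoundsError(CerevascError):
    """A derived ROI falls entirely outside the image."""


class NonPositiveReferenceError(CerevascError):
    """A ratio statistic's reference (denominator) mean is <= 0."""


class InvalidSceneError(CerevascError):
    """Synthetic scene is unphysical (empty body mask, overlapping vials...)."""


class DegenerateVarianceError(CerevascError):
    """Two-sample test with zero pooled variance but unequal means."""


class FormatError(CerevascError):
    """File on disk does not match the expected on-disk format."""
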