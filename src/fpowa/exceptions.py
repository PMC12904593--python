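"""Exception types shared across the package."""


class FpowaError(Exception):
    """Base class for all fpowa errors."""


class InvalidArgumentError(FpowaError, ValueError):
    """An argument is outside its admissible range."""


class IllPosedFitError(FpowaError):
    """The penalized least-squares system is singular (too few points for the basis)."""


class InsufficientSupportError(FpowaError):
    """A curve has too few observed points to support the requested operation."""


class DegenerateGCVError(FpowaError):
    """GCV denominator (n - df)^2 is nonpositive for every candidate smoothing value."""


class DegenerateFeaturesError(FpowaError):
    """Every per-time feature dimension is constant; segmentation has no signal."""


class DegenerateGridError(FpowaError):
    """All k-nearest-neighbour distances are zero; no eps search range exists."""


class AllNoiseError(FpowaError):
    """DBSCAN labelled every time point as noise; nothing to repair."""


class UndefinedSilhouetteError(FpowaError):
    """Fewer than two clusters; the silhouette coefficient is undefined."""
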