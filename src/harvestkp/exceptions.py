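"""Exception hierarchy shared across the package."""


class HarvestKPError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(HarvestKPError, ValueError):
    """An input violates a documented precondition."""


class SceneParseError(HarvestKPError):
    """An annotation file could not be interpreted; the message names the offending key."""


class GeometryError(HarvestKPError):
    """A geometric construction is degenerate (coincident centroids, empty side, ...)."""


class MaskTopologyError(HarvestKPError):
    """A raster mask cannot be expressed in the requested representation."""


class PlacementError(HarvestKPError):
    """Synthetic-scene placement failed after bounded retries."""


class PredictorContractError(HarvestKPError):
    """A user-supplied point predictor returned values outside [0, 1]."""
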