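"""Exception hierarchy for the worm imaging pipeline."""


class WormGlowError(Exception):
    """Base class for all pipeline errors."""


class UndefinedCorrelationError(WormGlowError):
    """NCC requested on data with zero variance in one operand."""


class EmptyShapeError(WormGlowError):
    """A binary mask expected to contain a worm is empty."""


class NoWormFoundError(WormGlowError):
    """No thresholded shape satisfied the worm-likeness area band."""


class ShapeTooThinError(WormGlowError):
    """Morphological erosion emptied the candidate worm shape."""


class AmbiguousTopologyError(WormGlowError):
    """Skeleton cannot be reduced to a two-endpoint path (e.g. curled worm)."""


class ManualAnnotationRequired(WormGlowError):
    """Head/tail/vulva assignment is ambiguous and needs a manual annotation."""


class MeshingFailedError(WormGlowError):
    """Anterior/posterior worm bodies do not form one connected shape."""


class DegenerateFitError(WormGlowError):
    """Least-squares brightness fit is underdetermined (constant overlap)."""


class BorderNotFoundError(WormGlowError):
    """Perpendicular border march left the image before leaving the worm."""
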