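"""Core containers shared across the pipeline.

Conventions used throughout:

* images are 2D ``numpy`` arrays indexed ``[y, x]`` (row, column), zero based;
* points are ``(x, y)`` tuples in pixel coordinates, x = column, y = row;
* the image y axis points down (screen convention), so "left" of a walking
  direction ``t = (tx, ty)`` is the vector ``(ty, -tx)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Optional

import numpy as np

#: membership codes in LabeledWormImage.membership
EXTERIOR, BORDER, INTERIOR = 0, 1, 2

#: blue-channel pixel values used when a labeled image is written to PNG
MEMBERSHIP_PNG_CODES = {EXTERIOR: 0, BORDER: 128, INTERIOR: 255}


class Channel(IntEnum):
    GFP = 0
    DIC = 1


@dataclass
class Micrograph:
    """Raw single-channel micrograph (camera counts, typically <= 12 bit)."""

    pixels: np.ndarray
    channel: Channel = Channel.GFP
    id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("Micrograph pixels must be a 2D array")
        if self.pixels.size and self.pixels.min() < 0:
            raise ValueError("Micrograph pixel values must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class Anatomy:
    """Head/tail endpoints and the lateral side of the vulva.

    ``vulva_side`` is 'left'/'right' relative to the head-to-tail walking
    direction with the image y axis pointing down, or 'unknown'.
    """

    head: tuple[int, int]
    tail: tuple[int, int]
    vulva_side: str = "unknown"

    def __post_init__(self) -> None:
        if tuple(self.head) == tuple(self.tail):
            raise ValueError("head and tail must differ")
        if self.vulva_side not in ("left", "right", "unknown"):
            raise ValueError(f"invalid vulva_side: {self.vulva_side!r}")


@dataclass
class LabeledWormImage:
    """Output of pixel classification: normalized intensity plus membership.

    ``green`` holds the min-max normalized 8-bit intensity, ``membership``
    the 3-class mask (exterior=0, border=1, interior=2), and ``raw`` the
    original non-normalized counts that all downstream intensity sampling
    reads. ``offset`` records the (x, y) position of this image's origin in
    its source frame when the image has been cropped.
    """

    green: np.ndarray
    membership: np.ndarray
    raw: np.ndarray
    channel: Channel = Channel.GFP
    id: str = ""
    anatomy: Optional[Anatomy] = None
    offset: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        self.green = np.asarray(self.green, dtype=np.uint8)
        self.membership = np.asarray(self.membership, dtype=np.uint8)
        self.raw = np.asarray(self.raw, dtype=np.float64)
        if not (self.green.shape == self.membership.shape == self.raw.shape):
            raise ValueError("green/membership/raw must share one shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.green.shape

    @property
    def worm_mask(self) -> np.ndarray:
        """Boolean border-or-interior mask."""
        return self.membership != EXTERIOR

    @property
    def interior_mask(self) -> np.ndarray:
        return self.membership == INTERIOR

    @property
    def border_mask(self) -> np.ndarray:
        return self.membership == BORDER


@dataclass
class ShiftModel:
    """Rigid integer shift plus linear brightness model between A and P.

    ``(sx, sy)`` places the posterior image origin at that position in the
    anterior image frame.  ``gain``/``offset`` map anterior green values onto
    the posterior scale, P ~ gain * A + offset.
    """

    sx: int
    sy: int
    gain: float = 1.0
    offset: float = 0.0
    ncc_at_best: float = 0.0


@dataclass
class Backbone:
    """Ordered head-to-tail medial path resampled to equidistant points."""

    points: np.ndarray  # (n, 2) float, columns (x, y)
    tangents: np.ndarray  # (n, 2) unit vectors
    arc_length: float

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64)
        self.tangents = np.asarray(self.tangents, dtype=np.float64)
        if self.points.shape != self.tangents.shape or self.points.shape[1] != 2:
            raise ValueError("points and tangents must be (n, 2) arrays")

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class IntensityImage2D:
    """Anatomically aligned h x w grid of mean raw intensities.

    Row 0 is the anterior (head) end, the last row the posterior (tail);
    the rightmost column is the vulva side.
    """

    values: np.ndarray
    channel: Channel = Channel.GFP
    id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[0] < 2:
            raise ValueError("IntensityImage2D needs an (h>=2, w>=1) array")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def left_of(tangent: np.ndarray) -> np.ndarray:
    """Unit vector pointing to the walker's left for a y-down image frame."""
    t = np.asarray(tangent, dtype=np.float64)
    return np.array([t[1], -t[0]])


def right_of(tangent: np.ndarray) -> np.ndarray:
    """Unit vector pointing to the walker's right for a y-down image frame."""
    t = np.asarray(tangent, dtype=np.float64)
    return np.array([-t[1], t[0]])
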