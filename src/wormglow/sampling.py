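"""Worm straightening by quadrangle-grid sampling (*sampleCE*).

The skeleton is tracked from head to tail in equal arc-length steps; at each
step the worm border is found perpendicular to the local backbone tangent,
and the border-to-border chord is split into equal intervals.  Consecutive
chords bound one row of quadrangles; each quadrangle averages the raw GFP
counts under it and becomes one pixel of the h x w (default 75 x 15)
anatomically aligned 2D intensity image (anterior at top, vulva side at the
rightmost column).
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from . import imaging
from .errors import (
    AmbiguousTopologyError,
    BorderNotFoundError,
    ManualAnnotationRequired,
)
from .types import (
    Anatomy,
    Backbone,
    Channel,
    IntensityImage2D,
    LabeledWormImage,
    Micrograph,
)

__all__ = [
    "track_backbone",
    "find_borders",
    "build_quadrangle_grid",
    "average_quadrangle",
    "quadrangle_area",
    "sample_intensity_image",
    "select_resolution",
    "DEFAULT_SHAPE_GFP",
    "DEFAULT_SHAPE_DIC",
]

DEFAULT_SHAPE_GFP = (75, 15)
DEFAULT_SHAPE_DIC = (520, 52)

_SQRT2 = np.sqrt(2.0)


def track_backbone(sk: imaging.Skeleton, head: tuple[int, int],
                   tail: tuple[int, int], h: int) -> Backbone:
    """Resample the skeleton path into ``h`` equidistant head-to-tail points.

    Arc length counts diagonal steps as sqrt(2).  Tangents are central
    differences of the resampled points (one-sided at the ends), unit
    normalized.
    """
    if h < 2:
        raise ValueError("h must be >= 2")
    if len(sk.endpoints) != 2:
        raise AmbiguousTopologyError(
            "backbone tracking requires a two-endpoint skeleton")
    if tuple(head) not in sk.endpoints or tuple(tail) not in sk.endpoints:
        raise ValueError("head/tail must be skeleton endpoints")
    path = np.asarray(imaging._pixel_path(sk.mask, tuple(head), tuple(tail)),
                      dtype=np.float64)
    steps = np.linalg.norm(np.diff(path, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(steps)])
    total = float(cum[-1])
    s = np.linspace(0.0, total, h)
    pts = np.column_stack([np.interp(s, cum, path[:, 0]),
                           np.interp(s, cum, path[:, 1])])
    tang = np.empty_like(pts)
    tang[1:-1] = pts[2:] - pts[:-2]
    tang[0] = pts[1] - pts[0]
    tang[-1] = pts[-1] - pts[-2]
    norms = np.linalg.norm(tang, axis=1)
    norms[norms == 0] = 1.0
    tang /= norms[:, None]
    return Backbone(points=pts, tangents=tang, arc_length=total)


def find_borders(mask: np.ndarray, p: Sequence[float],
                 tangent: Sequence[float], step: float = 0.5,
                 ) -> tuple[np.ndarray, np.ndarray]:
    """March perpendicular to the tangent until leaving the worm mask.

    Returns the last in-mask positions on the walker's left and right side
    (y-down frame: left of tangent (tx, ty) is (ty, -tx)).  The mask is
    sampled by nearest neighbor in 0.5 px steps.
    """
    m = np.asarray(mask, dtype=bool)
    h, w = m.shape
    p = np.asarray(p, dtype=np.float64)
    t = np.asarray(tangent, dtype=np.float64)
    t = t / np.linalg.norm(t)
    left = np.array([t[1], -t[0]])

    def march(direction):
        pos = p.copy()
        last = p.copy()
        while True:
            pos = pos + step * direction
            xi, yi = int(round(pos[0])), int(round(pos[1]))
            if not (0 <= xi < w and 0 <= yi < h):
                raise BorderNotFoundError(
                    "border march left the image while inside the mask")
            if not m[yi, xi]:
                return last
            last = pos.copy()

    xi, yi = int(round(p[0])), int(round(p[1]))
    if not (0 <= xi < w and 0 <= yi < h) or not m[yi, xi]:
        raise BorderNotFoundError("backbone point lies outside the mask")
    return march(left), march(-left)


def _chords(mask: np.ndarray, backbone: Backbone) -> np.ndarray:
    """(h, 2, 2) array of left/right border points at each backbone sample."""
    out = np.empty((len(backbone), 2, 2))
    for i, (p, t) in enumerate(zip(backbone.points, backbone.tangents)):
        l, r = find_borders(mask, p, t)
        out[i, 0] = l
        out[i, 1] = r
    return out


def build_quadrangle_grid(mask: np.ndarray, backbone: Backbone,
                          w: int) -> np.ndarray:
    """(h, w, 4, 2) grid of quadrangle corners covering the worm body.

    Each of the ``h`` backbone samples contributes a border-to-border chord
    split into ``w`` equal sub-segments; quadrangle (i, j) is bounded by
    sub-segment j of chords i and i+1.  The terminal row duplicates the last
    chord advanced half an arc step along the local tangent, so the output
    has exactly ``h`` rows.  Corners are ordered cyclically.
    """
    if w < 1:
        raise ValueError("w must be >= 1")
    h = len(backbone)
    chords = _chords(mask, backbone)
    step = backbone.arc_length / max(h - 1, 1)
    extra = chords[-1] + 0.5 * step * backbone.tangents[-1]
    chords = np.concatenate([chords, extra[None]], axis=0)  # (h+1, 2, 2)

    frac = np.linspace(0.0, 1.0, w + 1)
    # points along each chord from the left border to the right border
    pts = chords[:, 0:1, :] + frac[None, :, None] * (
        chords[:, 1:2, :] - chords[:, 0:1, :])  # (h+1, w+1, 2)

    quads = np.empty((h, w, 4, 2))
    quads[:, :, 0] = pts[:-1, :-1]
    quads[:, :, 1] = pts[:-1, 1:]
    quads[:, :, 2] = pts[1:, 1:]
    quads[:, :, 3] = pts[1:, :-1]
    return quads


def quadrangle_area(q: np.ndarray) -> float:
    """Shoelace area of one quadrangle (absolute value)."""
    x, y = q[:, 0], q[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def _points_in_quad(q: np.ndarray, px: np.ndarray, py: np.ndarray) -> np.ndarray:
    """Boolean inclusion of points in a convex quadrangle (boundary included)."""
    x, y = q[:, 0], q[:, 1]
    # orient counter-clockwise (positive shoelace)
    if np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)) < 0:
        x, y = x[::-1], y[::-1]
    inside = np.ones(px.shape, dtype=bool)
    for k in range(4):
        ex, ey = x[(k + 1) % 4] - x[k], y[(k + 1) % 4] - y[k]
        cross = ex * (py - y[k]) - ey * (px - x[k])
        inside &= cross >= 0
    return inside


def average_quadrangle(raw: np.ndarray, q: np.ndarray) -> float:
    """Mean raw value of pixels whose centers fall inside the quadrangle.

    If no pixel center lies inside (degenerate or sub-pixel quadrangle) the
    value is bilinearly interpolated at the centroid.
    """
    a = raw.pixels if isinstance(raw, Micrograph) else np.asarray(raw, np.float64)
    h, w = a.shape
    x0 = max(int(np.floor(q[:, 0].min())), 0)
    x1 = min(int(np.ceil(q[:, 0].max())) + 1, w)
    y0 = max(int(np.floor(q[:, 1].min())), 0)
    y1 = min(int(np.ceil(q[:, 1].max())) + 1, h)
    if x0 < x1 and y0 < y1:
        yy, xx = np.mgrid[y0:y1, x0:x1]
        inside = _points_in_quad(q, xx.astype(float), yy.astype(float))
        if inside.any():
            return float(a[y0:y1, x0:x1][inside].mean())
    # centroid fallback: bilinear sample
    cx = float(np.clip(q[:, 0].mean(), 0, w - 1))
    cy = float(np.clip(q[:, 1].mean(), 0, h - 1))
    xi, yi = int(np.floor(cx)), int(np.floor(cy))
    xi = min(xi, w - 2) if w > 1 else 0
    yi = min(yi, h - 2) if h > 1 else 0
    fx, fy = cx - xi, cy - yi
    if w == 1 or h == 1:
        return float(a[min(yi, h - 1), min(xi, w - 1)])
    return float(a[yi, xi] * (1 - fx) * (1 - fy) + a[yi, xi + 1] * fx * (1 - fy)
                 + a[yi + 1, xi] * (1 - fx) * fy + a[yi + 1, xi + 1] * fx * fy)


def sample_intensity_image(labeled: LabeledWormImage,
                           raw: Optional[np.ndarray] = None,
                           h: int = DEFAULT_SHAPE_GFP[0],
                           w: int = DEFAULT_SHAPE_GFP[1]) -> IntensityImage2D:
    """Sample the anatomically aligned h x w intensity image of one worm.

    Reads the RAW (non-normalized) counts.  Requires resolved anatomy: head
    and tail fix the row direction (anterior at row 0); if the vulva is on
    the worm's left, columns are mirrored so the vulva side is always the
    rightmost column.  ``vulva_side='unknown'`` raises
    :class:`ManualAnnotationRequired`.
    """
    anatomy = labeled.anatomy
    if anatomy is None or anatomy.vulva_side == "unknown":
        raise ManualAnnotationRequired(
            "head/tail/vulva anatomy must be resolved before sampling")
    a = labeled.raw if raw is None else (
        raw.pixels if isinstance(raw, Micrograph) else np.asarray(raw, np.float64))
    mask = imaging.fill_holes(labeled.worm_mask)
    sk = imaging.skeletonize(mask)
    if len(sk.endpoints) != 2:
        sk = imaging.reduce_to_two_endpoints(sk)
    # snap the annotated head/tail onto the nearest skeleton endpoints
    eps = np.asarray(sk.endpoints, dtype=float)
    head = np.asarray(anatomy.head, dtype=float)
    d = np.linalg.norm(eps - head, axis=1)
    head_ep = sk.endpoints[int(np.argmin(d))]
    tail_ep = sk.endpoints[1 - int(np.argmin(d))]

    backbone = track_backbone(sk, head_ep, tail_ep, h)
    quads = build_quadrangle_grid(mask, backbone, w)
    values = np.empty((h, w))
    for i in range(h):
        for j in range(w):
            values[i, j] = average_quadrangle(a, quads[i, j])
    # columns run left lateral -> right lateral; put the vulva at the right
    if anatomy.vulva_side == "left":
        values = values[:, ::-1]
    return IntensityImage2D(values=values, channel=labeled.channel,
                            id=labeled.id,
                            meta={"h": h, "w": w, "vulva_side": anatomy.vulva_side,
                                  "arc_length": backbone.arc_length})


def select_resolution(pair: Sequence[LabeledWormImage],
                      candidates: Sequence[tuple[int, int]],
                      drop_frac: float = 0.15) -> tuple[int, int]:
    """Pick the output resolution from two images of the same worm.

    At each candidate (h, w) both replicate images are sampled and compared
    by NCC; fine anatomical misalignment makes the correlation drop as the
    resolution grows.  The highest-resolution candidate whose NCC is still
    within ``drop_frac`` of the best NCC over all candidates is returned.
    """
    if len(candidates) < 2:
        raise ValueError("need at least two candidate resolutions")
    cands = sorted(candidates, key=lambda hw: hw[0] * hw[1])
    nccs = []
    for (h, w) in cands:
        i1 = sample_intensity_image(pair[0], h=h, w=w)
        i2 = sample_intensity_image(pair[1], h=h, w=w)
        nccs.append(imaging.ncc_arrays(i1.values, i2.values,
                                       zero_variance="zero"))
    best = max(nccs)
    cutoff = (1.0 - drop_frac) * best
    for (hw, r) in reversed(list(zip(cands, nccs))):
        if r >= cutoff:
            return hw
    return cands[0]
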