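"""Low-level image primitives: NCC, equalization, morphology, skeletons.

The normalized correlation coefficient here is the population Pearson
correlation between a template and the co-located image patch; it is the
single similarity used for registration, resolution selection and the
clustering distance, because it is invariant to positive-affine intensity
changes (exposure, autofluorescence level).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import skeletonize as _sk_skeletonize

from .errors import AmbiguousTopologyError, EmptyShapeError, UndefinedCorrelationError
from .types import Micrograph

__all__ = [
    "ncc",
    "ncc_arrays",
    "histogram_equalize",
    "largest_component",
    "fill_holes",
    "erode",
    "dilate",
    "trace_contour",
    "perimeter",
    "circularity",
    "skeletonize",
    "skeleton_endpoints",
    "reduce_to_two_endpoints",
    "Skeleton",
]

# 8-connectivity structuring element, used for foreground labeling and as the
# default erosion/dilation kernel (3x3 full square).
_SQUARE3 = np.ones((3, 3), dtype=bool)

_NEIGHBORS8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


# ---------------------------------------------------------------------------
# NCC
# ---------------------------------------------------------------------------

def ncc_arrays(a: np.ndarray, b: np.ndarray, zero_variance: str = "raise") -> float:
    """Population Pearson correlation between two equal-size arrays.

    Parameters
    ----------
    zero_variance:
        ``"raise"`` (analysis contexts) raises :class:`UndefinedCorrelationError`
        when either operand is constant; ``"zero"`` (search contexts) returns
        0.0 so exhaustive shift searches do not crash on flat regions.
    """
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    if a.shape != b.shape:
        raise ValueError("operands must have identical size")
    da = a - a.mean()
    db = b - b.mean()
    va = float(da @ da)
    vb = float(db @ db)
    if va == 0.0 or vb == 0.0:
        if zero_variance == "zero":
            return 0.0
        raise UndefinedCorrelationError("zero variance in NCC operand")
    r = float(da @ db) / np.sqrt(va * vb)
    # guard against rounding just outside [-1, 1]
    return float(min(1.0, max(-1.0, r)))


def ncc(template, image, x0: int = 0, y0: int = 0,
        zero_variance: str = "raise") -> float:
    """NCC of ``template`` laid over ``image`` with its (0,0) at (x0, y0)."""
    t = template.pixels if isinstance(template, Micrograph) else np.asarray(template)
    im = image.pixels if isinstance(image, Micrograph) else np.asarray(image)
    th, tw = t.shape
    ih, iw = im.shape
    if x0 < 0 or y0 < 0 or x0 + tw > iw or y0 + th > ih:
        raise IndexError("template placement exceeds image bounds")
    patch = im[y0:y0 + th, x0:x0 + tw]
    return ncc_arrays(t, patch, zero_variance=zero_variance)


# ---------------------------------------------------------------------------
# Histogram equalization
# ---------------------------------------------------------------------------

def histogram_equalize(img, levels: int = 256) -> np.ndarray:
    """Map intensities through the cumulative histogram onto [0, levels-1].

    A value v with cumulative probability F(v) maps to ``ceil(levels*F(v)) - 1``,
    which is monotone non-decreasing (rank order preserved up to ties) and
    yields an approximately flat histogram.  Works directly on arbitrary
    (e.g. 12-bit) value ranges because the mapping is built from the sorted
    unique values, not from a fixed bin grid.
    """
    a = img.pixels if isinstance(img, Micrograph) else np.asarray(img, dtype=np.float64)
    if a.size == 0:
        raise ValueError("empty image")
    if levels < 2:
        raise ValueError("levels must be >= 2")
    values, inverse, counts = np.unique(a, return_inverse=True, return_counts=True)
    cdf = np.cumsum(counts) / a.size
    mapped = np.ceil(levels * cdf) - 1.0
    mapped = np.clip(mapped, 0, levels - 1)
    return mapped[inverse].reshape(a.shape)


# ---------------------------------------------------------------------------
# Binary morphology and components
# ---------------------------------------------------------------------------

def largest_component(mask: np.ndarray) -> np.ndarray:
    """Keep only the largest 8-connected foreground component.

    Ties are broken by the component containing the first foreground pixel in
    raster order (smallest y, then x).
    """
    m = np.asarray(mask, dtype=bool)
    labels, n = ndi.label(m, structure=_SQUARE3)
    if n == 0:
        raise EmptyShapeError("mask has no foreground pixels")
    counts = np.bincount(labels.ravel())[1:]
    best_size = counts.max()
    # raster order of first occurrence breaks ties deterministically
    tied = set(np.flatnonzero(counts == best_size) + 1)
    if len(tied) == 1:
        best = tied.pop()
    else:
        flat = labels.ravel()
        best = next(int(l) for l in flat if l in tied)
    return labels == best


def fill_holes(mask: np.ndarray) -> np.ndarray:
    """Fill background regions not 4-connected to the image border."""
    # 4-connectivity for the background is the dual of 8-connected foreground
    return ndi.binary_fill_holes(np.asarray(mask, dtype=bool),
                                 structure=ndi.generate_binary_structure(2, 1))


def erode(mask: np.ndarray, iterations: int = 1) -> np.ndarray:
    """Binary erosion with a 3x3 square, ``iterations`` times."""
    m = np.asarray(mask, dtype=bool)
    if iterations == 0:
        return m.copy()
    return ndi.binary_erosion(m, structure=_SQUARE3, iterations=iterations)


def dilate(mask: np.ndarray, iterations: int = 1) -> np.ndarray:
    """Binary dilation with a 3x3 square, ``iterations`` times."""
    m = np.asarray(mask, dtype=bool)
    if iterations == 0:
        return m.copy()
    return ndi.binary_dilation(m, structure=_SQUARE3, iterations=iterations)


# ---------------------------------------------------------------------------
# Contour tracing, perimeter, circularity
# ---------------------------------------------------------------------------

def trace_contour(mask: np.ndarray) -> np.ndarray:
    """Moore-neighbor trace of the outer 8-connected contour.

    Returns an (n, 2) array of (x, y) pixel coordinates in traversal order.
    The mask must contain a single 8-connected component.
    """
    m = np.asarray(mask, dtype=bool)
    ys, xs = np.nonzero(m)
    if len(ys) == 0:
        raise EmptyShapeError("cannot trace an empty mask")
    if len(ys) == 1:
        return np.array([[xs[0], ys[0]]])
    h, w = m.shape

    def fg(x, y):
        return 0 <= x < w and 0 <= y < h and m[y, x]

    # clockwise on screen (y down): E, SE, S, SW, W, NW, N, NE
    dirs = [(1, 0), (1, 1), (0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1)]
    dir_index = {d: i for i, d in enumerate(dirs)}

    # start: first foreground pixel in raster order, backtrack = its west
    # neighbor, which is background by construction
    sy, sx = int(ys[0]), int(xs[0])
    cx, cy = sx, sy
    bx, by = sx - 1, sy

    contour = [(cx, cy)]
    seen_states: set[tuple[int, int, int, int]] = set()
    while True:
        i = dir_index[(bx - cx, by - cy)]
        nxt = None
        for k in range(1, 9):
            j = (i + k) % 8
            dx, dy = dirs[j]
            nx, ny = cx + dx, cy + dy
            if fg(nx, ny):
                pdx, pdy = dirs[(i + k - 1) % 8]
                nxt = (nx, ny, cx + pdx, cy + pdy)
                break
        if nxt is None:  # isolated pixel
            return np.array(contour)
        state = nxt
        if state in seen_states:
            return np.array(contour)
        seen_states.add(state)
        cx, cy, bx, by = nxt
        if (cx, cy) == (sx, sy) and (bx, by) == (sx - 1, sy):
            return np.array(contour)  # closed with Jacob's criterion
        contour.append((cx, cy))
        if len(contour) > 8 * m.size:  # safety net; cannot happen on valid input
            raise RuntimeError("contour tracing did not terminate")


def perimeter(mask: np.ndarray) -> float:
    """Contour length from 8-connected tracing, diagonal steps weighted sqrt(2)."""
    c = trace_contour(mask)
    if len(c) < 2:
        return 0.0
    closed = np.vstack([c, c[:1]])
    steps = np.abs(np.diff(closed, axis=0))
    lengths = np.where(steps.sum(axis=1) == 2, np.sqrt(2.0), 1.0)
    # consecutive duplicates (possible at trace turn-arounds) contribute 0
    lengths[steps.sum(axis=1) == 0] = 0.0
    return float(lengths.sum())


def circularity(mask: np.ndarray) -> float:
    """4*pi*Area / Perimeter^2: near 1 for disks, small for elongated shapes."""
    m = np.asarray(mask, dtype=bool)
    area = int(m.sum())
    if area < 4:
        raise EmptyShapeError("shape too small for circularity")
    p = perimeter(m)
    if p == 0:
        raise EmptyShapeError("degenerate contour")
    return float(4.0 * np.pi * area / (p * p))


# ---------------------------------------------------------------------------
# Skeletons
# ---------------------------------------------------------------------------

class Skeleton:
    """One-pixel-thin 8-connected skeleton with its endpoint list."""

    def __init__(self, mask: np.ndarray):
        self.mask = np.asarray(mask, dtype=bool)
        self.endpoints = skeleton_endpoints(self.mask)

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


def _neighbor_count(mask: np.ndarray) -> np.ndarray:
    """Number of foreground 8-neighbors at every pixel."""
    m = mask.astype(np.uint8)
    k = np.ones((3, 3), dtype=np.uint8)
    k[1, 1] = 0
    return ndi.convolve(m, k, mode="constant", cval=0)


def skeleton_endpoints(mask: np.ndarray) -> list[tuple[int, int]]:
    """Foreground pixels with exactly one foreground 8-neighbor, as (x, y)."""
    m = np.asarray(mask, dtype=bool)
    nc = _neighbor_count(m)
    ys, xs = np.nonzero(m & (nc == 1))
    return [(int(x), int(y)) for x, y in zip(xs, ys)]


def skeletonize(mask: np.ndarray) -> Skeleton:
    """Topology-preserving thinning of a filled worm mask to its backbone."""
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        raise EmptyShapeError("cannot skeletonize an empty mask")
    return Skeleton(_sk_skeletonize(m))


def reduce_to_two_endpoints(sk: Skeleton) -> Skeleton:
    """Prune a branched skeleton to a simple two-endpoint path.

    All current endpoint pixels are deleted synchronously, one layer per
    step, recording each pixel's deletion time, until at most two endpoints
    remain.  The two surviving endpoints are then extended back toward the
    original tips by reversing their own recorded shrinkage (walking onto the
    deleted neighbor with the highest deletion time, strictly decreasing).
    Side branches, whose chains do not end at the survivors, stay deleted.
    """
    mask = sk.mask.copy()
    if not mask.any():
        raise EmptyShapeError("empty skeleton")
    if len(sk.endpoints) == 2:
        return Skeleton(mask)
    if len(sk.endpoints) < 2:
        raise AmbiguousTopologyError(
            "skeleton has no endpoints (closed loop, e.g. a curled worm)")

    h, w = mask.shape
    deletion_time = np.zeros((h, w), dtype=np.int64)  # 0 = never deleted
    t = 0
    while True:
        eps = skeleton_endpoints(mask)
        if len(eps) <= 2:
            break
        t += 1
        for x, y in eps:
            mask[y, x] = False
            deletion_time[y, x] = t
        if not mask.any():
            raise AmbiguousTopologyError(
                "skeleton collapsed before reaching two endpoints")

    survivors = skeleton_endpoints(mask)
    if len(survivors) < 2:
        # a path of length <= 2 can lose its endpoint property; treat the
        # remaining pixels as the survivors if exactly two are left
        ys, xs = np.nonzero(mask)
        if len(ys) in (1, 2):
            survivors = [(int(x), int(y)) for x, y in zip(xs, ys)]
        if len(survivors) < 2:
            raise AmbiguousTopologyError(
                "could not identify two surviving endpoints")

    # regrow each survivor along strictly decreasing deletion times
    tips = []
    for ex, ey in survivors:
        cx, cy = ex, ey
        want = t  # the most recently deleted layer is adjacent to a survivor
        while want >= 1:
            candidates = []
            for dy, dx in _NEIGHBORS8:
                ny, nx = cy + dy, cx + dx
                if 0 <= ny < h and 0 <= nx < w and not mask[ny, nx] \
                        and deletion_time[ny, nx] == want:
                    candidates.append((ny, nx))
            if not candidates:
                break
            ny, nx = min(candidates)  # deterministic (y, x) tie-break
            mask[ny, nx] = True
            cx, cy = nx, ny
            want -= 1
        tips.append((cx, cy))

    # residual junction stubs (branch pixels that never became endpoints) are
    # dropped by keeping only the pixels on the path between the regrown tips
    path = _pixel_path(mask, tips[0], tips[1])
    pruned = np.zeros_like(mask)
    for x, y in path:
        pruned[y, x] = True

    out = Skeleton(pruned)
    if len(out.endpoints) != 2:
        raise AmbiguousTopologyError(
            f"endpoint reduction yielded {len(out.endpoints)} endpoints")
    return out


def _pixel_path(mask: np.ndarray, start: tuple[int, int],
                goal: tuple[int, int]) -> list[tuple[int, int]]:
    """Breadth-first 8-connected pixel path from start to goal, as (x, y)."""
    from collections import deque

    h, w = mask.shape
    prev: dict[tuple[int, int], tuple[int, int]] = {start: start}
    queue = deque([start])
    while queue:
        cx, cy = queue.popleft()
        if (cx, cy) == goal:
            break
        for dy, dx in _NEIGHBORS8:
            nx, ny = cx + dx, cy + dy
            if 0 <= nx < w and 0 <= ny < h and mask[ny, nx] \
                    and (nx, ny) not in prev:
                prev[(nx, ny)] = (cx, cy)
                queue.append((nx, ny))
    if goal not in prev:
        raise AmbiguousTopologyError("skeleton endpoints are disconnected")
    path = [goal]
    while path[-1] != start:
        path.append(prev[path[-1]])
    path.reverse()
    return path
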