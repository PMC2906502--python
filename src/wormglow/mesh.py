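"""Registration and fusion of anterior/posterior worm image pairs (*meshAB*).

The two images of one specimen are related by a pure integer translation
(same magnification, same camera).  The shift is found by a two-level NCC
search on the normalized green channel, exposure differences are removed by
a least-squares linear brightness model, the overlap is averaged, and the
worm memberships are fused.  Head/tail follow from the known anterior/
posterior source assignment; the vulva side follows from backbone convexity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import imaging
from .classify import membership_from_mask, normalize_to_8bit
from .errors import (
    DegenerateFitError,
    EmptyShapeError,
    ManualAnnotationRequired,
    MeshingFailedError,
)
from .types import (
    Anatomy,
    Channel,
    INTERIOR,
    LabeledWormImage,
    Micrograph,
    ShiftModel,
)

__all__ = [
    "crop_to_worm",
    "find_best_shift",
    "fit_brightness",
    "combine_images",
    "combine_membership",
    "assign_head_tail",
    "infer_vulva_side",
    "mesh",
    "MeshResult",
]

COARSE_STEP = 16
DEFAULT_MIN_OVERLAP = 1000


def crop_to_worm(img: LabeledWormImage) -> LabeledWormImage:
    """Cut down to the smallest rectangle containing all worm pixels."""
    worm = img.worm_mask
    if not worm.any():
        raise EmptyShapeError("labeled image contains no worm pixels")
    ys, xs = np.nonzero(worm)
    y0, y1 = ys.min(), ys.max() + 1
    x0, x1 = xs.min(), xs.max() + 1
    return LabeledWormImage(
        green=img.green[y0:y1, x0:x1],
        membership=img.membership[y0:y1, x0:x1],
        raw=img.raw[y0:y1, x0:x1],
        channel=img.channel,
        id=img.id,
        anatomy=img.anatomy,
        offset=(img.offset[0] + int(x0), img.offset[1] + int(y0)),
    )


def _overlap_slices(shape_a, shape_p, sx: int, sy: int):
    """Overlap windows of A and of P when P's origin sits at (sx, sy) in A."""
    ha, wa = shape_a
    hp, wp = shape_p
    x0, x1 = max(0, sx), min(wa, sx + wp)
    y0, y1 = max(0, sy), min(ha, sy + hp)
    if x0 >= x1 or y0 >= y1:
        return None
    a = (slice(y0, y1), slice(x0, x1))
    p = (slice(y0 - sy, y1 - sy), slice(x0 - sx, x1 - sx))
    return a, p


def _shift_ncc(ga: np.ndarray, gp: np.ndarray, sx: int, sy: int,
               min_overlap: int) -> Optional[float]:
    sl = _overlap_slices(ga.shape, gp.shape, sx, sy)
    if sl is None:
        return None
    a, p = sl
    if (a[0].stop - a[0].start) * (a[1].stop - a[1].start) < min_overlap:
        return None
    return imaging.ncc_arrays(ga[a], gp[p], zero_variance="zero")


def find_best_shift(A: LabeledWormImage, P: LabeledWormImage,
                    min_overlap: int = DEFAULT_MIN_OVERLAP) -> ShiftModel:
    """Two-level hierarchical NCC search for the integer shift of P over A.

    Level 1 evaluates every shift that is a multiple of 16 within the
    feasible range; level 2 exhaustively refines all integer shifts within
    +-16 of the level-1 argmax.  Ties prefer smaller ``|sx|+|sy|``, then
    smaller ``sy``, then ``sx``.
    """
    ga = np.asarray(A.green, dtype=np.float64)
    gp = np.asarray(P.green, dtype=np.float64)
    ha, wa = ga.shape
    hp, wp = gp.shape

    def better(cand, best):
        (r1, s1), (r0, s0) = cand, best
        if r1 != r0:
            return r1 > r0
        k1 = (abs(s1[0]) + abs(s1[1]), s1[1], s1[0])
        k0 = (abs(s0[0]) + abs(s0[1]), s0[1], s0[0])
        return k1 < k0

    def coarse_range(lo: int, hi: int):
        """Multiples of COARSE_STEP within [lo, hi]."""
        start = int(np.ceil(lo / COARSE_STEP)) * COARSE_STEP
        return range(start, hi + 1, COARSE_STEP)

    coarse: list[tuple[float, tuple[int, int]]] = []
    for sy in coarse_range(-(hp - 1), ha - 1):
        for sx in coarse_range(-(wp - 1), wa - 1):
            r = _shift_ncc(ga, gp, sx, sy, min_overlap)
            if r is not None:
                coarse.append((r, (sx, sy)))
    if not coarse:
        raise MeshingFailedError("no shift satisfies the minimum-overlap bound")
    # refine around the strongest coarse candidates; the NCC surface is a
    # narrow ridge along the worm, so the global coarse argmax can sit one
    # cell away from the true peak
    coarse.sort(key=lambda e: (-e[0], abs(e[1][0]) + abs(e[1][1]), e[1][1], e[1][0]))
    best = coarse[0]
    for _, (cx, cy) in coarse[:5]:
        for sy in range(cy - COARSE_STEP, cy + COARSE_STEP + 1):
            for sx in range(cx - COARSE_STEP, cx + COARSE_STEP + 1):
                r = _shift_ncc(ga, gp, sx, sy, min_overlap)
                if r is not None and better((r, (sx, sy)), best):
                    best = (r, (sx, sy))
    r, (sx, sy) = best
    return ShiftModel(sx=int(sx), sy=int(sy), ncc_at_best=float(r))


def fit_brightness(A: LabeledWormImage, P: LabeledWormImage,
                   shift: ShiftModel) -> tuple[float, float]:
    """Least-squares (gain, offset) with P ~ gain * A + offset in the overlap."""
    ga = np.asarray(A.green, dtype=np.float64)
    gp = np.asarray(P.green, dtype=np.float64)
    sl = _overlap_slices(ga.shape, gp.shape, shift.sx, shift.sy)
    if sl is None:
        raise DegenerateFitError("images do not overlap at the given shift")
    a = ga[sl[0]].ravel()
    p = gp[sl[1]].ravel()
    if a.size < 2 or np.ptp(a) == 0:
        raise DegenerateFitError("constant anterior values in the overlap")
    X = np.column_stack([a, np.ones_like(a)])
    (gain, offset), *_ = np.linalg.lstsq(X, p, rcond=None)
    return float(gain), float(offset)


def _canvas_geometry(shape_a, shape_p, sx: int, sy: int):
    """Union canvas extents; returns (height, width, origin_x, origin_y)."""
    ha, wa = shape_a
    hp, wp = shape_p
    ox = min(0, sx)
    oy = min(0, sy)
    w = max(wa, sx + wp) - ox
    h = max(ha, sy + hp) - oy
    return h, w, ox, oy


def combine_images(A: np.ndarray, P: np.ndarray, shift: ShiftModel,
                   gain: float = 1.0, offset: float = 0.0) -> np.ndarray:
    """Mosaic A and P on the union canvas, averaging the overlap.

    A is first mapped onto P's brightness scale via ``gain * A + offset``
    (identity by default, e.g. for the raw-count mosaic which must stay
    non-normalized).  Pixels outside both images are 0.
    """
    a = np.asarray(A, dtype=np.float64) * gain + offset
    p = np.asarray(P, dtype=np.float64)
    h, w, ox, oy = _canvas_geometry(a.shape, p.shape, shift.sx, shift.sy)
    acc = np.zeros((h, w))
    cnt = np.zeros((h, w))
    ya, xa = -oy, -ox
    acc[ya:ya + a.shape[0], xa:xa + a.shape[1]] += a
    cnt[ya:ya + a.shape[0], xa:xa + a.shape[1]] += 1
    yp, xp = shift.sy - oy, shift.sx - ox
    acc[yp:yp + p.shape[0], xp:xp + p.shape[1]] += p
    cnt[yp:yp + p.shape[0], xp:xp + p.shape[1]] += 1
    out = np.zeros((h, w))
    np.divide(acc, cnt, out=out, where=cnt > 0)
    return out


def combine_membership(A: LabeledWormImage, P: LabeledWormImage,
                       shift: ShiftModel) -> np.ndarray:
    """OR the worm interiors on the canvas and recompute the 1-px border."""
    ia = A.interior_mask
    ip = P.interior_mask
    h, w, ox, oy = _canvas_geometry(ia.shape, ip.shape, shift.sx, shift.sy)
    union = np.zeros((h, w), dtype=bool)
    union[-oy:-oy + ia.shape[0] or None, -ox:-ox + ia.shape[1] or None] |= ia
    yp, xp = shift.sy - oy, shift.sx - ox
    union[yp:yp + ip.shape[0], xp:xp + ip.shape[1]] |= ip
    from scipy import ndimage as ndi
    _, n = ndi.label(union, structure=np.ones((3, 3)))
    if n != 1:
        raise MeshingFailedError(
            f"combined worm interiors form {n} components, expected 1")
    union = imaging.fill_holes(union)
    return membership_from_mask(union)


def _region_masks(shape_canvas, shape_a, shape_p, sx: int, sy: int):
    """Boolean A-coverage and P-coverage masks on the union canvas."""
    h, w = shape_canvas
    _, _, ox, oy = _canvas_geometry(shape_a, shape_p, sx, sy)
    in_a = np.zeros((h, w), dtype=bool)
    in_p = np.zeros((h, w), dtype=bool)
    in_a[-oy:-oy + shape_a[0] or None, -ox:-ox + shape_a[1] or None] = True
    yp, xp = sy - oy, sx - ox
    in_p[yp:yp + shape_p[0], xp:xp + shape_p[1]] = True
    return in_a, in_p


def assign_head_tail(sk: imaging.Skeleton, a_only: np.ndarray,
                     p_only: np.ndarray) -> Anatomy:
    """Label skeleton endpoints as head (anterior) and tail (posterior).

    An endpoint inside the A-only canvas region is the head, one inside the
    P-only region the tail.  If both endpoints lie in the overlap (curled
    worm) a :class:`ManualAnnotationRequired` is raised; other unclear cases
    are resolved by distance to the exclusive-region centroids.
    """
    if len(sk.endpoints) != 2:
        raise ValueError("skeleton must have exactly two endpoints")
    (x1, y1), (x2, y2) = sk.endpoints
    e1_a, e1_p = bool(a_only[y1, x1]), bool(p_only[y1, x1])
    e2_a, e2_p = bool(a_only[y2, x2]), bool(p_only[y2, x2])
    if e1_a and e2_p:
        return Anatomy(head=(x1, y1), tail=(x2, y2))
    if e2_a and e1_p:
        return Anatomy(head=(x2, y2), tail=(x1, y1))
    in_overlap_1 = not (e1_a or e1_p)
    in_overlap_2 = not (e2_a or e2_p)
    if in_overlap_1 and in_overlap_2:
        raise ManualAnnotationRequired(
            "both skeleton endpoints lie in the overlap region")

    def centroid(m):
        ys, xs = np.nonzero(m)
        if len(ys) == 0:
            return None
        return np.array([xs.mean(), ys.mean()])

    ca, cp = centroid(a_only), centroid(p_only)
    if ca is None or cp is None:
        raise ManualAnnotationRequired("no exclusive region to anchor head/tail")
    e1 = np.array([x1, y1], dtype=float)
    e2 = np.array([x2, y2], dtype=float)
    # choose the endpoint pairing minimizing total centroid distance
    cost_12 = np.linalg.norm(e1 - ca) + np.linalg.norm(e2 - cp)
    cost_21 = np.linalg.norm(e2 - ca) + np.linalg.norm(e1 - cp)
    if cost_12 <= cost_21:
        return Anatomy(head=(x1, y1), tail=(x2, y2))
    return Anatomy(head=(x2, y2), tail=(x1, y1))


def infer_vulva_side(backbone_points: np.ndarray,
                     convexity_frac: float = 0.9,
                     smooth_window: int = 11) -> str:
    """Vulva side from backbone convexity.

    For a convex (C-shaped) backbone the vulva lies on the inner, more
    strongly curved side.  Signed curvature is the cross product of
    successive tangents, smoothed over ``smooth_window`` points; if at least
    ``convexity_frac`` of the absolute-curvature mass shares one sign the
    inner side is returned as 'left'/'right' w.r.t. head-to-tail travel
    (y-down frame), otherwise 'unknown' (straight or S-shaped worm).
    """
    pts = np.asarray(backbone_points, dtype=np.float64)
    if len(pts) < 10:
        return "unknown"
    # resample to equidistant points first: raw skeleton paths are quantized
    # to 8 directions and their step-to-step turning is dominated by pixel
    # zigzag rather than worm curvature
    steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(steps)])
    if cum[-1] <= 0:
        return "unknown"
    n_res = min(50, len(pts))
    s = np.linspace(0.0, cum[-1], n_res)
    pts = np.column_stack([np.interp(s, cum, pts[:, 0]),
                           np.interp(s, cum, pts[:, 1])])
    t = np.diff(pts, axis=0)
    norms = np.linalg.norm(t, axis=1)
    keep = norms > 0
    t = t[keep] / norms[keep, None]
    if len(t) < 3:
        return "unknown"
    cross = t[:-1, 0] * t[1:, 1] - t[:-1, 1] * t[1:, 0]
    if smooth_window > 1 and len(cross) >= smooth_window:
        kernel = np.ones(smooth_window) / smooth_window
        cross = np.convolve(cross, kernel, mode="same")
    total = np.abs(cross).sum()
    if total == 0:
        return "unknown"
    pos = cross[cross > 0].sum()
    neg = -cross[cross < 0].sum()
    # with y down, positive cross = turning toward the walker's right
    if pos / total >= convexity_frac:
        return "right"
    if neg / total >= convexity_frac:
        return "left"
    return "unknown"


@dataclass
class MeshResult:
    """Fused labeled image plus the registration/QC provenance."""

    labeled: LabeledWormImage
    shift: ShiftModel
    raw_mosaic: np.ndarray
    qc_overlap_ratio: float
    qc_passed: bool
    skeleton: imaging.Skeleton = field(repr=False, default=None)
    #: shift mapping the posterior SOURCE frame onto the anterior SOURCE
    #: frame (crop offsets undone); comparable with a planted ground truth
    source_shift: tuple[int, int] = (0, 0)


def mesh(A: LabeledWormImage, P: LabeledWormImage,
         min_overlap: int = DEFAULT_MIN_OVERLAP,
         qc_factor: float = 5.0) -> MeshResult:
    """Register, fuse, and annotate an anterior/posterior pair.

    The shift search and brightness model use only the normalized green
    channel; the raw-count mosaic retained for intensity sampling is combined
    without harmonization (overlap averaged), and the ratio of mean raw
    overlap intensities gates the QC verdict (``qc_factor``).
    """
    A = crop_to_worm(A)
    P = crop_to_worm(P)
    shift = find_best_shift(A, P, min_overlap=min_overlap)
    gain, offset = fit_brightness(A, P, shift)
    shift.gain, shift.offset = gain, offset

    green = combine_images(A.green, P.green, shift, gain, offset)
    membership = combine_membership(A, P, shift)
    raw_mosaic = combine_images(A.raw, P.raw, shift)  # non-normalized

    # QC: exposure mismatch visible as a raw mean-intensity ratio in overlap
    sl = _overlap_slices(A.shape, P.shape, shift.sx, shift.sy)
    mean_a = float(A.raw[sl[0]].mean())
    mean_p = float(P.raw[sl[1]].mean())
    lo, hi = sorted([max(mean_a, 1e-12), max(mean_p, 1e-12)])
    ratio = hi / lo
    qc_passed = ratio <= qc_factor

    worm = membership != 0
    sk = imaging.reduce_to_two_endpoints(imaging.skeletonize(imaging.fill_holes(worm)))
    in_a, in_p = _region_masks(membership.shape, A.shape, P.shape,
                               shift.sx, shift.sy)
    anatomy = assign_head_tail(sk, in_a & ~in_p, in_p & ~in_a)

    # order the backbone head -> tail for the convexity rule
    path = imaging._pixel_path(sk.mask, anatomy.head, anatomy.tail)
    anatomy.vulva_side = infer_vulva_side(np.asarray(path, dtype=float))

    labeled = LabeledWormImage(
        green=np.clip(np.round(green), 0, 255).astype(np.uint8),
        membership=membership,
        raw=raw_mosaic,
        channel=A.channel,
        id=A.id or P.id,
        anatomy=anatomy,
        offset=(min(A.offset[0], A.offset[0] + shift.sx),
                min(A.offset[1], A.offset[1] + shift.sy)),
    )
    source_shift = (shift.sx + A.offset[0] - P.offset[0],
                    shift.sy + A.offset[1] - P.offset[1])
    return MeshResult(labeled=labeled, shift=shift, raw_mosaic=raw_mosaic,
                      qc_overlap_ratio=ratio, qc_passed=qc_passed, skeleton=sk,
                      source_shift=source_shift)
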