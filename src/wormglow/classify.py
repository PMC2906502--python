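"""Per-pixel worm segmentation (*pixelClassification* stage).

A logistic model on two windowed features of the histogram-equalized GFP
image — the 5x5 window mean and relative standard deviation — yields a
per-pixel worm probability.  A sweep over thresholds generates candidate
shapes; the candidate within the 3-25% area band with the highest
circularity is selected and morphologically refined into a three-class
labeled image (exterior / one-pixel border / interior).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage as ndi
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression

from . import imaging
from .errors import EmptyShapeError, NoWormFoundError, ShapeTooThinError
from .types import BORDER, EXTERIOR, INTERIOR, Channel, LabeledWormImage, Micrograph

__all__ = [
    "PixelFeatures",
    "PixelModel",
    "WormPixelClassifier",
    "extract_features",
    "train_model",
    "predict_probability",
    "select_shape",
    "refine_shape",
    "classify_worm",
    "membership_from_mask",
    "DEFAULT_THRESHOLDS",
]

DEFAULT_THRESHOLDS: tuple[float, ...] = tuple(np.round(np.arange(0.05, 0.951, 0.05), 4))
WINDOW = 5


@dataclass
class PixelFeatures:
    """5x5-window mean and relative standard deviation per pixel.

    Windows are clipped at image borders (smaller effective windows at the
    edges, no padded values).  ``relstd5 = window std / window mean`` with the
    population (ddof=0) standard deviation, defined as 0 where the mean is 0.
    """

    mean5: np.ndarray
    relstd5: np.ndarray

    def stack(self) -> np.ndarray:
        """(n_pixels, 2) design matrix in (mean5, relstd5) column order."""
        return np.column_stack([self.mean5.ravel(), self.relstd5.ravel()])


def extract_features(img, window: int = WINDOW) -> PixelFeatures:
    """Windowed mean and relative std of an (equalized) intensity image."""
    a = img.pixels if isinstance(img, Micrograph) else np.asarray(img, np.float64)
    ones = np.ones_like(a)
    # mode="constant" zero-pads; dividing the window sums by the window pixel
    # counts turns that into exact clipped-window statistics
    cnt = ndi.uniform_filter(ones, window, mode="constant") * window**2
    s1 = ndi.uniform_filter(a, window, mode="constant") * window**2
    s2 = ndi.uniform_filter(a * a, window, mode="constant") * window**2
    mean = s1 / cnt
    var = np.maximum(s2 / cnt - mean**2, 0.0)
    std = np.sqrt(var)
    with np.errstate(divide="ignore", invalid="ignore"):
        relstd = np.where(mean > 0, std / np.where(mean > 0, mean, 1.0), 0.0)
    return PixelFeatures(mean5=mean, relstd5=relstd)


@dataclass
class PixelModel:
    """Logistic worm-pixel model: sigma(intercept + w_mean*mean5 + w_relstd*relstd5)."""

    intercept: float
    w_mean: float
    w_relstd: float
    metadata: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "intercept": self.intercept,
            "w_mean": self.w_mean,
            "w_relstd": self.w_relstd,
            "metadata": self.metadata,
        }, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "PixelModel":
        d = json.loads(Path(path).read_text())
        return cls(d["intercept"], d["w_mean"], d["w_relstd"], d.get("metadata", {}))


class WormPixelClassifier(BaseEstimator, ClassifierMixin):
    """Sklearn-style wrapper around the two-feature logistic pixel model.

    ``fit`` accepts lists of (equalized or raw) images and boolean worm masks;
    features are extracted internally.  A small ridge penalty (``C``) keeps
    the fit stable on perfectly separable synthetic data.
    """

    def __init__(self, C: float = 1.0, max_train_pixels: int = 200_000,
                 equalize: bool = True, random_state: int = 0):
        self.C = C
        self.max_train_pixels = max_train_pixels
        self.equalize = equalize
        self.random_state = random_state

    def fit(self, images: Sequence, masks: Sequence) -> "WormPixelClassifier":
        if len(images) == 0 or len(images) != len(masks):
            raise ValueError("need equally many images and label masks")
        xs, ys = [], []
        for img, m in zip(images, masks):
            a = img.pixels if isinstance(img, Micrograph) else np.asarray(img)
            if self.equalize:
                a = imaging.histogram_equalize(a)
            xs.append(extract_features(a).stack())
            ys.append(np.asarray(m, dtype=bool).ravel())
        X = np.concatenate(xs)
        y = np.concatenate(ys)
        if y.all() or not y.any():
            raise ValueError("training labels contain a single class")
        if len(y) > self.max_train_pixels:
            rng = np.random.default_rng(self.random_state)
            idx = rng.choice(len(y), self.max_train_pixels, replace=False)
            X, y = X[idx], y[idx]
        lr = LogisticRegression(C=self.C, solver="lbfgs", max_iter=1000)
        lr.fit(X, y)
        self.coef_ = lr.coef_.copy()
        self.intercept_ = lr.intercept_.copy()
        self.classes_ = lr.classes_
        self.n_train_pixels_ = int(len(y))
        self.class_balance_ = float(y.mean())
        return self

    def to_pixel_model(self) -> PixelModel:
        return PixelModel(
            intercept=float(self.intercept_[0]),
            w_mean=float(self.coef_[0, 0]),
            w_relstd=float(self.coef_[0, 1]),
            metadata={"n_pixels": self.n_train_pixels_,
                      "class_balance": self.class_balance_},
        )

    def predict_proba_image(self, img) -> np.ndarray:
        """Worm-pixel probability map for one (already equalized) image."""
        return predict_probability(self.to_pixel_model(), img)

    def predict_proba(self, X):  # standard flat-feature interface
        z = self.intercept_[0] + np.asarray(X) @ self.coef_[0]
        p = 1.0 / (1.0 + np.exp(-z))
        return np.column_stack([1 - p, p])

    def predict(self, X):
        return self.predict_proba(X)[:, 1] >= 0.5


def train_model(features, labels, C: float = 1.0, seed: int = 0) -> PixelModel:
    """Fit the logistic pixel model from per-image features and label masks."""
    if len(features) == 0:
        raise ValueError("need at least one labeled image")
    X = np.concatenate([f.stack() for f in features])
    y = np.concatenate([np.asarray(m, dtype=bool).ravel() for m in labels])
    if y.all() or not y.any():
        raise ValueError("training labels contain a single class")
    lr = LogisticRegression(C=C, solver="lbfgs", max_iter=1000)
    lr.fit(X, y)
    return PixelModel(
        intercept=float(lr.intercept_[0]),
        w_mean=float(lr.coef_[0, 0]),
        w_relstd=float(lr.coef_[0, 1]),
        metadata={"n_pixels": int(len(y)), "class_balance": float(y.mean())},
    )


def predict_probability(model: PixelModel, img) -> np.ndarray:
    """Per-pixel logistic worm probability of an equalized image."""
    f = extract_features(img)
    z = model.intercept + model.w_mean * f.mean5 + model.w_relstd * f.relstd5
    return 1.0 / (1.0 + np.exp(-z))


def select_shape(prob: np.ndarray,
                 thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
                 min_area_frac: float = 0.03,
                 max_area_frac: float = 0.25) -> np.ndarray:
    """Pick the most circular thresholded shape within the area band.

    For each threshold the largest 8-connected component of ``prob >= t`` is
    a candidate; among candidates occupying 3-25% of the image the one with
    the highest circularity wins (ties: lowest threshold, i.e. the larger
    shape).
    """
    prob = np.asarray(prob, dtype=np.float64)
    if len(thresholds) == 0:
        raise ValueError("thresholds must be nonempty")
    total = prob.size
    best: Optional[np.ndarray] = None
    best_circ = -np.inf
    for t in thresholds:
        binary = prob >= t
        if not binary.any():
            continue
        cand = imaging.largest_component(binary)
        frac = cand.sum() / total
        if frac < min_area_frac or frac > max_area_frac:
            continue
        try:
            c = imaging.circularity(cand)
        except EmptyShapeError:
            continue
        if c > best_circ:  # strict: ties keep the lowest threshold
            best_circ = c
            best = cand
    if best is None:
        raise NoWormFoundError(
            f"no thresholded shape within [{min_area_frac}, {max_area_frac}] area")
    return best


def _correct_contour(mask: np.ndarray, window: int = 10,
                     d_max: float = 3.0) -> np.ndarray:
    """Excise contour runs deviating strongly from the local tangent.

    The local tangent at contour point i is the chord between its anchors
    i-window and i+window; a point farther than ``d_max`` px from its own
    anchor chord is flagged.  Flagged runs separated by fewer than ``window``
    unflagged points are merged (the top of a round protrusion is locally
    smooth, its flanks are not), every flagged run is dropped, and the
    remaining polygon is re-rasterized, which replaces each run by the
    straight segment between its anchors.  In practice this removes eggs
    clinging to the body while leaving gentle body bends untouched: a bend
    of radius R deviates from a 2*window chord by only ~window^2/(2R).
    """
    contour = imaging.trace_contour(mask)
    n = len(contour)
    if n < 2 * window + 3:
        return mask
    pts = contour.astype(np.float64)
    prev = np.roll(pts, window, axis=0)   # anchor i - window
    nxt = np.roll(pts, -window, axis=0)   # anchor i + window
    chord = nxt - prev
    L = np.linalg.norm(chord, axis=1)
    L[L == 0] = 1.0
    dev = np.abs(chord[:, 0] * (pts[:, 1] - prev[:, 1])
                 - chord[:, 1] * (pts[:, 0] - prev[:, 0])) / L
    flagged = dev > d_max
    if not flagged.any() or flagged.all():
        return mask
    idx = np.where(flagged)[0]
    for a, b in zip(idx, np.roll(idx, -1)):
        gap = (int(b) - int(a)) % n
        if 1 < gap < window:
            for j in range(1, gap):
                flagged[(int(a) + j) % n] = True
    if flagged.all():
        return mask
    kept = pts[~flagged]
    from skimage.draw import polygon as _sk_polygon

    rr, cc = _sk_polygon(kept[:, 1], kept[:, 0], shape=mask.shape)
    out = np.zeros_like(mask)
    out[rr, cc] = True
    # the polygon fill can miss single contour pixels; retain only worm-like
    # structure: largest component, holes filled
    if not out.any():
        return mask
    out = imaging.fill_holes(imaging.largest_component(out))
    return out


def refine_shape(mask: np.ndarray, contour_window: int = 10,
                 contour_dmax: float = 3.0) -> np.ndarray:
    """Morphological cleanup: fill holes, open (3x erode + 3x dilate), de-egg."""
    m = imaging.fill_holes(np.asarray(mask, dtype=bool))
    m = imaging.erode(m, 3)
    if not m.any():
        raise ShapeTooThinError("erosion emptied the worm shape")
    m = imaging.dilate(m, 3)
    m = imaging.largest_component(m)
    m = imaging.fill_holes(m)
    m = _correct_contour(m, window=contour_window, d_max=contour_dmax)
    return imaging.fill_holes(imaging.largest_component(m))


def membership_from_mask(mask: np.ndarray) -> np.ndarray:
    """3-class membership: interior = eroded mask, border = 1-px rim."""
    m = np.asarray(mask, dtype=bool)
    interior = imaging.erode(m, 1)
    membership = np.full(m.shape, EXTERIOR, dtype=np.uint8)
    membership[m & ~interior] = BORDER
    membership[interior] = INTERIOR
    return membership


def normalize_to_8bit(raw: np.ndarray) -> np.ndarray:
    """Per-image min-max normalization to [0, 255] (display/meshing only)."""
    a = np.asarray(raw, dtype=np.float64)
    lo, hi = a.min(), a.max()
    if hi == lo:
        return np.zeros(a.shape, dtype=np.uint8)
    return np.round((a - lo) / (hi - lo) * 255.0).astype(np.uint8)


def classify_worm(raw: Micrograph, model: PixelModel,
                  thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
                  min_area_frac: float = 0.03,
                  max_area_frac: float = 0.25) -> LabeledWormImage:
    """Full segmentation of one raw GFP micrograph into a labeled image."""
    eq = imaging.histogram_equalize(raw.pixels)
    prob = predict_probability(model, eq)
    shape = select_shape(prob, thresholds, min_area_frac, max_area_frac)
    refined = refine_shape(shape)
    return LabeledWormImage(
        green=normalize_to_8bit(raw.pixels),
        membership=membership_from_mask(refined),
        raw=raw.pixels,
        channel=raw.channel,
        id=raw.id,
    )
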