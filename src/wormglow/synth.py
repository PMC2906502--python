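"""Synthetic worm micrograph generator with full ground truth.

Renders curved tubular worm bodies over an autofluorescent background, with
Gaussian expression loci placed in body coordinates (axial position along
the head-tail axis, lateral position across the body), pixel noise, known
anterior/posterior splits with planted shift and brightness mismatch, and a
population generator with Bright / DimA / DimB pattern classes plus
intermediate-brightness specimens, mirroring a brightness-sorted isogenic
worm experiment.

Every rendered specimen carries its ground truth: body mask, backbone,
head/tail/vulva anatomy, and the noise-free expression pattern on the
canonical 75 x 15 grid.  Lateral locus coordinates are vulva-positive
(+1 = vulva side), so the canonical truth pattern always has the vulva at
the rightmost column regardless of the rendered worm's handedness.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .types import (
    Anatomy,
    Backbone,
    Channel,
    IntensityImage2D,
    Micrograph,
    ShiftModel,
)

__all__ = [
    "Locus",
    "WormSpec",
    "RenderedWorm",
    "render_worm",
    "split_pair",
    "ClassTemplate",
    "PopulationSpec",
    "Specimen",
    "generate_population",
    "DEFAULT_TEMPLATES",
]


@dataclass
class Locus:
    """One Gaussian expression locus in body coordinates.

    ``axial`` in [0, 1] from head to tail; ``lateral`` in [-1, 1] with +1 on
    the vulva side; ``amplitude`` in camera counts above baseline.
    """

    axial: float
    lateral: float
    amplitude: float
    axial_sigma: float = 0.05
    lateral_sigma: float = 0.45


@dataclass
class WormSpec:
    """Geometry, brightness and noise of one synthetic worm."""

    body_length: float = 400.0
    body_halfwidth: float = 11.0
    pose: str = "straight"  # straight | c_shape | s_shape
    curvature: float = 1.8  # total turning angle (rad) for curved poses
    vulva_side: str = "right"
    baseline: float = 400.0
    loci: list[Locus] = field(default_factory=list)
    noise_sd: float = 15.0
    background_level: float = 100.0
    seed: int = 0
    margin: int = 20

    def __post_init__(self) -> None:
        if self.pose not in ("straight", "c_shape", "s_shape"):
            raise ValueError(f"unknown pose {self.pose!r}")
        if self.vulva_side not in ("left", "right"):
            raise ValueError("vulva_side must be 'left' or 'right'")
        for l in self.loci:
            if l.amplitude < 0 or l.axial_sigma <= 0 or l.lateral_sigma <= 0:
                raise ValueError("invalid locus parameters")


def _taper(u: np.ndarray) -> np.ndarray:
    """Smooth half-width profile: 1 at mid-body, 0.3 at head and tail."""
    return 0.3 + 0.7 * np.sqrt(np.clip(4.0 * u * (1.0 - u), 0.0, 1.0))


def _backbone_curve(spec: WormSpec, n: int = 2000) -> np.ndarray:
    """(n, 2) analytic backbone points at equal arc-length steps."""
    s = np.linspace(0.0, spec.body_length, n)
    # a real worm's vulva lies on the inner (more strongly curved) side, so
    # curved poses bend toward the declared vulva side
    sign = 1.0 if spec.vulva_side == "right" else -1.0
    if spec.pose == "straight":
        theta = np.zeros(n)
    elif spec.pose == "c_shape":
        # constant turn rate, total turn = curvature
        theta = sign * spec.curvature * (s / spec.body_length)
    else:  # s_shape: heading oscillates once, curvature flips sign mid-body
        u = s / spec.body_length
        theta = spec.curvature * np.sin(2.0 * np.pi * u) * 2.0 / np.pi
    ds = np.diff(s)
    dx = np.cos(theta[:-1]) * ds
    dy = np.sin(theta[:-1]) * ds
    pts = np.zeros((n, 2))
    pts[1:, 0] = np.cumsum(dx)
    pts[1:, 1] = np.cumsum(dy)
    return pts


@dataclass
class RenderedWorm:
    """A rendered specimen plus all of its ground truth."""

    gfp: Micrograph
    truth_mask: np.ndarray
    truth_backbone: Backbone
    anatomy: Anatomy
    truth_pattern: IntensityImage2D
    spec: WormSpec


def truth_pattern(spec: WormSpec, h: int = 75, w: int = 15) -> IntensityImage2D:
    """Noise-free expression pattern on the canonical grid (vulva right)."""
    u = (np.arange(h) + 0.5) / h  # axial, head at row 0
    v = -1.0 + 2.0 * (np.arange(w) + 0.5) / w  # lateral, vulva at +1 (right)
    uu, vv = np.meshgrid(u, v, indexing="ij")
    vals = np.full((h, w), spec.baseline, dtype=np.float64)
    for l in spec.loci:
        vals += l.amplitude * np.exp(
            -((uu - l.axial) ** 2) / (2.0 * l.axial_sigma ** 2)
            - ((vv - l.lateral) ** 2) / (2.0 * l.lateral_sigma ** 2))
    return IntensityImage2D(values=vals, channel=Channel.GFP, id="truth")


def render_worm(spec: WormSpec, worm_id: str = "synthetic") -> RenderedWorm:
    """Rasterize one worm: body mask, intensities, noise, and ground truth."""
    curve = _backbone_curve(spec)
    lo = curve.min(axis=0) - (spec.body_halfwidth + spec.margin)
    curve = curve - lo  # shift into positive coordinates
    hi = curve.max(axis=0) + (spec.body_halfwidth + spec.margin)
    w_img, h_img = int(np.ceil(hi[0])), int(np.ceil(hi[1]))

    n = len(curve)
    u_curve = np.linspace(0.0, 1.0, n)
    tang = np.gradient(curve, axis=0)
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)

    yy, xx = np.mgrid[0:h_img, 0:w_img]
    pix = np.column_stack([xx.ravel(), yy.ravel()]).astype(np.float64)
    tree = cKDTree(curve)
    dist, idx = tree.query(pix, k=1)
    u_pix = u_curve[idx]
    halfw = spec.body_halfwidth * _taper(u_pix)
    inside = dist <= halfw

    # signed lateral position: positive on the walker's right (y-down frame)
    d = pix - curve[idx]
    t = tang[idx]
    cross = t[:, 0] * d[:, 1] - t[:, 1] * d[:, 0]
    lat_right = np.where(halfw > 0, np.clip(dist / np.maximum(halfw, 1e-9), 0, 1), 0)
    lat_right = np.sign(cross) * lat_right
    # convert to vulva-positive lateral coordinate
    lat_v = lat_right if spec.vulva_side == "right" else -lat_right

    intensity = np.full(pix.shape[0], spec.background_level, dtype=np.float64)
    body = np.full(pix.shape[0], spec.baseline, dtype=np.float64)
    for l in spec.loci:
        body += l.amplitude * np.exp(
            -((u_pix - l.axial) ** 2) / (2.0 * l.axial_sigma ** 2)
            - ((lat_v - l.lateral) ** 2) / (2.0 * l.lateral_sigma ** 2))
    intensity[inside] = body[inside]

    rng = np.random.default_rng(spec.seed)
    if spec.noise_sd > 0:
        intensity = intensity + rng.normal(0.0, spec.noise_sd, intensity.shape)
    img = np.clip(intensity, 0.0, None).reshape(h_img, w_img)
    mask = inside.reshape(h_img, w_img)

    bb_tang = tang
    backbone = Backbone(points=curve, tangents=bb_tang,
                        arc_length=float(spec.body_length))
    head = (int(round(curve[0, 0])), int(round(curve[0, 1])))
    tail = (int(round(curve[-1, 0])), int(round(curve[-1, 1])))
    anatomy = Anatomy(head=head, tail=tail, vulva_side=spec.vulva_side)
    return RenderedWorm(
        gfp=Micrograph(pixels=img, channel=Channel.GFP, id=worm_id),
        truth_mask=mask,
        truth_backbone=backbone,
        anatomy=anatomy,
        truth_pattern=truth_pattern(spec),
        spec=spec,
    )


def split_pair(gfp: Micrograph, overlap_frac: float = 0.3,
               shift: tuple[int, int] = (0, 0), gain: float = 1.0,
               offset: float = 0.0, noise_sd: float = 0.0,
               seed: int = 0) -> tuple[Micrograph, Micrograph, ShiftModel]:
    """Cut a whole-worm image into an anterior/posterior pair with overlap.

    The posterior part is cropped at ``shift = (sx, sy)`` (sx, sy >= 0) of
    the source frame and its intensities transformed by ``gain * v + offset``
    (emulating exposure differences); the anterior part keeps columns up to
    ``sx + overlap_frac * width``.  The returned :class:`ShiftModel` is the
    exact planted registration truth (posterior origin at (sx, sy) in the
    anterior frame).
    """
    if not (0.05 <= overlap_frac <= 0.9):
        raise ValueError("overlap_frac must be in [0.05, 0.9]")
    img = gfp.pixels
    h, w = img.shape
    sx, sy = int(shift[0]), int(shift[1])
    if sx < 0 or sy < 0 or sx >= w - 1 or sy >= h - 1:
        raise ValueError("shift must be non-negative and inside the image")
    if sx == 0:
        sx = int(round(w * (1.0 - overlap_frac) / 2.0 / 16.0) * 16) or 16
    overlap_w = max(1, int(round(overlap_frac * w)))
    xa = min(w, sx + overlap_w)
    anterior = img[:, :xa].copy()
    posterior = img[sy:, sx:].astype(np.float64) * gain + offset
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        posterior = posterior + rng.normal(0.0, noise_sd, posterior.shape)
        anterior = anterior + rng.normal(0.0, noise_sd, anterior.shape)
    anterior = np.clip(anterior, 0.0, None)
    posterior = np.clip(posterior, 0.0, None)
    truth = ShiftModel(sx=sx, sy=sy, gain=gain, offset=offset)
    return (Micrograph(anterior, gfp.channel, f"{gfp.id}-A"),
            Micrograph(posterior, gfp.channel, f"{gfp.id}-P"), truth)


# ---------------------------------------------------------------------------
# Population generation
# ---------------------------------------------------------------------------

@dataclass
class ClassTemplate:
    """Prototype loci and brightness distribution for one worm class."""

    name: str
    loci: list[Locus]
    baseline_mean: float
    baseline_sd: float


#: Pattern classes: Bright has a mid-body locus opposite the vulva plus a
#: pharynx locus; DimA a locus near the head; DimB loci near the tail and
#: (weaker) at mid-body.
DEFAULT_TEMPLATES: dict[str, ClassTemplate] = {
    "Bright": ClassTemplate(
        name="Bright",
        loci=[Locus(axial=0.45, lateral=-0.8, amplitude=1600.0,
                    axial_sigma=0.06, lateral_sigma=0.45),
              Locus(axial=0.10, lateral=0.0, amplitude=900.0,
                    axial_sigma=0.04, lateral_sigma=0.6)],
        baseline_mean=900.0, baseline_sd=60.0),
    "DimA": ClassTemplate(
        name="DimA",
        loci=[Locus(axial=0.08, lateral=0.0, amplitude=420.0,
                    axial_sigma=0.05, lateral_sigma=0.6)],
        baseline_mean=250.0, baseline_sd=20.0),
    "DimB": ClassTemplate(
        name="DimB",
        loci=[Locus(axial=0.90, lateral=0.0, amplitude=420.0,
                    axial_sigma=0.05, lateral_sigma=0.6),
              Locus(axial=0.50, lateral=0.2, amplitude=200.0,
                    axial_sigma=0.07, lateral_sigma=0.5)],
        baseline_mean=250.0, baseline_sd=20.0),
}

POSES = ("straight", "c_shape", "s_shape")


@dataclass
class PopulationSpec:
    """Composition and variability of a synthetic worm population.

    Default counts mirror a post-QC brightness-sorted experiment: 16 Bright,
    22 Dim (11 + 11 across the two dim patterns) and 22 intermediate (All)
    specimens.  ``axial_jitter``/``lateral_jitter`` shift locus positions per
    specimen, ``amplitude_jitter`` scales amplitudes multiplicatively
    (lognormal sigma), emulating inter-individual variation.
    """

    n_bright: int = 16
    n_dimA: int = 11
    n_dimB: int = 11
    n_all: int = 22
    templates: dict[str, ClassTemplate] = field(
        default_factory=lambda: dict(DEFAULT_TEMPLATES))
    axial_jitter: float = 0.02
    lateral_jitter: float = 0.08
    amplitude_jitter: float = 0.15
    noise_sd: float = 15.0
    pattern_noise_sd: float = 12.0
    seed: int = 0


@dataclass
class Specimen:
    """One population member: label, spec, truth pattern, optional render."""

    id: str
    label: str  # Bright | DimA | DimB | All
    spec: WormSpec
    pattern: IntensityImage2D
    rendered: Optional[RenderedWorm] = None


def _jitter_loci(loci: Sequence[Locus], pspec: PopulationSpec,
                 rng: np.random.Generator) -> list[Locus]:
    out = []
    for l in loci:
        out.append(Locus(
            axial=float(np.clip(l.axial + rng.normal(0, pspec.axial_jitter),
                                0.02, 0.98)),
            lateral=float(np.clip(l.lateral + rng.normal(0, pspec.lateral_jitter),
                                  -1.0, 1.0)),
            amplitude=float(l.amplitude * rng.lognormal(0, pspec.amplitude_jitter)),
            axial_sigma=l.axial_sigma,
            lateral_sigma=l.lateral_sigma,
        ))
    return out


def generate_population(pspec: PopulationSpec, render: bool = False
                        ) -> list[Specimen]:
    """Draw a deterministic synthetic population from a population spec.

    Every specimen always carries its noisy 75 x 15 expression pattern (the
    template pattern with per-specimen jitter plus pixel noise, i.e. what a
    perfect segmentation/straightening would measure); with ``render=True``
    full micrographs with ground truth are rasterized as well.

    ``All`` specimens interpolate between the Bright template and one of the
    Dim templates with a uniform mixing weight and intermediate brightness,
    emulating worms sampled from the middle of the brightness range.
    """
    rng = np.random.default_rng(pspec.seed)
    tpl = pspec.templates
    specimens: list[Specimen] = []

    def make_spec(loci, baseline, seed):
        return WormSpec(
            pose=POSES[int(rng.integers(0, len(POSES)))],
            curvature=float(rng.uniform(1.0, 2.2)),
            vulva_side="right" if rng.random() < 0.5 else "left",
            baseline=baseline,
            loci=loci,
            noise_sd=pspec.noise_sd,
            seed=seed,
        )

    def add(label, loci, baseline, tag, k):
        seed = int(rng.integers(0, 2**31 - 1))
        spec = make_spec(loci, baseline, seed)
        pat = truth_pattern(spec)
        if pspec.pattern_noise_sd > 0:
            pat_noise = np.random.default_rng(seed + 7).normal(
                0.0, pspec.pattern_noise_sd, pat.values.shape)
            pat = IntensityImage2D(np.clip(pat.values + pat_noise, 0, None),
                                   id=f"{tag}{k:02d}")
        else:
            pat.id = f"{tag}{k:02d}"
        rendered = render_worm(spec, worm_id=f"{tag}{k:02d}") if render else None
        specimens.append(Specimen(id=f"{tag}{k:02d}", label=label, spec=spec,
                                  pattern=pat, rendered=rendered))

    for k in range(pspec.n_bright):
        t = tpl["Bright"]
        add("Bright", _jitter_loci(t.loci, pspec, rng),
            float(max(rng.normal(t.baseline_mean, t.baseline_sd), 50)), "B", k)
    for k in range(pspec.n_dimA):
        t = tpl["DimA"]
        add("DimA", _jitter_loci(t.loci, pspec, rng),
            float(max(rng.normal(t.baseline_mean, t.baseline_sd), 50)), "DA", k)
    for k in range(pspec.n_dimB):
        t = tpl["DimB"]
        add("DimB", _jitter_loci(t.loci, pspec, rng),
            float(max(rng.normal(t.baseline_mean, t.baseline_sd), 50)), "DB", k)
    for k in range(pspec.n_all):
        alpha = float(rng.uniform(0.25, 0.75))  # mixing toward Bright
        dim = tpl["DimA"] if rng.random() < 0.5 else tpl["DimB"]
        bright = tpl["Bright"]
        loci = ([replace(l, amplitude=l.amplitude * alpha)
                 for l in _jitter_loci(bright.loci, pspec, rng)]
                + [replace(l, amplitude=l.amplitude * (1 - alpha))
                   for l in _jitter_loci(dim.loci, pspec, rng)])
        baseline = (1 - alpha) * dim.baseline_mean + alpha * bright.baseline_mean
        baseline = float(max(rng.normal(baseline, 40.0), 50))
        add("All", loci, baseline, "A", k)
    return specimens
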