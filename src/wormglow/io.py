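"""File formats: micrographs, labeled images, 2D intensity images, results.

* Micrographs: grayscale TIFF (8/12/16 bit) or PNG, read without rescaling
  (12-bit data stored in 16-bit containers keeps its raw counts).
* Labeled images: RGB PNG with the normalized intensity in the green channel
  and the 3-class membership in the blue channel (0 exterior, 128 border,
  255 interior); the raw counts travel in a sibling ``.raw.tif``.
* 2D intensity images: ``.i2d.csv`` (h rows x w columns of raw means) plus a
  ``.i2d.json`` sidecar with specimen id, channel and orientation metadata.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

from .types import (
    Anatomy,
    BORDER,
    Channel,
    EXTERIOR,
    INTERIOR,
    IntensityImage2D,
    LabeledWormImage,
    MEMBERSHIP_PNG_CODES,
    Micrograph,
)

__all__ = [
    "read_micrograph",
    "write_micrograph",
    "write_labeled",
    "read_labeled",
    "write_i2d",
    "read_i2d",
    "dendrogram_to_newick",
]

_PNG_TO_MEMBERSHIP = {v: k for k, v in MEMBERSHIP_PNG_CODES.items()}


def read_micrograph(path: str | Path, channel: Channel = Channel.GFP,
                    id: str | None = None) -> Micrograph:
    """Load a grayscale TIFF/PNG as raw counts (no rescaling)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        a = tifffile.imread(path)
    else:
        a = np.asarray(Image.open(path))
    if a.ndim == 3:  # accept single-channel images stored as RGB
        if not (a[..., 0] == a[..., 1]).all():
            raise ValueError(f"{path} is not a grayscale image")
        a = a[..., 0]
    return Micrograph(pixels=a.astype(np.float64), channel=channel,
                      id=id or path.stem)


def write_micrograph(path: str | Path, img: Micrograph) -> None:
    """Write raw counts to TIFF (16-bit if needed, else 8-bit)."""
    a = np.round(img.pixels)
    dtype = np.uint8 if a.max() <= 255 else np.uint16
    tifffile.imwrite(Path(path), a.astype(dtype))


def write_labeled(path: str | Path, labeled: LabeledWormImage) -> None:
    """Write the labeled image as RGB PNG plus the raw counts and metadata."""
    path = Path(path)
    h, w = labeled.shape
    rgb = np.zeros((h, w, 3), dtype=np.uint8)
    rgb[..., 1] = labeled.green
    code = np.zeros((h, w), dtype=np.uint8)
    for cls, val in MEMBERSHIP_PNG_CODES.items():
        code[labeled.membership == cls] = val
    rgb[..., 2] = code
    Image.fromarray(rgb).save(path)
    tifffile.imwrite(path.with_suffix(".raw.tif"),
                     np.round(labeled.raw).astype(np.uint16))
    meta = {"id": labeled.id, "channel": labeled.channel.name,
            "offset": list(labeled.offset)}
    if labeled.anatomy is not None:
        meta["anatomy"] = {"head": list(labeled.anatomy.head),
                           "tail": list(labeled.anatomy.tail),
                           "vulva_side": labeled.anatomy.vulva_side}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def read_labeled(path: str | Path) -> LabeledWormImage:
    """Read a labeled image written by :func:`write_labeled`."""
    path = Path(path)
    rgb = np.asarray(Image.open(path))
    green = rgb[..., 1]
    membership = np.zeros(green.shape, dtype=np.uint8)
    for val, cls in _PNG_TO_MEMBERSHIP.items():
        membership[rgb[..., 2] == val] = cls
    raw_path = path.with_suffix(".raw.tif")
    raw = tifffile.imread(raw_path).astype(np.float64) if raw_path.exists() \
        else green.astype(np.float64)
    meta_path = path.with_suffix(".json")
    anatomy, wid, channel, offset = None, path.stem, Channel.GFP, (0, 0)
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        wid = meta.get("id", wid)
        channel = Channel[meta.get("channel", "GFP")]
        offset = tuple(meta.get("offset", [0, 0]))
        if "anatomy" in meta:
            a = meta["anatomy"]
            anatomy = Anatomy(head=tuple(a["head"]), tail=tuple(a["tail"]),
                              vulva_side=a["vulva_side"])
    return LabeledWormImage(green=green, membership=membership, raw=raw,
                            channel=channel, id=wid, anatomy=anatomy,
                            offset=offset)


def write_i2d(path: str | Path, img: IntensityImage2D,
              provenance: str = "auto") -> None:
    """Write an intensity image as CSV plus a JSON orientation sidecar."""
    path = Path(path)
    np.savetxt(path, img.values, delimiter=",", fmt="%.6g")
    sidecar = {
        "id": img.id,
        "channel": img.channel.name,
        "orientation": {"row0": "anterior", "last_row": "posterior",
                        "rightmost_column": "vulva side"},
        "anatomy_provenance": provenance,
        "shape": list(img.values.shape),
    }
    sidecar.update(img.meta)
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2, default=str))


def read_i2d(path: str | Path) -> IntensityImage2D:
    path = Path(path)
    values = np.loadtxt(path, delimiter=",", ndmin=2)
    meta_path = Path(str(path) + ".json")
    wid, channel, meta = path.stem, Channel.GFP, {}
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        wid = meta.get("id", wid)
        channel = Channel[meta.get("channel", "GFP")]
    return IntensityImage2D(values=values, channel=channel, id=wid, meta=meta)


def dendrogram_to_newick(dend, confidence=None) -> str:
    """Newick string of a dendrogram, AU/BP as node comments when given."""
    Z = dend.Z
    n = len(Z) + 1
    ids = dend.ids

    conf_by_set = {}
    if confidence is not None:
        for node, bp, au in zip(confidence.nodes, confidence.bp, confidence.au):
            conf_by_set[node] = (bp, au)

    leafsets = {i: frozenset([i]) for i in range(n)}

    def label(k: int, parent_height: float) -> str:
        if k < n:
            return f"{ids[k]}:{parent_height:.6g}"
        i, j, height = int(Z[k - n, 0]), int(Z[k - n, 1]), Z[k - n, 2]
        s = leafsets[k]
        ann = ""
        if s in conf_by_set:
            bp, au = conf_by_set[s]
            ann = f"[&&NHX:AU={au:.1f}:BP={bp:.1f}]"
        return (f"({label(i, height)},{label(j, height)})"
                f"{ann}:{max(parent_height - height, 0.0):.6g}")

    # populate leaf sets bottom-up
    for k, (i, j, *_r) in enumerate(Z):
        leafsets[n + k] = leafsets[int(i)] | leafsets[int(j)]
    root_height = Z[-1, 2]
    return label(2 * n - 2, root_height) + ";"
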