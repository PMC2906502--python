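"""End-to-end orchestration: classify -> mesh -> sample -> cluster -> validate.

A run is driven by a serializable :class:`RunConfig`; every specimen either
produces a 2D intensity image or is quarantined with a reason (QC failures,
unresolved anatomy, segmentation failures) without aborting the run, and the
report records the resolved configuration, a config hash, per-specimen
verdicts and all outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import classify, cluster, io, mesh, sampling
from .errors import WormGlowError
from .types import Anatomy, IntensityImage2D, LabeledWormImage, Micrograph

__all__ = ["RunConfig", "RunReport", "run_pipeline", "load_manual_annotations"]

log = logging.getLogger("wormglow")


@dataclass
class RunConfig:
    """Everything a reproducible pipeline run needs."""

    out_dir: str = "wormglow-out"
    model_path: Optional[str] = None
    height: int = 75
    width: int = 15
    metric: str = "ncc_squared"
    linkage: str = "average"
    n_clusters: int = 3
    n_boot: int = 0
    scales: list = field(default_factory=lambda: list(cluster.DEFAULT_SCALES))
    seed: int = 0
    qc_factor: float = 5.0
    min_overlap: int = mesh.DEFAULT_MIN_OVERLAP
    #: specimen id -> {"head": [x,y], "tail": [x,y], "vulva_side": str}
    manual_annotations: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml
            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls(**data)


def load_manual_annotations(path: str | Path) -> dict:
    """CSV override file: specimen_id,head_x,head_y,tail_x,tail_y,vulva_side."""
    import csv

    out = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out[row["specimen_id"]] = {
                "head": [int(row["head_x"]), int(row["head_y"])],
                "tail": [int(row["tail_x"]), int(row["tail_y"])],
                "vulva_side": row["vulva_side"],
            }
    return out


@dataclass
class RunReport:
    config: dict
    config_hash: str
    processed: list = field(default_factory=list)
    excluded: list = field(default_factory=list)  # (id, reason)
    outputs: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps({
            "config": self.config, "config_hash": self.config_hash,
            "processed": self.processed, "excluded": self.excluded,
            "outputs": self.outputs,
        }, indent=2, default=str)

    def to_text(self) -> str:
        lines = [f"wormglow run {self.config_hash}",
                 f"processed: {len(self.processed)} specimens"]
        for sid, reason in self.excluded:
            lines.append(f"excluded {sid}: {reason}")
        for k, v in self.outputs.items():
            lines.append(f"{k}: {v}")
        return "\n".join(lines)


def _apply_annotation(labeled: LabeledWormImage, override: dict) -> None:
    labeled.anatomy = Anatomy(head=tuple(override["head"]),
                              tail=tuple(override["tail"]),
                              vulva_side=override["vulva_side"])


def run_pipeline(config: RunConfig, specimens: list[dict],
                 model: Optional[classify.PixelModel] = None) -> RunReport:
    """Process a specimen list end to end.

    Each specimen dict has an ``id`` plus either ``image`` (one whole-worm
    :class:`Micrograph`) or ``anterior``/``posterior`` (a pair to be meshed).
    Per-specimen failures quarantine the specimen with a reason; the run
    never aborts.  When at least two intensity images survive, they are
    clustered and the dendrogram/matrix outputs are written to ``out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=config.to_dict(), config_hash=config.config_hash())
    if model is None:
        if config.model_path is None:
            raise WormGlowError("a pixel model is required (model_path)")
        model = classify.PixelModel.from_json(config.model_path)

    images: list[IntensityImage2D] = []
    for spec in specimens:
        sid = spec["id"]
        try:
            if "image" in spec:
                labeled = classify.classify_worm(spec["image"], model)
                labeled.id = sid
            else:
                la = classify.classify_worm(spec["anterior"], model)
                lp = classify.classify_worm(spec["posterior"], model)
                result = mesh.mesh(la, lp, min_overlap=config.min_overlap,
                                   qc_factor=config.qc_factor)
                if not result.qc_passed:
                    report.excluded.append(
                        (sid, "overlap-intensity-mismatch "
                              f"(factor {result.qc_overlap_ratio:.2f} > "
                              f"{config.qc_factor})"))
                    continue
                labeled = result.labeled
                labeled.id = sid
            if sid in config.manual_annotations:
                _apply_annotation(labeled, config.manual_annotations[sid])
            elif "anatomy" in spec:
                labeled.anatomy = spec["anatomy"]
            img2d = sampling.sample_intensity_image(
                labeled, h=config.height, w=config.width)
            img2d.id = sid
            path = out / f"{sid}.i2d.csv"
            io.write_i2d(path, img2d,
                         provenance="manual" if sid in config.manual_annotations
                         else "auto")
            images.append(img2d)
            report.processed.append(sid)
            report.outputs[f"i2d/{sid}"] = str(path)
        except WormGlowError as exc:
            log.warning("specimen %s quarantined: %s", sid, exc)
            report.excluded.append((sid, f"{type(exc).__name__}: {exc}"))

    if len(images) >= 2:
        pc = cluster.PatternClustering(
            metric=config.metric, linkage=config.linkage,
            n_clusters=config.n_clusters, n_boot=config.n_boot,
            scales=tuple(config.scales), seed=config.seed).fit(images)
        pc.dendrogram_.ids = [i.id for i in images]
        np.savetxt(out / "distance_matrix.csv", pc.distance_matrix_,
                   delimiter=",", fmt="%.6g",
                   header=",".join(i.id for i in images))
        newick = io.dendrogram_to_newick(
            pc.dendrogram_, getattr(pc, "confidence_", None))
        (out / "dendrogram.nwk").write_text(newick)
        labels = {img.id: int(l) for img, l in zip(images, pc.labels_)}
        (out / "clusters.json").write_text(json.dumps(labels, indent=2))
        report.outputs["distance_matrix"] = str(out / "distance_matrix.csv")
        report.outputs["dendrogram"] = str(out / "dendrogram.nwk")
        report.outputs["clusters"] = str(out / "clusters.json")
        report.outputs["n_clusters_found"] = len(set(labels.values()))

    (out / "report.json").write_text(report.to_json())
    (out / "report.txt").write_text(report.to_text())
    return report
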