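"""Shared fixtures: synthetic worms and a session-wide trained pixel model."""

from __future__ import annotations

import numpy as np
import pytest

from wormglow import classify, synth


def make_disk(radius: int, pad: int = 3) -> np.ndarray:
    n = 2 * (radius + pad) + 1
    c = radius + pad
    yy, xx = np.mgrid[0:n, 0:n]
    return (xx - c) ** 2 + (yy - c) ** 2 <= radius**2


@pytest.fixture(scope="session")
def training_worms():
    """Eight rendered worms with ground-truth masks (training set size as in
    a typical manual-labeling bootstrap)."""
    specs = [
        synth.WormSpec(pose=pose, curvature=curv, seed=seed, vulva_side=side,
                       loci=[synth.Locus(0.5, 0.0, 500.0)])
        for pose, curv, side, seed in [
            ("straight", 0.0, "right", 101),
            ("c_shape", 1.2, "right", 102),
            ("c_shape", 1.8, "left", 103),
            ("s_shape", 1.5, "right", 104),
            ("straight", 0.0, "left", 105),
            ("c_shape", 1.5, "right", 106),
            ("s_shape", 1.2, "left", 107),
            ("c_shape", 2.0, "right", 108),
        ]
    ]
    return [synth.render_worm(s, worm_id=f"train{i}") for i, s in enumerate(specs)]


@pytest.fixture(scope="session")
def pixel_model(training_worms):
    clf = classify.WormPixelClassifier().fit(
        [w.gfp for w in training_worms],
        [w.truth_mask for w in training_worms])
    return clf.to_pixel_model()
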