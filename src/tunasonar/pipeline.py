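"""End-to-end convenience layer: rendered scene -> labelled feature table.

Chains preprocessing, segmentation and morphology over synthetic scenes,
assigning each recovered blob the class of the ground-truth instance it
overlaps.  This is the path used to study how well the classification
protocol recovers the generator's configured tuna/clutter separation.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import synthgen
from .balance import NEGATIVE_CLASS, TrainingTable
from .morphfeatures import compute_features
from .preprocess import clean_frame
from .segment import binarize, filter_blobs, label_blobs

log = logging.getLogger(__name__)


def extract_blob_rows(cfg, image, gt, min_area: int = 100,
                      id_prefix: str = "scene") -> list[dict]:
    """Run preprocess -> segment -> features on one rendered scene and
    label each recovered blob by majority overlap with the ground truth."""
    frame = synthgen.make_frame(cfg, image, frame_id=id_prefix)
    region = clean_frame(frame)
    blobs = filter_blobs(
        label_blobs(binarize(region, "auto"), id_prefix=f"{id_prefix}_"),
        min_area)
    x0, y0 = region.origin
    rows = []
    for blob in blobs:
        px = blob.pixels + np.array([x0, y0])
        vals = gt.labels[px[:, 1], px[:, 0]]
        vals = vals[vals > 0]
        label = NEGATIVE_CLASS
        if len(vals):
            label = gt.blobs[int(np.bincount(vals).argmax()) - 1][1]
        rows.append(compute_features(blob, label).as_dict())
    return rows


def simulate_survey(n_scenes: int, seed: int = 0, tuna_prob: float = 0.5,
                    noise_level: float = 0.3,
                    tuna_params=None, clutter_params=None,
                    min_area: int = 100) -> TrainingTable:
    """Render ``n_scenes`` sonar scenes (alternating black/blue backgrounds,
    surface noise on) and return the labelled blob feature table produced
    by the full pipeline."""
    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    for i in range(n_scenes):
        scene_seed = int(rng.integers(2 ** 31))
        cfg = synthgen.SceneConfig(
            background_style="black" if i % 2 == 0 else "blue",
            surface_noise_level=noise_level, seed=scene_seed)
        specs = []
        if rng.random() < tuna_prob:
            specs += synthgen.sample_blob_specs(
                synthgen.TUNA, int(rng.integers(1, 3)),
                morphology_params=tuna_params, seed=scene_seed, config=cfg)
        specs += synthgen.sample_blob_specs(
            synthgen.NO_TUNA, int(rng.integers(2, 5)),
            morphology_params=clutter_params, seed=scene_seed + 1,
            config=cfg, existing=specs)
        image, gt = synthgen.render_scene(cfg, specs)
        rows.extend(extract_blob_rows(cfg, image, gt, min_area,
                                      id_prefix=f"scene{i:04d}"))
    return TrainingTable(pd.DataFrame(rows))
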