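"""Shared fixtures: synthetic sections and the standard analysis pipeline.

The expensive session-scoped fixtures render one clean (jitter-free,
noise-free) section of ~100 lobules and run the centroid pipeline on it
once; many tests read off different aspects of the same run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

import lobulizer as lb
from lobulizer.synthetic import SyntheticConfig, generate_tissue


@pytest.fixture(scope="session")
def clean_gt():
    """Clean hex-lattice section, ~100 lobules, zero jitter/noise."""
    return generate_tissue(SyntheticConfig.clean(rng_seed=1, image_size=(1280, 1280)))


@dataclass
class PipelineRun:
    gt: object
    mask: object
    comps: object
    tessellation: object
    pred_labels: np.ndarray
    zones: list
    per_lobule_overlap: list
    mean_overlap: float
    report: object


@pytest.fixture(scope="session")
def clean_pipeline(clean_gt) -> PipelineRun:
    """Centroid method + zonation + scoring on the clean section."""
    cfg = clean_gt.config
    mask = lb.despeckle(lb.threshold_marker(clean_gt.image, cfg.scale))
    comps = lb.connected_components(mask, 50)
    tess = lb.centroid_method(mask, 50)
    pred = lb.rasterize_tessellation(tess, clean_gt.image.shape)
    per, mean = lb.lobule_overlap(pred, clean_gt.true_lobule_labels)
    zones = lb.zonate_tessellation(tess, mask, region_labels=pred)
    report = lb.zonal_accuracy(zones, clean_gt.annotations, mask)
    return PipelineRun(clean_gt, mask, comps, tess, pred, zones, per, mean, report)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_blob_mask(rng, shape=(128, 128), n_blobs=10, r_range=(4, 9)):
    """Non-overlapping random discs: a stand-in segmented marker mask."""
    grid = np.zeros(shape, dtype=bool)
    centers = []
    tries = 0
    while len(centers) < n_blobs and tries < 2000:
        tries += 1
        r = rng.uniform(*r_range)
        x = rng.uniform(r + 1, shape[1] - r - 1)
        y = rng.uniform(r + 1, shape[0] - r - 1)
        if any(np.hypot(x - cx, y - cy) < r + cr + 3 for cx, cy, cr in centers):
            continue
        centers.append((x, y, r))
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
        grid |= (xx - x) ** 2 + (yy - y) ** 2 <= r**2
    return grid, centers
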