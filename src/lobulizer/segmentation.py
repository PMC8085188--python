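"""Raster preprocessing of marker immunostain images.

Mirrors the classic ImageJ workflow for extracting glutamine-synthetase
(GS) positive perivenular areas: 8-bit conversion, iterative-intermeans
(isodata) thresholding, 3x3 median despeckling, 8-connected particle
analysis with centroid extraction.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_isodata

__all__ = [
    "BinaryMask",
    "ComponentSet",
    "threshold_marker",
    "despeckle",
    "connected_components",
    "load_annotations",
]

_CONN8 = np.ones((3, 3), dtype=int)


@dataclass
class BinaryMask:
    """Boolean raster (True = marker-positive) with its physical scale."""

    grid: np.ndarray
    scale: float = 1.0  # µm per pixel

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=bool)

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape


@dataclass
class ComponentSet:
    """8-connected foreground particles of a mask.

    ``labels`` is an integer raster (0 = background, particles numbered
    1..n contiguously); ``components`` holds (label, pixel_count,
    centroid) with the centroid as (x, y) mean of member pixel centers.
    """

    labels: np.ndarray
    components: list[tuple[int, int, tuple[float, float]]] = field(default_factory=list)
    scale: float = 1.0

    def __len__(self) -> int:
        return len(self.components)

    @property
    def centroids(self) -> np.ndarray:
        """(n, 2) array of (x, y) centroids in component-label order."""
        if not self.components:
            return np.empty((0, 2))
        return np.array([c for _, _, c in self.components])


def to_uint8(image: np.ndarray) -> np.ndarray:
    """Rescale an arbitrary grayscale raster to 8 bit (min→0, max→255)."""
    img = np.asarray(image, dtype=float)
    lo, hi = float(img.min()), float(img.max())
    if hi == lo:
        raise ValueError("constant image: no threshold exists")
    return np.round((img - lo) * (255.0 / (hi - lo))).astype(np.uint8)


def threshold_marker(
    image: np.ndarray, scale: float = 1.0, marker_polarity: str = "bright"
) -> BinaryMask:
    """Binarize a marker image by the iterative-intermeans (isodata) threshold.

    The image is first rescaled to 8 bit, then the threshold is computed
    on its 256-bin histogram.  ``marker_polarity`` selects which side is
    marker-positive: "bright" (synthetic renderings, fluorescence) keeps
    pixels above the threshold; "dark" (brightfield DAB, where stain
    absorbs light) keeps pixels at or below it.
    """
    if marker_polarity not in ("bright", "dark"):
        raise ValueError(f"unknown marker polarity {marker_polarity!r}")
    img8 = to_uint8(image)
    thresh = threshold_isodata(img8, nbins=256)
    fg = img8 > thresh if marker_polarity == "bright" else img8 <= thresh
    return BinaryMask(fg, scale)


def despeckle(mask: BinaryMask) -> BinaryMask:
    """One pass of a 3x3 median filter (border pixels use edge replication).

    Removes salt-and-pepper noise: an isolated foreground pixel vanishes,
    a solid block survives.  Idempotent only on already-smooth masks.
    """
    filtered = ndimage.median_filter(
        mask.grid.astype(np.uint8), size=3, mode="nearest"
    ).astype(bool)
    return BinaryMask(filtered, mask.scale)


def connected_components(mask: BinaryMask, min_area_px: int = 50) -> ComponentSet:
    """8-connected particle analysis with a minimum-size floor.

    Particles smaller than ``min_area_px`` pixels are discarded (a
    denoising floor below any plausible GS-positive perivenular area);
    surviving particles are relabeled 1..n in scan order.  An empty mask
    yields an empty ComponentSet.
    """
    raw, n = ndimage.label(mask.grid, structure=_CONN8)
    if n == 0:
        return ComponentSet(np.zeros_like(raw, dtype=np.int32), [], mask.scale)
    counts = np.bincount(raw.ravel())
    keep = [lab for lab in range(1, n + 1) if counts[lab] >= min_area_px]
    labels = np.zeros_like(raw, dtype=np.int32)
    components = []
    for new, old in enumerate(keep, start=1):
        sel = raw == old
        labels[sel] = new
        ys, xs = np.nonzero(sel)
        components.append((new, int(counts[old]), (float(xs.mean()), float(ys.mean()))))
    return ComponentSet(labels, components, mask.scale)


def load_annotations(
    path: str | Path,
    image_shape: tuple[int, int] | None = None,
    septa_mask: "BinaryMask | None" = None,
):
    """Read portal-tract / central-vein point annotations from CSV or GeoJSON.

    CSV dialect: comma-separated, UTF-8, header ``kind,x,y`` with kind in
    {portal_tract, central_vein}.  GeoJSON: Point features with a ``kind``
    property.  Points are validated against ``image_shape`` (rows, cols)
    when given; violations report the offending row.
    """
    from .metrics import AnnotationSet  # AnnotationSet lives with the scoring code

    path = Path(path)
    pts: dict[str, list[tuple[float, float]]] = {"portal_tract": [], "central_vein": []}

    def _add(kind: str, x: float, y: float, where: str) -> None:
        if kind not in pts:
            raise ValueError(f"unknown annotation kind {kind!r} at {where}")
        if image_shape is not None:
            rows, cols = image_shape
            if not (0 <= x < cols and 0 <= y < rows):
                raise ValueError(
                    f"point ({x}, {y}) at {where} lies outside image bounds "
                    f"{cols}x{rows}"
                )
        pts[kind].append((x, y))

    if path.suffix.lower() in (".geojson", ".json"):
        payload = json.loads(path.read_text())
        for i, feat in enumerate(payload.get("features", [])):
            kind = feat.get("properties", {}).get("kind", "")
            x, y = feat["geometry"]["coordinates"]
            _add(kind, float(x), float(y), f"feature {i}")
    else:
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None:  # empty file
                rows = []
            else:
                rows = list(reader)
            for i, row in enumerate(rows, start=2):  # header is line 1
                _add(row["kind"], float(row["x"]), float(row["y"]), f"row {i}")

    return AnnotationSet(
        portal_tracts=np.array(pts["portal_tract"]).reshape(-1, 2),
        central_veins=np.array(pts["central_vein"]).reshape(-1, 2),
        septa_mask=septa_mask,
    )


def save_annotations(ann, path: str | Path) -> None:
    """Write an AnnotationSet's points back to the CSV dialect above."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["kind", "x", "y"])
        for x, y in np.atleast_2d(ann.portal_tracts).reshape(-1, 2):
            writer.writerow(["portal_tract", repr(float(x)), repr(float(y))])
        for x, y in np.atleast_2d(ann.central_veins).reshape(-1, 2):
            writer.writerow(["central_vein", repr(float(x)), repr(float(y))])
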