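"""File formats: GeoJSON regions, PNG rasters, CSV tables, JSON reports.

GeoJSON coordinates are pixel coordinates (x right, y down); the physical
scale travels in feature properties as ``scale_um_per_px``.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .geometry import PolygonRegion, Tessellation
from .methods import LabelPartition
from .zonation import ZonePartition

__all__ = [
    "load_image",
    "save_mask_png",
    "load_mask_png",
    "save_label_png",
    "load_label_png",
    "save_tessellation_geojson",
    "load_tessellation_geojson",
    "save_zone_raster_png",
    "save_morphometry_csv",
    "write_report",
    "read_report",
]

ZONE_PNG_VALUES = {0: 0, 1: 85, 2: 170, 3: 255}


def load_image(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF image as 2D grayscale (RGB collapsed by luminance)."""
    img = np.asarray(iio.imread(path))
    if img.ndim == 3:
        img = img[..., :3] @ np.array([0.2126, 0.7152, 0.0722])
    return img


def save_mask_png(mask, path: str | Path) -> None:
    grid = mask.grid if hasattr(mask, "grid") else np.asarray(mask, bool)
    iio.imwrite(path, (grid.astype(np.uint8) * 255))


def load_mask_png(path: str | Path, scale: float = 1.0):
    from .segmentation import BinaryMask

    return BinaryMask(load_image(path) > 127, scale)


def save_label_png(labels: np.ndarray, path: str | Path) -> None:
    """Label raster as 16-bit grayscale PNG (labels must fit in uint16)."""
    arr = np.asarray(labels)
    if arr.max(initial=0) > np.iinfo(np.uint16).max:
        raise ValueError("labels exceed the 16-bit PNG range")
    iio.imwrite(path, arr.astype(np.uint16))


def load_label_png(path: str | Path) -> np.ndarray:
    return np.asarray(iio.imread(path)).astype(np.int32)


def save_label_partition(part: LabelPartition, path_png: str | Path,
                         path_json: str | Path) -> None:
    """LabelPartition = 16-bit label raster + JSON generator table."""
    save_label_png(part.labels, path_png)
    table = {
        "scale_um_per_px": part.scale,
        "generators": [
            {"label": lab, "pixel_count": n, "centroid": [cx, cy]}
            for lab, n, (cx, cy) in part.generators.components
        ],
    }
    Path(path_json).write_text(json.dumps(table, indent=2, sort_keys=True))


def save_tessellation_geojson(t: Tessellation, path: str | Path) -> None:
    features = []
    for r in t.regions:
        features.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "Polygon",
                    "coordinates": [
                        [[float(x), float(y)] for x, y in r.vertices]
                        + [[float(r.vertices[0, 0]), float(r.vertices[0, 1])]]
                    ],
                },
                "properties": {
                    "region_id": int(r.region_id),
                    "site": [float(r.site[0]), float(r.site[1])],
                    "scale_um_per_px": float(t.scale),
                },
            }
        )
    payload = {
        "type": "FeatureCollection",
        "bbox_px": [0.0, 0.0, float(t.width), float(t.height)],
        "features": features,
    }
    Path(path).write_text(json.dumps(payload, sort_keys=True))


def load_tessellation_geojson(path: str | Path) -> Tessellation:
    payload = json.loads(Path(path).read_text())
    regions = []
    sites = []
    scale = 1.0
    for feat in payload["features"]:
        props = feat["properties"]
        ring = np.asarray(feat["geometry"]["coordinates"][0][:-1], dtype=float)
        site = np.asarray(props["site"], dtype=float)
        scale = float(props.get("scale_um_per_px", 1.0))
        regions.append(PolygonRegion(ring, site, int(props["region_id"])))
        sites.append(site)
    regions.sort(key=lambda r: r.region_id)
    sites = np.array([r.site for r in regions])
    w, h = payload.get("bbox_px", [0, 0, 0, 0])[2:]
    return Tessellation((w, h), sites, regions, scale)


def save_zone_raster_png(zone_map: np.ndarray, path: str | Path) -> None:
    """Zone map as 8-bit PNG: 0/85/170/255 for outside/zone1/zone2/zone3."""
    out = np.zeros_like(zone_map, dtype=np.uint8)
    for zone, value in ZONE_PNG_VALUES.items():
        out[zone_map == zone] = value
    iio.imwrite(path, out)


def save_zone3_geojson(zones: list[ZonePartition], scale: float,
                       path: str | Path) -> None:
    features = [
        {
            "type": "Feature",
            "geometry": {
                "type": "Polygon",
                "coordinates": [
                    [[float(x), float(y)] for x, y in zp.zone3_vertices]
                    + [[float(zp.zone3_vertices[0, 0]), float(zp.zone3_vertices[0, 1])]]
                ],
            },
            "properties": {
                "region_id": int(zp.region_id),
                "chosen_scale": float(zp.chosen_scale),
                "scale_um_per_px": float(scale),
            },
        }
        for zp in zones
    ]
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features}, sort_keys=True)
    )


def save_morphometry_csv(df, path: str | Path) -> None:
    cols = ["region_id", "side_count", "area_mm2", "circumcircle_diameter_mm",
            "centroid_x", "centroid_y"]
    df.to_csv(path, index=False, columns=cols)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_report(report, path: str | Path, display_decimals: int = 1) -> None:
    """Write a report (AccuracyReport or plain dict) as stable-key JSON.

    Floats are emitted at full precision; a parallel ``display`` block
    carries rounded values for human reading.
    """
    data = report.to_dict() if hasattr(report, "to_dict") else dict(report)
    data = _jsonable(data)
    display = {
        k: (round(v, display_decimals) if isinstance(v, float) else v)
        for k, v in data.items()
        if not isinstance(v, (dict, list))
    }
    data["display"] = display
    Path(path).write_text(json.dumps(data, indent=2, sort_keys=True))


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
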