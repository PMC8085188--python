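"""Accuracy scoring and lobular morphometrics.

Two accuracy notions, matching how lobule models are validated:

* septal overlap (pig) — per-lobule area overlap between predicted
  regions and ground-truth lobule labels, since pig lobule boundaries
  are visible as interlobular septa;
* zonal landmark accuracy (human) — the fraction of portal tracts
  falling in zone 1 and of GS-positive area falling in zone 3, since
  human lobule boundaries leave no histologic trace.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely

from .geometry import (
    MorphometryRecord,
    Tessellation,
    min_enclosing_circle_diameter,
    polygon_area,
    rasterize_polygons,
    side_count,
)
from .methods import LabelPartition
from .segmentation import BinaryMask, ComponentSet
from .zonation import ZonePartition, combine_zone_rasters

__all__ = [
    "AnnotationSet",
    "AccuracyReport",
    "SpecialLobules",
    "lobule_overlap",
    "zonal_accuracy",
    "morphometry_report",
    "shape_histogram",
    "flag_special_lobules",
]


@dataclass
class AnnotationSet:
    """Histologic landmark annotations for one tissue section."""

    portal_tracts: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    central_veins: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    septa_mask: BinaryMask | None = None
    true_lobule_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.portal_tracts = np.asarray(self.portal_tracts, float).reshape(-1, 2)
        self.central_veins = np.asarray(self.central_veins, float).reshape(-1, 2)


@dataclass
class AccuracyReport:
    per_lobule_overlap: list[float] | None = None
    mean_overlap: float | None = None
    pct_pt_zone1: float | None = None
    pct_gs_zone3: float | None = None
    total_accuracy: float | None = None
    counts: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "mean_overlap": self.mean_overlap,
            "pct_pt_zone1": self.pct_pt_zone1,
            "pct_gs_zone3": self.pct_gs_zone3,
            "total_accuracy": self.total_accuracy,
            "counts": dict(self.counts),
            "warnings": list(self.warnings),
            "per_lobule_overlap": self.per_lobule_overlap,
        }


def _prediction_labels(pred, shape: tuple[int, int]) -> np.ndarray:
    if isinstance(pred, Tessellation):
        return rasterize_polygons(pred, shape)
    if isinstance(pred, LabelPartition):
        return pred.labels
    return np.asarray(pred)


def lobule_overlap(
    pred, truth_labels: np.ndarray, overlap_def: str = "iou"
) -> tuple[list[float], float]:
    """Per-lobule and mean surface-overlap percentage against truth labels.

    Each true lobule is matched to the predicted region with which it
    shares the largest pixel intersection (greedy over all pairs in
    descending intersection size, ties to the lower ids; every predicted
    region is consumed by at most one lobule).  The per-lobule score is
    100·|R∩L|/|R∪L| by default, or 100·|R∩L|/|L| with
    ``overlap_def="intersection-over-truth"``; the mean is unweighted
    across lobules.  ``pred`` may be a Tessellation, LabelPartition, or
    a label raster; zero pixels in ``truth_labels`` are ignored.
    """
    if overlap_def not in ("iou", "intersection-over-truth"):
        raise ValueError(f"unknown overlap definition {overlap_def!r}")
    truth = np.asarray(truth_labels)
    if not np.any(truth > 0):
        raise ValueError("empty truth labeling")
    labels = _prediction_labels(pred, truth.shape)
    if labels.shape != truth.shape:
        raise ValueError("prediction and truth rasters differ in shape")

    true_ids = np.unique(truth[truth > 0])
    pred_ids = np.unique(labels[labels > 0])
    t_index = {v: i for i, v in enumerate(true_ids)}
    p_index = {v: i for i, v in enumerate(pred_ids)}
    inter = np.zeros((len(true_ids), len(pred_ids)), dtype=np.int64)
    sel = (truth > 0) & (labels > 0)
    pair, counts = np.unique(
        np.stack([truth[sel], labels[sel]]), axis=1, return_counts=True
    )
    for (tv, pv), c in zip(pair.T, counts):
        inter[t_index[tv], p_index[pv]] = c
    t_sizes = np.array([np.count_nonzero(truth == v) for v in true_ids])
    p_sizes = np.array([np.count_nonzero(labels == v) for v in pred_ids])

    order = sorted(
        ((int(inter[i, j]), i, j) for i in range(len(true_ids)) for j in range(len(pred_ids))
         if inter[i, j] > 0),
        key=lambda x: (-x[0], x[1], x[2]),
    )
    match: dict[int, int] = {}
    used_pred: set[int] = set()
    for _, i, j in order:
        if i in match or j in used_pred:
            continue
        match[i] = j
        used_pred.add(j)

    scores: list[float] = []
    for i in range(len(true_ids)):
        if i not in match:
            scores.append(0.0)
            continue
        j = match[i]
        ij = float(inter[i, j])
        if overlap_def == "iou":
            scores.append(100.0 * ij / float(t_sizes[i] + p_sizes[j] - ij))
        else:
            scores.append(100.0 * ij / float(t_sizes[i]))
    return scores, float(np.mean(scores))


def zonal_accuracy(
    zones: list[ZonePartition] | np.ndarray,
    ann: AnnotationSet,
    gs_mask: BinaryMask,
) -> AccuracyReport:
    """Score zonation against portal-tract and GS landmarks.

    pct_pt_zone1: portal tracts whose pixel is labeled zone 1, among
    portal tracts in the zoned area.  pct_gs_zone3: GS-positive pixels
    labeled zone 3, among GS-positive pixels in the zoned area.  Total
    accuracy is the unweighted mean of the two; with no portal tracts the
    PT term is reported missing and the total falls back to the GS term.
    """
    shape = gs_mask.shape
    zone_map = (
        combine_zone_rasters(zones, shape) if isinstance(zones, list) else np.asarray(zones)
    )
    report = AccuracyReport()

    pts = ann.portal_tracts
    n_pt_covered = 0
    n_pt_zone1 = 0
    for x, y in pts:
        r = min(max(int(round(y)), 0), shape[0] - 1)
        c = min(max(int(round(x)), 0), shape[1] - 1)
        z = zone_map[r, c]
        if z > 0:
            n_pt_covered += 1
            n_pt_zone1 += int(z == 1)
    if n_pt_covered:
        report.pct_pt_zone1 = 100.0 * n_pt_zone1 / n_pt_covered
    else:
        report.warnings.append("no portal tracts in zoned area; PT accuracy undefined")
        warnings.warn(report.warnings[-1], stacklevel=2)

    gs_cov = gs_mask.grid & (zone_map > 0)
    n_gs = int(np.count_nonzero(gs_cov))
    if n_gs:
        report.pct_gs_zone3 = 100.0 * int(np.count_nonzero(gs_cov & (zone_map == 3))) / n_gs

    terms = [v for v in (report.pct_pt_zone1, report.pct_gs_zone3) if v is not None]
    report.total_accuracy = float(np.mean(terms)) if terms else None
    report.counts = {"portal_tracts": int(len(pts)), "portal_tracts_covered": n_pt_covered,
                     "gs_positive_px": n_gs, "lobules": len(np.unique(zone_map)) - 1}
    return report


def morphometry_report(
    t: Tessellation,
    scale: float | None = None,
    angle_tol: float = 10.0,
    merge_dist: float = 2.0,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Per-region morphometry, side-count histogram, and summary stats.

    Returns (records, histogram, summary): ``records`` has one row per
    region with the CSV-ready columns; ``histogram`` tabulates region
    shapes with percentage shares; ``summary`` carries mean/SD area and
    mean/median circumcircle diameter in mm-based units (raw floats —
    display rounding is the caller's business).
    """
    scale = t.scale if scale is None else scale
    records = [
        MorphometryRecord(
            region_id=r.region_id,
            side_count=side_count(r, angle_tol, merge_dist),
            area_mm2=polygon_area(r, scale),
            circumcircle_diameter_mm=min_enclosing_circle_diameter(r, scale),
            centroid=tuple(r.centroid()),
        )
        for r in t.regions
    ]
    df = pd.DataFrame(
        {
            "region_id": [m.region_id for m in records],
            "side_count": [m.side_count for m in records],
            "area_mm2": [m.area_mm2 for m in records],
            "circumcircle_diameter_mm": [m.circumcircle_diameter_mm for m in records],
            "centroid_x": [m.centroid[0] for m in records],
            "centroid_y": [m.centroid[1] for m in records],
        }
    )
    hist = shape_histogram(df["side_count"].tolist())
    if len(df):
        summary = {
            "n_regions": len(df),
            "area_mean_mm2": float(df["area_mm2"].mean()),
            "area_sd_mm2": float(df["area_mm2"].std(ddof=1)) if len(df) > 1 else 0.0,
            "circumcircle_diameter_mean_mm": float(df["circumcircle_diameter_mm"].mean()),
            "circumcircle_diameter_median_mm": float(
                df["circumcircle_diameter_mm"].median()
            ),
        }
    else:
        summary = {"n_regions": 0, "area_mean_mm2": 0.0, "area_sd_mm2": 0.0,
                   "circumcircle_diameter_mean_mm": 0.0,
                   "circumcircle_diameter_median_mm": 0.0}
    return df, hist, summary


_SHAPE_NAMES = {3: "triangle", 4: "quadrilateral", 5: "pentagon", 6: "hexagon",
                7: "heptagon", 8: "octagon", 9: "nonagon", 10: "decagon"}


def shape_histogram(side_counts: list[int]) -> pd.DataFrame:
    """Tabulate polygon shapes with counts and percentage shares."""
    counts = pd.Series(side_counts).value_counts().sort_index()
    total = int(counts.sum())
    return pd.DataFrame(
        {
            "side_count": counts.index,
            "shape": [_SHAPE_NAMES.get(int(k), f"{int(k)}-gon") for k in counts.index],
            "count": counts.values,
            "pct": 100.0 * counts.values / total,
        }
    ).reset_index(drop=True)


@dataclass
class SpecialLobules:
    """Compound and small/tangential lobule regions of a tessellation."""

    compound_ids: list[int]
    small_ids: list[int]
    compound_fraction: float
    small_fraction: float


def flag_special_lobules(
    t: Tessellation, gs: ComponentSet, small_quantile: float = 0.05
) -> SpecialLobules:
    """Flag compound lobules and small/tangential cross-sections.

    Compound: regions containing two or more GS particle centroids
    (several central-vein profiles in one lobule profile) — evaluated
    before any splitting.  Small: regions whose area falls below the
    ``small_quantile`` area quantile, or that contain no GS centroid at
    all (a tangential cut misses the perivenular core).  Fractions are
    over all regions.
    """
    centroids = gs.centroids
    areas = np.array([r.polygon.area for r in t.regions])
    cutoff = float(np.quantile(areas, small_quantile)) if len(areas) else 0.0
    compound, small = [], []
    for r, area in zip(t.regions, areas):
        if len(centroids):
            inside = shapely.contains_xy(r.polygon, centroids[:, 0], centroids[:, 1])
            n_inside = int(np.count_nonzero(inside))
        else:
            n_inside = 0
        if n_inside >= 2:
            compound.append(r.region_id)
        if area < cutoff or n_inside == 0:
            small.append(r.region_id)
    n = max(len(t.regions), 1)
    return SpecialLobules(compound, small, len(compound) / n, len(small) / n)
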