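"""The five routes from a marker image to a lobule tessellation.

1. seeded (``seeded_method``): Voronoi diagram of user-supplied central-vein
   sites.  The historical workflow placed and nudged these points
   interactively; here the human loop is externalized — sites come from a
   file and the diagram is recomputed on each edit.
2. centroid (``centroid_method``): Voronoi diagram of the centroids of the
   segmented GS-positive particles.
3. object edge (``object_edge_method``): generalized Voronoi-like partition
   where every pixel joins the particle whose *boundary* (pixel set) is
   nearest, not whose centroid is.
4. modified object edge (``modified_object_edge_method``): the same
   computation run on a curated annotation mask instead of the raw
   threshold output.
5. algorithm (``algorithm_method``): centroid diagram, then compound-region
   splitting, then landmark-constrained refinement of vertices with a
   per-region mismatch bound.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy import ndimage
from shapely import affinity
from shapely.geometry import Polygon, box
from shapely.geometry.polygon import orient

from .geometry import PolygonRegion, Tessellation, voronoi_partition
from .segmentation import BinaryMask, ComponentSet, connected_components

__all__ = [
    "LabelPartition",
    "RefinementResult",
    "seeded_method",
    "centroid_method",
    "object_edge_method",
    "modified_object_edge_method",
    "refine_to_landmarks",
    "split_compound_regions",
    "algorithm_method",
]


@dataclass
class LabelPartition:
    """Pixel-level partition by nearest object boundary.

    ``labels[r, c]`` is the generator whose pixel set is nearest to
    (c, r) (ties to the lowest label); generator pixels keep their own
    label.  Zero never appears: every pixel belongs to some generator.
    """

    labels: np.ndarray
    generators: ComponentSet
    scale: float = 1.0


@dataclass
class RefinementResult:
    """A refined tessellation plus the diagnostics of the refinement."""

    tessellation: Tessellation
    per_region_mismatch: list[float] = field(default_factory=list)
    moves_applied: list[tuple[tuple[float, float], tuple[float, float]]] = field(
        default_factory=list
    )


def seeded_method(
    sites: np.ndarray, bbox: tuple[float, float], scale: float = 1.0
) -> Tessellation:
    """Voronoi diagram of explicitly supplied central-vein sites."""
    return voronoi_partition(sites, bbox, scale)


def centroid_method(gs_mask: BinaryMask, min_area_px: int = 50) -> Tessellation:
    """Voronoi diagram generated by the centroids of GS-positive particles.

    Region ``i`` corresponds to particle label ``i + 1`` of the returned
    component analysis (components are ordered; region ids follow suit).
    """
    comps = connected_components(gs_mask, min_area_px)
    if len(comps) == 0:
        raise ValueError("no generating sites: mask has no particle above min_area_px")
    rows, cols = gs_mask.shape
    return voronoi_partition(comps.centroids, (cols, rows), gs_mask.scale)


def object_edge_method(object_mask: BinaryMask, min_area_px: int = 1) -> LabelPartition:
    """Generalized Voronoi-like partition from object boundaries.

    Every background pixel is assigned to the particle with the minimum
    Euclidean distance from the pixel center to the particle's pixel set;
    particle pixels keep their own label; distance ties go to the lowest
    label.  Computed as the label-wise minimum over exact Euclidean
    distance transforms, which degenerates to the point-Voronoi diagram
    when every particle is a single pixel.
    """
    comps = connected_components(object_mask, min_area_px)
    if len(comps) == 0:
        raise ValueError("empty mask: no generating objects")
    labels = comps.labels
    out = np.zeros_like(labels, dtype=np.int32)
    best = np.full(labels.shape, np.inf)
    for lab, _, _ in comps.components:  # ascending labels: lowest wins ties
        d = ndimage.distance_transform_edt(labels != lab)
        closer = d < best
        best[closer] = d[closer]
        out[closer] = lab
    return LabelPartition(out, comps, object_mask.scale)


def modified_object_edge_method(
    annotated_mask: BinaryMask, min_area_px: int = 1
) -> LabelPartition:
    """Object-edge partition of a curated annotation mask.

    Identical computation to :func:`object_edge_method`; the input is a
    hand-annotated mask of GS areas and central veins rather than raw
    threshold output, so spurious specks never become generators.
    """
    return object_edge_method(annotated_mask, min_area_px)


def _vertex_groups(t: Tessellation, tol: float = 1e-6):
    """Group coincident region vertices into shared topological vertices.

    Returns a list of (position, [(region_index, vertex_index), ...])
    sorted by (y, x) — the deterministic traversal order for refinement.
    """
    groups: dict[tuple[float, float], list[tuple[int, int]]] = {}
    coords: dict[tuple[float, float], tuple[float, float]] = {}
    for ri, region in enumerate(t.regions):
        for vi, (x, y) in enumerate(region.vertices):
            key = (round(x / tol) * tol, round(y / tol) * tol)
            groups.setdefault(key, []).append((ri, vi))
            coords.setdefault(key, (x, y))  # exact position, not the rounded key
    items = [(np.array(coords[k]), v) for k, v in groups.items()]
    items.sort(key=lambda kv: (kv[0][1], kv[0][0]))
    return items


def _on_bbox_edge(pos: np.ndarray, bbox: tuple[float, float], tol: float = 1e-6) -> bool:
    x, y = pos
    w, h = bbox
    return x < tol or y < tol or x > w - tol or y > h - tol


def refine_to_landmarks(
    t: Tessellation,
    landmarks: np.ndarray,
    max_mismatch: float = 0.05,
    snap_radius_um: float = 150.0,
) -> RefinementResult:
    """Snap tessellation vertices onto nearby anatomic landmarks.

    Vertices are visited in (y, x) order; each may move to the nearest
    unclaimed landmark within ``snap_radius_um``.  A move is kept only if
    every region incident to the vertex stays a simple polygon and its
    accumulated symmetric-difference fraction against the *original*
    region stays within ``max_mismatch``; otherwise the move is undone
    and the next-nearest candidate tried (depth-first with backtracking).
    Vertices on the image border are pinned — moving them would uncover
    the rectangle, and landmarks are interior structures.

    Returns the adjusted tessellation (regions may be non-convex) with
    per-region mismatch fractions and the (vertex, landmark) moves kept.
    """
    if not (0.0 < max_mismatch <= 1.0):
        raise ValueError("max_mismatch must lie in (0, 1]")
    landmarks = np.asarray(landmarks, dtype=float).reshape(-1, 2)
    snap_radius_px = snap_radius_um / t.scale

    regions = [
        PolygonRegion(r.vertices.copy(), r.site.copy(), r.region_id) for r in t.regions
    ]
    originals = [r.polygon for r in t.regions]
    orig_areas = [p.area for p in originals]
    claimed = np.zeros(len(landmarks), dtype=bool)
    moves: list[tuple[tuple[float, float], tuple[float, float]]] = []

    def mismatch(ri: int) -> float:
        p = Polygon(regions[ri].vertices)
        if not p.is_valid:
            return math.inf
        return p.symmetric_difference(originals[ri]).area / orig_areas[ri]

    for pos, incident in _vertex_groups(t):
        if _on_bbox_edge(pos, t.bbox):
            continue
        if len(landmarks) == 0:
            break
        d = np.hypot(landmarks[:, 0] - pos[0], landmarks[:, 1] - pos[1])
        candidates = np.argsort(d, kind="stable")
        for li in candidates:
            if claimed[li] or d[li] > snap_radius_px:
                continue
            target = landmarks[li]
            saved = [(ri, regions[ri].vertices[vi].copy()) for ri, vi in incident]
            for ri, vi in incident:
                regions[ri].vertices[vi] = target
            if all(mismatch(ri) <= max_mismatch for ri, _ in incident):
                claimed[li] = True
                moves.append((tuple(pos), tuple(target)))
                break
            for (ri, vi), (_, old) in zip(incident, saved):
                regions[ri].vertices[vi] = old

    refined = Tessellation(t.bbox, t.sites.copy(), regions, t.scale)
    per_region = [
        Polygon(r.vertices).symmetric_difference(originals[i]).area / orig_areas[i]
        for i, r in enumerate(regions)
    ]
    return RefinementResult(refined, per_region, moves)


def _single_linkage_clusters(points: np.ndarray, cutoff: float) -> list[np.ndarray]:
    """Indices of single-linkage clusters at distance ``cutoff``."""
    n = len(points)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if np.hypot(*(points[i] - points[j])) <= cutoff:
                parent[find(i)] = find(j)
    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)
    return [np.array(v) for v in clusters.values()]


def split_compound_regions(
    t: Tessellation, gs: ComponentSet, min_separation_um: float = 200.0
) -> Tessellation:
    """Split regions that contain several well-separated GS areas.

    A compound lobule shows up as one Voronoi region holding two or more
    GS-positive particle centroids.  Centroids inside a region are
    single-linkage clustered at ``min_separation_um`` (closer centroids
    are treated as one fragmented GS area); a region with >= 2 clusters
    is replaced by the Voronoi sub-partition of its polygon generated by
    the cluster mean positions.  Sub-region areas sum to the parent's.
    Region ids are renumbered consecutively in the output.
    """
    centroids = gs.centroids
    sep_px = min_separation_um / t.scale
    new_regions: list[tuple[np.ndarray, np.ndarray]] = []  # (vertices, site)
    for region in t.regions:
        poly = region.polygon
        if len(centroids):
            inside = shapely.contains_xy(poly, centroids[:, 0], centroids[:, 1])
            pts = centroids[inside]
        else:
            pts = np.empty((0, 2))
        clusters = _single_linkage_clusters(pts, sep_px) if len(pts) else []
        if len(clusters) < 2:
            new_regions.append((region.vertices, region.site))
            continue
        seeds = np.array([pts[c].mean(axis=0) for c in clusters])
        x0, y0, x1, y1 = poly.bounds
        pad = 1.0
        local = voronoi_partition(
            seeds - [x0 - pad, y0 - pad], (x1 - x0 + 2 * pad, y1 - y0 + 2 * pad)
        )
        for sub, seed in zip(local.regions, seeds):
            cell = affinity.translate(sub.polygon, x0 - pad, y0 - pad)
            piece = cell.intersection(poly)
            if piece.geom_type == "MultiPolygon":  # non-convex parent
                piece = max(piece.geoms, key=lambda g: g.area)
            verts = np.asarray(orient(piece, sign=1.0).exterior.coords[:-1])
            new_regions.append((verts, seed))
    regions = [
        PolygonRegion(v, s, i) for i, (v, s) in enumerate(new_regions)
    ]
    sites = np.array([s for _, s in new_regions])
    return Tessellation(t.bbox, sites, regions, t.scale)


def algorithm_method(
    gs_mask: BinaryMask,
    landmarks: np.ndarray,
    min_area_px: int = 50,
    max_mismatch: float = 0.05,
    snap_radius_um: float = 150.0,
    min_separation_um: float = 200.0,
) -> RefinementResult:
    """Full automated pipeline: centroid diagram, splitting, refinement.

    ``landmarks`` are interlobular-septum points (pig) or annotated portal
    tracts (human) toward which vertices are drawn, subject to the
    per-region mismatch bound.  Pass an empty array to skip refinement.
    """
    comps = connected_components(gs_mask, min_area_px)
    if len(comps) == 0:
        raise ValueError("no generating sites: mask has no particle above min_area_px")
    rows, cols = gs_mask.shape
    t = voronoi_partition(comps.centroids, (cols, rows), gs_mask.scale)
    t = split_compound_regions(t, comps, min_separation_um)
    return refine_to_landmarks(
        t, np.asarray(landmarks, float).reshape(-1, 2), max_mismatch, snap_radius_um
    )
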