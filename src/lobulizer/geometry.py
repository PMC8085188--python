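"""Exact 2D computational geometry for lobule tessellations.

Bounded Voronoi diagrams (cells clipped to the image rectangle), their
Delaunay dual, and polygon morphometrics (area, side count, minimum
enclosing circle) in physical units.

Coordinate convention: 0-based pixel coordinates, x rightward, y downward,
pixel centers at integer coordinates.  Physical scale (µm per pixel) is
carried explicitly; areas are reported in mm² and lengths in mm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy.spatial import Voronoi
from shapely.geometry import Polygon, box
from shapely.geometry.polygon import orient

__all__ = [
    "PolygonRegion",
    "Tessellation",
    "MorphometryRecord",
    "voronoi_partition",
    "delaunay_dual",
    "polygon_area",
    "side_count",
    "min_enclosing_circle_diameter",
    "regular_polygon_area",
    "rasterize_tessellation",
    "rasterize_polygons",
    "interior_region_ids",
]

UM2_PER_MM2 = 1.0e6


@dataclass
class PolygonRegion:
    """A single lobule region: a simple polygon with its generating site.

    ``vertices`` is an (n, 2) float array of (x, y) pixel coordinates in
    counter-clockwise order (positive shoelace area), closed implicitly.
    True Voronoi regions are convex and contain their site; refined
    regions may be simple but non-convex.
    """

    vertices: np.ndarray
    site: np.ndarray
    region_id: int

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.site = np.asarray(self.site, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must be an (n, 2) array")
        if not np.all(np.isfinite(self.vertices)):
            raise ValueError("vertices must be finite")

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.vertices)

    def pixel_area(self) -> float:
        """Shoelace area in px² (always positive for a valid region)."""
        return abs(_shoelace(self.vertices))

    def centroid(self) -> np.ndarray:
        c = self.polygon.centroid
        return np.array([c.x, c.y])


@dataclass
class Tessellation:
    """Sites plus polygonal regions tiling a bounding rectangle.

    ``bbox`` is (width, height) in pixels; the rectangle spans
    [0, width] x [0, height].  Exactly one region per site; region
    interiors are pairwise disjoint and their union is the rectangle.
    """

    bbox: tuple[float, float]
    sites: np.ndarray
    regions: list[PolygonRegion] = field(default_factory=list)
    scale: float = 1.0  # µm per pixel

    def __post_init__(self) -> None:
        self.sites = np.atleast_2d(np.asarray(self.sites, dtype=float))

    @property
    def width(self) -> float:
        return float(self.bbox[0])

    @property
    def height(self) -> float:
        return float(self.bbox[1])

    def region_by_id(self, region_id: int) -> PolygonRegion:
        for r in self.regions:
            if r.region_id == region_id:
                return r
        raise KeyError(f"no region with id {region_id}")


@dataclass
class MorphometryRecord:
    region_id: int
    side_count: int
    area_mm2: float
    circumcircle_diameter_mm: float
    centroid: tuple[float, float]


def _shoelace(vertices: np.ndarray) -> float:
    x = vertices[:, 0]
    y = vertices[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def _ccw(vertices: np.ndarray) -> np.ndarray:
    return vertices if _shoelace(vertices) > 0 else vertices[::-1]


def voronoi_partition(
    sites: np.ndarray, bbox: tuple[float, float], scale: float = 1.0
) -> Tessellation:
    """Voronoi diagram of ``sites`` clipped to the rectangle ``bbox``.

    Unbounded cells are bounded by reflecting every site across the four
    rectangle edges and computing the Voronoi diagram of the augmented
    point set: the cells of the original sites in that diagram are exactly
    the original cells intersected with the rectangle (each rectangle edge
    is the perpendicular bisector of a site and its mirror image).

    Parameters
    ----------
    sites : (n, 2) array of (x, y) site coordinates, all strictly inside
        the rectangle, no two coincident.
    bbox : (width, height) of the rectangle [0, w] x [0, h] in pixels.
    scale : physical scale in µm per pixel.

    Raises
    ------
    ValueError
        On duplicate sites (the offending pair is named) or sites outside
        the rectangle.
    """
    sites = np.atleast_2d(np.asarray(sites, dtype=float))
    if sites.size == 0:
        raise ValueError("at least one site is required")
    w, h = float(bbox[0]), float(bbox[1])
    inside = (
        (sites[:, 0] >= 0) & (sites[:, 0] <= w) & (sites[:, 1] >= 0) & (sites[:, 1] <= h)
    )
    if not np.all(inside):
        bad = int(np.flatnonzero(~inside)[0])
        raise ValueError(f"site {bad} at {tuple(sites[bad])} lies outside bbox {bbox}")
    # duplicate detection: exact coincidence breaks the diagram's one-cell-per-site contract
    n = len(sites)
    if n > 1:
        from scipy.spatial import cKDTree

        pairs = cKDTree(sites).query_pairs(r=1e-9)
        if pairs:
            i, j = sorted(next(iter(pairs)))
            raise ValueError(f"duplicate sites: indices {i} and {j} coincide")

    rect = box(0.0, 0.0, w, h)
    if n == 1:
        verts = np.array([[0.0, 0.0], [w, 0.0], [w, h], [0.0, h]])
        region = PolygonRegion(_ccw(verts), sites[0], 0)
        return Tessellation((w, h), sites, [region], scale)

    mirrored = np.vstack(
        [
            sites,
            np.column_stack([-sites[:, 0], sites[:, 1]]),  # left edge x=0
            np.column_stack([2 * w - sites[:, 0], sites[:, 1]]),  # right edge
            np.column_stack([sites[:, 0], -sites[:, 1]]),  # top edge y=0
            np.column_stack([sites[:, 0], 2 * h - sites[:, 1]]),  # bottom edge
        ]
    )
    vor = Voronoi(mirrored)
    regions: list[PolygonRegion] = []
    for i in range(n):
        ridx = vor.point_region[i]
        vidx = vor.regions[ridx]
        if -1 in vidx or len(vidx) < 3:  # pragma: no cover - cannot occur post-mirroring
            raise RuntimeError("unbounded cell survived mirroring")
        poly = Polygon(vor.vertices[vidx])
        clipped = poly.intersection(rect)
        verts = np.asarray(orient(clipped, sign=1.0).exterior.coords[:-1])
        # squash clipping fuzz: vertices within 1e-9 px of a rectangle edge sit on it
        for axis, limit in ((0, w), (1, h)):
            near0 = np.abs(verts[:, axis]) < 1e-9
            nearL = np.abs(verts[:, axis] - limit) < 1e-9
            verts[near0, axis] = 0.0
            verts[nearL, axis] = limit
        regions.append(PolygonRegion(_ccw(verts), sites[i], i))
    return Tessellation((w, h), sites, regions, scale)


def delaunay_dual(t: Tessellation, min_shared_length: float = 1e-9) -> list[tuple[int, int]]:
    """Delaunay edges of the bounded diagram: site-index pairs (i, j), i < j,
    whose regions share a boundary segment of positive length.

    Clipping can cut a ridge of the unbounded diagram down to nothing, so
    adjacency is read off the clipped regions, not the raw Delaunay graph.
    """
    if len(t.sites) < 2:
        raise ValueError("at least two sites are required")
    polys = [r.polygon for r in t.regions]
    edges: list[tuple[int, int]] = []
    tree = shapely.STRtree(polys)
    for i, p in enumerate(polys):
        for j in tree.query(p):
            j = int(j)
            if j <= i:
                continue
            shared = p.intersection(polys[j])
            if shared.length > min_shared_length:
                edges.append((i, j))
    return sorted(edges)


def polygon_area(p: PolygonRegion | np.ndarray, scale: float) -> float:
    """Polygon area in mm² at ``scale`` µm per pixel (shoelace × scale²)."""
    vertices = p.vertices if isinstance(p, PolygonRegion) else np.asarray(p, float)
    poly = Polygon(vertices)
    if not poly.is_valid:
        raise ValueError("polygon is self-intersecting or degenerate")
    return poly.area * scale**2 / UM2_PER_MM2


def side_count(
    p: PolygonRegion | np.ndarray,
    angle_tol: float = 10.0,
    merge_dist: float = 2.0,
) -> int:
    """Number of polygon sides after cleaning rasterization/clipping artifacts.

    Vertices closer than ``merge_dist`` pixels are collapsed, then a vertex
    is dropped when the turning angle there is below ``angle_tol`` degrees
    (near-collinear edges merge).  Clipped Voronoi cells often carry such
    spurious vertices; the cleaned count is what a histologist would call
    the number of lobule facets.
    """
    vertices = p.vertices if isinstance(p, PolygonRegion) else np.asarray(p, float)
    if abs(_shoelace(vertices)) <= 0:
        raise ValueError("degenerate (zero-area) polygon")
    # collapse runs of near-coincident vertices (keep the first of each run)
    kept = [vertices[0]]
    for v in vertices[1:]:
        if np.hypot(*(v - kept[-1])) >= merge_dist:
            kept.append(v)
    if len(kept) > 1 and np.hypot(*(kept[0] - kept[-1])) < merge_dist:
        kept.pop()
    verts = np.asarray(kept)
    n = len(verts)
    if n < 3:
        raise ValueError("polygon collapses below 3 vertices at this merge distance")
    keep = np.ones(n, dtype=bool)
    for i in range(n):
        a, b, c = verts[(i - 1) % n], verts[i], verts[(i + 1) % n]
        u, v = b - a, c - b
        cross = u[0] * v[1] - u[1] * v[0]
        dot = float(u @ v)
        turn = abs(math.degrees(math.atan2(cross, dot)))
        if turn < angle_tol:
            keep[i] = False
    return max(int(keep.sum()), 3)


def min_enclosing_circle_diameter(p: PolygonRegion | np.ndarray, scale: float) -> float:
    """Diameter in mm of the smallest circle containing all polygon vertices.

    Operationalizes the "circumcircle diameter" of an irregular lobule: for
    regular polygons it coincides with the classical circumcircle.
    """
    vertices = p.vertices if isinstance(p, PolygonRegion) else np.asarray(p, float)
    if len(vertices) < 3:
        raise ValueError("need at least 3 vertices")
    r_px = shapely.minimum_bounding_radius(shapely.MultiPoint(vertices))
    return 2.0 * r_px * scale / 1000.0


def regular_polygon_area(n: int, circumradius_mm: float) -> float:
    """Area in mm² of a regular n-gon with circumcircle radius R mm:
    (n/2) · R² · sin(2π/n).  Tends to πR² as n → ∞."""
    if n < 3:
        raise ValueError("a polygon needs at least 3 sides")
    if circumradius_mm <= 0:
        raise ValueError("circumradius must be positive")
    return 0.5 * n * circumradius_mm**2 * math.sin(2.0 * math.pi / n)


def rasterize_tessellation(
    t: Tessellation, shape: tuple[int, int] | None = None
) -> np.ndarray:
    """Per-pixel region labels (region_id + 1; 0 reserved for background).

    Labels are assigned by the Voronoi definition itself — nearest site,
    ties broken by lowest site index — so the raster is exact regardless
    of polygon clipping fuzz.  ``shape`` is (rows, cols); defaults to
    (ceil(h), ceil(w)).
    """
    if shape is None:
        shape = (int(math.ceil(t.height)), int(math.ceil(t.width)))
    rows, cols = shape
    yy, xx = np.mgrid[0:rows, 0:cols]
    best = np.full(shape, np.inf)
    labels = np.zeros(shape, dtype=np.int32)
    for r in t.regions:
        x0, y0 = r.site
        d = (xx - x0) ** 2 + (yy - y0) ** 2
        closer = d < best  # strict: earlier (lower-id) site keeps ties
        best[closer] = d[closer]
        labels[closer] = r.region_id + 1
    return labels


def interior_region_ids(t: Tessellation, margin: float = 1e-6) -> list[int]:
    """Ids of regions not touching the bounding rectangle (uncut lobules)."""
    w, h = t.bbox
    out = []
    for r in t.regions:
        x, y = r.vertices[:, 0], r.vertices[:, 1]
        if (x > margin).all() and (y > margin).all() and (x < w - margin).all() and (
            y < h - margin
        ).all():
            out.append(r.region_id)
    return out


def rasterize_polygons(t: Tessellation, shape: tuple[int, int] | None = None) -> np.ndarray:
    """Per-pixel labels (region_id + 1) by polygon membership.

    Unlike :func:`rasterize_tessellation` this honors the region polygons
    themselves, so it is the right rasterizer for refined or split
    tessellations whose regions are no longer nearest-site cells.  Pixels
    claimed by several polygons (shared boundaries) or by none (float
    fuzz between neighbors) go to the region whose boundary is nearest,
    ties to the lowest region_id.
    """
    if shape is None:
        shape = (int(math.ceil(t.height)), int(math.ceil(t.width)))
    rows, cols = shape
    labels = np.zeros(shape, dtype=np.int32)
    order = sorted(t.regions, key=lambda r: r.region_id, reverse=True)
    for r in order:  # descending: lowest id painted last wins overlaps
        poly = r.polygon
        x0, y0, x1, y1 = poly.bounds
        c0, c1 = max(int(math.floor(x0)), 0), min(int(math.ceil(x1)) + 1, cols)
        r0, r1 = max(int(math.floor(y0)), 0), min(int(math.ceil(y1)) + 1, rows)
        if c0 >= c1 or r0 >= r1:
            continue
        yy, xx = np.mgrid[r0:r1, c0:c1]
        inside = shapely.contains_xy(poly, xx.ravel(), yy.ravel()).reshape(xx.shape)
        sub = labels[r0:r1, c0:c1]
        sub[inside] = r.region_id + 1
    holes = labels == 0
    if np.any(holes):
        yy, xx = np.nonzero(holes)
        pts = shapely.points(xx.astype(float), yy.astype(float))
        best = np.full(len(pts), np.inf)
        fill = np.zeros(len(pts), dtype=np.int32)
        for r in t.regions:
            d = shapely.distance(r.polygon, pts)
            closer = d < best
            best[closer] = d[closer]
            fill[closer] = r.region_id + 1
        labels[yy, xx] = fill
    return labels
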