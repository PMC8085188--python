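"""Synthetic liver-tissue generator with exact ground truth.

Emulates the geometry a GS-stained liver section presents at overview
resolution: lobules as Voronoi regions of jittered central-vein sites
(hexagonal lattice or Poisson point process), star-convex GS-positive
blobs around each site, portal tracts near region vertices, optional
interlobular septa along region edges (pig mode), occasional compound
lobules (two fused regions sharing one septal outline), and Gaussian
intensity noise.  Every stochastic layer is driven by one seeded RNG, so
identical config + seed reproduces identical output.

It does not emulate stain variability, vascular texture, sectioning
artifacts, or sub-lobular histology — tests passing on this material
validate the geometry pipeline, not stain robustness.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage.draw import polygon as draw_polygon
from skimage.segmentation import find_boundaries

from .geometry import Tessellation, rasterize_tessellation, voronoi_partition
from .metrics import AnnotationSet
from .segmentation import BinaryMask

__all__ = ["SyntheticConfig", "GroundTruth", "generate_tissue", "corrupt",
           "merged_lobule_tessellation"]

BACKGROUND_INTENSITY = 40.0
MARKER_INTENSITY = 200.0


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic tissue section.

    Lengths are µm; the lattice pitch is derived from
    ``mean_lobule_diameter_um`` (circumcircle diameter of the ideal
    hexagonal lobule, 1.2 mm).  Defaults describe a moderately irregular
    section: site jitter of 100 µm reproduces the observed 3–8-sided
    shape range, and a 10% compound-event rate matches the reported
    frequency of compound lobules.
    """

    mode: str = "human"  # "pig" adds interlobular septa
    image_size: tuple[int, int] = (1152, 1152)  # rows, cols
    scale: float = 8.0  # µm per pixel (overview rendering of a 0.5 µm/px scan)
    lattice: str = "hex"  # or "poisson"
    mean_lobule_diameter_um: float = 1200.0
    site_jitter_sigma_um: float = 100.0
    gs_blob_radius_um: tuple[float, float] = (150.0, 250.0)
    gs_centroid_jitter_um: float = 25.0
    pt_vertex_jitter_um: float = 25.0
    pt_dropout: float = 0.05
    septa_width_um: float = 40.0
    compound_event: float = 0.1
    noise_sigma: float = 10.0
    rng_seed: int = 0

    @classmethod
    def clean(cls, **overrides) -> "SyntheticConfig":
        """Noise-free, jitter-free conditions: truth-recovery baseline."""
        base = dict(
            site_jitter_sigma_um=0.0,
            gs_centroid_jitter_um=0.0,
            pt_vertex_jitter_um=0.0,
            pt_dropout=0.0,
            compound_event=0.0,
            noise_sigma=0.0,
        )
        base.update(overrides)
        return cls(**base)

    def validate(self) -> None:
        for p in (self.pt_dropout, self.compound_event):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.gs_blob_radius_um[1] >= self.mean_lobule_diameter_um / 2:
            raise ValueError(
                "infeasible geometry: GS blob radius reaches the lobule radius"
            )
        if self.scale <= 0 or self.mean_lobule_diameter_um <= 0:
            raise ValueError("lengths must be positive")
        if self.mode not in ("pig", "human"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.lattice not in ("hex", "poisson"):
            raise ValueError(f"unknown lattice {self.lattice!r}")


@dataclass
class GroundTruth:
    """A rendered section with every truth layer the scorers need."""

    config: SyntheticConfig
    image: np.ndarray
    true_sites: np.ndarray
    true_regions: Tessellation
    true_lobule_labels: np.ndarray
    gs_truth_mask: BinaryMask
    pt_points: np.ndarray
    septa_mask: BinaryMask | None
    compound_flags: list[tuple[int, int]]
    # render internals kept so corrupt() can re-render consistently
    gs_blobs: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)
    noise_field: np.ndarray | None = None

    @property
    def annotations(self) -> AnnotationSet:
        return AnnotationSet(
            portal_tracts=self.pt_points,
            central_veins=self.true_sites,
            septa_mask=self.septa_mask,
            true_lobule_labels=self.true_lobule_labels,
        )


def _hex_lattice(shape_px: tuple[int, int], pitch_px: float) -> np.ndarray:
    rows, cols = shape_px
    dy = pitch_px * np.sqrt(3.0) / 2.0
    pts = []
    j = 0
    y = dy / 2.0
    while y < rows:
        x0 = pitch_px / 2.0 if j % 2 else pitch_px
        x = x0
        while x < cols:
            pts.append((x, y))
            x += pitch_px
        y += dy
        j += 1
    return np.array(pts)


def _star_blob(rng: np.random.Generator, radius_px: float, n_theta: int = 64,
               wobble: float = 0.08) -> np.ndarray:
    """Star-convex blob outline: a disc with low-order radial Fourier ripple."""
    theta = np.linspace(0.0, 2.0 * np.pi, n_theta, endpoint=False)
    r = np.full(n_theta, radius_px)
    for k in (2, 3, 4, 5):
        amp = rng.uniform(0.0, wobble / 2.0) * radius_px
        phase = rng.uniform(0.0, 2.0 * np.pi)
        r += amp * np.cos(k * theta + phase)
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def _render(
    shape: tuple[int, int],
    blobs: list[tuple[np.ndarray, np.ndarray]],
) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize blobs: returns (clean float image, boolean GS mask)."""
    gs = np.zeros(shape, dtype=bool)
    for center, outline in blobs:
        xs = center[0] + outline[:, 0]
        ys = center[1] + outline[:, 1]
        rr, cc = draw_polygon(ys, xs, shape=shape)
        gs[rr, cc] = True
    img = np.full(shape, BACKGROUND_INTENSITY)
    img[gs] = MARKER_INTENSITY
    return img, gs


def _unique_interior_vertices(t: Tessellation, edge_tol: float = 1e-6) -> np.ndarray:
    w, h = t.bbox
    seen: dict[tuple[float, float], None] = {}
    for r in t.regions:
        for x, y in r.vertices:
            if x < edge_tol or y < edge_tol or x > w - edge_tol or y > h - edge_tol:
                continue
            seen[(round(x, 6), round(y, 6))] = None
    return np.array(list(seen.keys())).reshape(-1, 2)


def generate_tissue(config: SyntheticConfig) -> GroundTruth:
    """Render one synthetic section plus all ground-truth layers."""
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    rows, cols = config.image_size
    px = config.scale
    pitch_px = (config.mean_lobule_diameter_um * np.sqrt(3.0) / 2.0) / px

    if config.lattice == "hex":
        sites = _hex_lattice((rows, cols), pitch_px)
    else:
        cell_area = np.sqrt(3.0) / 2.0 * pitch_px**2
        n = max(int(round(rows * cols / cell_area)), 1)
        sites = np.column_stack(
            [rng.uniform(2.0, cols - 2.0, n), rng.uniform(2.0, rows - 2.0, n)]
        )
    if config.site_jitter_sigma_um > 0:
        sites = sites + rng.normal(0.0, config.site_jitter_sigma_um / px, sites.shape)
    sites[:, 0] = np.clip(sites[:, 0], 1.0, cols - 1.0)
    sites[:, 1] = np.clip(sites[:, 1], 1.0, rows - 1.0)

    tess = voronoi_partition(sites, (cols, rows), px)
    labels = rasterize_tessellation(tess, (rows, cols))

    # compound lobules: a pair of adjacent regions fused in the truth labels
    compound_flags: list[tuple[int, int]] = []
    if config.compound_event > 0:
        from .geometry import delaunay_dual

        adjacency: dict[int, list[int]] = {}
        for i, j in delaunay_dual(tess):
            adjacency.setdefault(i, []).append(j)
            adjacency.setdefault(j, []).append(i)
        merged: set[int] = set()
        for i in range(len(sites)):
            if i in merged or rng.random() >= config.compound_event:
                continue
            free = [j for j in adjacency.get(i, []) if j not in merged]
            if not free:
                continue
            j = free[rng.integers(len(free))]
            labels[labels == j + 1] = i + 1
            merged.update((i, j))
            compound_flags.append((i, j))

    # GS blobs near each site (both blobs of a compound pair are kept)
    lo, hi = config.gs_blob_radius_um
    blobs: list[tuple[np.ndarray, np.ndarray]] = []
    for site in sites:
        center = site.copy()
        if config.gs_centroid_jitter_um > 0:
            center = center + rng.normal(0.0, config.gs_centroid_jitter_um / px, 2)
        radius_px = rng.uniform(lo, hi) / px
        blobs.append((center, _star_blob(rng, radius_px)))
    clean, gs = _render((rows, cols), blobs)

    noise = (
        rng.normal(0.0, config.noise_sigma, (rows, cols))
        if config.noise_sigma > 0
        else np.zeros((rows, cols))
    )
    image = np.clip(clean + noise, 0, 255).astype(np.uint8)

    # portal tracts near the lattice vertices, with jitter and dropout
    pts = _unique_interior_vertices(tess)
    if len(pts) and config.pt_vertex_jitter_um > 0:
        pts = pts + rng.normal(0.0, config.pt_vertex_jitter_um / px, pts.shape)
        pts[:, 0] = np.clip(pts[:, 0], 0.0, cols - 1.0)
        pts[:, 1] = np.clip(pts[:, 1], 0.0, rows - 1.0)
    if len(pts) and config.pt_dropout > 0:
        keep = rng.random(len(pts)) >= config.pt_dropout
        pts = pts[keep]

    septa = None
    if config.mode == "pig":
        edges = find_boundaries(labels, mode="thick")
        half_w = max(int(round(config.septa_width_um / px / 2.0)), 1)
        septa_grid = ndimage.binary_dilation(edges, iterations=half_w)
        septa = BinaryMask(septa_grid, px)

    return GroundTruth(
        config=config,
        image=image,
        true_sites=sites,
        true_regions=tess,
        true_lobule_labels=labels,
        gs_truth_mask=BinaryMask(gs, px),
        pt_points=pts,
        septa_mask=septa,
        compound_flags=compound_flags,
        gs_blobs=blobs,
        noise_field=noise,
    )


def merged_lobule_tessellation(gt: GroundTruth) -> Tessellation:
    """Lobule-level regions of the truth: compound pairs fused into one.

    The generator's ``true_regions`` keeps one Voronoi cell per site;
    compound events only fuse labels in the raster.  This view fuses the
    corresponding polygons too (the site of the lower-indexed member is
    kept), which is what compound-lobule flagging and per-lobule overlap
    scoring operate on.  Region ids are renumbered consecutively.
    """
    from shapely.geometry.polygon import orient

    from .geometry import PolygonRegion

    partner = {}
    for i, j in gt.compound_flags:
        partner[i] = j
        partner[j] = i
    regions = []
    consumed: set[int] = set()
    for r in gt.true_regions.regions:
        i = r.region_id
        if i in consumed:
            continue
        if i in partner:
            j = partner[i]
            fused = r.polygon.union(gt.true_regions.regions[j].polygon)
            if fused.geom_type == "MultiPolygon":  # touching along a point only
                fused = fused.buffer(1e-9)
            verts = np.asarray(orient(fused, sign=1.0).exterior.coords[:-1])
            regions.append((verts, gt.true_regions.regions[min(i, j)].site))
            consumed.update((i, j))
        else:
            regions.append((r.vertices, r.site))
            consumed.add(i)
    out = [PolygonRegion(v, s, k) for k, (v, s) in enumerate(regions)]
    sites = np.array([s for _, s in regions])
    return Tessellation(gt.true_regions.bbox, sites, out, gt.config.scale)


def corrupt(
    gt: GroundTruth,
    gs_jitter_um: float = 0.0,
    pt_dropout: float = 0.0,
    extra_noise_sigma: float = 0.0,
    seed: int = 0,
) -> GroundTruth:
    """Degrade a rendered section for stress curves; truth regions unchanged.

    GS blobs are re-rendered at jittered centers (the GS truth mask moves
    with them — that is its meaning), portal tracts are additionally
    dropped, and extra Gaussian noise is added on top of the original
    noise field.  All-zero levels return a byte-identical section.
    """
    rng = np.random.default_rng(seed)
    px = gt.config.scale
    shape = gt.image.shape

    blobs = gt.gs_blobs
    if gs_jitter_um > 0:
        blobs = [
            (center + rng.normal(0.0, gs_jitter_um / px, 2), outline)
            for center, outline in blobs
        ]
    clean, gs = _render(shape, blobs)
    noise = gt.noise_field if gt.noise_field is not None else 0.0
    if extra_noise_sigma > 0:
        noise = noise + rng.normal(0.0, extra_noise_sigma, shape)
    image = np.clip(clean + noise, 0, 255).astype(np.uint8)

    pts = gt.pt_points
    if pt_dropout > 0 and len(pts):
        keep = rng.random(len(pts)) >= pt_dropout
        pts = pts[keep]
    if pt_dropout >= 1.0:
        pts = np.empty((0, 2))

    return replace(
        gt,
        image=image,
        gs_truth_mask=BinaryMask(gs, px),
        pt_points=pts,
        gs_blobs=blobs,
        noise_field=noise if isinstance(noise, np.ndarray) else gt.noise_field,
    )
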