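# Methods

## Model

The classic liver lobule is modeled as a cell of a planar Voronoi
diagram whose generating sites are the central veins: every point of a
lobule is nearer (Euclidean distance) to its own central vein than to
any neighbor's. The package works in image coordinates — 0-based, x
rightward, y downward, pixel centers at integers — and carries the
physical scale (µm per pixel) explicitly; areas are reported in mm²,
lengths in mm.

Bounded diagrams are computed with `scipy.spatial.Voronoi` on the site
set augmented with its reflections across the four image edges: each
edge is the perpendicular bisector of a site and its mirror image, so
the cells of the original sites in the augmented diagram are exactly
the unbounded cells clipped to the rectangle. Residual floating-point
fuzz (~1e-15 px) is snapped onto the rectangle edges. Per-pixel
rasterization uses the Voronoi definition directly (nearest site,
strict-inequality update over ascending site index), which makes the
tie-break rule — lowest site index — exact rather than dependent on
polygon boundary arithmetic.

The Delaunay dual is read off the *clipped* regions (pairs sharing a
boundary segment of positive length), not the raw triangulation:
clipping can remove an adjacency whose shared ridge lies wholly outside
the image.

## Segmentation

The marker-segmentation chain mirrors the standard ImageJ workflow:
8-bit rescale (min→0, max→255), iterative-intermeans/isodata threshold
on the 256-bin histogram (`skimage.filters.threshold_isodata`), one
3×3 median pass, 8-connected particle labeling with centroid
extraction. Marker polarity is explicit config: `bright` for synthetic
renderings and fluorescence, `dark` for brightfield DAB. Bit-exact
replication of ImageJ's tie-handling is not claimed. A particle floor
of `min_area_px = 50` (at the default scales, well below any plausible
GS-positive perivenular area) suppresses residual specks; it is
configurable. Note that a 3×3 median necessarily rounds the convex
corners of any solid rectangle (a corner has 4 of 9 foreground
neighbors); the tests assert this true behavior.

## Generalized (object-edge) partition

Each pixel joins the particle whose *pixel set* is nearest. This is
computed as the label-wise minimum over exact Euclidean distance
transforms, updating with strict inequality over ascending labels so
that distance ties deterministically go to the lowest label — the same
rule the brute-force oracle uses, which is why agreement can be asserted
at 100% of pixels. When every particle is a single pixel this
degenerates to the point-site Voronoi diagram.

## Refinement (algorithm method)

Vertices of the centroid diagram are visited in (y, x) order; each may
snap to the nearest unclaimed landmark within `snap_radius_um`
(default 150 µm, about half a lobule radius). A move is kept only if
every incident region stays a simple polygon and its accumulated
symmetric-difference fraction against the *original* region stays
within `max_mismatch` (default 0.05); rejected moves are undone and the
next-nearest candidate tried (depth-first with backtracking). The bound
is enforced per region, not summed over the diagram — it most naturally
limits each lobule's distortion. Vertices on the image border are
pinned: moving them would uncover the rectangle, and landmarks (portal
tracts, septal points) are interior structures. Refined regions may be
non-convex; all downstream code accepts simple polygons and rasterizes
them by polygon membership (overlaps and float gaps resolved by nearest
region boundary, ties to lowest region id).

Compound lobules — one region holding several GS-positive areas — are
split before refinement: GS centroids inside a region are single-linkage
clustered at `min_separation_um` (default 200 µm; closer centroids are
treated as one fragmented GS area), and a region with ≥ 2 clusters is
replaced by the Voronoi sub-partition of its polygon generated by the
cluster means. Sub-region areas sum exactly to the parent's.

## Zonation

Zone 3 keeps "the same polygon configuration" as its lobule: it is the
homothet of the region polygon, contracted about the centroid of the
GS-positive pixels inside the region (region centroid if there are
none), with the contraction factor chosen from a grid
(default 0.05–0.95 in steps of 0.05) to maximize

  J(s) = (GS covered / GS total) − λ · (GS-negative covered / GS-negative total),

λ = 1 by default, ties to the smaller scale. The two terms are coverage
*fractions* deliberately: with absolute pixel counts, fully covering a
compact GS core is never optimal whenever the region shape differs from
the blob shape (the background cost of the polygon's corners always
exceeds the last slice of signal), so an absolute-count objective cannot
express "maximum coverage of the marker" — it plateaus around 92–95%
GS-in-zone-3 even on ideal data, versus ≥ 98% for the fractional form.
With no GS signal the objective is monotone decreasing and the smallest
grid scale is returned; with GS filling the region, the largest.

Zones 1 and 2 split the remainder by the normalized periportal
coordinate u = d_edge / (d_edge + d_z3), where the distances are to the
region boundary and the zone-3 boundary respectively: zone 1 is
u ≤ 0.5 (the band between the lobule edge and the midline toward zone
3 — interface points go to the outer zone, so portal tracts on edges
are always zone 1), zone 2 the rest. Along any ray from the core to the
edge the two bands have equal width; for a convex region with a
homothetic core at scale s, the zone-1/2 interface is the homothet at
(1+s)/2. Zone labels are assigned on the image grid, within per-region
footprints taken from the tessellation raster, so the zones of
neighboring lobules partition the tissue exactly.

## Scoring

Per-lobule "surface overlap" is operationalized as
intersection-over-union after greedy matching (all truth-prediction
pairs in descending intersection size, ties to lower ids, each
predicted region consumed once); `intersection-over-truth` is available
as an alternative definition. The mean is unweighted across lobules.
Zonal accuracy is the fraction of portal-tract points labeled zone 1
and of GS-positive pixels labeled zone 3, within the zoned area; the
total is their unweighted mean, falling back to the GS term (with a
warning) when no portal tracts are present. "Circumcircle diameter" of
an irregular lobule is the minimum enclosing circle of its vertices
(`shapely.minimum_bounding_radius`), which equals the classical
circumcircle for regular polygons. Side counts first collapse vertices
closer than 2 px, then merge edges turning by less than 10° — both
configurable — to suppress rasterization and clipping artifacts.

## Synthetic tissue

The generator emulates what a GS immunostain presents at overview
resolution. Defaults, chosen once as the study conditions:

| parameter | default | meaning |
|---|---|---|
| scale | 8 µm/px | overview rendering; a ~100-lobule field at full 0.5 µm/px scan resolution would be ~20,000 px square, and the geometry is resolution-independent |
| mean_lobule_diameter_um | 1200 | circumcircle diameter of the ideal hexagonal lobule; sets the lattice pitch d = (√3/2)·1200 µm |
| site_jitter_sigma_um | 100 | lattice irregularity; reproduces the observed 3–8-side shape range |
| gs_blob_radius_um | 150–250 | star-convex GS blobs (disc with ±8% low-order radial Fourier ripple) |
| gs_centroid_jitter_um / pt_vertex_jitter_um | 25 | marker and portal-tract placement noise |
| pt_dropout | 0.05 | annotation incompleteness |
| compound_event | 0.1 | probability a lobule fuses with a neighbor (two central-vein profiles, one septal outline) |
| noise_sigma | 10 | Gaussian intensity noise on a 40/200 background/marker rendering |
| septa_width_um | 40 | pig mode only |

`SyntheticConfig.clean()` zeroes all stochastic degradations for
truth-recovery baselines. A single seeded RNG drives every layer, so
config + seed reproduces byte-identical output; `corrupt()` re-renders
a section at higher jitter/dropout/noise while keeping the truth
regions fixed, for degradation curves.

The generator does **not** emulate stain intensity variation, vascular
texture, sectioning artifacts, nuclei, or 3D effects — tests passing on
this material validate the geometric pipeline, not robustness to
histochemical variability.

## Problem sizes and numerics

Default test and reproduction runs use 640–1280 px sections (27–105
lobules) and five replicates for the jitter-degradation curve; oracle
comparisons run on ≤256² grids with ≤50 generators, where brute-force
per-pixel labeling is exact. Raster areas count pixel centers, so
zone-area comparisons across resolutions carry a half-pixel-rim
discretization error that shrinks with resolution. Duplicate sites are
rejected (the offending pair is named), as are sites outside the image,
constant images (no threshold exists), self-intersecting polygons, and
zone-3 polygons not contained in their region.

## Known limitations

* The refinement search is greedy per vertex with backtracking over
  candidate landmarks only; it does not explore joint moves of several
  vertices.
* Zone-3 anchoring uses the pooled GS centroid when a region retains
  several GS components after splitting fails or is disabled.
* The object-edge partition is Voronoi-like, not a true Voronoi
  diagram, whenever generators are extended objects; its regions are
  pixel sets, not polygons, and are scored only in raster form.
* Weighted Voronoi variants, geodesic distances, and 3D polyhedral
  lobules are out of scope.
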