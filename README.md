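# lobulizer

Voronoi-diagram modeling of the liver's classic lobular architecture,
with Rappaport-style zonation.

## The problem

The classic (Kiernan) lobule is the polygonal histologic unit of the
liver: a central vein near its middle, portal tracts at its vertices.
Textbooks draw lobules as juxtaposed regular hexagons, but real sections
— pig livers with their visible interlobular septa, or human livers
stained for glutamine synthetase (GS) — show polygons of 3–8 sides with
eccentric central veins. That variability is exactly what a **Voronoi
diagram** predicts: partition the plane by *n* generating sites so that
each convex region contains all points nearer to its site than to any
other, with the central veins as sites. The Delaunay triangulation (the
diagram's dual graph) then encodes lobule adjacency.

`lobulizer` is for liver pathologists and image-analysis researchers who
want to construct such tessellations from marker images or point
annotations, subdivide each lobule into functional zones, and measure
how well the model fits tissue.

## What it computes

Five routes from a section to a lobule map:

| method | input | output |
|---|---|---|
| `seeded_method` | central-vein site coordinates | Voronoi diagram clipped to the image |
| `centroid_method` | GS marker image/mask | Voronoi diagram of GS-particle centroids |
| `object_edge_method` | GS mask | generalized (nearest-object-boundary) partition |
| `modified_object_edge_method` | curated annotation mask | same computation, curated generators |
| `algorithm_method` | GS mask + landmarks | centroid diagram → compound-lobule splitting → landmark-constrained vertex refinement (per-lobule symmetric-difference bound, default 5%) |

Zonation subdivides each region into three concentric zones: zone 3 is
the homothetic shrink of the region polygon maximizing GS coverage while
minimizing GS-negative coverage; zone 1 is the band between the region
edge and the midline toward zone 3 (`u = d_edge/(d_edge+d_z3) ≤ 0.5`);
zone 2 is the equal-width band between them.

Scoring and morphometrics: per-lobule intersection-over-union against
ground-truth labels, portal-tract-in-zone-1 and GS-in-zone-3
percentages, side-count histograms, areas (mm²), and minimum-enclosing
("circumcircle") diameters (mm). A synthetic-tissue generator renders
GS-stain-like sections with exact ground truth (hexagonal-lattice or
Poisson lobules, star-convex GS blobs, portal tracts at vertices,
optional pig-mode septa, compound lobules) so every stage is testable
without slide data.

## Worked example

```python
import lobulizer as lb
from lobulizer.synthetic import SyntheticConfig, generate_tissue

cfg = SyntheticConfig.clean(image_size=(640, 640), rng_seed=0)
gt = generate_tissue(cfg)
mask = lb.despeckle(lb.threshold_marker(gt.image, cfg.scale))
tess = lb.centroid_method(mask, min_area_px=50)
zones = lb.zonate_tessellation(tess, mask)
report = lb.zonal_accuracy(zones, gt.annotations, mask)
print(report.pct_pt_zone1, report.pct_gs_zone3)
```

Running `python examples/02_zonation.py` (which does the above) prints:

```
zonated 27 lobules; zone-3 shrink factors 0.30-0.50
portal tracts in zone 1: 100.0%
GS-positive area in zone 3:  94.4%
total zonal accuracy:  97.2%
```

All portal tracts land in zone 1 because they sit on region edges, where
the periportal coordinate `u` is 0; the GS percentage measures how
tightly the fitted zone-3 cores wrap the perivenular signal. The other
scripts in `examples/` cover the tessellation methods (IoU against
ground truth: 100% seeded, 99.6% centroid, 93.2% object-edge on the
same section), morphometry (the heptagon consistency check prints
0.6597, 0.8891, and 1.1561 mm² for circumradii 0.491, 0.57, 0.65 mm),
and landmark refinement (largest per-lobule mismatch 0.049 against the
0.05 bound).

A thin CLI mirrors the library: `lobulizer simulate | segment |
tessellate | zonate | score | morph` (see `lobulizer --help`).

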