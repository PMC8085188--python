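"""Subdivide each lobule into Rappaport zones 1-3 and score the zonation.

Zone 3 is fitted as the homothetic shrink of each region that best covers
the GS signal; zones 1 and 2 split the remainder into equal-width bands.
Accuracy uses the anatomic landmarks: portal tracts belong in zone 1,
GS-positive tissue in zone 3.
"""

import lobulizer as lb
from lobulizer.synthetic import SyntheticConfig, generate_tissue

cfg = SyntheticConfig.clean(image_size=(640, 640), rng_seed=0)
gt = generate_tissue(cfg)
mask = lb.despeckle(lb.threshold_marker(gt.image, cfg.scale))
tess = lb.centroid_method(mask, min_area_px=50)

zones = lb.zonate_tessellation(tess, mask)
report = lb.zonal_accuracy(zones, gt.annotations, mask)

scales = [z.chosen_scale for z in zones]
print(f"zonated {len(zones)} lobules; zone-3 shrink factors "
      f"{min(scales):.2f}-{max(scales):.2f}")
print(f"portal tracts in zone 1: {report.pct_pt_zone1:5.1f}%")
print(f"GS-positive area in zone 3: {report.pct_gs_zone3:5.1f}%")
print(f"total zonal accuracy: {report.total_accuracy:5.1f}%")
# Portal tracts sit on region edges (u = 0), so a correct tessellation
# puts them all in zone 1; the GS percentage measures how tightly the
# fitted zone-3 cores wrap the perivenular marker signal.
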