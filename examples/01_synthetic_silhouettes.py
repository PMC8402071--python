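"""Generate synthetic berry silhouettes and check them against ground truth.

Builds one outline per shape family, rasterizes it at 0.05 mm/px, and
compares the pixel-count area with the polygon's exact (shoelace) area.
"""

import numpy as np

from berrymorph import synth

for spec in (
    synth.OutlineSpec("circle", 20.0, 20.0),
    synth.OutlineSpec("ellipse", 30.0, 22.0),
    synth.OutlineSpec("drop", 30.0, 22.0, asym=0.3),
):
    poly = synth.make_outline(spec)
    mask = synth.rasterize(poly, scale=0.05)
    area_poly, _, _ = synth._shoelace_centroid(poly)
    area_px = mask.pixels.sum() * mask.scale**2
    print(
        f"{spec.family:8s} L={spec.length:5.1f} W={spec.width:5.1f}  "
        f"polygon area {area_poly:7.2f} mm^2, raster area {area_px:7.2f} mm^2 "
        f"({100 * (area_px / area_poly - 1):+.2f}%)"
    )

# a small two-variety panel with recorded (L, W, T) truth per berry
configs = [
    synth.VarietyConfig("Round", "sphere", 25.0, 1.0, 24.5, 1.0, 24.5, 1.0, n_berries=5),
    synth.VarietyConfig("Long", "ellipse", 33.0, 1.5, 21.0, 1.0, 21.5, 1.0, n_berries=5),
]
masks, truth = synth.generate_dataset(configs, master_seed=11, scale=0.1)
print(f"\n{len(masks)} masks (two orientations per berry); truth table:")
print(truth.round(2).to_string(index=False))
print("\nThe horizontal view is the L x W silhouette; the vertical view is "
      "the W x T cross-section.")
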