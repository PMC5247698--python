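"""Hepatocyte and lobule morphometry from raw measurements.

A hepatocyte measured along two perpendicular diameters is treated as an
ellipse; the lobule is a regular hexagon whose radius is the
portal-tract-to-central-vein distance; their area ratio approximates the
hepatocytes per lobule.
"""

import numpy as np

from steatoquant import (
    HepatocyteMeasure,
    biopsy_hepatocyte_area,
    biopsy_lobule_radius,
    ellipse_area,
    hepatocytes_per_lobule,
)

print(f"ellipse_area(20, 20) = {ellipse_area(20, 20):.1f} um^2 (circle, d=20 um)")

rng = np.random.default_rng(1)
hepatocytes = [
    HepatocyteMeasure(d1, d2)
    for d1, d2 in zip(rng.normal(19, 2, 50).clip(5), rng.normal(19, 2, 50).clip(5))
]
distances = rng.normal(500, 40, 8).clip(300)

ha = biopsy_hepatocyte_area(hepatocytes)
lr = biopsy_lobule_radius(distances)
print(f"median hepatocyte area HA = {ha:.1f} um^2 (50 cells, ~19 um diameters)")
print(f"median lobule radius   LR = {lr:.1f} um (8 portal-tract distances)")
print(f"hepatocytes per lobule (circumradius hexagon) = {hepatocytes_per_lobule(lr, ha):.0f}")
print(f"hepatocytes per lobule (apothem hexagon)      = "
      f"{hepatocytes_per_lobule(lr, ha, 'apothem'):.0f}  (exactly 4/3 larger)")

# HpL is an areas ratio on the section plane, not a counted cell number:
# roughly two thousand hepatocyte cross-sections tile a healthy lobule.
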