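"""CIELAB skin color and adapted Michelson facial contrast.

Builds one color measurement from per-region CIELAB values, computes the
overall skin color (mean of the five skin areas) and the feature/skin
contrasts, then shows the same region-mean machinery working on an sRGB
image with a binary mask.
"""

import numpy as np

from facedim import ColorMeasurement, contrast_profile, mean_skin_color, region_mean

m = ColorMeasurement(
    specimen_id="demo",
    sex="F",
    region_means={
        "cheek": (62.0, 13.0, 16.0),
        "forehead": (60.0, 13.0, 17.0),
        "eye_skin": (58.0, 12.0, 16.0),
        "brow_skin": (59.0, 12.0, 16.0),
        "lips_skin": (57.0, 13.0, 16.0),
        "eye_feature": (28.0, 6.0, 8.0),
        "brow_feature": (22.0, 8.0, 10.0),
        "lips_feature": (45.0, 22.0, 14.0),
    },
)

L, a, b = mean_skin_color(m)
print(f"overall skin color: L*={L:.2f} a*={a:.2f} b*={b:.2f}")

prof = contrast_profile(m)
for feature in ("eye", "brow", "lips"):
    c = prof.get(feature, "L")
    print(f"{feature:5s} luminance contrast C_f = {c:+.3f}")
# C_f = (L_s - L_f)/(L_f + L_s): positive = feature darker than its
# surrounding skin; brows are darkest, so they carry the largest contrast.

# The same measurement from pixels: a uniform mid-gray patch
img = np.full((8, 8, 3), 128, dtype=np.uint8)
mask = np.zeros((8, 8), dtype=bool)
mask[2:6, 2:6] = True
print("region mean of uniform gray patch:", tuple(round(v, 3) for v in region_mean(img, mask)))
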