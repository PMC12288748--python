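"""How sensitive is the extracted pattern to the yellowness threshold?

The default rule marks a pixel as pattern when its red-minus-blue value
exceeds 110% of the scute mean. This script perturbs that ratio by ±5% and
±20% on a scute with an analytically known answer: a radial gradient whose
fractional area obeys FA(tau) = (1 - tau/3)², so the printed percent
changes can be checked against the closed form.
"""

import numpy as np

import scutepattern as sp
from scutepattern.calibration import CalibratedImage, ImageMeta, ScuteMask
from scutepattern.extraction import ExtractionConfig

# disc scute, red-minus-blue falling linearly from d0 at the center to 0
R, size, d0 = 250, 540, 0.5
rr, cc = np.mgrid[0:size, 0:size]
r = np.hypot(rr - (size - 1) / 2, cc - (size - 1) / 2)
mask_arr = r <= R
d = np.where(mask_arr, d0 * (1 - r / R), 0.0)
pixels = np.zeros((size, size, 3))
pixels[..., 2] = 0.05
pixels[..., 0] = 0.05 + d
pixels[..., 1] = 0.30
image = CalibratedImage(pixels, mm_per_pixel=0.2, meta=ImageMeta(view="top"))
mask = ScuteMask(mask_arr, np.zeros_like(mask_arr))

# morphology off: the gradient analysis isolates the thresholding step
config = ExtractionConfig(min_object_mm2=0, max_hole_mm2=0, opening_mm=0)
table = sp.threshold_sensitivity(
    [(image, mask)], taus=(0.90, 1.05, 1.15, 1.30), baseline=1.10, config=config
)

base = (1 - 1.10 / 3) ** 2
print(f"{'tau':>5} {'measured %change':>17} {'closed form':>12}")
for _, row in table.iterrows():
    closed = ((1 - row["tau"] / 3) ** 2 - base) / base * 100
    print(f"{row['tau']:>5.2f} {row['pct_change']:>16.2f}% {closed:>11.2f}%")
print("\nLowering the threshold admits more pixels (positive change); raising"
      "\nit removes them. Small ±5% nudges move the area by ~5%, the ±20%"
      "\nextremes by ~20%.")
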