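"""Four-step yellow-pattern extraction.

Within a scute, pattern pixels are those whose red-minus-blue value exceeds
a dynamic threshold — 110% of the scute's mean red-minus-blue by default.
(Yellow is predominantly red plus green light with little blue, so R − B is
a cheap yellowness score that adapts to each image's lighting.) The raw
"prepattern" is then cleaned at a fixed physical scale: connected groups
smaller than 1 mm² are removed, enclosed holes smaller than 1 mm² are
filled, and the edges are smoothed by a morphological opening with a
0.5 mm × 0.5 mm square structuring element.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import morphology

from .calibration import CalibratedImage, ScuteMask

_STRUCT4 = ndimage.generate_binary_structure(2, 1)
_STRUCT8 = ndimage.generate_binary_structure(2, 2)


@dataclass(frozen=True)
class ExtractionConfig:
    """Tunable parameters of the extraction pipeline.

    tau — threshold ratio on the mean red-minus-blue (1.10 = "10% more
    yellow than average"); min_object_mm2 / max_hole_mm2 — physical size
    cutoffs for steps 2 and 3; opening_mm — side of the square structuring
    element for step 4; connectivity — object connectivity (8 by default,
    holes always use the complementary 4).
    """

    tau: float = 1.10
    min_object_mm2: float = 1.0
    max_hole_mm2: float = 1.0
    opening_mm: float = 0.5
    connectivity: int = 8

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if min(self.min_object_mm2, self.max_hole_mm2, self.opening_mm) < 0:
            raise ValueError("sizes must be >= 0")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


@dataclass
class BinaryPattern:
    """Boolean pattern grid plus the scale and config that produced it."""

    pattern: np.ndarray
    mm_per_pixel: float
    config_used: ExtractionConfig = dataclasses.field(default_factory=ExtractionConfig)

    def __post_init__(self):
        self.pattern = np.asarray(self.pattern, dtype=bool)
        if self.mm_per_pixel <= 0:
            raise ValueError("mm_per_pixel must be > 0")

    @property
    def n_pixels(self) -> int:
        return int(self.pattern.sum())


def _structure(connectivity: int):
    return _STRUCT8 if connectivity == 8 else _STRUCT4


def mm2_to_px(area_mm2: float, mm_per_pixel: float) -> int:
    """Pixel count for a physical area; round() reproduces the canonical
    25 px (at 5 px/mm) and 400 px (at 20 px/mm) endpoints for 1 mm²."""
    return int(round(area_mm2 / mm_per_pixel**2))


def yellow_prepattern(
    image: CalibratedImage, mask: ScuteMask, tau: float = 1.10
) -> BinaryPattern:
    """Step 1: dynamic red-minus-blue threshold.

    A scute pixel is pattern iff R − B > tau · mean(R − B over the scute).
    If the scute mean is not positive (a bluer-than-red scute) the rule is
    still applied literally, with a warning — the threshold then selects
    pixels *less* blue-dominant than tau times the mean.
    """
    if not mask.mask.any():
        raise ValueError("empty scute mask")
    d = image.pixels[..., 0] - image.pixels[..., 2]
    m = float(d[mask.mask].mean())
    if m <= 0:
        warnings.warn(
            f"mean red-minus-blue over the scute is {m:.4g} <= 0; "
            "thresholding rule applied literally",
            stacklevel=2,
        )
    pattern = mask.mask & (d > tau * m)
    return BinaryPattern(pattern, image.mm_per_pixel)


def remove_small_objects(
    pattern: BinaryPattern, min_mm2: float = 1.0, connectivity: int = 8
) -> BinaryPattern:
    """Step 2: drop connected groups smaller than ``min_mm2``.

    Surviving components have pixel count >= round(min_mm2 / mm_per_pixel²);
    no pixel is added.
    """
    min_px = mm2_to_px(min_mm2, pattern.mm_per_pixel)
    if min_px <= 1:
        return dataclasses.replace(pattern, pattern=pattern.pattern.copy())
    # max_size removes components <= max_size, so min_px - 1 keeps >= min_px
    cleaned = morphology.remove_small_objects(
        pattern.pattern, max_size=min_px - 1, connectivity=2 if connectivity == 8 else 1
    )
    return dataclasses.replace(pattern, pattern=cleaned)


def fill_small_holes(pattern: BinaryPattern, max_hole_mm2: float = 1.0) -> BinaryPattern:
    """Step 3: fill enclosed gaps strictly smaller than ``max_hole_mm2``.

    A hole is a 4-connected background component fully enclosed by pattern
    (i.e. not connected to the region outside it); holes with pixel count
    < round(max_hole_mm2 / mm_per_pixel²) become pattern. A hole exactly at
    the threshold stays open.
    """
    max_px = mm2_to_px(max_hole_mm2, pattern.mm_per_pixel)
    out = pattern.pattern.copy()
    labels, n = ndimage.label(~out, structure=_STRUCT4)
    if n:
        border = np.unique(
            np.concatenate([labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]])
        )
        counts = np.bincount(labels.ravel(), minlength=n + 1)
        fill = np.ones(n + 1, dtype=bool)
        fill[0] = False
        fill[border] = False
        fill &= counts < max_px
        out[fill[labels]] = True
    return dataclasses.replace(pattern, pattern=out)


def smooth_edges(pattern: BinaryPattern, opening_mm: float = 0.5) -> BinaryPattern:
    """Step 4: morphological opening with a square structuring element.

    The side is k = max(1, round(opening_mm / mm_per_pixel)) pixels; opening
    (erosion then dilation) removes protrusions and thin bridges thinner
    than k without growing the pattern, so the output is a subset of the
    input and the operation is idempotent.
    """
    k = max(1, int(round(opening_mm / pattern.mm_per_pixel)))
    if k == 1:
        return dataclasses.replace(pattern, pattern=pattern.pattern.copy())
    se = np.ones((k, k), dtype=bool)
    opened = ndimage.binary_opening(pattern.pattern, structure=se)
    return dataclasses.replace(pattern, pattern=opened)


def extract_pattern(
    image: CalibratedImage, mask: ScuteMask, config: ExtractionConfig | None = None
) -> BinaryPattern:
    """Full extraction: threshold, remove small objects, fill small holes,
    smooth edges — in that exact order."""
    cfg = config or ExtractionConfig()
    p = yellow_prepattern(image, mask, tau=cfg.tau)
    p = remove_small_objects(p, cfg.min_object_mm2, cfg.connectivity)
    p = fill_small_holes(p, cfg.max_hole_mm2)
    p = smooth_edges(p, cfg.opening_mm)
    return dataclasses.replace(p, config_used=cfg)
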