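"""Image loading, gray-card color calibration, scale estimation and scute
mask extraction.

A photograph enters the pipeline as an RGB array together with the location
of an 18% gray reference card. Calibration is a per-channel linear gain that
maps the card to its nominal reflectance, after which pixel values are
interpreted as reflectance in [0, 1]. The physical scale is recovered from
the pixel length of the card's 50 mm edge. The analysis region (one scute)
is delimited by a hand-drawn closed outline in a color not found elsewhere
in the image — pure green (0, 255, 0) by convention.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

import imageio.v3 as iio

#: Reflectance of the standard gray card.
GRAY_CARD_REFLECTANCE = 0.18
#: Length of the card edge used for scale estimation, in mm.
GRAY_CARD_EDGE_MM = 50.0
#: The five standardized viewpoints.
VIEWS = ("top", "left", "right", "front", "back")
#: Outline color convention: pure green, in [0, 1] units.
DEFAULT_OUTLINE_RGB = (0.0, 1.0, 0.0)

_STRUCT4 = ndimage.generate_binary_structure(2, 1)  # 4-connectivity
_STRUCT8 = ndimage.generate_binary_structure(2, 2)  # 8-connectivity


@dataclass(frozen=True)
class ImageMeta:
    """Replicate metadata attached to each photograph."""

    turtle_id: str = "unknown"
    view: str = "top"
    replicate: int = 1
    source: str = "synthetic"

    def __post_init__(self):
        if self.view not in VIEWS:
            raise ValueError(f"view must be one of {VIEWS}, got {self.view!r}")
        if self.replicate < 1:
            raise ValueError("replicate must be >= 1")


@dataclass
class CalibratedImage:
    """Reflectance-scaled RGB image with physical scale and metadata.

    ``pixels`` is an H×W×3 float array clipped to [0, 1]; ``mm_per_pixel``
    converts pixel lengths to millimetres.
    """

    pixels: np.ndarray
    mm_per_pixel: float
    meta: ImageMeta = dataclasses.field(default_factory=ImageMeta)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be an H x W x 3 array")
        if self.mm_per_pixel <= 0:
            raise ValueError("mm_per_pixel must be > 0")


@dataclass
class ScuteMask:
    """Boolean scute-interior mask plus the outline pixels it came from."""

    mask: np.ndarray
    outline: np.ndarray

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        self.outline = np.asarray(self.outline, dtype=bool)
        if self.mask.shape != self.outline.shape:
            raise ValueError("mask and outline shapes differ")
        if not self.mask.any():
            raise ValueError("scute mask is empty")
        if (self.mask & self.outline).any():
            raise ValueError("mask and outline overlap")
        _, n = ndimage.label(self.mask, structure=_STRUCT8)
        if n != 1:
            raise ValueError(f"scute mask has {n} components, expected 1")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


def load_image(path) -> np.ndarray:
    """Read an 8- or 16-bit RGB PNG/TIFF into a float array in [0, 1]."""
    arr = iio.imread(path)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[2] == 4:  # drop alpha
        arr = arr[..., :3]
    if arr.dtype == np.uint8:
        return arr.astype(float) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(float) / 65535.0
    return np.clip(arr.astype(float), 0.0, 1.0)


def save_image(path, pixels: np.ndarray) -> None:
    """Write a float [0, 1] RGB array as an 8-bit PNG."""
    arr = np.clip(np.asarray(pixels, dtype=float), 0.0, 1.0)
    iio.imwrite(path, np.round(arr * 255.0).astype(np.uint8))


def save_mask(path, mask: np.ndarray) -> None:
    """Write a boolean mask as a 0/255 8-bit PNG."""
    iio.imwrite(path, np.where(np.asarray(mask, bool), 255, 0).astype(np.uint8))


def load_mask(path) -> np.ndarray:
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr > 0


def estimate_scale(card_edge_pixels: float, card_edge_mm: float = GRAY_CARD_EDGE_MM) -> float:
    """mm per pixel from the measured pixel length of the card edge.

    The 50 mm card edge spanning ``card_edge_pixels`` pixels gives
    ``50 / card_edge_pixels`` mm per pixel.
    """
    if card_edge_pixels <= 0:
        raise ValueError("card_edge_pixels must be > 0")
    return card_edge_mm / card_edge_pixels


def calibrate_gray_card(
    raw: np.ndarray,
    card_roi: tuple[int, int, int, int],
    mm_per_pixel: float = 1.0,
    meta: ImageMeta | None = None,
    target: float = GRAY_CARD_REFLECTANCE,
) -> CalibratedImage:
    """Linear gray-card calibration.

    Each channel is multiplied by ``target / mean(channel over card_roi)``
    and clipped to [0, 1], so the card region averages the nominal 18%
    reflectance afterwards. ``card_roi`` is (row, col, height, width); under
    uneven lighting the caller may pass any sub-region of the card that is
    lit like the subject.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 3 or raw.shape[2] != 3:
        raise ValueError("raw must be an H x W x 3 array")
    r, c, h, w = card_roi
    if r < 0 or c < 0 or h <= 0 or w <= 0 or r + h > raw.shape[0] or c + w > raw.shape[1]:
        raise ValueError("card_roi out of image bounds")
    card = raw[r : r + h, c : c + w, :]
    means = card.reshape(-1, 3).mean(axis=0)
    if np.any(means <= 0):
        raise ValueError("degenerate card ROI: zero-mean channel")
    gains = target / means
    pixels = np.clip(raw * gains[None, None, :], 0.0, 1.0)
    return CalibratedImage(pixels=pixels, mm_per_pixel=mm_per_pixel, meta=meta or ImageMeta())


def extract_scute_mask(
    image,
    outline_rgb: tuple[float, float, float] = DEFAULT_OUTLINE_RGB,
    tolerance: float = 0.0,
) -> ScuteMask:
    """Locate the hand-drawn outline and flood-fill its interior.

    Outline pixels match ``outline_rgb`` within ``tolerance`` per channel
    (exact match by default — outlines are drawn digitally so the color is
    exact). The exterior is found by 4-connected flood fill from the image
    border over non-outline pixels; the interior is everything else. The
    interior must be exactly one connected region, otherwise the outline is
    not closed or is ambiguous.
    """
    pixels = image.pixels if isinstance(image, CalibratedImage) else np.asarray(image, dtype=float)
    target = np.asarray(outline_rgb, dtype=float)
    outline = np.all(np.abs(pixels - target[None, None, :]) <= tolerance, axis=2)
    if not outline.any():
        raise ValueError("no outline found")
    # exterior: non-outline pixels 4-connected to the border
    free = ~outline
    labels, _ = ndimage.label(free, structure=_STRUCT4)
    border_labels = np.unique(
        np.concatenate([labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]])
    )
    border_labels = border_labels[border_labels != 0]
    exterior = np.isin(labels, border_labels)
    interior = free & ~exterior
    if not interior.any():
        raise ValueError("outline not closed / ambiguous: empty interior")
    # the interior must be a single region
    int_labels = np.unique(labels[interior])
    if len(int_labels) != 1:
        raise ValueError("outline not closed / ambiguous: multiple interior regions")
    return ScuteMask(mask=interior, outline=outline)


SIDECAR_COLUMNS = [
    "image_path",
    "turtle_id",
    "view",
    "replicate",
    "source",
    "card_x",
    "card_y",
    "card_w",
    "card_h",
    "card_edge_px",
]


def read_sidecar(path) -> pd.DataFrame:
    """Read the per-image sidecar CSV (one row per photograph)."""
    df = pd.read_csv(path)
    missing = [c for c in SIDECAR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sidecar CSV missing columns: {missing}")
    return df


def load_calibrated(row: pd.Series | dict, root=None) -> CalibratedImage:
    """Load and calibrate one image described by a sidecar row."""
    import os

    row = dict(row)
    path = row["image_path"]
    if root is not None:
        path = os.path.join(root, path)
    raw = load_image(path)
    roi = (int(row["card_y"]), int(row["card_x"]), int(row["card_h"]), int(row["card_w"]))
    meta = ImageMeta(
        turtle_id=str(row["turtle_id"]),
        view=str(row["view"]),
        replicate=int(row["replicate"]),
        source=str(row["source"]),
    )
    return calibrate_gray_card(
        raw, roi, mm_per_pixel=estimate_scale(float(row["card_edge_px"])), meta=meta
    )


def load_scene(
    row: pd.Series | dict,
    root=None,
    outline_rgb: tuple[float, float, float] = DEFAULT_OUTLINE_RGB,
    tolerance: float = 0.0,
) -> tuple[CalibratedImage, ScuteMask]:
    """Load one sidecar row and return the calibrated image plus its scute
    mask.

    The outline is located on the stored image *before* the gray-card gain
    is applied: the outline is drawn digitally at an exact color, and the
    per-channel calibration gain would shift that color. Calibration does
    not move pixels, so the mask remains valid for the calibrated image.
    """
    import os

    row = dict(row)
    path = row["image_path"]
    if root is not None:
        path = os.path.join(root, path)
    raw = load_image(path)
    mask = extract_scute_mask(raw, outline_rgb=outline_rgb, tolerance=tolerance)
    roi = (int(row["card_y"]), int(row["card_x"]), int(row["card_h"]), int(row["card_w"]))
    meta = ImageMeta(
        turtle_id=str(row["turtle_id"]),
        view=str(row["view"]),
        replicate=int(row["replicate"]),
        source=str(row["source"]),
    )
    image = calibrate_gray_card(
        raw, roi, mm_per_pixel=estimate_scale(float(row["card_edge_px"])), meta=meta
    )
    return image, mask
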