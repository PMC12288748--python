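"""Synthetic scute scenes and surveys with exact ground truth.

Every downstream stage of the toolkit (calibration, pattern extraction, the
19 measurements, the CV framework, consensus scoring) is testable against
scenes generated here: a dark scute region bounded by a closed pure-green
outline, yellow pattern objects of controllable number/size/shape/contrast,
a uniform gray-card patch, and photo-to-photo replicate jitter (illumination
gain, sub-pixel shift, small rotation) emulating duplicate hand-held
photographs.

Rasterization is deliberately simple so ground truth is exact: a disc
includes a pixel iff the pixel center lies within the radius; stripes are
axis-aligned rectangles; blobs are unions of overlapping discs. The outline
is drawn 2 px thick (the inner boundary ring of the scute polygon) so it
stays closed under jitter.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import polygon2mask

from .calibration import GRAY_CARD_EDGE_MM

#: Nine pattern categories shown to survey volunteers.
SURVEY_CATEGORIES = (
    "M-shaped",
    "Single spotted",
    "Striated",
    "Blotchy",
    "Spotted",
    "Speckled",
    "Banded",
    "Patchy",
    "Starburst",
)

_STRUCT4 = ndimage.generate_binary_structure(2, 1)
_STRUCT8 = ndimage.generate_binary_structure(2, 2)

# Study-condition defaults: 5 px/mm scale, dark olive scute ground, yellow
# ochre pattern, card painted one stop brighter than its 18% target so the
# calibration gain is non-trivial.
DEFAULT_MM_PER_PIXEL = 0.2
DEFAULT_BACKGROUND_RGB = (0.13, 0.11, 0.07)
DEFAULT_OBJECT_RGB = (0.55, 0.42, 0.08)
DEFAULT_CARD_RGB = (0.36, 0.36, 0.36)
DEFAULT_BIN_RGB = (0.75, 0.73, 0.70)
DEFAULT_NOISE_SD = 0.01


@dataclass(frozen=True)
class ObjectSpec:
    """One pattern object. ``center`` is (row, col) in pixels; sizes in mm."""

    shape: str  # disc | stripe | blob
    center: tuple[float, float]
    radius_mm: float | None = None
    width_mm: float | None = None
    height_mm: float | None = None
    rgb: tuple[float, float, float] = DEFAULT_OBJECT_RGB
    seed: int = 0  # used by blob lobes

    def __post_init__(self):
        if self.shape not in ("disc", "stripe", "blob"):
            raise ValueError(f"unknown object shape {self.shape!r}")


@dataclass(frozen=True)
class SyntheticSceneSpec:
    image_size: tuple[int, int] = (240, 320)
    scute_polygon: tuple[tuple[float, float], ...] = ()
    background_rgb: tuple[float, float, float] = DEFAULT_BACKGROUND_RGB
    objects: tuple[ObjectSpec, ...] = ()
    card_rect: tuple[int, int, int, int] = (10, 240, 40, 60)  # row, col, h, w
    card_rgb: tuple[float, float, float] = DEFAULT_CARD_RGB
    bin_rgb: tuple[float, float, float] = DEFAULT_BIN_RGB
    mm_per_pixel: float = DEFAULT_MM_PER_PIXEL
    noise_sd: float = DEFAULT_NOISE_SD
    seed: int = 0

    def __post_init__(self):
        if self.mm_per_pixel <= 0:
            raise ValueError("mm_per_pixel must be > 0")
        for rgb in (self.background_rgb, self.card_rgb, self.bin_rgb):
            if min(rgb) < 0 or max(rgb) > 1:
                raise ValueError("rgb values must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def card_edge_px(self) -> float:
        """Pixel length of the 50 mm card edge at this scene's scale."""
        return GRAY_CARD_EDGE_MM / self.mm_per_pixel


@dataclass(frozen=True)
class ReplicateJitterSpec:
    """Photo-to-photo jitter for duplicate shots of the same view."""

    gain_sd: float = 0.05
    shift_px_sd: float = 1.0
    rot_deg_sd: float = 1.0
    n_replicates: int = 2
    seed: int = 0

    def __post_init__(self):
        if min(self.gain_sd, self.shift_px_sd, self.rot_deg_sd) < 0:
            raise ValueError("jitter sds must be >= 0")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")


@dataclass
class GroundTruth:
    """Exact per-scene truth, recorded at rasterization time."""

    n_objects: int
    object_pixel_areas: list[int]
    scute_interior_px: int
    fractional_area: float
    mm_per_pixel: float
    scute_mask: np.ndarray = field(repr=False)
    object_mask: np.ndarray = field(repr=False)
    outline: np.ndarray = field(repr=False)


def _rasterize_object(obj: ObjectSpec, shape, mm_per_pixel: float) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    r0, c0 = obj.center
    if obj.shape == "disc":
        if obj.radius_mm is None:
            raise ValueError("disc needs radius_mm")
        rad_px = obj.radius_mm / mm_per_pixel
        return (rr - r0) ** 2 + (cc - c0) ** 2 <= rad_px**2
    if obj.shape == "stripe":
        if obj.width_mm is None or obj.height_mm is None:
            raise ValueError("stripe needs width_mm and height_mm")
        hw = 0.5 * obj.width_mm / mm_per_pixel
        hh = 0.5 * obj.height_mm / mm_per_pixel
        return (np.abs(rr - r0) <= hh) & (np.abs(cc - c0) <= hw)
    # blob: union of a few jittered discs around the center
    if obj.radius_mm is None:
        raise ValueError("blob needs radius_mm")
    rng = np.random.default_rng(obj.seed)
    rad_px = obj.radius_mm / mm_per_pixel
    m = np.zeros(shape, dtype=bool)
    for _ in range(4):
        dr, dc = rng.normal(0.0, 0.6 * rad_px, size=2)
        m |= (rr - (r0 + dr)) ** 2 + (cc - (c0 + dc)) ** 2 <= (0.7 * rad_px) ** 2
    m |= (rr - r0) ** 2 + (cc - c0) ** 2 <= rad_px**2
    return m


def _scute_regions(spec: SyntheticSceneSpec):
    """Polygon mask, 2-px outline ring, and the interior they enclose."""
    poly = polygon2mask(spec.image_size, np.asarray(spec.scute_polygon, dtype=float))
    if not poly.any():
        raise ValueError("scute polygon rasterizes to an empty region")
    interior = ndimage.binary_erosion(poly, structure=_STRUCT4, iterations=2)
    outline = poly & ~interior
    if not interior.any():
        raise ValueError("scute polygon too small for a 2 px outline")
    return poly, outline, interior


def generate_scene(spec: SyntheticSceneSpec) -> tuple[np.ndarray, GroundTruth]:
    """Rasterize a scene and record its exact ground truth.

    Returns the H×W×3 float image (values in [0, 1]; the outline is exactly
    pure green) and a :class:`GroundTruth` with the true object count,
    per-object pixel areas, scute-interior pixel count and fractional area.
    """
    H, W = spec.image_size
    _, outline, interior = _scute_regions(spec)

    r, c, h, w = spec.card_rect
    card = np.zeros((H, W), dtype=bool)
    card[r : r + h, c : c + w] = True
    if (card & (outline | interior)).any():
        raise ValueError("card_rect overlaps the scute region")

    union = np.zeros((H, W), dtype=bool)
    img = np.empty((H, W, 3), dtype=float)
    img[:] = np.asarray(spec.bin_rgb)
    img[interior] = np.asarray(spec.background_rgb)
    per_object_px = []
    for obj in spec.objects:
        m = _rasterize_object(obj, (H, W), spec.mm_per_pixel)
        if (m & outline).any() or (m & ~interior).any():
            raise ValueError(f"object {obj} overlaps the scute outline or exterior")
        per_object_px.append(int(m.sum()))
        union |= m
        img[m] = np.asarray(obj.rgb)
    img[card] = np.asarray(spec.card_rgb)

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 1.0)
    img[outline] = (0.0, 1.0, 0.0)  # drawn last so the color stays exact

    # connected object count of the union (overlapping objects merge)
    _, n_obj = ndimage.label(union, structure=_STRUCT8)
    n_int = int(interior.sum())
    gt = GroundTruth(
        n_objects=int(n_obj),
        object_pixel_areas=per_object_px,
        scute_interior_px=n_int,
        fractional_area=float(union.sum()) / n_int,
        mm_per_pixel=spec.mm_per_pixel,
        scute_mask=interior,
        object_mask=union,
        outline=outline,
    )
    return img, gt


def _rigid(points, angle_deg: float, shift, center) -> np.ndarray:
    pts = np.asarray(points, dtype=float) - np.asarray(center)
    a = np.deg2rad(angle_deg)
    rot = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
    return pts @ rot.T + np.asarray(center) + np.asarray(shift)


def generate_replicates(
    spec: SyntheticSceneSpec, jitter: ReplicateJitterSpec
) -> list[tuple[np.ndarray, GroundTruth]]:
    """Duplicate photographs of one scene under independent jitter.

    Each replicate draws a multiplicative illumination gain, a sub-pixel
    translation and a small rotation about the image center; the rigid part
    is applied to the scene geometry (polygon vertices and object centers)
    before re-rasterization, so outlines remain exact-color and each
    replicate carries exact ground truth. With all-zero jitter the
    replicates are bit-identical.
    """
    rng = np.random.default_rng(jitter.seed)
    center = (np.asarray(spec.image_size, dtype=float) - 1.0) / 2.0
    out = []
    for _ in range(jitter.n_replicates):
        gain = float(rng.normal(1.0, jitter.gain_sd)) if jitter.gain_sd > 0 else 1.0
        shift = rng.normal(0.0, jitter.shift_px_sd, size=2) if jitter.shift_px_sd > 0 else (0.0, 0.0)
        angle = float(rng.normal(0.0, jitter.rot_deg_sd)) if jitter.rot_deg_sd > 0 else 0.0

        poly = tuple(map(tuple, _rigid(spec.scute_polygon, angle, shift, center)))
        objs = []
        for obj in spec.objects:
            (nc,) = _rigid([obj.center], angle, shift, center)
            objs.append(dataclasses.replace(obj, center=(float(nc[0]), float(nc[1]))))

        def g(rgb):
            return tuple(float(np.clip(v * gain, 0.0, 1.0)) for v in rgb)

        jit_spec = dataclasses.replace(
            spec,
            scute_polygon=poly,
            objects=tuple(
                dataclasses.replace(o, rgb=g(o.rgb)) for o in objs
            ),
            background_rgb=g(spec.background_rgb),
            card_rgb=g(spec.card_rgb),
            bin_rgb=g(spec.bin_rgb),
        )
        out.append(generate_scene(jit_spec))
    return out


def octagon_polygon(center, radius_px: float) -> tuple[tuple[float, float], ...]:
    """A regular octagon approximating a roundish scute boundary."""
    ang = np.deg2rad(np.arange(8) * 45.0 + 22.5)
    return tuple(
        (center[0] + radius_px * np.sin(a), center[1] + radius_px * np.cos(a)) for a in ang
    )


def random_disc_scene(
    seed: int,
    n_objects: int | None = None,
    image_size=(240, 320),
    mm_per_pixel: float = DEFAULT_MM_PER_PIXEL,
    radius_mm_range=(2.0, 3.0),
    min_separation_mm: float = 2.0,
    noise_sd: float = DEFAULT_NOISE_SD,
) -> SyntheticSceneSpec:
    """A scene of well-separated yellow discs inside an octagonal scute.

    Disc radii and the pairwise separation respect the extraction
    constraints (objects at least ``min_separation_mm`` apart and well above
    the 1 mm² minimum size), so the true object count is recoverable.
    """
    rng = np.random.default_rng(seed)
    H, W = image_size
    cy, cx = H * 0.55, W * 0.38
    radius_px = 0.42 * min(H, W)
    poly = octagon_polygon((cy, cx), radius_px)
    if n_objects is None:
        n_objects = int(rng.integers(2, 7))
    sep_px = min_separation_mm / mm_per_pixel
    placed, objs = [], []
    inner = radius_px * np.cos(np.pi / 8) - 4  # inradius minus outline margin
    for _ in range(n_objects):
        radius = float(rng.uniform(*radius_mm_range))
        rad_px = radius / mm_per_pixel
        for _attempt in range(500):
            rr = float(rng.uniform(cy - inner, cy + inner))
            cc = float(rng.uniform(cx - inner, cx + inner))
            if np.hypot(rr - cy, cc - cx) + rad_px + sep_px > inner:
                continue
            if all(
                np.hypot(rr - pr, cc - pc) >= rad_px + prad + sep_px
                for pr, pc, prad in placed
            ):
                placed.append((rr, cc, rad_px))
                objs.append(ObjectSpec("disc", (rr, cc), radius_mm=radius))
                break
        else:  # pragma: no cover - placement failure at sane densities
            raise RuntimeError("could not place all objects")
    return SyntheticSceneSpec(
        image_size=image_size,
        scute_polygon=poly,
        objects=tuple(objs),
        mm_per_pixel=mm_per_pixel,
        noise_sd=noise_sd,
        seed=seed,
    )


def generate_survey(
    n_turtles: int,
    n_volunteers: int,
    category_probs,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate binary category votes, one Bernoulli draw per
    (turtle, volunteer, category).

    ``category_probs`` gives, per category, the probability a volunteer
    marks it as applying. Returns a long-format DataFrame with columns
    turtle_id, volunteer, category, vote.
    """
    probs = np.asarray(category_probs, dtype=float)
    if probs.shape != (len(SURVEY_CATEGORIES),):
        raise ValueError(f"category_probs must have length {len(SURVEY_CATEGORIES)}")
    if probs.min() < 0 or probs.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    votes = rng.random((n_turtles, n_volunteers, len(SURVEY_CATEGORIES))) < probs
    idx = pd.MultiIndex.from_product(
        [
            [f"t{i:03d}" for i in range(n_turtles)],
            [f"v{j:02d}" for j in range(n_volunteers)],
            list(SURVEY_CATEGORIES),
        ],
        names=["turtle_id", "volunteer", "category"],
    )
    return pd.DataFrame({"vote": votes.astype(int).ravel()}, index=idx).reset_index()
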