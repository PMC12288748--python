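import numpy as np
import pytest

import scutepattern as sp
from scutepattern.calibration import CalibratedImage, ImageMeta, ScuteMask


@pytest.fixture(scope="session")
def disc_scene():
    """One seeded multi-disc scene with its exact ground truth."""
    spec = sp.random_disc_scene(seed=7)
    img, gt = sp.generate_scene(spec)
    return spec, img, gt


@pytest.fixture(scope="session")
def analyzed_scene(disc_scene):
    """The disc scene carried through mask extraction, calibration and
    pattern extraction."""
    spec, img, gt = disc_scene
    mask = sp.extract_scute_mask(img)
    r, c, h, w = spec.card_rect
    cal = sp.calibrate_gray_card(img, (r, c, h, w), mm_per_pixel=spec.mm_per_pixel)
    pattern = sp.extract_pattern(cal, mask)
    return spec, cal, mask, pattern, gt


def rect_scute(shape, box):
    """ScuteMask that is a solid rectangle (no outline pixels)."""
    mask = np.zeros(shape, dtype=bool)
    r0, c0, r1, c1 = box
    mask[r0:r1, c0:c1] = True
    return ScuteMask(mask, np.zeros(shape, dtype=bool))


def flat_image(shape, rgb, mm_per_pixel=1.0, view="top", **meta):
    px = np.empty((*shape, 3), dtype=float)
    px[:] = np.asarray(rgb, dtype=float)
    return CalibratedImage(px, mm_per_pixel, ImageMeta(view=view, **meta))


def radial_gradient_scene(R=250, size=540, d0=0.5, mm_per_pixel=0.2, view="top"):
    """Disc scute whose red-minus-blue falls off linearly with radius.

    With d(r) = d0 (1 - r/R), the scute mean is d0/3, so the pattern at
    threshold ratio tau is the disc r < R (1 - tau/3) and the fractional
    area has the closed form FA(tau) = (1 - tau/3)^2.
    """
    rr, cc = np.mgrid[0:size, 0:size]
    c0 = (size - 1) / 2
    r = np.hypot(rr - c0, cc - c0)
    mask = r <= R
    d = np.where(mask, d0 * (1 - r / R), 0.0)
    px = np.zeros((size, size, 3))
    px[..., 2] = 0.05
    px[..., 0] = 0.05 + d
    px[..., 1] = 0.30
    img = CalibratedImage(px, mm_per_pixel, ImageMeta(view=view))
    return img, ScuteMask(mask, np.zeros_like(mask))


def gradient_fa_closed_form(tau: float) -> float:
    return (1.0 - tau / 3.0) ** 2


def symmetry_oracle(arr, grid):
    """Exhaustive mirror-overlap search by direct set intersection.

    Independent of the package's correlation-based search: the mirror copy
    is built here from first principles (mirror about the centroid, rotate,
    round to the pixel grid) and the maximum is taken by pure Python loops
    over the identical transform grid.
    """
    coords = np.argwhere(arr).astype(float)
    A = set(map(tuple, np.argwhere(arr)))
    centroid = coords.mean(axis=0)
    best = 0
    for ang in grid.angles():
        a = np.deg2rad(float(ang))
        cos_a, sin_a = np.cos(a), np.sin(a)
        B = set()
        for r, c in coords:
            # mirror left-right about the centroid, then rotate about it
            mr, mc = r - centroid[0], -(c - centroid[1])
            qr = cos_a * mr - sin_a * mc + centroid[0]
            qc = sin_a * mr + cos_a * mc + centroid[1]
            B.add((int(np.rint(qr)), int(np.rint(qc))))
        for dr in range(-grid.trans_range, grid.trans_range + 1, grid.trans_step):
            for dc in range(-grid.trans_range, grid.trans_range + 1, grid.trans_step):
                ov = sum((r + dr, c + dc) in A for r, c in B)
                if ov > best:
                    best = ov
    return best / len(A)
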