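"""Synthetic test images: ramps, occluded shapes, rings, valleys, blobs.

Every generator is deterministic under a fixed seed and returns float
images in [0, 1] with the dark-objects-on-bright-background convention.
The occluded-shape generators also return the occlusion mask and the
unoccluded ground truth so reconstructions can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.special import ndtr


def gen_sigmoid(shape=(64, 64), center_col=None, width=3.0, noise_sd=0.0,
                seed=0):
    """Smooth vertical edge: Gaussian-CDF ramp along the column axis.

    ``v(r, c) = Phi((c - center) / width)``; the value at the centre column
    is exactly one half and the profile is nondecreasing in the column
    index.  ``width -> 0`` degenerates to a hard step.
    """
    nr, nc = shape
    if center_col is None:
        center_col = nc // 2
    if not 0 <= center_col < nc:
        raise ValueError("center column outside the grid")
    if width <= 0:
        raise ValueError("sigmoid width must be positive")
    cols = np.arange(nc, dtype=float)
    v = np.tile(ndtr((cols - center_col) / width), (nr, 1))
    if noise_sd > 0:
        v = v + np.random.default_rng(seed).normal(0, noise_sd, size=v.shape)
    return v


def sigmoid_derivative(shape, center_col, width):
    """Analytic column derivative of the noiseless sigmoid ramp."""
    nr, nc = shape
    cols = np.arange(nc, dtype=float)
    d = np.exp(-0.5 * ((cols - center_col) / width) ** 2) \
        / (width * np.sqrt(2 * np.pi))
    return np.tile(d, (nr, 1))


@dataclass
class OccludedShape:
    image: np.ndarray    # occluded image (occlusion painted at 0.5)
    omega: np.ndarray    # bool, True on hidden pixels
    truth: np.ndarray    # unoccluded ground-truth image


# presets reproduce the classic synthetic geometries: a 20-pixel-tall black
# rectangle crossed by a hidden vertical strip of width 20 / 40 / 80 (the
# 20-pixel strip hides ~800 pixels), and a black disc with a square bite
RECT_GAPS = (20, 40, 80)


def gen_rect_occlusion(gap=20, shape=(160, 160), rect_rows=(70, 90),
                       rect_cols=(20, 140), occ_rows=(60, 100),
                       noise_sd=0.0, seed=0):
    """Long dark rectangle crossed by a hidden vertical strip of width gap.

    The strip is centred on the rectangle; its height spans the rectangle
    plus a margin, so the hidden zone contains the continuation of both
    horizontal edges.  gap=0 returns the clean image with an empty mask.
    """
    nr, nc = shape
    truth = np.ones(shape)
    truth[rect_rows[0]:rect_rows[1], rect_cols[0]:rect_cols[1]] = 0.0
    omega = np.zeros(shape, dtype=bool)
    if gap > 0:
        c0 = nc // 2 - gap // 2
        omega[occ_rows[0]:occ_rows[1], c0:c0 + gap] = True
    if noise_sd > 0:
        truth = truth + np.random.default_rng(seed).normal(
            0, noise_sd, size=shape)
    image = truth.copy()
    image[omega] = 0.5
    return OccludedShape(image, omega, truth)


def gen_disc_occlusion(shape=(128, 128), center=(64, 64), radius=30.0,
                       occ_size=20, noise_sd=0.0, seed=0):
    """Dark disc with a square occlusion straddling its left boundary arc."""
    nr, nc = shape
    rr, cc = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
    truth = (np.hypot(rr - center[0], cc - center[1]) > radius).astype(float)
    omega = np.zeros(shape, dtype=bool)
    r0 = center[0] - occ_size // 2
    c0 = int(center[1] - radius) - occ_size // 2
    omega[r0:r0 + occ_size, c0:c0 + occ_size] = True
    if noise_sd > 0:
        truth = truth + np.random.default_rng(seed).normal(
            0, noise_sd, size=shape)
    image = truth.copy()
    image[omega] = 0.5
    return OccludedShape(image, omega, truth)


def gen_shape_occlusion(kind="rect", gap=20, **kwargs):
    """Dispatch to the rectangle or disc occlusion preset."""
    if kind == "rect":
        return gen_rect_occlusion(gap=gap, **kwargs)
    if kind == "disc":
        return gen_disc_occlusion(occ_size=gap, **kwargs)
    raise ValueError(f"unknown occluded shape kind {kind!r}")


def gen_ring(shape=(96, 96), center=(48, 48), radius=30.0, sigma=1.2,
             depth=0.85, noise_sd=0.0, impulse_fraction=0.0, seed=0):
    """Thin dark annulus (a drawn circle) on a bright field.

    ``noise_sd`` adds Gaussian noise; ``impulse_fraction`` replaces that
    fraction of pixels with uniform random values (speckle/debris
    clutter, the kind of localised disturbance that corrupts a local
    gradient map far more than a global sensitivity).  Returns the image
    and the set of centreline pixels (those nearest to the true circle).
    """
    nr, nc = shape
    rng = np.random.default_rng(seed)
    rr, cc = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
    d = np.hypot(rr - center[0], cc - center[1])
    v = 1.0 - depth * np.exp(-0.5 * ((d - radius) / sigma) ** 2)
    if noise_sd > 0:
        v = v + rng.normal(0, noise_sd, size=shape)
    if impulse_fraction > 0:
        idx = rng.choice(v.size, int(impulse_fraction * v.size),
                         replace=False)
        flat = v.ravel()
        flat[idx] = rng.uniform(0, 1, idx.size)
        v = flat.reshape(shape)
    centerline = np.abs(d - radius) <= 0.5
    return v, centerline


def gen_valley(shape=(40, 80), row=20, sigma=1.2, depth=0.85):
    """Straight dark horizontal band (a drawn line) on a bright field."""
    nr, nc = shape
    rr = np.arange(nr, dtype=float)[:, None]
    v = 1.0 - depth * np.exp(-0.5 * ((rr - row) / sigma) ** 2)
    return np.tile(v, (1, nc))


def gen_blobs(shape=(96, 96), n_blobs=2, radius_range=(10, 16),
              blur_sigma=1.0, noise_sd=0.01, seed=0, min_gap=8,
              max_tries=200):
    """Seeded random dark discs with blurred edges, emulating a cell field.

    Disc centres are rejection-sampled until pairwise boundary gaps exceed
    ``min_gap``; raises after ``max_tries`` failed attempts.  Returns the
    image and the list of (center, radius) ground-truth circles.
    """
    rng = np.random.default_rng(seed)
    nr, nc = shape
    circles = []
    tries = 0
    while len(circles) < n_blobs:
        if tries > max_tries:
            raise RuntimeError("could not place non-overlapping blobs")
        tries += 1
        rad = rng.uniform(*radius_range)
        r = rng.uniform(rad + 4, nr - rad - 4)
        c = rng.uniform(rad + 4, nc - rad - 4)
        ok = all(np.hypot(r - r2, c - c2) > rad + rad2 + min_gap
                 for (r2, c2), rad2 in circles)
        if ok:
            circles.append(((r, c), rad))
    rr, cc = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
    v = np.ones(shape)
    for (r, c), rad in circles:
        v[np.hypot(rr - r, cc - c) <= rad] = 0.0
    if blur_sigma > 0:
        v = ndimage.gaussian_filter(v, blur_sigma)
    if noise_sd > 0:
        v = v + rng.normal(0, noise_sd, size=shape)
    return v, circles
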