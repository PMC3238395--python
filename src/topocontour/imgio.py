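"""Image, mask and contour I/O.

Grayscale PNG/TIFF in, floats in [0, 1] inside the library, and exact
round-trips out: integer images are rescaled by their bit depth and the
scale is remembered so writing restores the original values; float TIFF is
used for diagnostic fields (sensitivities, arrival times) without any
rescaling.  Masks are PNGs with nonzero meaning True.  Contours travel as
``path_id,row,col`` CSV (0-based).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

logger = logging.getLogger(__name__)


@dataclass
class LoadedImage:
    """Float image in [0, 1] plus what is needed to write it back."""

    values: np.ndarray
    scale: float          # original max representable value (1.0 for float)
    dtype: np.dtype


def read_image(path) -> LoadedImage:
    """Read a grayscale PNG/TIFF (8/16-bit integer or float)."""
    path = Path(path)
    arr = iio.imread(path)
    if arr.ndim == 3:
        logger.warning("%s is not single-channel; converting to luminance",
                       path)
        arr = arr[..., :3] @ np.array([0.2126, 0.7152, 0.0722])
    dtype = arr.dtype
    if np.issubdtype(dtype, np.integer):
        scale = float(np.iinfo(dtype).max)
        values = arr.astype(float) / scale
    else:
        scale = 1.0
        values = arr.astype(float)
    return LoadedImage(values, scale, dtype)


def write_image(path, values, like: LoadedImage | None = None):
    """Write a [0, 1] float image, restoring the source scale if known."""
    path = Path(path)
    values = np.asarray(values, dtype=float)
    if path.suffix.lower() in (".tif", ".tiff") and like is None:
        tifffile.imwrite(path, values.astype(np.float32))
        return
    if like is not None and np.issubdtype(like.dtype, np.integer):
        out = np.clip(np.round(values * like.scale), 0,
                      like.scale).astype(like.dtype)
    else:
        out = np.clip(np.round(values * 255), 0, 255).astype(np.uint8)
    iio.imwrite(path, out)


def write_field(path, values):
    """Write a raw float field (sensitivity, distance map) as 32-bit TIFF."""
    tifffile.imwrite(Path(path), np.asarray(values, dtype=np.float32))


def read_field(path):
    return tifffile.imread(Path(path)).astype(float)


def read_mask(path):
    """Read a mask PNG: nonzero pixels are True."""
    arr = iio.imread(Path(path))
    if arr.ndim == 3:
        arr = arr.max(axis=-1)
    return arr > 0


def write_mask(path, mask):
    iio.imwrite(Path(path),
                (np.asarray(mask, dtype=bool) * np.uint8(255)))


def write_contours(path, contour_sets):
    """Write contour paths as ``path_id,row,col`` CSV rows."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["path_id", "row", "col"])
        pid = 0
        for cs in contour_sets:
            for contour in cs.contours:
                for (r, c) in contour.pixels:
                    w.writerow([pid, r, c])
                pid += 1


def read_contours(path):
    """Read contour CSV back into a list of pixel paths."""
    paths = {}
    with Path(path).open() as fh:
        rd = csv.reader(fh)
        header = next(rd)
        if header[:3] != ["path_id", "row", "col"]:
            raise ValueError("not a contour CSV (bad header)")
        for pid, r, c in rd:
            paths.setdefault(int(pid), []).append((int(r), int(c)))
    return [paths[k] for k in sorted(paths)]
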