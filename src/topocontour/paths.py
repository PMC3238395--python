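"""Keypoint selection, minimal-path back-propagation and contour assembly.

Keypoints are deep minima of the topological gradient; fronts are marched
from all of them at once, and every pair of adjacent fronts meets at a
saddle.  Back-propagating from each side of a saddle down the arrival-time
field yields the minimal path to each keypoint, and pairing saddles in
ascending order while capping every keypoint at degree two assembles the
paths into one or several continuous contours.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import fastmarch, topograd
from .fastmarch import ArrivalState, Potential, Saddle

logger = logging.getLogger(__name__)

_STEPS8 = ((-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0),
           (1, 1))


def admissible_set(lambda_min, fraction=0.5, domain=None):
    """Pixels whose sensitivity is within ``fraction`` of the deepest one.

    ``mask = {lambda_min <= fraction * min(lambda_min)}`` over the domain;
    empty (with a warning) when the sensitivity is nowhere negative.
    """
    lam = np.asarray(lambda_min, dtype=float)
    if domain is None:
        domain = np.ones(lam.shape, dtype=bool)
    domain = np.asarray(domain, dtype=bool)
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    lo = float(lam[domain].min())
    # a floor absorbs pure round-off "negativity" of flat sensitivities
    floor = 1e-10 * max(1.0, float(np.abs(lam[domain]).max()))
    if lo >= -floor:
        logger.warning("sensitivity is nowhere negative; admissible set "
                       "is empty")
        return np.zeros(lam.shape, dtype=bool)
    return domain & (lam <= fraction * lo)


@dataclass
class KeypointSet:
    pixels: list                 # ordered (row, col) tuples
    admissible: np.ndarray       # mask used for selection

    def __len__(self):
        return len(self.pixels)


def _argmin_in(lam, mask):
    vals = np.where(mask, lam, np.inf)
    return tuple(int(x) for x in np.unravel_index(np.argmin(vals),
                                                  lam.shape))


def select_keypoints(lambda_min, n, potential: Potential, domain=None,
                     fraction=0.5, manual=None, h=1.0,
                     restrict_component=True, component_dilation=3):
    """Pick seeds: the global sensitivity minimum, then farthest points.

    The first keypoint is the argmin of ``lambda_min``; each subsequent one
    is the admissible pixel maximising the multi-source weighted distance
    from the keypoints chosen so far, so the seeds spread out along the
    cheap valleys.  With ``restrict_component`` (default) the later
    keypoints are confined to the connected component of the (slightly
    dilated) admissible set holding the first one, so that on an image
    with several objects one run traces one object and the restart
    mechanism picks up the next.  A ``manual`` pixel list bypasses
    selection entirely.
    """
    lam = np.asarray(lambda_min, dtype=float)
    if manual is not None:
        pts = [tuple(map(int, p)) for p in manual]
        if len(set(pts)) != len(pts):
            raise ValueError("manual keypoints must be distinct")
        return KeypointSet(pts, np.zeros(lam.shape, dtype=bool))
    if n < 1:
        raise ValueError("need at least one keypoint")
    adm = admissible_set(lam, fraction, domain)
    if not adm.any():
        return KeypointSet([], adm)
    pts = [_argmin_in(lam, adm)]
    if restrict_component:
        bridged = ndimage.binary_dilation(adm,
                                          iterations=component_dilation)
        labels, _n = ndimage.label(bridged, structure=np.ones((3, 3)))
        adm = adm & (labels == labels[pts[0]])
    n_avail = int(adm.sum())
    if n > n_avail:
        logger.warning("requested %d keypoints but only %d admissible "
                       "pixels; returning all", n, n_avail)
    while len(pts) < min(n, n_avail):
        arr = fastmarch.march(potential, pts, h=h)
        cand = adm & np.isfinite(arr.D)
        for p in pts:
            cand[p] = False
        if not cand.any():
            break
        vals = np.where(cand, arr.D, -np.inf)
        pts.append(tuple(int(x) for x in
                         np.unravel_index(np.argmax(vals), lam.shape)))
    return KeypointSet(pts, adm)


def backpropagate(arr: ArrivalState, start, target_label):
    """Steepest-descent path from ``start`` down to its keypoint.

    Repeatedly steps to the 8-neighbour with the smallest arrival time,
    restricted to the Voronoi region of ``target_label`` (the start pixel
    excepted), so paths never wander into a competing front.  The arrival
    time is strictly decreasing along the path, which therefore terminates
    at the keypoint (the only local minimum of its region).
    """
    D, label = arr.D, arr.label
    nr, nc = D.shape
    start = tuple(map(int, start))
    goal = tuple(arr.seeds[target_label])
    if not np.isfinite(D[start]):
        raise ValueError("start pixel was not reached by the march")
    path = [start]
    current = start
    limit = D.size
    while current != goal:
        best = None
        for dr, dc in _STEPS8:
            q = (current[0] + dr, current[1] + dc)
            if not (0 <= q[0] < nr and 0 <= q[1] < nc):
                continue
            if label[q] != target_label:
                continue
            if D[q] >= D[current]:
                continue
            diag = 1 if dr != 0 and dc != 0 else 0
            key = (D[q], diag, q[0], q[1])
            if best is None or key < best[0]:
                best = (key, q)
        if best is None:
            raise RuntimeError(
                f"descent stalled at {current}: no strictly smaller "
                "neighbour before the keypoint (marching inconsistency)")
        current = best[1]
        path.append(current)
        if len(path) > limit:
            raise RuntimeError("descent exceeded the pixel budget")
    return path


@dataclass
class Contour:
    """One merged minimal path connecting a keypoint pair via a saddle."""

    pair: tuple
    saddle: Saddle
    pixels: list   # keypoint i ... saddle ... keypoint j, 8-connected


@dataclass
class ContourSet:
    contours: list = field(default_factory=list)
    degree: dict = field(default_factory=dict)

    def all_pixels(self):
        seen = []
        for c in self.contours:
            seen.extend(c.pixels)
        return seen


def connect_all(arr: ArrivalState, saddles, keypoints: KeypointSet,
                max_degree=2, path_filter=None) -> ContourSet:
    """Pair keypoints through saddles, cheapest first, degree-capped.

    Saddles are consumed in ascending value order; one is skipped when its
    two keypoints are already connected to each other or either has reached
    ``max_degree`` connections.  ``path_filter`` may veto a candidate
    contour (it receives the merged pixel path and the saddle) — used by
    the inpainting driver to reject connections that stray out of the
    sensitivity valleys.
    """
    result = ContourSet(degree={i: 0 for i in range(len(keypoints))})
    connected = set()
    for s in saddles:
        i, j = s.labels
        if result.degree.get(i, 0) >= max_degree:
            continue
        if result.degree.get(j, 0) >= max_degree:
            continue
        if (i, j) in connected:
            continue
        side_i = s.pixels[0] if arr.label[s.pixels[0]] == i else s.pixels[1]
        side_j = s.pixels[0] if arr.label[s.pixels[0]] == j else s.pixels[1]
        path_i = backpropagate(arr, side_i, i)
        path_j = backpropagate(arr, side_j, j)
        merged = list(reversed(path_i)) + path_j
        if path_filter is not None and not path_filter(merged, s):
            continue
        result.contours.append(Contour((i, j), s, merged))
        result.degree[i] = result.degree.get(i, 0) + 1
        result.degree[j] = result.degree.get(j, 0) + 1
        connected.add((i, j))
    return result


def contours_to_mask(contours: ContourSet, shape):
    """Rasterise all contour pixels into a boolean mask."""
    mask = np.zeros(shape, dtype=bool)
    for p in contours.all_pixels():
        mask[p] = True
    return mask


@dataclass
class SegmentParams:
    """Configuration for the hybrid segmentation driver."""

    c: float = 1.0                    # diffusion conductivity
    n_keypoints: int = 3
    admissible_fraction: float = 0.5  # admissible-set depth fraction
    alpha: float | None = None        # path-length regularisation (auto)
    #: Gaussian sigma applied to the sensitivity before building the
    #: potential.  Line-like features (thin dark curves) produce twin
    #: sensitivity valleys flanking the line; a smoothing of about the
    #: line width merges them into a single valley on the centreline.
    #: Zero (default) leaves the sensitivity untouched.
    potential_smoothing: float = 0.0
    restarts: int = 0                 # extra contours from fresh keypoints
    exclusion_radius: int = 3         # pixels masked around found contours
    potential_source: str = "topological"  # or "standard"
    manual_keypoints: list | None = None
    h: float = 1.0


def _sensitivity_field(image, params: SegmentParams):
    if params.potential_source == "standard":
        # negated gradient magnitude: most negative on the strongest edges,
        # so the same valley-following machinery applies unchanged
        return -topograd.standard_gradient_magnitude(image, h=params.h), None
    result, u0, p0 = topograd.topological_gradient(image, c=params.c,
                                                   h=params.h)
    return result.lambda_min, result


def segment(image, params: SegmentParams | None = None):
    """End-to-end hybrid segmentation of a 2D grayscale image.

    Pipeline: topological gradient -> keypoints -> potential -> fast
    marching -> saddles -> degree-capped contour assembly; optionally
    restarted with keypoints excluded from a dilated neighbourhood of the
    contours already found, to pick up further objects.

    Returns
    -------
    contour_sets : list of ContourSet
        One entry per (re)start.
    diagnostics : dict
        lambda_min, potential, per-run arrival states, keypoints, saddles.
    """
    params = params or SegmentParams()
    image = np.asarray(image, dtype=float)
    lam, topo = _sensitivity_field(image, params)
    if params.potential_smoothing > 0:
        lam = ndimage.gaussian_filter(lam, params.potential_smoothing)
    domain = np.ones(image.shape, dtype=bool)
    diagnostics = {"lambda_min": lam, "topograd": topo, "runs": []}
    contour_sets = []
    excluded = np.zeros(image.shape, dtype=bool)
    manual = params.manual_keypoints
    for run in range(1 + params.restarts):
        sel_domain = domain & ~excluded
        if not sel_domain.any():
            break
        pot = fastmarch.build_potential(lam, params.alpha, domain)
        kps = select_keypoints(lam, params.n_keypoints, pot,
                               domain=sel_domain,
                               fraction=params.admissible_fraction,
                               manual=manual if run == 0 else None,
                               h=params.h)
        if len(kps) == 0:
            logger.warning("no admissible keypoints; empty contour set")
            diagnostics["runs"].append({"keypoints": kps})
            contour_sets.append(ContourSet())
            break
        arr = fastmarch.march(pot, kps.pixels, h=params.h)
        saddles = fastmarch.find_saddles(arr)
        contours = connect_all(arr, saddles, kps)
        contour_sets.append(contours)
        diagnostics["runs"].append({
            "keypoints": kps, "arrival": arr, "saddles": saddles,
            "potential": pot})
        if params.restarts:
            cmask = contours_to_mask(contours, image.shape)
            if params.exclusion_radius > 0:
                cmask = ndimage.binary_dilation(
                    cmask, iterations=params.exclusion_radius)
            excluded |= cmask
            if not contours.contours:
                break
    return contour_sets, diagnostics
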