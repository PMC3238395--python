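"""Benchmark experiments on the synthetic fixtures.

Each function regenerates its inputs, runs the relevant pipeline and
returns plain numbers, so the same code backs the validation suite and
the reproduction script.  Problem sizes are desk-scale: every experiment
runs in seconds on one CPU.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from scipy.stats import spearmanr
from skimage import measure

from . import fastmarch as fm
from . import fixtures, paths, pde, topograd
from .inpaint import Occlusion, fill, harmonic_pair, inpaint, misfit_cost
from .paths import SegmentParams


def _occluded(f):
    v = f.truth.copy()
    v[f.omega] = 0.5
    return v


def _mismatch_pct(filled, f):
    bad = ((filled > 0.5) != (f.truth > 0.5)) & f.omega
    return 100.0 * float(bad.sum()) / float(f.omega.sum())


def rect_inpaint(gap, seed=0):
    """Hybrid vs plain harmonic reconstruction of the occluded rectangle.

    Returns percent of hidden pixels wrong after thresholding at the
    midtone, for the crack-aware hybrid fill and for the plain fill.
    """
    f = fixtures.gen_rect_occlusion(gap=gap, seed=seed)
    v = _occluded(f)
    filled, diag = inpaint(v, f.omega)
    plain = fill(v, Occlusion(f.omega), set())
    return {
        "hybrid_mismatch_pct": _mismatch_pct(filled, f),
        "plain_mismatch_pct": _mismatch_pct(plain, f),
        "n_hidden": int(f.omega.sum()),
        "cost_before": diag.cost_before,
        "cost_after": diag.cost_after,
    }


def disc_inpaint(seed=0):
    """Curved-edge completion: Hausdorff distance of the recovered
    midtone level set to the true circle arc, inside the hidden zone."""
    f = fixtures.gen_disc_occlusion(seed=seed)
    center, radius = (64.0, 64.0), 30.0
    v = _occluded(f)
    filled, _diag = inpaint(v, f.omega)
    interior = ndimage.binary_erosion(f.omega, iterations=2)

    pts = np.vstack(measure.find_contours(filled, 0.5))
    level = np.array([p for p in pts
                      if interior[int(round(p[0])), int(round(p[1]))]])
    theta = np.linspace(0, 2 * np.pi, 2000)
    circle = np.stack([center[0] + radius * np.sin(theta),
                       center[1] + radius * np.cos(theta)], axis=1)
    arc = np.array([p for p in circle
                    if interior[int(round(p[0])), int(round(p[1]))]])
    if level.size == 0 or arc.size == 0:
        return {"hausdorff_px": float("inf"), "n_hidden": int(f.omega.sum())}
    d_level = np.abs(np.hypot(level[:, 0] - center[0],
                              level[:, 1] - center[1]) - radius).max()
    d_arc = cKDTree(level).query(arc)[0].max()
    return {"hausdorff_px": float(max(d_level, d_arc)),
            "n_hidden": int(f.omega.sum())}


def eigen_oracle(n_matrices=1000, n_angles=3600, seed=0):
    """Closed-form smallest eigenvalue vs angular brute force."""
    rng = np.random.default_rng(seed)
    m11, m12, m22 = rng.uniform(-1, 1, size=(3, n_matrices))
    res = topograd.eigen_min(topograd.MatrixField(
        m11[:, None], m12[:, None], m22[:, None]))
    thetas = np.linspace(0, np.pi, n_angles, endpoint=False)
    n1, n2 = np.cos(thetas), np.sin(thetas)
    quad = (m11[:, None] * n1 ** 2 + 2 * m12[:, None] * n1 * n2
            + m22[:, None] * n2 ** 2)
    err = np.abs(res.lambda_min.ravel() - quad.min(axis=1))
    return {"max_abs_err": float(err.max()), "n": n_matrices}


def eikonal_accuracy(n=101):
    """Uniform-speed front vs Euclidean distance, plus grid refinement.

    The coarse grid has ``n`` pixels per side and unit spacing; the fine
    grid halves the spacing over the same physical square.  Errors are
    measured outside a 10-unit disc around the seed, where the known
    near-source overshoot of the first-order scheme has been advected
    away.
    """
    def run(m, h):
        pot = fm.Potential(np.ones((m, m)), 1.0, np.ones((m, m), bool))
        seed = (m // 2, m // 2)
        arr = fm.march(pot, [seed], h=h)
        rr, cc = np.meshgrid(np.arange(m), np.arange(m), indexing="ij")
        true = np.hypot((rr - seed[0]) * h, (cc - seed[1]) * h)
        far = true >= 10.0
        rel = np.abs(arr.D - true)[far] / true[far]
        return float(rel.max())

    coarse = run(n, 1.0)
    fine = run(2 * n - 1, 0.5)
    return {"max_rel_err": coarse, "max_rel_err_half_h": fine,
            "refinement_ratio": fine / coarse, "n": n * n}


def pde_oracles(seed=0):
    """Sparse solvers vs dense direct solves on small grids."""
    rng = np.random.default_rng(seed)
    shape = (16, 16)
    links = pde.LinkField.uniform(shape)
    links.horiz = rng.uniform(0.2, 2.0, links.horiz.shape)
    links.vert = rng.uniform(0.2, 2.0, links.vert.shape)
    n = shape[0] * shape[1]
    dense = np.zeros((n, n))
    for r in range(shape[0]):
        for c in range(shape[1]):
            i = r * shape[1] + c
            dense[i, i] += 1.0
            for dr, dc, w in ((0, 1, links.horiz), (1, 0, links.vert)):
                r2, c2 = r + dr, c + dc
                if r2 < shape[0] and c2 < shape[1]:
                    wv = w[r, c]
                    j = r2 * shape[1] + c2
                    dense[i, i] += wv
                    dense[j, j] += wv
                    dense[i, j] -= wv
                    dense[j, i] -= wv
    v = rng.normal(size=shape)
    u = pde.solve_diffusion(v, links)
    diff_err = float(np.abs(u.ravel()
                            - np.linalg.solve(dense, v.ravel())).max())
    cons_err = float(abs(u.sum() - v.sum()) / abs(v.sum()))

    omega = np.zeros((12, 12), bool)
    omega[2:10, 2:10] = True
    vd = rng.normal(size=(12, 12))
    ud = pde.solve_dirichlet_laplace(omega, vd)
    idx = np.full((12, 12), -1)
    idx[omega] = np.arange(64)
    A = np.zeros((64, 64))
    b = np.zeros(64)
    for r in range(12):
        for c in range(12):
            if not omega[r, c]:
                continue
            i = idx[r, c]
            for dr, dc in ((0, 1), (1, 0), (0, -1), (-1, 0)):
                r2, c2 = r + dr, c + dc
                if not (0 <= r2 < 12 and 0 <= c2 < 12):
                    continue
                A[i, i] += 1.0
                if omega[r2, c2]:
                    A[i, idx[r2, c2]] -= 1.0
                else:
                    b[i] += vd[r2, c2]
    dir_err = float(np.abs(ud[omega] - np.linalg.solve(A, b)).max())

    w = rng.normal(size=(12, 12))
    flux = pde.normal_flux_estimate(w, omega)
    un = pde.solve_neumann_laplace(omega, flux, anchor=0.0)
    K = A.copy()
    bn = np.zeros(64)
    for r in range(12):
        for c in range(12):
            if not omega[r, c]:
                continue
            i = idx[r, c]
            for dr, dc in ((0, 1), (1, 0), (0, -1), (-1, 0)):
                r2, c2 = r + dr, c + dc
                if (0 <= r2 < 12 and 0 <= c2 < 12
                        and not omega[r2, c2]):
                    K[i, i] -= 1.0   # strip the Dirichlet closure
                    bn[i] += flux.get(((r, c), (dr, dc)), 0.0)
    bn -= bn.mean()
    sol = np.linalg.lstsq(K, bn, rcond=None)[0]
    sol -= sol.mean()
    neu_err = float(np.abs(un[omega] - sol).max())

    # crack insulation: a closed curtain decouples inside from outside
    omega2 = np.zeros((14, 14), bool)
    omega2[2:12, 2:12] = True
    omega2[5:9, 5:9] = False
    curt = pde.LinkField.uniform((14, 14))
    for c in range(4, 10):
        curt.cut(("v", 3, c))
        curt.cut(("v", 9, c))
    for r in range(4, 10):
        curt.cut(("h", r, 3))
        curt.cut(("h", r, 9))
    inside = np.zeros((14, 14), bool)
    inside[4:10, 4:10] = True
    v1 = rng.normal(size=(14, 14))
    v2 = v1.copy()
    v2[~inside] = rng.normal(size=int((~inside).sum()))
    u1 = pde.solve_dirichlet_laplace(omega2, v1, curt)
    u2 = pde.solve_dirichlet_laplace(omega2, v2, curt)
    band = omega2 & inside
    insulation_err = float(np.abs(u1[band] - u2[band]).max())

    return {"diffusion_vs_dense": diff_err, "conservation_rel": cons_err,
            "dirichlet_vs_dense": dir_err, "neumann_vs_dense": neu_err,
            "insulation_err": insulation_err}


def sensitivity_ordering(seed=0, n_sample=50):
    """Predicted crack sensitivities vs exhaustive re-solves.

    Covers both costs: the gradient energy of the diffused image on a
    step edge, and the Dirichlet/Neumann mismatch on a small occluded
    rectangle.  Reports Spearman rank correlations and whether the
    deepest true energy change lies on the step.
    """
    rng = np.random.default_rng(seed)
    v = np.ones((16, 16))
    v[:8, :] = 0.0
    res, _, _ = topograd.topological_gradient(v)
    links = [("v", r, c) for r in range(15) for c in range(16)]
    links += [("h", r, c) for r in range(16) for c in range(15)]
    sample = [links[i] for i in rng.choice(len(links), n_sample,
                                           replace=False)]
    dj = np.array([topograd.crack_insertion_oracle(v, l) for l in sample])
    g = np.array([topograd.link_sensitivity(res, l) for l in sample])
    rho_edge = float(spearmanr(dj, g).statistic)
    all_dj = {l: topograd.crack_insertion_oracle(v, l) for l in links}
    best = min(all_dj, key=all_dj.get)
    step_hit = best[0] == "v" and best[1] == 7

    f = fixtures.gen_rect_occlusion(gap=8, shape=(26, 30),
                                    rect_rows=(10, 17), rect_cols=(4, 26),
                                    occ_rows=(6, 21))
    occ = Occlusion(f.omega)
    vi = _occluded(f)
    uD, uN = harmonic_pair(vi, occ)
    j0 = misfit_cost(uD, uN, occ.omega)
    from .inpaint import adjoint_pair, assemble_M_inpaint
    pD, pN = adjoint_pair(uD, uN, occ)
    M = assemble_M_inpaint(uD, uN, pD, pN, occ)
    inner = []
    nr, nc = occ.shape
    for r in range(nr - 1):
        for c in range(nc):
            if occ.omega[r, c] and occ.omega[r + 1, c]:
                inner.append(("v", r, c))
    for r in range(nr):
        for c in range(nc - 1):
            if occ.omega[r, c] and occ.omega[r, c + 1]:
                inner.append(("h", r, c))
    sample = [inner[i] for i in rng.choice(len(inner), n_sample,
                                           replace=False)]
    dJ, gi = [], []
    for link in sample:
        uD2, uN2 = harmonic_pair(vi, occ, cracks={link})
        dJ.append(misfit_cost(uD2, uN2, occ.omega) - j0)
        kind, r, c = link
        n = (1.0, 0.0) if kind == "v" else (0.0, 1.0)
        pix = [(r, c), (r + 1, c)] if kind == "v" else [(r, c), (r, c + 1)]
        q = M.quad_form(n)
        gi.append(float(np.mean([q[p] for p in pix])))
    rho_inpaint = float(spearmanr(dJ, gi).statistic)
    return {"spearman_edge": rho_edge, "spearman_inpaint": rho_inpaint,
            "deepest_cut_on_step": bool(step_hit)}


RING_KEYPOINTS = [(18, 48), (62, 23), (62, 73)]
RING_SEGMENT_PARAMS = dict(n_keypoints=3, c=0.25, potential_smoothing=1.5)


def ring_segmentation(seed=0, n_clutter=3, impulse_fraction=0.08):
    """Closed-contour extraction on the ring, and the potential duel.

    First: automatic three-keypoint segmentation of the clean ring,
    scored as the fraction of centreline pixels with a contour pixel
    within 1.5 px (one pixel, diagonals included).  Second: on cluttered
    copies of the ring (a fraction of pixels replaced by random values),
    the same completion is run from fixed manual keypoints on the
    topological-sensitivity potential and on the (negated) standard
    gradient-magnitude potential; mean contour-to-centreline distances
    are averaged over the clutter realisations.
    """
    img, centerline = fixtures.gen_ring()
    cl = np.argwhere(centerline)
    css, _ = paths.segment(img, SegmentParams(**RING_SEGMENT_PARAMS))
    pix = np.array(sorted(set(css[0].all_pixels())))
    coverage = float((cKDTree(pix).query(cl)[0] <= 1.5).mean())
    closed = all(d == 2 for d in css[0].degree.values())

    rng = np.random.default_rng(seed)
    topo_d, std_d = [], []
    for _ in range(n_clutter):
        sub = int(rng.integers(0, 2 ** 31 - 1))
        noisy, _ = fixtures.gen_ring(impulse_fraction=impulse_fraction,
                                     seed=sub)
        for source, acc in (("topological", topo_d), ("standard", std_d)):
            p = SegmentParams(manual_keypoints=RING_KEYPOINTS,
                              potential_source=source,
                              **{k: v for k, v in
                                 RING_SEGMENT_PARAMS.items()
                                 if k != "n_keypoints"})
            out, _ = paths.segment(noisy, p)
            cpix = np.array(sorted(set(out[0].all_pixels())))
            acc.append(float(cKDTree(cl).query(cpix)[0].mean()))
    return {"coverage_pct": 100.0 * coverage, "closed": bool(closed),
            "topo_mean_dist_px": float(np.mean(topo_d)),
            "std_mean_dist_px": float(np.mean(std_d))}


def structural_invariants(seed=0):
    """Degree caps, descent monotonicity, marcher monotonicity,
    determinism — measured on the ring segmentation."""
    img, _ = fixtures.gen_ring()
    params = SegmentParams(**RING_SEGMENT_PARAMS)
    css, diag = paths.segment(img, params)
    run = diag["runs"][0]
    arr = run["arrival"]
    max_degree = max(css[0].degree.values()) if css[0].degree else 0
    d_seq = [arr.D[p] for p in arr.order]
    monotone_order = all(a <= b + 1e-12 for a, b in zip(d_seq, d_seq[1:]))
    strict_paths = True
    for contour in css[0].contours:
        s = contour.saddle
        for side, lab in zip(s.pixels, s.labels):
            bp = paths.backpropagate(arr, side, lab)
            dd = [arr.D[p] for p in bp]
            strict_paths &= all(a > b for a, b in zip(dd, dd[1:]))
    css2, _ = paths.segment(img, params)
    deterministic = ([c.pixels for c in css[0].contours]
                     == [c.pixels for c in css2[0].contours])
    rng = np.random.default_rng(seed)
    noisy, _ = fixtures.gen_ring(noise_sd=0.05,
                                 seed=int(rng.integers(0, 2 ** 31 - 1)))
    a1, _ = paths.segment(noisy, params)
    a2, _ = paths.segment(noisy, params)
    deterministic &= ([c.pixels for c in a1[0].contours]
                      == [c.pixels for c in a2[0].contours])
    return {"max_keypoint_degree": int(max_degree),
            "acceptance_order_monotone": bool(monotone_order),
            "paths_strictly_decreasing": bool(strict_paths),
            "deterministic": bool(deterministic)}
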