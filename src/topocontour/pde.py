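"""Discrete elliptic solvers on pixel grids with crack-aware link topology.

The image domain is a regular pixel grid with spacing ``h`` (default 1).
Fields are plain 2D :class:`numpy.ndarray` objects indexed ``(row, col)``,
row-major, 0-based.  Diffusivity and crack information live on the
*interfaces* between 4-adjacent pixels (:class:`LinkField`): a link value of
exactly zero is an insulating crack, which realises a homogeneous Neumann
condition on both faces simply by omitting the link from the assembled
operator.  Domain borders are handled the same way (natural Neumann
boundaries), so the stiffness operator always annihilates constants and the
diffusion solve conserves the total image mass.

All solvers are 5-point finite differences assembled as sparse SPD (or
semi-definite) systems and factorised directly; the grids involved are
desk-scale so a direct factorisation keeps runs bit-stable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import splu

logger = logging.getLogger(__name__)

#: A link (pixel-pair interface) is identified by ``("h", r, c)`` for the
#: interface between pixels (r, c) and (r, c+1), or ``("v", r, c)`` for the
#: interface between (r, c) and (r+1, c).
Link = tuple


@dataclass
class LinkField:
    """Per-interface conductivity values; zero marks an insulating crack.

    Attributes
    ----------
    horiz : ndarray, shape (n_rows, n_cols - 1)
        Values on interfaces between column-adjacent pixels.
    vert : ndarray, shape (n_rows - 1, n_cols)
        Values on interfaces between row-adjacent pixels.
    """

    horiz: np.ndarray
    vert: np.ndarray

    def __post_init__(self):
        self.horiz = np.asarray(self.horiz, dtype=float)
        self.vert = np.asarray(self.vert, dtype=float)
        if (self.horiz < 0).any() or (self.vert < 0).any():
            raise ValueError("link conductivities must be nonnegative")

    @classmethod
    def uniform(cls, shape, value=1.0):
        nr, nc = shape
        if nr < 1 or nc < 1 or nr * nc < 2:
            raise ValueError("grid must contain at least two pixels")
        return cls(np.full((nr, nc - 1), float(value)),
                   np.full((nr - 1, nc), float(value)))

    @property
    def shape(self):
        return (self.vert.shape[0] + 1, self.horiz.shape[1] + 1)

    def copy(self):
        return LinkField(self.horiz.copy(), self.vert.copy())

    def cut(self, link: Link):
        """Set one interface conductivity to zero (insert a crack)."""
        kind, r, c = link
        if kind == "h":
            self.horiz[r, c] = 0.0
        elif kind == "v":
            self.vert[r, c] = 0.0
        else:
            raise ValueError(f"unknown link kind {kind!r}")

    def cut_many(self, links):
        for link in links:
            self.cut(link)

    def is_cut(self, link: Link) -> bool:
        kind, r, c = link
        return (self.horiz if kind == "h" else self.vert)[r, c] == 0.0

    def value(self, link: Link) -> float:
        kind, r, c = link
        return (self.horiz if kind == "h" else self.vert)[r, c]


def _check_field(v):
    v = np.asarray(v, dtype=float)
    if v.ndim != 2:
        raise ValueError("fields must be 2D")
    if not np.isfinite(v).all():
        raise ValueError("field contains non-finite values")
    return v


def _links_or_uniform(links, shape, value=1.0):
    if links is None:
        return LinkField.uniform(shape, value)
    if links.shape != tuple(shape):
        raise ValueError("link field shape does not match grid")
    return links


def _interior_link_arrays(mask, links):
    """Row/col index pairs and weights for open links with both pixels masked."""
    nr, nc = mask.shape
    out = []
    hsel = mask[:, :-1] & mask[:, 1:] & (links.horiz > 0)
    rr, cc = np.nonzero(hsel)
    out.append((rr, cc, rr, cc + 1, links.horiz[rr, cc]))
    vsel = mask[:-1, :] & mask[1:, :] & (links.vert > 0)
    rr, cc = np.nonzero(vsel)
    out.append((rr, cc, rr + 1, cc, links.vert[rr, cc]))
    return out


def assemble_operator(mask, links=None, mass_coefficient=0.0, h=1.0):
    """Assemble ``mass*u - div(c grad u)`` on the masked pixels.

    Homogeneous Neumann conditions at the mask border and on cracks are
    realised by omitting the corresponding links; rows for a cut link carry
    no entry on either side.

    Parameters
    ----------
    mask : bool ndarray
        True on the pixels belonging to the solve region.
    links : LinkField, optional
        Interface conductivities (default: uniform 1).
    mass_coefficient : float
        Nonnegative coefficient of the zeroth-order term.
    h : float
        Pixel spacing.

    Returns
    -------
    A : csr_matrix, shape (n, n)
        Symmetric positive-(semi)definite operator over masked pixels.
    index : int ndarray
        Per-pixel row index into ``A`` (-1 outside the mask).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask selects no pixels")
    if mass_coefficient < 0:
        raise ValueError("mass coefficient must be nonnegative")
    links = _links_or_uniform(links, mask.shape)
    n = int(mask.sum())
    index = np.full(mask.shape, -1, dtype=np.int64)
    index[mask] = np.arange(n)

    rows, cols, vals = [], [], []
    inv_h2 = 1.0 / (h * h)
    for ri, ci, rj, cj, w in _interior_link_arrays(mask, links):
        i = index[ri, ci]
        j = index[rj, cj]
        w = w * inv_h2
        rows.extend([i, j, i, j])
        cols.extend([i, j, j, i])
        vals.extend([w, w, -w, -w])
    if mass_coefficient > 0:
        rng = np.arange(n)
        rows.append(rng)
        cols.append(rng)
        vals.append(np.full(n, float(mass_coefficient)))
    if rows:
        rows = np.concatenate([np.atleast_1d(a) for a in rows])
        cols = np.concatenate([np.atleast_1d(a) for a in cols])
        vals = np.concatenate([np.atleast_1d(a) for a in vals])
    A = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    return A, index


def components(mask, links=None):
    """Connected components of the masked pixels under open links.

    Returns
    -------
    labels : int ndarray
        Per-pixel component id (-1 outside the mask).
    n_comp : int
    """
    mask = np.asarray(mask, dtype=bool)
    links = _links_or_uniform(links, mask.shape)
    n = int(mask.sum())
    index = np.full(mask.shape, -1, dtype=np.int64)
    index[mask] = np.arange(n)
    rows, cols = [], []
    for ri, ci, rj, cj, _w in _interior_link_arrays(mask, links):
        rows.append(index[ri, ci])
        cols.append(index[rj, cj])
    if rows:
        rows = np.concatenate(rows)
        cols = np.concatenate(cols)
        data = np.ones(rows.size)
        adj = sp.coo_matrix((data, (rows, cols)), shape=(n, n))
    else:
        adj = sp.coo_matrix((n, n))
    n_comp, comp = connected_components(adj, directed=False)
    labels = np.full(mask.shape, -1, dtype=np.int64)
    labels[mask] = comp
    return labels, n_comp


def _boundary_link_iter(omega):
    """Yield (inside pixel, outside pixel, link) for every omega-exterior
    interface that stays inside the grid."""
    nr, nc = omega.shape
    rr, cc = np.nonzero(omega)
    for r, c in zip(rr.tolist(), cc.tolist()):
        if c + 1 < nc and not omega[r, c + 1]:
            yield (r, c), (r, c + 1), ("h", r, c)
        if c - 1 >= 0 and not omega[r, c - 1]:
            yield (r, c), (r, c - 1), ("h", r, c - 1)
        if r + 1 < nr and not omega[r + 1, c]:
            yield (r, c), (r + 1, c), ("v", r, c)
        if r - 1 >= 0 and not omega[r - 1, c]:
            yield (r, c), (r - 1, c), ("v", r - 1, c)


def boundary_ring(omega):
    """Exterior boundary gamma: pixels outside omega, 4-adjacent to it."""
    omega = np.asarray(omega, dtype=bool)
    gamma = np.zeros_like(omega)
    for _inside, outside, _link in _boundary_link_iter(omega):
        gamma[outside] = True
    return gamma


def solve_diffusion(v, links=None, h=1.0, mass=1.0):
    """Solve ``mass*u - div(c grad u) = v`` on the full grid, Neumann borders.

    This is a single implicit linear-diffusion restoration step.  With
    ``mass=1`` the solve conserves the total intensity: summing the discrete
    equation over all pixels cancels the stiffness part exactly, hence
    ``sum(u) == sum(v)`` up to factorisation roundoff.
    """
    v = _check_field(v)
    mask = np.ones(v.shape, dtype=bool)
    A, index = assemble_operator(mask, links, mass_coefficient=mass, h=h)
    u = splu(A.tocsc()).solve(v.ravel())
    return u.reshape(v.shape)


def solve_with_rhs(mask, rhs_flat, links=None, h=1.0, mass=0.0):
    """Low-level helper: solve the assembled operator against a flat RHS."""
    A, index = assemble_operator(mask, links, mass_coefficient=mass, h=h)
    sol = splu(A.tocsc()).solve(np.asarray(rhs_flat, dtype=float))
    return sol, index


def solve_dirichlet_laplace(omega, v, links=None, h=1.0, fallback=None,
                            volume_rhs=None):
    """Harmonic extension into ``omega`` with Dirichlet data read from ``v``.

    Solves the 5-point Laplace equation on the omega pixels, taking the
    values of ``v`` on the exterior ring gamma as boundary data through the
    open omega-gamma links; cut links carry zero normal flux.  Satisfies the
    discrete maximum principle per reachable component.

    Components with no open link to any gamma pixel (fully enclosed by
    cracks) are unconstrained; they are filled with ``fallback`` (default:
    the mean of ``v`` over gamma) and a warning is logged.

    ``volume_rhs`` (full-grid array, read on omega) adds a Poisson source
    term, turning the solve into ``-div(c grad u) = f`` with the same
    boundary handling.

    Returns the full-grid field: ``v`` outside omega, the solution inside.
    """
    omega = np.asarray(omega, dtype=bool)
    v = _check_field(v)
    if not omega.any():
        raise ValueError("empty occlusion")
    links = _links_or_uniform(links, omega.shape)
    n = int(omega.sum())
    index = np.full(omega.shape, -1, dtype=np.int64)
    index[omega] = np.arange(n)

    inv_h2 = 1.0 / (h * h)
    rows, cols, vals = [], [], []
    diag = np.zeros(n)
    rhs = np.zeros(n)
    if volume_rhs is not None:
        rhs += np.asarray(volume_rhs, dtype=float)[omega]
    for ri, ci, rj, cj, w in _interior_link_arrays(omega, links):
        i = index[ri, ci]
        j = index[rj, cj]
        w = w * inv_h2
        np.add.at(diag, i, w)
        np.add.at(diag, j, w)
        rows.extend([i, j])
        cols.extend([j, i])
        vals.extend([-w, -w])
    rows = (np.concatenate([np.atleast_1d(a) for a in rows])
            if rows else np.zeros(0, dtype=np.int64))
    cols = (np.concatenate([np.atleast_1d(a) for a in cols])
            if cols else np.zeros(0, dtype=np.int64))
    vals = (np.concatenate([np.atleast_1d(a) for a in vals])
            if vals else np.zeros(0))
    dirichlet_touch = np.zeros(n, dtype=bool)
    for (r, c), (ro, co), link in _boundary_link_iter(omega):
        w = links.value(link)
        if w <= 0:
            continue
        i = index[r, c]
        diag[i] += w * inv_h2
        rhs[i] += w * inv_h2 * v[ro, co]
        dirichlet_touch[i] = True

    comp_labels, n_comp = components(omega, links)
    comp_flat = comp_labels[omega]
    constrained_comps = set(comp_flat[dirichlet_touch].tolist())
    solvable = np.isin(comp_flat, list(constrained_comps))

    u = v.astype(float).copy()
    if solvable.any():
        sub = np.nonzero(solvable)[0]
        remap = np.full(n, -1, dtype=np.int64)
        remap[sub] = np.arange(sub.size)
        keep = solvable[rows] & solvable[cols]
        A = sp.coo_matrix(
            (np.concatenate([vals[keep], diag[sub]]),
             (np.concatenate([remap[rows[keep]], np.arange(sub.size)]),
              np.concatenate([remap[cols[keep]], np.arange(sub.size)]))),
            shape=(sub.size, sub.size)).tocsc()
        sol = splu(A).solve(rhs[sub])
        full = np.full(n, np.nan)
        full[sub] = sol
        u[omega] = full
    if len(constrained_comps) < n_comp:
        if fallback is None:
            gamma = boundary_ring(omega)
            fallback = float(v[gamma].mean()) if gamma.any() else 0.0
        logger.warning(
            "Dirichlet solve: %d component(s) have no boundary contact; "
            "filled with constant %.6g",
            n_comp - len(constrained_comps), fallback)
        uo = u[omega]
        uo[~solvable] = fallback
        u[omega] = uo
    return u


def normal_flux_estimate(v, omega, h=1.0):
    """One-sided estimate of the outward normal derivative of ``v`` on gamma.

    For each omega-gamma interface the flux is estimated from the two
    nearest pixels outside omega along the normal direction (two-point
    stencil).  Interfaces lacking a second exterior pixel fall back to zero
    flux (logged).

    Returns
    -------
    dict mapping ``((r, c), (dr, dc)) -> flux`` where (r, c) is the omega
    pixel and (dr, dc) the outward direction toward its gamma neighbour.
    """
    omega = np.asarray(omega, dtype=bool)
    v = _check_field(v)
    nr, nc = omega.shape
    flux = {}
    n_fallback = 0
    for (r, c), (ro, co), _link in _boundary_link_iter(omega):
        d = (ro - r, co - c)
        r2, c2 = ro + d[0], co + d[1]
        if 0 <= r2 < nr and 0 <= c2 < nc and not omega[r2, c2]:
            flux[((r, c), d)] = (v[r2, c2] - v[ro, co]) / h
        else:
            flux[((r, c), d)] = 0.0
            n_fallback += 1
    if n_fallback:
        logger.info("flux estimate: %d interface(s) fell back to zero flux",
                    n_fallback)
    return flux


def solve_neumann_laplace(omega, flux, links=None, h=1.0, anchor=None,
                          v=None, volume_rhs=None):
    """Harmonic extension into ``omega`` with prescribed boundary fluxes.

    The pure-Neumann problem is singular per connected component: the
    right-hand side is mean-projected per component (compatibility) and the
    additive constant is fixed so the component mean of the solution equals
    the anchor.  The anchor is, per component: a scalar if ``anchor`` is a
    number; the mean of the ``anchor`` field over the component's contact
    gamma pixels if it is an array; the mean of ``v`` over those pixels if
    only ``v`` is given; else zero.

    Returns the full-grid field (``v`` outside omega when given, else 0).
    """
    omega = np.asarray(omega, dtype=bool)
    if not omega.any():
        raise ValueError("empty occlusion")
    links = _links_or_uniform(links, omega.shape)
    n = int(omega.sum())
    index = np.full(omega.shape, -1, dtype=np.int64)
    index[omega] = np.arange(n)

    A, _ = assemble_operator(omega, links, mass_coefficient=0.0, h=h)
    rhs = np.zeros(n)
    if volume_rhs is not None:
        rhs += np.asarray(volume_rhs, dtype=float)[omega]
    touch = {}  # row -> gamma pixel, for anchoring
    for (r, c), (ro, co), link in _boundary_link_iter(omega):
        if links.value(link) <= 0:
            continue
        i = index[r, c]
        g = flux.get(((r, c), (ro - r, co - c)), 0.0)
        rhs[i] += g / h
        touch.setdefault(i, []).append((ro, co))

    comp_labels, n_comp = components(omega, links)
    comp_flat = comp_labels[omega]
    sol = np.zeros(n)
    anchor_field = None
    if anchor is not None and np.ndim(anchor) == 2:
        anchor_field = np.asarray(anchor, dtype=float)
    elif anchor is None and v is not None:
        anchor_field = np.asarray(v, dtype=float)

    A = A.tolil()
    for comp in range(n_comp):
        sel = np.nonzero(comp_flat == comp)[0]
        b = rhs[sel].copy()
        proj = b.mean()
        if abs(proj) > 1e-12:
            logger.info("Neumann solve: component %d flux projection %.3e",
                        comp, proj)
        b -= proj
        sub = A[np.ix_(sel, sel)].tocsr()
        # pin the first pixel; valid because the projected RHS is compatible
        sub = sub.tolil()
        sub.rows[0] = [0]
        sub.data[0] = [1.0]
        b0 = b.copy()
        b0[0] = 0.0
        x = splu(sub.tocsc()).solve(b0)
        if np.isscalar(anchor) and anchor is not None:
            target = float(anchor)
        elif anchor_field is not None:
            gps = [gp for i in sel for gp in touch.get(i, [])]
            target = (float(np.mean([anchor_field[gp] for gp in gps]))
                      if gps else 0.0)
        else:
            target = 0.0
        sol[sel] = x - x.mean() + target

    out = (np.asarray(v, dtype=float).copy() if v is not None
           else np.zeros(omega.shape))
    out[omega] = sol
    return out


def gradient(u, links=None, h=1.0):
    """Per-pixel gradient ``(du/drow, du/dcol)``, crack- and border-aware.

    Central differences in the interior; one-sided at domain borders; a
    difference across a cut link is replaced by the one-sided difference
    from the other side (the field is discontinuous across cracks).  Both
    sides cut gives a zero component.
    """
    u = _check_field(u)
    nr, nc = u.shape
    links = _links_or_uniform(links, u.shape)
    out = np.zeros((nr, nc, 2))

    # column derivative: neighbours along axis 1
    open_w = np.zeros((nr, nc), dtype=bool)
    open_e = np.zeros((nr, nc), dtype=bool)
    open_w[:, 1:] = links.horiz > 0
    open_e[:, :-1] = links.horiz > 0
    fwd = np.zeros((nr, nc))
    bwd = np.zeros((nr, nc))
    fwd[:, :-1] = (u[:, 1:] - u[:, :-1]) / h
    bwd[:, 1:] = (u[:, 1:] - u[:, :-1]) / h
    both = open_w & open_e
    out[:, :, 1] = np.where(both, (fwd + bwd) / 2.0,
                            np.where(open_e, fwd, np.where(open_w, bwd, 0.0)))

    # row derivative: neighbours along axis 0
    open_n = np.zeros((nr, nc), dtype=bool)
    open_s = np.zeros((nr, nc), dtype=bool)
    open_n[1:, :] = links.vert > 0
    open_s[:-1, :] = links.vert > 0
    fwd = np.zeros((nr, nc))
    bwd = np.zeros((nr, nc))
    fwd[:-1, :] = (u[1:, :] - u[:-1, :]) / h
    bwd[1:, :] = (u[1:, :] - u[:-1, :]) / h
    both = open_n & open_s
    out[:, :, 0] = np.where(both, (fwd + bwd) / 2.0,
                            np.where(open_s, fwd, np.where(open_n, bwd, 0.0)))
    return out


def energy_cost(u, links=None, h=1.0):
    """Gradient energy ``sum ||grad u||^2 h^2`` as a link-based quadratic form.

    Each open interface contributes its squared jump; cut interfaces
    contribute nothing (the crack makes the field discontinuous there at no
    energy cost).
    """
    u = _check_field(u)
    links = _links_or_uniform(links, u.shape)
    dh = (u[:, 1:] - u[:, :-1])[links.horiz > 0]
    dv = (u[1:, :] - u[:-1, :])[links.vert > 0]
    return float((dh ** 2).sum() + (dv ** 2).sum())
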