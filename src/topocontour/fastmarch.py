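"""Multi-source fast marching on a topological-gradient potential.

Solves the Eikonal equation ``||grad D|| = P + alpha`` with a first-order
Godunov upwind discretisation and a min-heap (single-pass, Dijkstra-like).
Each pixel additionally inherits the label of the seed whose front reaches
it first, producing the weighted-Voronoi partition, and the meeting points
of two fronts yield the saddle points used for contour completion.

The potential is the topological gradient shifted to be nonnegative plus a
small ``alpha > 0``; alpha regularises path length and keeps the front
speed finite at the potential minimum.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np

FAR, TRIAL, ACCEPTED = 0, 1, 2

_STEPS4 = ((-1, 0), (1, 0), (0, -1), (0, 1))


@dataclass
class Potential:
    """Nonnegative cost-per-unit-length field ``P + alpha`` on a domain."""

    values: np.ndarray
    alpha: float
    domain: np.ndarray

    @property
    def shape(self):
        return self.values.shape


def default_alpha(P, domain=None):
    """Small length regularisation: 1e-3 of the potential range."""
    P = np.asarray(P, dtype=float)
    top = float(P[domain].max()) if domain is not None else float(P.max())
    return 1e-3 * top + 1e-12


def build_potential(g, alpha=None, domain=None):
    """Shift a sensitivity field to a positive front-slowness potential.

    ``P(x) = g(x) - min(g)`` over the domain, returned as ``P + alpha``.
    The most negative sensitivities become the cheapest points, so minimal
    paths follow the valley lines of ``g``.
    """
    g = np.asarray(g, dtype=float)
    if domain is None:
        domain = np.ones(g.shape, dtype=bool)
    domain = np.asarray(domain, dtype=bool)
    if not domain.any():
        raise ValueError("empty potential domain")
    P = g - float(g[domain].min())
    if alpha is None:
        alpha = default_alpha(P, domain)
    alpha = float(alpha)
    if alpha <= 0:
        raise ValueError("alpha must be strictly positive")
    return Potential(P + alpha, alpha, domain)


@dataclass
class Saddle:
    """Cheapest meeting interface between two labelled fronts."""

    pixels: tuple          # ((r1, c1), (r2, c2)) carrying labels i, j
    labels: tuple          # (i, j), i < j
    value: float           # max of the two arrival times


@dataclass
class ArrivalState:
    """Output of the marcher: arrival times, labels, acceptance order."""

    D: np.ndarray
    status: np.ndarray
    label: np.ndarray
    order: list = field(default_factory=list)
    seeds: list = field(default_factory=list)
    h: float = 1.0


def _godunov_update(a, b, f):
    """Tentative arrival from the smallest accepted axis neighbours.

    ``a``/``b`` are the best accepted horizontal/vertical values (inf if
    none); ``f = (P + alpha) * h`` is the local cost of one step.
    """
    lo, hi = (a, b) if a <= b else (b, a)
    if hi - lo >= f:
        return lo + f
    return 0.5 * (a + b + np.sqrt(2.0 * f * f - (a - b) ** 2))


def march(potential: Potential, seeds, h=1.0) -> ArrivalState:
    """Propagate fronts from all seeds simultaneously.

    Parameters
    ----------
    potential : Potential
    seeds : sequence of (row, col)
        Pairwise-distinct pixels inside the potential domain.
    h : float
        Pixel spacing; arrival times scale linearly with it.

    Returns
    -------
    ArrivalState
        Arrival time ``D`` (+inf where unreached), per-pixel seed label
        (-1 where unreached) and the acceptance order.  D is exactly zero at
        the seeds and nondecreasing along the acceptance order; each
        accepted non-seed pixel has an accepted upwind neighbour with
        strictly smaller D.
    """
    dom = potential.domain
    nr, nc = dom.shape
    seeds = [tuple(map(int, s)) for s in seeds]
    if len(set(seeds)) != len(seeds):
        raise ValueError("seeds must be pairwise distinct")
    for s in seeds:
        if not (0 <= s[0] < nr and 0 <= s[1] < nc) or not dom[s]:
            raise ValueError(f"seed {s} outside the domain")

    D = np.full(dom.shape, np.inf)
    status = np.full(dom.shape, FAR, dtype=np.int8)
    label = np.full(dom.shape, -1, dtype=np.int64)
    order = []
    heap = []
    counter = 0
    for i, s in enumerate(seeds):
        D[s] = 0.0
        label[s] = i
        status[s] = TRIAL
        heapq.heappush(heap, (0.0, counter, s))
        counter += 1

    f_grid = potential.values * h
    while heap:
        d, _, p = heapq.heappop(heap)
        if status[p] == ACCEPTED:
            continue
        status[p] = ACCEPTED
        order.append(p)
        # label from the accepted upwind neighbour of smallest D
        if label[p] < 0 or D[p] > 0.0:
            best = None
            for dr, dc in _STEPS4:
                q = (p[0] + dr, p[1] + dc)
                if 0 <= q[0] < nr and 0 <= q[1] < nc and dom[q] \
                        and status[q] == ACCEPTED and q != p:
                    key = (D[q], label[q])
                    if best is None or key < best[0]:
                        best = (key, label[q])
            if best is not None:
                label[p] = best[1]
        for dr, dc in _STEPS4:
            q = (p[0] + dr, p[1] + dc)
            if not (0 <= q[0] < nr and 0 <= q[1] < nc) or not dom[q]:
                continue
            if status[q] == ACCEPTED:
                continue
            a = np.inf  # best accepted horizontal neighbour
            for dc2 in (-1, 1):
                m = (q[0], q[1] + dc2)
                if 0 <= m[1] < nc and dom[m] and status[m] == ACCEPTED:
                    a = min(a, D[m])
            b = np.inf  # best accepted vertical neighbour
            for dr2 in (-1, 1):
                m = (q[0] + dr2, q[1])
                if 0 <= m[0] < nr and dom[m] and status[m] == ACCEPTED:
                    b = min(b, D[m])
            t = _godunov_update(a, b, f_grid[q])
            if t < D[q]:
                D[q] = t
                status[q] = TRIAL
                heapq.heappush(heap, (t, counter, q))
                counter += 1
    return ArrivalState(D, status, label, order, seeds, h)


def path_energy(path, potential: Potential, h=1.0):
    """Discrete path cost: mean endpoint potential times step length.

    Steps must be 8-adjacent; axis steps have length ``h`` and diagonal
    steps ``sqrt(2) h``.
    """
    path = [tuple(p) for p in path]
    total = 0.0
    vals = potential.values
    for p, q in zip(path[:-1], path[1:]):
        dr, dc = abs(q[0] - p[0]), abs(q[1] - p[1])
        if max(dr, dc) != 1:
            raise ValueError(f"path step {p}->{q} is not 8-adjacent")
        length = np.sqrt(2.0) if dr == 1 and dc == 1 else 1.0
        total += 0.5 * (vals[p] + vals[q]) * length * h
    return float(total)


def find_saddles(arr: ArrivalState):
    """Cheapest meeting interface for every pair of front labels.

    For each 4-interface whose pixels carry different labels the candidate
    value is the larger of the two arrival times; per label pair the
    minimal-value interface is kept.  Sorted ascending by value so that the
    most confident connections come first.
    """
    D, label = arr.D, arr.label
    nr, nc = D.shape
    best = {}

    def consider(p, q):
        li, lj = label[p], label[q]
        if li < 0 or lj < 0 or li == lj:
            return
        if li > lj:
            li, lj = lj, li
            p, q = q, p
        val = max(D[p], D[q])
        cur = best.get((li, lj))
        if cur is None or val < cur.value:
            best[(li, lj)] = Saddle((p, q), (li, lj), float(val))

    for r in range(nr):
        for c in range(nc):
            if c + 1 < nc:
                consider((r, c), (r, c + 1))
            if r + 1 < nr:
                consider((r, c), (r + 1, c))
    return sorted(best.values(), key=lambda s: (s.value, s.labels))
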