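import numpy as np
import pytest

from topocontour import fixtures


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def step_image():
    """16x16 hard horizontal step: dark top half, bright bottom half."""
    v = np.ones((16, 16))
    v[:8, :] = 0.0
    return v


@pytest.fixture
def rect20():
    """Rectangle fixture with the 20-pixel hidden strip."""
    return fixtures.gen_rect_occlusion(gap=20)


@pytest.fixture
def small_rect():
    """Down-scaled occluded rectangle for exhaustive perturbation oracles."""
    return fixtures.gen_rect_occlusion(
        gap=8, shape=(26, 30), rect_rows=(10, 17), rect_cols=(4, 26),
        occ_rows=(6, 21))


def all_links(shape):
    nr, nc = shape
    links = [("h", r, c) for r in range(nr) for c in range(nc - 1)]
    links += [("v", r, c) for r in range(nr - 1) for c in range(nc)]
    return links


def dense_diffusion_matrix(shape, links, mass=1.0, h=1.0):
    """Independent dense assembly of mass*I - div(c grad), 5-point stencil."""
    nr, nc = shape
    n = nr * nc
    A = np.zeros((n, n))
    inv_h2 = 1.0 / (h * h)
    for r in range(nr):
        for c in range(nc):
            i = r * nc + c
            A[i, i] += mass
            if c + 1 < nc:
                w = links.horiz[r, c] * inv_h2
                j = i + 1
                A[i, i] += w
                A[j, j] += w
                A[i, j] -= w
                A[j, i] -= w
            if r + 1 < nr:
                w = links.vert[r, c] * inv_h2
                j = i + nc
                A[i, i] += w
                A[j, j] += w
                A[i, j] -= w
                A[j, i] -= w
    return A
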