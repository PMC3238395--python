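"""Grid PDE engine: assembly, solvers, gradients, crack handling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from topocontour import pde

from conftest import dense_diffusion_matrix


class TestAssembly:
    def test_stiffness_annihilates_constants(self):
        A, _ = pde.assemble_operator(np.ones((2, 2), bool),
                                     mass_coefficient=1.0)
        ones = np.ones(4)
        np.testing.assert_allclose(A @ ones, ones)

    def test_fully_cracked_pixel_reduces_to_mass_term(self):
        links = pde.LinkField.uniform((3, 3))
        for link in [("h", 1, 0), ("h", 1, 1), ("v", 0, 1), ("v", 1, 1)]:
            links.cut(link)
        A, index = pde.assemble_operator(np.ones((3, 3), bool), links,
                                         mass_coefficient=2.5)
        row = A.toarray()[index[1, 1]]
        expected = np.zeros(9)
        expected[index[1, 1]] = 2.5
        np.testing.assert_allclose(row, expected)

    def test_matches_dense_assembly_on_random_links(self, rng):
        links = pde.LinkField.uniform((8, 8))
        links.horiz = rng.uniform(0.1, 2.0, links.horiz.shape)
        links.vert = rng.uniform(0.1, 2.0, links.vert.shape)
        A, _ = pde.assemble_operator(np.ones((8, 8), bool), links,
                                     mass_coefficient=1.0)
        D = dense_diffusion_matrix((8, 8), links)
        np.testing.assert_allclose(A.toarray(), D, atol=1e-14)

    def test_rejects_empty_mask_and_negative_links(self):
        with pytest.raises(ValueError):
            pde.assemble_operator(np.zeros((3, 3), bool))
        with pytest.raises(ValueError):
            pde.LinkField(np.full((3, 2), -1.0), np.ones((2, 3)))


class TestDiffusion:
    def test_constant_image_is_fixed_point(self):
        v = np.full((6, 7), 3.25)
        np.testing.assert_allclose(pde.solve_diffusion(v), v, rtol=1e-12)

    def test_impulse_mass_is_conserved(self):
        v = np.zeros((9, 9))
        v[4, 4] = 1.0
        u = pde.solve_diffusion(v)
        assert abs(u.sum() - 1.0) <= 1e-10

    @settings(max_examples=20, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_conservation_for_arbitrary_images(self, seed):
        v = np.random.default_rng(seed).normal(size=(12, 12))
        u = pde.solve_diffusion(v)
        assert abs(u.sum() - v.sum()) <= 1e-10 * max(1.0, abs(v.sum()))

    def test_matches_dense_direct_solve(self, rng):
        v = rng.normal(size=(16, 16))
        links = pde.LinkField.uniform(v.shape)
        u = pde.solve_diffusion(v, links)
        D = dense_diffusion_matrix(v.shape, links)
        np.testing.assert_allclose(u.ravel(), np.linalg.solve(D, v.ravel()),
                                   atol=1e-10)

    def test_rejects_non_finite_input(self):
        v = np.ones((4, 4))
        v[0, 0] = np.nan
        with pytest.raises(ValueError):
            pde.solve_diffusion(v)


class TestDirichlet:
    def test_constant_boundary_gives_constant_interior(self):
        omega = np.zeros((8, 8), bool)
        omega[2:6, 2:6] = True
        u = pde.solve_dirichlet_laplace(omega, np.full((8, 8), 7.0))
        np.testing.assert_allclose(u, 7.0)

    def test_linear_ramp_is_discrete_harmonic(self):
        omega = np.zeros((10, 12), bool)
        omega[2:8, 3:9] = True
        v = np.tile(np.arange(12.0), (10, 1))
        u = pde.solve_dirichlet_laplace(omega, v)
        np.testing.assert_allclose(u, v, atol=1e-10)

    def test_crack_split_gives_piecewise_constants(self):
        omega = np.zeros((12, 14), bool)
        omega[2:10, 2:12] = True
        v = np.zeros((12, 14))
        v[:, 7:] = 1.0
        links = pde.LinkField.uniform((12, 14))
        for r in range(12):
            links.cut(("h", r, 6))
        u = pde.solve_dirichlet_laplace(omega, v, links)
        np.testing.assert_allclose(u[2:10, 2:7], 0.0, atol=1e-14)
        np.testing.assert_allclose(u[2:10, 7:12], 1.0, atol=1e-14)

    def test_maximum_principle(self, rng):
        omega = np.zeros((11, 11), bool)
        omega[2:9, 2:9] = True
        v = rng.uniform(-3, 5, (11, 11))
        u = pde.solve_dirichlet_laplace(omega, v)
        gamma = pde.boundary_ring(omega)
        assert u[omega].min() >= v[gamma].min() - 1e-12
        assert u[omega].max() <= v[gamma].max() + 1e-12

    def test_enclosed_component_gets_fallback(self, caplog):
        omega = np.zeros((9, 9), bool)
        omega[2:7, 2:7] = True
        links = pde.LinkField.uniform((9, 9))
        # wall off the centre pixel entirely
        for link in [("h", 4, 3), ("h", 4, 4), ("v", 3, 4), ("v", 4, 4)]:
            links.cut(link)
        v = np.full((9, 9), 2.0)
        u = pde.solve_dirichlet_laplace(omega, v, links, fallback=-1.0)
        assert u[4, 4] == -1.0
        np.testing.assert_allclose(u[2, 2], 2.0)


class TestNeumann:
    def test_zero_flux_gives_anchor_constant(self):
        omega = np.zeros((8, 8), bool)
        omega[2:6, 2:6] = True
        u = pde.solve_neumann_laplace(omega, {}, anchor=4.5)
        np.testing.assert_allclose(u[omega], 4.5)

    def test_ramp_recovered_from_its_fluxes(self):
        omega = np.zeros((10, 12), bool)
        omega[2:8, 3:9] = True
        v = np.tile(np.arange(12.0), (10, 1))
        flux = pde.normal_flux_estimate(v, omega)
        u = pde.solve_neumann_laplace(omega, flux, v=v)
        np.testing.assert_allclose(u[omega], v[omega], atol=1e-8)

    def test_random_compatible_flux_matches_dense_pseudoinverse(self, rng):
        omega = np.zeros((12, 12), bool)
        omega[1:11, 1:11] = True
        # build a compatible flux from a known harmonic-free field w
        w = rng.normal(size=(12, 12))
        flux = pde.normal_flux_estimate(w, omega)
        u = pde.solve_neumann_laplace(omega, flux, anchor=0.0)
        # dense oracle: pure-Neumann stiffness, least-squares solve
        idx = np.full((12, 12), -1)
        idx[omega] = np.arange(100)
        K = np.zeros((100, 100))
        rhs = np.zeros(100)
        for r in range(12):
            for c in range(12):
                if not omega[r, c]:
                    continue
                i = idx[r, c]
                for dr, dc in ((0, 1), (1, 0), (0, -1), (-1, 0)):
                    r2, c2 = r + dr, c + dc
                    if not (0 <= r2 < 12 and 0 <= c2 < 12):
                        continue
                    if omega[r2, c2]:
                        j = idx[r2, c2]
                        K[i, i] += 1.0
                        K[i, j] -= 1.0
                    else:
                        rhs[i] += flux.get(((r, c), (dr, dc)), 0.0)
        rhs -= rhs.mean()
        sol = np.linalg.lstsq(K, rhs, rcond=None)[0]
        sol -= sol.mean()
        np.testing.assert_allclose(u[omega], sol, atol=1e-8)


class TestGradientAndEnergy:
    def test_constant_field_zero_gradient(self):
        g = pde.gradient(np.full((5, 6), 2.0))
        np.testing.assert_allclose(g, 0.0)

    def test_column_ramp_unit_gradient(self):
        u = np.tile(np.arange(7.0), (5, 1))
        g = pde.gradient(u)
        np.testing.assert_allclose(g[..., 1], 1.0)
        np.testing.assert_allclose(g[..., 0], 0.0)

    def test_cut_link_switches_to_one_sided_difference(self):
        u = np.array([[0.0, 1.0, 5.0],
                      [0.0, 1.0, 5.0],
                      [0.0, 1.0, 5.0]])
        links = pde.LinkField.uniform((3, 3))
        links.cut(("h", 1, 1))  # between (1,1) and (1,2)
        g = pde.gradient(u, links)
        # (1,1): right neighbour is insulated -> backward difference
        assert g[1, 1, 1] == pytest.approx(1.0)
        # (1,2): left neighbour insulated -> forward is border, one-sided
        assert g[1, 2, 1] == pytest.approx(0.0)
        # untouched row keeps the central difference
        assert g[0, 1, 1] == pytest.approx(2.5)

    def test_energy_of_single_step(self):
        u = np.array([[0.0, 1.0]])
        assert pde.energy_cost(u) == pytest.approx(1.0)
        links = pde.LinkField.uniform((1, 2))
        links.cut(("h", 0, 0))
        assert pde.energy_cost(u, links) == 0.0

    def test_energy_of_constant_is_zero(self):
        assert pde.energy_cost(np.full((4, 4), 9.0)) == 0.0


class TestNormalFlux:
    def test_constant_exterior_zero_flux(self):
        omega = np.zeros((8, 8), bool)
        omega[3:6, 3:6] = True
        flux = pde.normal_flux_estimate(np.full((8, 8), 1.5), omega)
        assert all(abs(g) < 1e-14 for g in flux.values())

    def test_ramp_flux_signs(self):
        omega = np.zeros((9, 9), bool)
        omega[3:6, 3:6] = True
        v = 2.0 * np.tile(np.arange(9.0), (9, 1))
        flux = pde.normal_flux_estimate(v, omega)
        for ((r, c), (dr, dc)), g in flux.items():
            expected = {(0, 1): 2.0, (0, -1): -2.0}.get((dr, dc), 0.0)
            assert g == pytest.approx(expected)

    def test_sigmoid_flux_matches_analytic_derivative(self):
        from topocontour.fixtures import gen_sigmoid, sigmoid_derivative
        v = gen_sigmoid((20, 40), center_col=20, width=4.0)
        dv = sigmoid_derivative((20, 40), 20, 4.0)
        omega = np.zeros((20, 40), bool)
        omega[5:15, 16:25] = True
        flux = pde.normal_flux_estimate(v, omega)
        for ((r, c), (dr, dc)), g in flux.items():
            if dc == 0:
                assert abs(g) < 1e-12   # no row variation
            else:
                target = dc * dv[r, c + 2 * dc]
                assert g == pytest.approx(target, abs=0.25 * abs(target)
                                          + 1e-6)


def test_crack_insulation_is_exact(rng):
    """A closed crack curtain makes the solve inside it independent of any
    change to the data outside the curtain."""
    omega = np.zeros((14, 14), bool)
    omega[2:12, 2:12] = True
    omega[5:9, 5:9] = False  # known core supplies Dirichlet data inside
    links = pde.LinkField.uniform((14, 14))
    # closed square curtain around the 4:10 block
    for c in range(4, 10):
        links.cut(("v", 3, c))
        links.cut(("v", 9, c))
    for r in range(4, 10):
        links.cut(("h", r, 3))
        links.cut(("h", r, 9))
    inside = np.zeros((14, 14), bool)
    inside[4:10, 4:10] = True
    v1 = rng.normal(size=(14, 14))
    v2 = v1.copy()
    v2[~inside] = rng.normal(size=(~inside).sum())  # outside-curtain change
    u1 = pde.solve_dirichlet_laplace(omega, v1, links)
    u2 = pde.solve_dirichlet_laplace(omega, v2, links)
    band = omega & inside
    assert band.any()
    np.testing.assert_array_equal(u1[band], u2[band])
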