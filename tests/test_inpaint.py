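"""Inpainting: harmonic pair, adjoints, crack rasterisation, full driver."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from topocontour import inpaint as ip
from topocontour import pde
from topocontour.inpaint import InpaintParams, Occlusion
from topocontour.topograd import eigen_min


def occluded_image(f):
    v = f.truth.copy()
    v[f.omega] = 0.5
    return v


class TestHarmonicPair:
    def test_constant_image_zero_cost(self):
        omega = np.zeros((10, 10), bool)
        omega[3:7, 3:7] = True
        occ = Occlusion(omega)
        uD, uN = ip.harmonic_pair(np.full((10, 10), 4.0), occ)
        np.testing.assert_allclose(uD, 4.0)
        np.testing.assert_allclose(uN, 4.0)
        assert ip.misfit_cost(uD, uN, omega) == pytest.approx(0.0)

    def test_linear_ramp_recovered_by_both(self):
        omega = np.zeros((12, 16), bool)
        omega[3:9, 4:12] = True
        occ = Occlusion(omega)
        v = np.tile(np.arange(16.0), (12, 1))
        uD, uN = ip.harmonic_pair(v, occ)
        np.testing.assert_allclose(uD, v, atol=1e-8)
        np.testing.assert_allclose(uN, v, atol=1e-8)

    def test_hidden_edge_makes_extensions_disagree(self, rect20):
        occ = Occlusion(rect20.omega)
        uD, uN = ip.harmonic_pair(occluded_image(rect20), occ)
        assert ip.misfit_cost(uD, uN, rect20.omega) > 1.0


class TestMisfitCost:
    def test_uniform_unit_difference(self):
        omega = np.zeros((5, 5), bool)
        omega[0, :2] = True
        omega[1, :] = True
        omega[2, :3] = True       # 10 pixels
        uD = np.ones((5, 5))
        uN = np.zeros((5, 5))
        assert ip.misfit_cost(uD, uN, omega) == pytest.approx(5.0)

    def test_matches_direct_summation(self, rng):
        omega = rng.uniform(size=(8, 8)) > 0.4
        uD = rng.normal(size=(8, 8))
        uN = rng.normal(size=(8, 8))
        direct = 0.0
        for r in range(8):
            for c in range(8):
                if omega[r, c]:
                    direct += 0.5 * (uD[r, c] - uN[r, c]) ** 2
        assert ip.misfit_cost(uD, uN, omega) == pytest.approx(direct)


class TestAdjointPair:
    def test_matching_extensions_give_zero_adjoints(self):
        omega = np.zeros((9, 9), bool)
        omega[2:7, 2:7] = True
        occ = Occlusion(omega)
        u = np.tile(np.arange(9.0), (9, 1))
        pD, pN = ip.adjoint_pair(u, u, occ)
        np.testing.assert_allclose(pD[omega], 0.0, atol=1e-12)
        np.testing.assert_allclose(pN[omega], 0.0, atol=1e-12)

    def test_dirichlet_adjoint_matches_dense_oracle(self, rng):
        omega = np.zeros((12, 12), bool)
        omega[1:11, 1:11] = True
        occ = Occlusion(omega)
        uD = rng.normal(size=(12, 12))
        uN = rng.normal(size=(12, 12))
        pD, pN = ip.adjoint_pair(uD, uN, occ)
        m = (uD - uN)
        idx = np.full((12, 12), -1)
        idx[omega] = np.arange(100)
        A = np.zeros((100, 100))
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
                    # gamma neighbour: zero Dirichlet value, no rhs term
        np.testing.assert_allclose(pD[omega],
                                   np.linalg.solve(A, -m[omega]), atol=1e-8)
        # Neumann adjoint: singular stiffness, projected source, zero mean
        K = np.zeros((100, 100))
        for r in range(12):
            for c in range(12):
                if not omega[r, c]:
                    continue
                i = idx[r, c]
                for dr, dc in ((0, 1), (1, 0), (0, -1), (-1, 0)):
                    r2, c2 = r + dr, c + dc
                    if 0 <= r2 < 12 and 0 <= c2 < 12 and omega[r2, c2]:
                        K[i, i] += 1.0
                        K[i, idx[r2, c2]] -= 1.0
        rhs = m[omega] - m[omega].mean()
        sol = np.linalg.lstsq(K, rhs, rcond=None)[0]
        sol -= sol.mean()
        np.testing.assert_allclose(pN[omega], sol, atol=1e-8)

    def test_sensitivity_ranks_match_exhaustive_cuts(self, small_rect, rng):
        """The predicted directional sensitivity of the mismatch cost
        rank-correlates with actually cutting links and re-solving."""
        occ = Occlusion(small_rect.omega)
        v = occluded_image(small_rect)
        uD, uN = ip.harmonic_pair(v, occ)
        j0 = ip.misfit_cost(uD, uN, occ.omega)
        pD, pN = ip.adjoint_pair(uD, uN, occ)
        M = ip.assemble_M_inpaint(uD, uN, pD, pN, occ)
        links = []
        nr, nc = occ.shape
        for r in range(nr - 1):
            for c in range(nc):
                if occ.omega[r, c] and occ.omega[r + 1, c]:
                    links.append(("v", r, c))
        for r in range(nr):
            for c in range(nc - 1):
                if occ.omega[r, c] and occ.omega[r, c + 1]:
                    links.append(("h", r, c))
        sample = [links[i] for i in
                  rng.choice(len(links), 50, replace=False)]
        dj, g = [], []
        for link in sample:
            uD2, uN2 = ip.harmonic_pair(v, occ, cracks={link})
            dj.append(ip.misfit_cost(uD2, uN2, occ.omega) - j0)
            kind, r, c = link
            if kind == "v":
                n, pix = (1.0, 0.0), [(r, c), (r + 1, c)]
            else:
                n, pix = (0.0, 1.0), [(r, c), (r, c + 1)]
            q = M.quad_form(n)
            g.append(float(np.mean([q[p] for p in pix])))
        assert spearmanr(dj, g).statistic > 0


class TestAssembleMInpaint:
    def test_zero_gradients_zero_matrix(self):
        omega = np.zeros((8, 8), bool)
        omega[2:6, 2:6] = True
        occ = Occlusion(omega)
        flat = np.ones((8, 8))
        M = ip.assemble_M_inpaint(flat, flat, np.zeros((8, 8)),
                                  np.zeros((8, 8)), occ)
        np.testing.assert_allclose(M.m11, 0.0, atol=1e-14)
        np.testing.assert_allclose(M.m22, 0.0, atol=1e-14)

    def test_rank_one_substitution(self):
        """grad uD = grad pD = (1, 0) and flat Neumann states give the
        rank-one matrix with lambda_min = -1 along the row axis."""
        omega = np.zeros((8, 8), bool)
        omega[2:6, 2:6] = True
        occ = Occlusion(omega)
        ramp = np.tile(np.arange(8.0)[:, None], (1, 8))
        flat = np.zeros((8, 8))
        M = ip.assemble_M_inpaint(ramp, flat + 1.0, ramp, flat, occ)
        # interior of omega sees clean central differences
        assert M.m11[3, 3] == pytest.approx(-1.0)
        assert M.m22[3, 3] == pytest.approx(0.0)
        res = eigen_min(M)
        assert res.lambda_min[3, 3] == pytest.approx(-1.0)
        assert abs(res.n_min[3, 3, 0]) == pytest.approx(1.0)

    def test_quadratic_form_reproduces_directional_formula(self, rng):
        omega = np.zeros((9, 9), bool)
        omega[1:8, 1:8] = True
        occ = Occlusion(omega)
        uD, uN, qD, qN = rng.normal(size=(4, 9, 9))
        M = ip.assemble_M_inpaint(uD, uN, qD, qN, occ)
        border_cut = pde.LinkField.uniform((9, 9))
        for _i, _o, link in pde._boundary_link_iter(omega):
            border_cut.cut(link)
        guD, guN = pde.gradient(uD), pde.gradient(uN)
        gpD = pde.gradient(qD)
        gpN = pde.gradient(qN, links=border_cut)
        for theta in rng.uniform(0, 2 * np.pi, 100):
            n = (np.cos(theta), np.sin(theta))
            direct = -((guD[..., 0] * n[0] + guD[..., 1] * n[1])
                       * (gpD[..., 0] * n[0] + gpD[..., 1] * n[1])
                       + (guN[..., 0] * n[0] + guN[..., 1] * n[1])
                       * (gpN[..., 0] * n[0] + gpN[..., 1] * n[1]))
            np.testing.assert_allclose(M.quad_form(n)[omega],
                                       direct[omega], atol=1e-12)


class TestPathsToCracks:
    def test_single_pixel_path_cuts_nothing(self):
        omega = np.zeros((6, 6), bool)
        omega[1:5, 1:5] = True
        assert ip.paths_to_cracks([[(2, 2)]], Occlusion(omega)) == set()

    def test_horizontal_path_insulates_top_from_bottom(self):
        omega = np.zeros((10, 12), bool)
        omega[2:8, 2:10] = True
        occ = Occlusion(omega)
        path = [(4, c) for c in range(2, 10)]
        cracks = ip.paths_to_cracks([path], occ, side="below")
        assert {("v", 4, c) for c in range(2, 10)} <= cracks
        v = np.zeros((10, 12))
        v[5:, :] = 1.0   # 0 above the crack, 1 below
        u = ip.fill(v, occ, cracks)
        np.testing.assert_allclose(u[2:5, 2:10], 0.0, atol=1e-12)
        np.testing.assert_allclose(u[5:8, 2:10], 1.0, atol=1e-12)

    def test_diagonal_staircase_insulates(self):
        omega = np.zeros((12, 12), bool)
        omega[2:10, 2:10] = True
        occ = Occlusion(omega)
        path = [(2 + k, 2 + k) for k in range(8)]
        cracks = ip.paths_to_cracks([path], occ, side="below")
        links = pde.LinkField.uniform((12, 12))
        links.cut_many(cracks)
        labels, _ = pde.components(omega, links)
        # strictly-above and strictly-below quadrants are disconnected
        assert labels[2, 9] != labels[9, 2]
        # and a two-sided fill shows no flux leak across the staircase
        v = np.zeros((12, 12))
        v[np.tril_indices(12, -1)] = 1.0
        u = ip.fill(v, occ, cracks)
        assert abs(u[3, 8]) < 1e-12
        assert abs(u[8, 3] - 1.0) < 1e-12


class TestFill:
    def test_constant_stays_constant(self):
        omega = np.zeros((8, 8), bool)
        omega[2:6, 2:6] = True
        u = ip.fill(np.full((8, 8), 0.3), Occlusion(omega), set())
        np.testing.assert_allclose(u, 0.3)

    def test_untouched_outside_omega(self, rect20, rng):
        v = occluded_image(rect20)
        u = ip.fill(v, Occlusion(rect20.omega), set())
        np.testing.assert_array_equal(u[~rect20.omega], v[~rect20.omega])

    def test_manual_straight_cracks_restore_binary_rectangle(self, rect20):
        occ = Occlusion(rect20.omega)
        v = occluded_image(rect20)
        cracks = set()
        for c in range(70, 90):
            cracks.add(("v", 69, c))   # above the top dark row
            cracks.add(("v", 89, c))   # below the bottom dark row
        u = ip.fill(v, occ, cracks)
        thr = u > 0.5
        np.testing.assert_array_equal(thr[rect20.omega],
                                      rect20.truth[rect20.omega] > 0.5)

    def test_no_cracks_blurs_between_tones(self, rect20):
        occ = Occlusion(rect20.omega)
        u = ip.fill(occluded_image(rect20), occ, set())
        gap_interior = np.zeros(rect20.omega.shape, bool)
        gap_interior[72:88, 75:85] = True
        assert (u[gap_interior] > 0.0).all()
        assert (u[gap_interior] < 1.0).all()

    def test_neumann_mode_runs_and_matches_tones(self, rect20):
        occ = Occlusion(rect20.omega)
        u = ip.fill(occluded_image(rect20), occ, set(), mode="neumann")
        assert np.isfinite(u[rect20.omega]).all()


class TestInpaintDriver:
    def test_constant_image_is_identity(self):
        omega = np.zeros((24, 24), bool)
        omega[8:16, 8:16] = True
        v = np.full((24, 24), 0.7)
        out, diag = ip.inpaint(v, omega)
        np.testing.assert_allclose(out, v, atol=1e-12)
        assert diag.cracks == set()

    def test_rect20_near_perfect_reconstruction(self, rect20):
        out, diag = ip.inpaint(occluded_image(rect20), rect20.omega)
        mism = ((out > 0.5) != (rect20.truth > 0.5)) & rect20.omega
        assert mism.sum() <= 0.005 * rect20.omega.sum()
        assert diag.cost_after <= diag.cost_before

    def test_wide_gap_pipeline_completes(self):
        """At four times the object size the completion is no longer
        guaranteed to reconnect the object; the pipeline must still run
        to completion and leave the surroundings untouched."""
        from topocontour.fixtures import gen_rect_occlusion
        f = gen_rect_occlusion(gap=80)
        v = occluded_image(f)
        out, diag = ip.inpaint(v, f.omega)
        assert np.isfinite(out).all()
        np.testing.assert_array_equal(out[~f.omega], v[~f.omega])

    def test_true_cracks_do_not_increase_cost(self, rect20):
        occ = Occlusion(rect20.omega)
        v = occluded_image(rect20)
        uD, uN = ip.harmonic_pair(v, occ)
        j_plain = ip.misfit_cost(uD, uN, occ.omega)
        cracks = {("v", 69, c) for c in range(70, 90)}
        cracks |= {("v", 89, c) for c in range(70, 90)}
        uD2, uN2 = ip.harmonic_pair(v, occ, cracks=cracks)
        assert ip.misfit_cost(uD2, uN2, occ.omega) <= j_plain
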