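"""Finite-element chamber solver: cavity-volume functional, inflation
solves, the thick-wall closed-form oracle, stress post-processing and the
solver invariants."""

import numpy as np
import pytest
from scipy.integrate import quad

from pulseloop.fe import ChamberProblem, ChamberSolveError, cavity_volume
from pulseloop.geometry import AortaGeometry, build_aorta_mesh, \
    assign_aorta_fiber_families
from pulseloop.materials import LVMaterial


class TestCavityVolume:
    def test_analytic_half_ellipsoid(self, lv_geom, lv_mesh):
        V = cavity_volume(np.zeros((lv_mesh.n_nodes, 3)), lv_mesh)
        assert V == pytest.approx(lv_geom.cavity_volume, rel=0.03)

    def test_radial_scaling_cubes_volume(self, lv_mesh):
        alpha = 1.1
        u = (alpha - 1.0) * lv_mesh.nodes
        V0 = cavity_volume(np.zeros_like(u), lv_mesh)
        assert cavity_volume(u, lv_mesh) == pytest.approx(alpha**3 * V0, rel=1e-10)

    def test_in_plane_translation_invariance(self, lv_mesh):
        u = np.zeros((lv_mesh.n_nodes, 3))
        u[:, 0], u[:, 1] = 0.43, -0.17
        V0 = cavity_volume(np.zeros_like(u), lv_mesh)
        assert cavity_volume(u, lv_mesh) == pytest.approx(V0, abs=1e-9 * V0)

    def test_gradient_matches_fd(self, tube_problem, rng):
        prob = tube_problem
        mesh = prob.mesh
        u = 0.01 * rng.standard_normal((mesh.n_nodes, 3))
        u.reshape(-1)[prob.udof < 0] = 0.0
        g, _ = prob._volume_gradient(u)
        free = np.nonzero(prob.udof >= 0)[0]
        h = 1e-6
        for gi in rng.choice(free, 20, replace=False):
            up, um = u.copy().reshape(-1), u.copy().reshape(-1)
            up[gi] += h
            um[gi] -= h
            fd = (cavity_volume(up.reshape(-1, 3), mesh)
                  - cavity_volume(um.reshape(-1, 3), mesh)) / (2 * h)
            assert abs(fd - g[prob.udof[gi]]) < 1e-7 * max(abs(fd), 1.0)


class TestChamberSolve:
    def test_reference_state_is_stress_free(self, lv_problem):
        st = lv_problem.solve(V_target=lv_problem.V_ref, t=0.0)
        assert np.abs(st.u).max() < 1e-10
        assert abs(st.P_cav) < 1e-10

    def test_passive_inflation_monotone(self, lv_problem):
        st = lv_problem.solve(V_target=lv_problem.V_ref, t=0.0)
        Ps = []
        for fac in (1.05, 1.1, 1.15, 1.2, 1.25, 1.3):
            st = lv_problem.solve(V_target=lv_problem.V_ref * fac, t=0.0,
                                  state=st)
            Ps.append(st.P_cav)
        assert np.all(np.diff(Ps) > 0)

    def test_volume_constraint_satisfied(self, lv_problem):
        Vt = 1.12 * lv_problem.V_ref
        st = lv_problem.solve(V_target=Vt, t=0.0)
        assert abs(st.V_cav - Vt) < 1e-6 * Vt

    def test_rigid_modes_removed(self, lv_problem):
        st = lv_problem.solve(V_target=1.15 * lv_problem.V_ref, t=0.0)
        prob = lv_problem
        ured = st.u.reshape(-1)[prob.udof >= 0]
        resid = prob.C_rigid @ ured
        scale = max(np.abs(st.u).max(), 1e-12) * prob.domain_volume
        assert np.abs(resid).max() < 1e-8 * scale

    def test_solution_invariant_to_rigid_guess_perturbation(self, lv_problem):
        Vt = 1.1 * lv_problem.V_ref
        st_a = lv_problem.solve(V_target=Vt, t=0.0)
        guess = st_a.copy()
        guess.u = guess.u + np.array([0.05, -0.03, 0.0])  # in-plane shift
        st_b = lv_problem.solve(V_target=Vt, t=0.0, state=guess)
        assert np.abs(st_b.u - st_a.u).max() < 1e-6

    def test_incompressibility_weak_and_volume_conservation(self, lv_problem):
        st = lv_problem.solve(V_target=1.2 * lv_problem.V_ref, t=0.0)
        J = lv_problem.jacobian_field(st)
        # signed volume-average of (J-1) vanishes (constants lie in the
        # pressure space), and total tissue volume is conserved
        javg = ((J - 1.0) * lv_problem.wdet).sum() / lv_problem.domain_volume
        assert abs(javg) < 1e-6
        assert lv_problem.tissue_volume(st) == pytest.approx(
            lv_problem.domain_volume, rel=1e-6)

    def test_invalid_targets_rejected(self, lv_problem):
        with pytest.raises(ValueError):
            lv_problem.solve(V_target=-5.0)
        with pytest.raises(ValueError):
            lv_problem.solve()
        with pytest.raises(ValueError):
            lv_problem.solve(V_target=100.0, P_target=1.0)


class TestNeoHookeanOracle:
    """Inflation of an elastin-only straight tube against the closed-form
    incompressible thick-wall cylinder solution (plane strain)."""

    @staticmethod
    def _closed_form(mu, A, B, a):
        b = np.sqrt(B**2 + a**2 - A**2)

        def integrand(r):
            R2 = r * r - a * a + A * A
            return mu * (r * r / R2 - R2 / (r * r)) / r

        return quad(integrand, a, b, limit=200)[0]

    def test_pressure_matches_closed_form(self, tube_problem, elastin_material):
        mu = elastin_material.phi_e * elastin_material.c1
        A, B = 1.0, 1.2
        st = None
        for fac in (1.1, 1.2, 1.44):
            st = tube_problem.solve(V_target=tube_problem.V_ref * fac, state=st)
            a = np.sqrt(fac) * A  # incompressible plane strain
            P_cf = self._closed_form(mu, A, B, a)
            assert st.P_cav == pytest.approx(P_cf, rel=0.01)

    def test_energy_volume_duality(self, tube_problem):
        """dW/dV along quasistatic inflation equals the pressure
        multiplier (energy consistency of the constraint)."""
        st1 = tube_problem.solve(V_target=1.2 * tube_problem.V_ref)
        st2 = tube_problem.solve(V_target=1.21 * tube_problem.V_ref, state=st1)
        dWdV = (tube_problem.strain_energy(st2)
                - tube_problem.strain_energy(st1)) / (st2.V_cav - st1.V_cav)
        assert dWdV == pytest.approx(0.5 * (st1.P_cav + st2.P_cav), rel=0.01)

    def test_pressure_driven_mode_consistent(self, tube_problem):
        st_v = tube_problem.solve(V_target=1.2 * tube_problem.V_ref)
        st_p = tube_problem.solve(P_target=st_v.P_cav, state=st_v)
        assert st_p.V_cav == pytest.approx(st_v.V_cav, rel=1e-6)


class TestStressField:
    def test_reference_stress_vanishes(self, lv_problem):
        st = lv_problem.solve(V_target=lv_problem.V_ref, t=0.0)
        sig = lv_problem.stress_field(st)
        assert np.abs(sig).max() < 1e-8

    def test_symmetry(self, lv_problem):
        st = lv_problem.solve(V_target=1.2 * lv_problem.V_ref, t=0.0)
        sig = lv_problem.stress_field(st)
        assert np.abs(sig - np.swapaxes(sig, -1, -2)).max() < 1e-8

    def test_pressurized_tube_stress_ordering(self, tube_problem):
        """Circumferential > longitudinal > radial mid-wall stress in an
        inflated tube (Lame-type ordering)."""
        st = tube_problem.solve(V_target=1.15 * tube_problem.V_ref)
        sig = tube_problem.stress_field(st)
        mesh = tube_problem.mesh
        # mid-wall elements away from the ends
        s_mid = mesh.node_param[mesh.tets[:, :4], 2].mean(axis=1)
        v_mid = mesh.node_param[mesh.tets[:, :4], 1].mean(axis=1)
        sel = (np.abs(s_mid - 0.5) < 0.3) & (v_mid > 0.2) & (v_mid < 0.8)
        fr = tube_problem.frame.vectors
        circ = np.einsum("eqd,eqdf,eqf->eq", fr["e2"][sel], sig[sel], fr["e2"][sel])
        lon = np.einsum("eqd,eqdf,eqf->eq", fr["e1"][sel], sig[sel], fr["e1"][sel])
        rad = np.einsum("eqd,eqdf,eqf->eq", fr["radial"][sel], sig[sel],
                        fr["radial"][sel])
        assert circ.mean() > lon.mean() > rad.mean()

    def test_frobenius_arithmetic(self):
        from pulseloop.analysis import frobenius_peak

        sig = np.diag([3.0, 4.0, 0.0])
        assert frobenius_peak(sig[None]) == pytest.approx(5.0)


class TestActiveSolve:
    def test_isovolumic_pressure_rises_with_activation(self, lv_problem):
        st = lv_problem.solve(V_target=lv_problem.V_ref, t=0.0)
        Ps = [st.P_cav]
        for t in (20.0, 40.0, 60.0):
            st = lv_problem.solve(V_target=lv_problem.V_ref, t=t, state=st)
            Ps.append(st.P_cav)
        assert np.all(np.diff(Ps) > 0)
        assert Ps[-1] > 5.0  # well into the systolic pressure range

    def test_failure_reports_last_volume(self, lv_problem):
        st = lv_problem.solve(V_target=lv_problem.V_ref, t=0.0)
        old = lv_problem.max_bisect
        lv_problem.max_bisect = 3  # cap the continuation depth for speed
        try:
            with pytest.raises(ChamberSolveError) as err:
                # far beyond the inflation range of the soft passive LV
                lv_problem.solve(V_target=6.0 * lv_problem.V_ref, t=0.0,
                                 state=st)
        finally:
            lv_problem.max_bisect = old
        assert err.value.last_volume is not None


class TestMeshConvergenceOfPressure:
    def test_tube_pressure_converges_under_refinement(self, elastin_material):
        mu = elastin_material.phi_e * elastin_material.c1
        A, B = 1.0, 1.2
        errs = []
        for scale in (0.75, 1.5):
            geom = AortaGeometry(r_inner=A, thickness=0.2, arch_radius=None,
                                 length_asc=2.0, length_desc=3.0,
                                 taper_ratio=1.0, n_circ=8, n_axial=3,
                                 n_trans=1)
            mesh = build_aorta_mesh(geom, resolution=scale)
            prob = ChamberProblem(mesh, assign_aorta_fiber_families(mesh),
                                  elastin_material, active=False)
            st = prob.solve(V_target=1.2 * prob.V_ref)
            P_cf = TestNeoHookeanOracle._closed_form(mu, A, B, np.sqrt(1.2) * A)
            errs.append(abs(st.P_cav / P_cf - 1.0))
        assert errs[1] <= errs[0] + 1e-4
        assert errs[1] < 0.01
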