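"""Constitutive laws: hand-computed values, finite-difference stress
consistency, frame indifference, and the compiled-kernel parity check."""

import numpy as np
import pytest

from pulseloop.materials import (
    AortaMaterial,
    LVMaterial,
    MaterialOverflow,
    active_tension,
    aorta_energy,
    aorta_response,
    aorta_stress,
    lv_active_response,
    lv_active_stress,
    lv_passive_energy,
    lv_passive_response,
    lv_passive_stress,
)

EYE_FRAME = tuple(np.eye(3))


def _aorta_frame():
    e1 = np.array([0.0, 0.0, 1.0])
    e2 = np.array([1.0, 0.0, 0.0])
    rt2 = np.sqrt(0.5)
    return {"e1": e1, "e2": e2, "e3": rt2 * (e1 + e2), "e4": rt2 * (e1 - e2)}


def _fd_stress(energy, F, h=1e-7):
    P = np.zeros((3, 3))
    for i in range(3):
        for j in range(3):
            Fp, Fm = F.copy(), F.copy()
            Fp[i, j] += h
            Fm[i, j] -= h
            P[i, j] = (energy(Fp) - energy(Fm)) / (2 * h)
    return P


def _random_isochoric(rng, scale=0.08):
    F = np.eye(3) + scale * rng.standard_normal((3, 3))
    return F / np.linalg.det(F) ** (1.0 / 3.0)


class TestLVPassive:
    def test_zero_energy_and_stress_at_identity(self):
        mat = LVMaterial()
        ef, es, en = EYE_FRAME
        assert lv_passive_energy(np.eye(3), ef, es, en, mat) == 0.0
        P = lv_passive_stress(np.eye(3), ef, es, en, mat)
        assert np.abs(P).max() == 0.0

    def test_pure_fiber_stretch_hand_value(self):
        # E_ff = (1.1^2-1)/2 = 0.105, Q = b_ff E_ff^2,
        # W = C/2 (e^Q - 1) with C = 0.10 kPa, b_ff = 29.9
        mat = LVMaterial()
        F = np.diag([1.1, 1.0, 1.0])
        Eff = 0.5 * (1.1**2 - 1.0)
        expected = 0.05 * (np.exp(29.9 * Eff**2) - 1.0)
        W = lv_passive_energy(F, *EYE_FRAME, mat)
        assert W == pytest.approx(expected, rel=1e-12)
        assert W == pytest.approx(0.0195239, rel=1e-5)

    def test_frame_indifference(self, rng):
        mat = LVMaterial()
        F = _random_isochoric(rng)
        W0 = lv_passive_energy(F, *EYE_FRAME, mat)
        for _ in range(100):
            Q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
            Q *= np.linalg.det(Q)
            assert abs(lv_passive_energy(Q @ F, *EYE_FRAME, mat) - W0) < 1e-10

    def test_stress_matches_energy_fd(self, rng):
        mat = LVMaterial()
        for _ in range(50):
            F = _random_isochoric(rng)
            P = lv_passive_stress(F, *EYE_FRAME, mat)
            Pfd = _fd_stress(
                lambda FF: lv_passive_energy(FF, *EYE_FRAME, mat), F)
            assert np.abs(P - Pfd).max() < 1e-6 * max(np.abs(P).max(), 1.0)

    def test_monotone_along_fiber_stretch(self):
        mat = LVMaterial()
        lams = np.linspace(1.0, 1.3, 16)
        Ws = [lv_passive_energy(np.diag([l, 1, 1]), *EYE_FRAME, mat)
              for l in lams]
        assert np.all(np.diff(Ws) > 0)

    def test_tangent_consistency(self, rng):
        mat = LVMaterial()
        F = _random_isochoric(rng)
        S0, C4 = lv_passive_response(F, *EYE_FRAME, mat)
        dF = 1e-6 * rng.standard_normal((3, 3))
        dE = 0.5 * (F.T @ dF + dF.T @ F)
        S1, _ = lv_passive_response(F + dF, *EYE_FRAME, mat, tangent=False)
        dS = np.einsum("ijkl,kl->ij", C4, dE)
        assert np.abs((S1 - S0) - dS).max() < 1e-4 * np.abs(dS).max()

    def test_overflow_reported(self):
        mat = LVMaterial()
        with pytest.raises(MaterialOverflow):
            lv_passive_energy(np.diag([2.5, 1.0, 1.0]), *EYE_FRAME, mat)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            LVMaterial(C=-1.0)
        with pytest.raises(ValueError):
            LVMaterial(l_0=2.0)  # above l_r


class TestActiveTension:
    def test_zero_at_activation_onset(self):
        assert active_tension(0.0, 1.85, LVMaterial()) == 0.0

    def test_peak_value_at_t0(self):
        # ECa50 = 4.35/sqrt(e^{4.75*0.27}-1) ~ 2.6948 uM;
        # T = 200.7 * Ca0^2/(Ca0^2+ECa50^2) ~ 145.04 kPa
        mat = LVMaterial()
        eca = 4.35 / np.sqrt(np.exp(4.75 * (1.85 - 1.58)) - 1.0)
        assert eca == pytest.approx(2.69483, rel=1e-5)
        T = active_tension(mat.t_0, 1.85, mat)
        assert T == pytest.approx(200.7 * 4.35**2 / (4.35**2 + eca**2), rel=1e-9)
        assert T == pytest.approx(145.04, rel=1e-3)

    def test_no_tension_below_slack_length(self):
        mat = LVMaterial()
        assert active_tension(mat.t_0, mat.l_0, mat) == 0.0
        assert active_tension(mat.t_0, mat.l_0 - 0.3, mat) == 0.0

    def test_twitch_ends_after_relaxation(self):
        mat = LVMaterial()
        t_end = mat.t_0 + mat.m * 1.85 + mat.b
        assert active_tension(t_end + 1.0, 1.85, mat) == 0.0

    def test_active_stress_rank_one(self, rng):
        mat = LVMaterial()
        F = _random_isochoric(rng)
        ef = np.array([1.0, 0.0, 0.0])
        P = lv_active_stress(F, ef, mat, mat.t_0)
        # P = T e_f x e_f0 with e_f = F e_f0 / |F e_f0|
        lam = np.linalg.norm(F @ ef)
        T = active_tension(mat.t_0, lam * mat.l_r, mat)
        expected = T * np.outer(F @ ef / lam, ef)
        assert np.abs(P - expected).max() < 1e-10 * T

    def test_zero_at_t0_zero_everything(self, rng):
        mat = LVMaterial()
        S, _ = lv_active_response(np.eye(3), np.array([1.0, 0, 0]), mat, 0.0,
                                  tangent=False)
        assert np.abs(S).max() == 0.0


class TestAortaMixture:
    def test_zero_energy_at_identity_passive(self):
        mat = AortaMaterial()
        assert aorta_energy(np.eye(3), _aorta_frame(), mat, active=False) == 0.0

    def test_family3_hand_value(self):
        # W_c3 = phi3 (c2/4c3)(exp[c3 (lam^2-1)^2]-1), phi3 = 0.4*0.544,
        # lam = 1.2 -> ~1.088e-3 kPa
        lam2 = 1.2**2
        phi3, c2, c3 = 0.4 * 0.544, 0.08, 2.54
        W = phi3 * c2 / (4 * c3) * (np.exp(c3 * (lam2 - 1) ** 2) - 1.0)
        assert W == pytest.approx(1.0883e-3, rel=1e-4)

    def test_deviatoric_stress_zero_at_identity(self):
        mat = AortaMaterial()
        S, _ = aorta_response(np.eye(3), _aorta_frame(), mat, active=False,
                              tangent=False)
        dev = S - np.trace(S) / 3.0 * np.eye(3)
        assert np.abs(dev).max() < 1e-12

    def test_stress_matches_energy_fd(self, rng):
        mat = AortaMaterial()
        frame = _aorta_frame()
        for active in (False, True):
            for _ in range(25):
                F = _random_isochoric(rng)
                P = aorta_stress(F, frame, mat, active=active)
                Pfd = _fd_stress(
                    lambda FF: aorta_energy(FF, frame, mat, active=active), F)
                assert np.abs(P - Pfd).max() < 1e-6 * np.abs(P).max()

    def test_frame_indifference(self, rng):
        mat = AortaMaterial()
        frame = _aorta_frame()
        F = _random_isochoric(rng)
        W0 = aorta_energy(F, frame, mat)
        for _ in range(100):
            Q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
            assert abs(aorta_energy(Q @ F, frame, mat) - W0) < 1e-10

    def test_equibiaxial_circumferential_bias(self):
        # SMC and family-2 collagen make the circumferential direction
        # stiffer than the longitudinal one
        mat = AortaMaterial()
        frame = _aorta_frame()
        lam = 1.15
        F = np.diag([lam, 1.0 / lam**2, lam])  # e2=x, e1=z equibiaxial
        S, _ = aorta_response(F, frame, mat, active=True, tangent=False)
        assert S[0, 0] > S[2, 2]

    def test_active_tone_vanishing_slope_at_lam0(self):
        mat = AortaMaterial()
        frame = _aorta_frame()
        lam0 = mat.lam_0
        F = np.diag([lam0, 1.0 / np.sqrt(lam0), 1.0 / np.sqrt(lam0)])
        Sa, _ = aorta_response(F, frame, mat, active=True, tangent=False)
        Sp, _ = aorta_response(F, frame, mat, active=False, tangent=False)
        assert abs((Sa - Sp)[0, 0]) < 1e-12

    def test_active_tone_bounded_by_phi_m_Sm(self):
        mat = AortaMaterial()
        frame = _aorta_frame()
        lamM = mat.lam_M
        F = np.diag([lamM, 1.0 / np.sqrt(lamM), 1.0 / np.sqrt(lamM)])
        Sa, _ = aorta_response(F, frame, mat, active=True, tangent=False)
        Sp, _ = aorta_response(F, frame, mat, active=False, tangent=False)
        cauchy_act = lamM**2 * (Sa - Sp)[0, 0]  # sigma = lam^2 S (J=1)
        assert cauchy_act == pytest.approx(mat.phi_m * mat.S_m * lamM, rel=1e-9)
        assert mat.phi_m * mat.S_m == pytest.approx(8.1)

    def test_collagen_mass_split(self):
        # sum_k M_k = (1 - phi_e - phi_m) rho exactly, split 10/10/40/40
        mat = AortaMaterial()
        Mk = mat.phi_k * mat.rho
        assert Mk.sum() == pytest.approx(
            (1.0 - mat.phi_e - mat.phi_m) * mat.rho, abs=1e-9)
        assert np.allclose(mat.phi_k / mat.phi_c, (0.1, 0.1, 0.4, 0.4))

    def test_fraction_validation(self):
        with pytest.raises(ValueError):
            AortaMaterial(phi_e=0.5)  # fractions no longer sum to 1
        with pytest.raises(ValueError):
            AortaMaterial(lam_0=1.5)  # above lam_M


class TestKernelParity:
    """The compiled assembly kernels must reproduce the numpy element
    blocks exactly (same material arithmetic, two implementations)."""

    @pytest.mark.parametrize("chamber", ["lv", "aorta"])
    def test_element_blocks_match(self, chamber, lv_problem, aorta_problem, rng):
        from pulseloop.fe import ChamberProblem

        prob = lv_problem if chamber == "lv" else aorta_problem
        ref = ChamberProblem(prob.mesh, prob.frame, prob.material,
                             active=prob.active, use_kernels=False,
                             kappa_stab=prob.kappa_stab)
        u = 0.004 * rng.standard_normal((prob.mesh.n_nodes, 3))
        pf = 0.1 * rng.standard_normal(prob.npr)
        t = 120.0
        bk = prob._element_blocks(u, pf, t, want_K=True)
        bp = ref._element_blocks(u, pf, t, want_K=True)
        for a, b in zip(bk, bp):
            a, b = np.asarray(a), np.asarray(b)
            scale = max(np.abs(b).max(), 1.0)
            assert np.abs(a - b).max() < 1e-8 * scale
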