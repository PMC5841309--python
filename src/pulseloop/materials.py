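"""Material-point constitutive laws for the two chambers.

Left ventricle
    Passive: Fung-type transversely isotropic exponential law
    W = (C/2)(exp(Q) - 1) with Q quadratic in the Green strain expressed in
    the fiber/sheet/normal frame.  Active: time- and sarcomere-length-
    dependent tension acting along the fiber direction,
    T = T_max Ca0^2 / (Ca0^2 + ECa50(l)^2) * Ct(t, l), with the
    length-dependent calcium sensitivity
    ECa50 = Ca0_max / sqrt(exp(B (l - l0)) - 1) and a raised-cosine
    activation Ct over the twitch.

Aorta
    Mass-fraction-weighted mixture of an elastin neo-Hookean matrix, four
    collagen fiber families (longitudinal, circumferential, +-45 deg) with
    identical exponential fiber energies, and circumferential smooth
    muscle with a passive exponential part plus an active-tone potential
    whose stress vanishes at stretch lam_0 and peaks at lam_M.

All energies are per unit reference volume, in kPa; constituent mass
densities enter only through mass fractions (M/rho).  The laws describe
the isochoric response; incompressibility is enforced at the FE level by a
pressure multiplier.

Functions are vectorized over arbitrary leading axes: F has shape
(..., 3, 3) and direction vectors (..., 3).  Stress routines return the
second Piola-Kirchhoff tensor S and (optionally) the material tangent
dS/dE with minor symmetries, both in the global frame.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, asdict
import numpy as np

__all__ = [
    "LVMaterial",
    "AortaMaterial",
    "MaterialOverflow",
    "active_tension",
    "lv_passive_energy",
    "lv_passive_response",
    "lv_active_response",
    "lv_passive_stress",
    "lv_active_stress",
    "aorta_energy",
    "aorta_response",
    "aorta_stress",
    "green_strain",
    "pk2_to_pk1",
]

_EXP_CAP = 60.0  # exp argument beyond which we declare material failure


class MaterialOverflow(FloatingPointError):
    """Raised when an exponential energy overflows at extreme strain."""


@dataclass
class LVMaterial:
    """Constants of the LV passive and active laws.

    Units: stresses kPa, sarcomere lengths um, times ms, calcium uM.
    """

    C: float = 0.10
    b_ff: float = 29.9
    b_xx: float = 13.3
    b_fx: float = 26.6
    T_max: float = 200.7
    Ca0: float = 4.35
    Ca0_max: float = 4.35
    B: float = 4.75
    l_0: float = 1.58
    t_0: float = 171.0
    m: float = 1049.0
    # relaxation-duration intercept: negative, so that t_r = m l + b stays
    # well below the cycle length and the twitch relaxes within the beat
    b: float = -1500.0
    l_r: float = 1.85

    def __post_init__(self) -> None:
        vals = asdict(self)
        vals.pop("b")
        if any(v <= 0 for v in vals.values()):
            raise ValueError("LV material constants must be positive")
        if self.l_0 >= self.l_r:
            raise ValueError("zero-tension length l_0 must be below l_r")
        if self.m * self.l_0 + self.b <= 0:
            raise ValueError("relaxation duration t_r = m l + b must be "
                             "positive over the working sarcomere range")

    def scaled(self, *, passive: float = 1.0, contractility: float = 1.0) -> "LVMaterial":
        return replace(self, C=self.C * passive, T_max=self.T_max * contractility)


@dataclass
class AortaMaterial:
    """Constants of the arterial mixture law (stresses in kPa)."""

    c1: float = 160.0
    c2: float = 0.08
    c3: float = 2.54
    c4: float = 0.01
    c5: float = 7.28
    phi_e: float = 0.306
    phi_m: float = 0.15
    phi_c: float = 0.544
    collagen_split: tuple[float, float, float, float] = (0.1, 0.1, 0.4, 0.4)
    rho: float = 1050.0
    S_m: float = 54.0
    lam_M: float = 1.4
    lam_0: float = 0.8

    def __post_init__(self) -> None:
        # tolerance accommodates 3-decimal rounding of published
        # constituent-fraction sets (e.g. 0.122 + 0.061 + 0.816 = 0.999)
        if abs(self.phi_e + self.phi_m + self.phi_c - 1.0) > 5e-3:
            raise ValueError("constituent mass fractions must sum to 1")
        if abs(sum(self.collagen_split) - 1.0) > 1e-12:
            raise ValueError("within-collagen split must sum to 1")
        if not self.lam_0 < self.lam_M:
            raise ValueError("active-tone stretches must satisfy lam_0 < lam_M")

    @property
    def phi_k(self) -> np.ndarray:
        """Total mass fraction of each collagen family, phi_k * phi_c."""
        return self.phi_c * np.asarray(self.collagen_split)

    def with_fractions(self, phi_e: float, phi_m: float, phi_c: float) -> "AortaMaterial":
        return replace(self, phi_e=phi_e, phi_m=phi_m, phi_c=phi_c)


# ---------------------------------------------------------------------------
# small tensor helpers
# ---------------------------------------------------------------------------


def green_strain(F: np.ndarray) -> np.ndarray:
    C = np.einsum("...ki,...kj->...ij", F, F, optimize=True)
    return 0.5 * (C - np.eye(3))


def pk2_to_pk1(F: np.ndarray, S: np.ndarray) -> np.ndarray:
    return np.einsum("...ik,...kj->...ij", F, S, optimize=True)


def _outer(v: np.ndarray) -> np.ndarray:
    return np.einsum("...i,...j->...ij", v, v, optimize=True)


def _checked_exp(arg: np.ndarray) -> np.ndarray:
    if np.any(arg > _EXP_CAP) or not np.all(np.isfinite(arg)):
        raise MaterialOverflow("exponential energy overflow (extreme strain)")
    return np.exp(arg)


_SYM4 = 0.5 * (
    np.einsum("ik,jl->ijkl", np.eye(3), np.eye(3), optimize=True)
    + np.einsum("il,jk->ijkl", np.eye(3), np.eye(3), optimize=True)
)


# ---------------------------------------------------------------------------
# LV passive law
# ---------------------------------------------------------------------------


def _q_matrix(mat: LVMaterial) -> np.ndarray:
    bff, bxx, bfx = mat.b_ff, mat.b_xx, mat.b_fx
    return np.array([[bff, bfx, bfx], [bfx, bxx, bxx], [bfx, bxx, bxx]])


def _frame_rotation(ef, es, en) -> np.ndarray:
    """R with columns (e_f, e_s, e_n): hat(E) = R^T E R."""
    return np.stack([ef, es, en], axis=-1)


def lv_passive_energy(F, ef, es, en, mat: LVMaterial):
    """Strain-energy density W (kPa) of the Fung-type law."""
    E = green_strain(np.asarray(F, float))
    R = _frame_rotation(ef, es, en)
    Eh = np.einsum("...ai,...ab,...bj->...ij", R, E, R, optimize=True)
    Q = np.einsum("ij,...ij->...", _q_matrix(mat), Eh**2, optimize=True)
    return 0.5 * mat.C * (_checked_exp(Q) - 1.0)


def lv_passive_response(F, ef, es, en, mat: LVMaterial, tangent: bool = True):
    """PK2 stress and (optionally) material tangent dS/dE, global frame."""
    F = np.asarray(F, float)
    E = green_strain(F)
    R = _frame_rotation(ef, es, en)
    Eh = np.einsum("...ai,...ab,...bj->...ij", R, E, R, optimize=True)
    q = _q_matrix(mat)
    Q = np.einsum("ij,...ij->...", q, Eh**2, optimize=True)
    expQ = _checked_exp(Q)
    qE = q * Eh  # elementwise; symmetric
    Sh = mat.C * expQ[..., None, None] * qE
    S = np.einsum("...ia,...ab,...jb->...ij", R, Sh, R, optimize=True)
    if not tangent:
        return S, None
    # dSh_ij/dEh_kl = C e^Q [2 (qE)_ij (qE)_kl + q_ij Sym_ijkl]
    C4h = 2.0 * np.einsum("...ij,...kl->...ijkl", qE, qE, optimize=True)
    C4h = C4h + q[..., :, :, None, None] * _SYM4
    C4h = mat.C * expQ[..., None, None, None, None] * C4h
    C4 = np.einsum("...ia,...jb,...kc,...ld,...abcd->...ijkl", R, R, R, R, C4h, optimize=True)
    return S, C4


def lv_passive_stress(F, ef, es, en, mat: LVMaterial) -> np.ndarray:
    """First Piola-Kirchhoff passive stress dW/dF."""
    S, _ = lv_passive_response(F, ef, es, en, mat, tangent=False)
    return pk2_to_pk1(F, S)


# ---------------------------------------------------------------------------
# LV active contraction
# ---------------------------------------------------------------------------


def active_tension(t: float, l, mat: LVMaterial):
    """Active fiber tension (kPa) at time t (ms from activation onset) and
    sarcomere length l (um).  Zero for l <= l_0 and outside the twitch."""
    l = np.asarray(l, dtype=float)
    above = l > mat.l_0 + 1e-12
    lsafe = np.where(above, l, mat.l_0 + 1.0)
    eca50 = mat.Ca0_max / np.sqrt(np.expm1(mat.B * (lsafe - mat.l_0)))
    t_r = mat.m * lsafe + mat.b
    if t < 0:
        raise ValueError("activation time must be non-negative")
    omega = np.where(
        t < mat.t_0,
        np.pi * t / mat.t_0,
        np.where(t < mat.t_0 + t_r, np.pi * (t - mat.t_0 + t_r) / t_r, 0.0),
    )
    ct = 0.5 * (1.0 - np.cos(omega))
    ca2 = mat.Ca0**2
    tension = mat.T_max * ca2 / (ca2 + eca50**2) * ct
    return np.where(above, tension, 0.0)


def _tension_and_slope(t: float, l, mat: LVMaterial, h: float = 1e-6):
    T = active_tension(t, l, mat)
    dT = (active_tension(t, l + h, mat) - active_tension(t, l - h, mat)) / (2 * h)
    return T, dT


def lv_active_response(F, ef0, mat: LVMaterial, t: float, tangent: bool = True):
    """Active PK2 stress (T/lam) ef0 x ef0 and its tangent."""
    F = np.asarray(F, float)
    C = np.einsum("...ki,...kj->...ij", F, F, optimize=True)
    lam2 = np.einsum("...i,...ij,...j->...", ef0, C, ef0, optimize=True)
    lam = np.sqrt(lam2)
    l = lam * mat.l_r
    T, dT = _tension_and_slope(t, l, mat)
    ee = _outer(ef0)
    S = (T / lam)[..., None, None] * ee
    if not tangent:
        return S, None
    coef = (dT * mat.l_r * lam - T) / lam**3
    C4 = coef[..., None, None, None, None] * np.einsum("...ij,...kl->...ijkl", ee, ee, optimize=True)
    return S, C4


def lv_active_stress(F, ef0, mat: LVMaterial, t: float) -> np.ndarray:
    """First Piola-Kirchhoff active stress, rank-one along e_f x e_f0."""
    S, _ = lv_active_response(F, ef0, mat, t, tangent=False)
    return pk2_to_pk1(F, S)


# ---------------------------------------------------------------------------
# aorta mixture law
# ---------------------------------------------------------------------------


def _fiber_terms(lam2, phi, c_a, c_b):
    """Energy, first and second derivatives w.r.t. y = lam^2 of the
    exponential fiber potential phi*(c_a/4c_b)(exp(c_b (y-1)^2) - 1)."""
    y1 = lam2 - 1.0
    e = _checked_exp(c_b * y1**2)
    W = phi * c_a / (4.0 * c_b) * (e - 1.0)
    W1 = phi * 0.5 * c_a * y1 * e
    W2 = phi * 0.5 * c_a * e * (1.0 + 2.0 * c_b * y1**2)
    return W, W1, W2


def _active_terms(lam, mat: AortaMaterial):
    """Active-tone potential and lam-derivatives, mass-weighted."""
    span = mat.lam_M - mat.lam_0
    W = mat.phi_m * mat.S_m * (lam + (mat.lam_M - lam) ** 3 / (3.0 * span**2))
    g = mat.phi_m * mat.S_m * (1.0 - ((mat.lam_M - lam) / span) ** 2)
    gp = mat.phi_m * mat.S_m * 2.0 * (mat.lam_M - lam) / span**2
    return W, g, gp


def aorta_energy(F, frame: dict, mat: AortaMaterial, active: bool = True):
    """Mixture strain-energy density (kPa); set active=False for S_m = 0."""
    F = np.asarray(F, float)
    C = np.einsum("...ki,...kj->...ij", F, F, optimize=True)
    I1 = np.einsum("...ii->...", C, optimize=True)
    W = mat.phi_e * 0.5 * mat.c1 * (I1 - 3.0)
    phis = mat.phi_k
    for k, key in enumerate(("e1", "e2", "e3", "e4")):
        lam2 = np.einsum("...i,...ij,...j->...", frame[key], C, frame[key], optimize=True)
        Wk, _, _ = _fiber_terms(lam2, phis[k], mat.c2, mat.c3)
        W = W + Wk
    lam2m = np.einsum("...i,...ij,...j->...", frame["e2"], C, frame["e2"], optimize=True)
    Wm, _, _ = _fiber_terms(lam2m, mat.phi_m, mat.c4, mat.c5)
    W = W + Wm
    if active and mat.S_m != 0.0:
        Wa, _, _ = _active_terms(np.sqrt(lam2m), mat)
        W = W + Wa
    return W


def aorta_response(F, frame: dict, mat: AortaMaterial, active: bool = True,
                   tangent: bool = True):
    """PK2 stress and tangent of the mixture law."""
    F = np.asarray(F, float)
    C = np.einsum("...ki,...kj->...ij", F, F, optimize=True)
    S = mat.phi_e * mat.c1 * np.broadcast_to(np.eye(3), C.shape).copy()
    C4 = np.zeros(C.shape + (3, 3)) if tangent else None

    def add_fiber(e, phi, ca, cb):
        nonlocal S, C4
        lam2 = np.einsum("...i,...ij,...j->...", e, C, e, optimize=True)
        _, W1, W2 = _fiber_terms(lam2, phi, ca, cb)
        ee = _outer(e)
        S = S + 2.0 * W1[..., None, None] * ee
        if tangent:
            C4 += 4.0 * W2[..., None, None, None, None] * np.einsum(
                "...ij,...kl->...ijkl", ee, ee
            , optimize=True)

    phis = mat.phi_k
    for k, key in enumerate(("e1", "e2", "e3", "e4")):
        add_fiber(frame[key], phis[k], mat.c2, mat.c3)
    add_fiber(frame["e2"], mat.phi_m, mat.c4, mat.c5)

    if active and mat.S_m != 0.0:
        e2 = frame["e2"]
        lam2 = np.einsum("...i,...ij,...j->...", e2, C, e2, optimize=True)
        lam = np.sqrt(lam2)
        _, g, gp = _active_terms(lam, mat)
        ee = _outer(e2)
        S = S + (g / lam)[..., None, None] * ee
        if tangent:
            coef = (gp * lam - g) / lam**3
            C4 += coef[..., None, None, None, None] * np.einsum(
                "...ij,...kl->...ijkl", ee, ee
            , optimize=True)
    return S, C4


def aorta_stress(F, frame: dict, mat: AortaMaterial, active: bool = True) -> np.ndarray:
    """First Piola-Kirchhoff stress dW_art/dF."""
    S, _ = aorta_response(F, frame, mat, active=active, tangent=False)
    return pk2_to_pk1(F, S)
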