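"""Incompressible finite-elasticity chamber solver.

Each chamber (LV or aorta) is a quasistatic mixed finite-element problem:
quadratic (P2) displacements, linear continuous (P1) pressure-multiplier
field enforcing J = 1 (a Taylor-Hood-type pair), a scalar Lagrange
multiplier constraining the cavity volume to a prescribed value -- the
converged multiplier *is* the cavity pressure, which is what the
closed-loop circulation needs -- and three scalar multipliers removing the
rigid modes left over after the in-plane (zero normal displacement)
conditions on the base/end planes.

The cavity volume is the surface functional
    V(u) = -(1/3) int_{Gamma_inner} x . n da  (+ planar end-cap closures),
evaluated on the deformed inner surface; its exact gradient and Hessian
(the follower-load stiffness) enter the Newton system.

Stationarity of the Lagrangian
    L = int W dV - int p (J - 1) dV - P_cav (V(u) - V_target) - c . (C u)
is solved by Newton's method with an analytic consistent tangent.  Between
timesteps the factorized Jacobian is reused for cheap chord iterations;
full re-assembly happens only when contraction stalls.  If a volume step
fails to converge the load increment is bisected (continuation).

Element blocks are assembled by compiled kernels (:mod:`._kernels`); a
pure-numpy implementation of the same blocks is kept for verification.

Units: cm, kPa, ml (cm^3); the circulation layer converts to Pa.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from ._tet import (
    line3_shape,
    line_quadrature,
    tet10_shape,
    tet_quadrature,
    tri6_shape,
    tri_quadrature,
)
from .geometry import ChamberMesh, FiberFrame, cap_area
from .materials import (
    AortaMaterial,
    LVMaterial,
    MaterialOverflow,
    aorta_energy,
    aorta_response,
    lv_active_response,
    lv_passive_energy,
    lv_passive_response,
)

__all__ = ["FEState", "ChamberProblem", "ChamberSolveError", "cavity_volume"]

_EPS3 = np.zeros((3, 3, 3))
for _i, _j, _k in ((0, 1, 2), (1, 2, 0), (2, 0, 1)):
    _EPS3[_i, _j, _k] = 1.0
    _EPS3[_i, _k, _j] = -1.0


class ChamberSolveError(RuntimeError):
    """Newton failed to converge; carries the last converged load level."""

    def __init__(self, msg: str, last_volume: float | None = None):
        super().__init__(msg)
        self.last_volume = last_volume


@dataclass
class FEState:
    """Converged chamber state."""

    u: np.ndarray            # (n_nodes, 3) displacement, cm
    p: np.ndarray            # (n_pnodes,) incompressibility multiplier, kPa
    P_cav: float             # cavity pressure multiplier, kPa
    c_rigid: np.ndarray      # rigid-mode multipliers (tx, ty, rot z)
    V_cav: float = 0.0       # cavity volume at this state, ml
    t_act: float = 0.0       # activation time of the converged state, ms
    converged: bool = True
    newton_iters: int = 0

    def copy(self) -> "FEState":
        return FEState(
            self.u.copy(), self.p.copy(), self.P_cav, self.c_rigid.copy(),
            self.V_cav, self.t_act, self.converged, self.newton_iters,
        )


def cavity_volume(u: np.ndarray, mesh: ChamberMesh) -> float:
    """Cavity (lumen) volume in ml for displacement field ``u`` (n, 3).

    Signed surface integral over the deformed inner surface, closed by the
    base plane (LV, zero contribution at z = 0) or the planar end caps
    (aorta)."""
    u = np.asarray(u, dtype=float)
    pts, w = tri_quadrature(5)
    Ns, dNs = tri6_shape(pts)
    x = (mesh.nodes + u)[mesh.surfaces["inner"]]
    A = np.einsum("qa,fad->fqd", Ns, x, optimize=True)
    B = np.einsum("qa,fad->fqd", dNs[:, :, 0], x, optimize=True)
    Cc = np.einsum("qa,fad->fqd", dNs[:, :, 1], x, optimize=True)
    V = -(1.0 / 3.0) * np.einsum(
        "q,ijk,fqi,fqj,fqk->", w, _EPS3, A, B, Cc, optimize=True
    )
    xy = mesh.nodes + u
    for cap in mesh.caps:
        V += (1.0 / 3.0) * cap.outward_sign * cap.z * cap.ring_sign * cap_area(xy, cap)
    return float(V)


class ChamberProblem:
    """Assembles and solves one chamber's FE problem.

    Parameters
    ----------
    mesh, frame : geometry and material directions (frame sampled at this
        problem's volume quadrature points).
    material : LVMaterial or AortaMaterial.
    active : for the aorta, include the smooth-muscle tone term.  (LV
        active stress is controlled by the activation time of each solve.)
    use_kernels : route element assembly through the compiled kernels.
    """

    rtol = 1e-9
    max_iter = 50
    max_bisect = 10
    n_chord = 12

    def __init__(self, mesh: ChamberMesh, frame: FiberFrame, material,
                 active: bool = True, use_kernels: bool = True,
                 kappa_stab: float | None = None):
        self.mesh = mesh
        self.frame = frame
        self.material = material
        self.active = active
        self.is_lv = isinstance(material, LVMaterial)
        self.use_kernels = use_kernels
        # Augmented-Lagrangian volumetric stiffness kappa (kPa): penalizes
        # pointwise J != 1 inside elements (the multiplier field enforces
        # the constraint only weakly).  The soft passive myocardium under
        # near-peak fiber tension admits local collapse modes, so kappa is
        # scaled with the instantaneous twitch tension:
        # kappa(t) = kappa_stab + kappa_act * T(t, l_r); it is consistent
        # (vanishes where J = 1) and nearly inactive in diastole.
        if kappa_stab is None:
            kappa_stab = 10.0 if self.is_lv else 0.0
        self.kappa_stab = float(kappa_stab)
        self.kappa_act = 7.0 if self.is_lv else 0.0
        self._lu = None
        self._setup_volume()
        self._setup_surface()
        self._setup_dofs()
        self._setup_kernel_data()
        self.V_ref = self._cavity_volume(np.zeros((mesh.n_nodes, 3)))
        if self.V_ref <= 0:  # pragma: no cover - orientation invariant
            raise RuntimeError("cavity volume functional returned non-positive "
                               "reference volume (surface orientation)")

    # ------------------------------------------------------------------
    # precomputation
    # ------------------------------------------------------------------

    def _setup_volume(self) -> None:
        mesh = self.mesh
        pts, w = tet_quadrature(4)
        if self.frame.qp_points.shape != pts.shape or not np.allclose(
            self.frame.qp_points, pts
        ):
            raise ValueError("fiber frame was not sampled at the volume "
                             "quadrature points")
        N, dN = tet10_shape(pts)
        X = mesh.nodes[mesh.tets]                    # (E,10,3)
        # J0[e,q,d,m] = dX_d/dxi_m; inv over the last two axes gives
        # J0inv[e,q,m,d] = dxi_m/dX_d, so dN/dX_a,d = dN/dxi_a,m J0inv_m,d
        J0 = np.einsum("qam,ead->eqdm", dN, X, optimize=True)
        detJ0 = np.linalg.det(J0)
        J0inv = np.linalg.inv(J0)
        self.dNdX = np.ascontiguousarray(
            np.einsum("qam,eqmd->eqad", dN, J0inv, optimize=True)
        )
        # quadrature weights sum to 1/6 (reference-tet volume), so the
        # physical measure is w * detJ0 directly
        self.wdet = np.ascontiguousarray(w[None, :] * detJ0)
        self.Nvol = N
        lam = np.stack([1 - pts.sum(1), pts[:, 0], pts[:, 1], pts[:, 2]], axis=1)
        self.Np = np.ascontiguousarray(lam)          # (Q,4) P1 pressure
        self.Xqp = np.einsum("qa,ead->eqd", N, X, optimize=True)

    def _setup_surface(self) -> None:
        pts, w = tri_quadrature(5)
        Ns, dNs = tri6_shape(pts)
        self.faces = self.mesh.surfaces["inner"]
        self.Ns, self.dNs, self.ws = Ns, dNs, w
        # weighted shape tables for the fast volume/gradient path
        self._wNs = np.ascontiguousarray(w[:, None] * Ns)
        self._wdX = np.ascontiguousarray(w[:, None] * dNs[:, :, 0])
        self._wdY = np.ascontiguousarray(w[:, None] * dNs[:, :, 1])
        xq, wq = line_quadrature(3)
        Nl, dNl = line3_shape(xq)
        Kseg = np.einsum("q,qa,qb->ab", wq, Nl, dNl, optimize=True)
        self.Mseg = 0.5 * (Kseg - Kseg.T)

    def _setup_dofs(self) -> None:
        mesh = self.mesh
        n = mesh.n_nodes
        fixed = np.zeros(3 * n, dtype=bool)
        fixed[3 * mesh.constrained_nodes() + 2] = True   # u_z = 0 in-plane
        self.udof = -np.ones(3 * n, dtype=int)
        self.udof[~fixed] = np.arange((~fixed).sum())
        self.nu = int((~fixed).sum())
        verts = mesh.vertex_ids
        pmap = -np.ones(n, dtype=int)
        pmap[verts] = np.arange(len(verts))
        self.pnode = verts
        self.npr = len(verts)
        self.pdof_of_corner = self.nu + pmap[mesh.tets[:, :4]]   # (E,4)
        self.iP = self.nu + self.npr
        self.ic = self.iP + 1

        conn = mesh.tets
        ud = self.udof.reshape(-1, 3)
        self.edofs = ud[conn].reshape(conn.shape[0], 30)
        self.fdofs = ud[self.faces].reshape(self.faces.shape[0], 18)

        # rigid-mode constraint rows: mean x/y translation, mean z rotation
        w_nodal = np.zeros(n)
        Xw = np.zeros((n, 2))
        WN = np.einsum("eq,qa->ea", self.wdet, self.Nvol, optimize=True)
        np.add.at(w_nodal, conn, WN)
        WXx = np.einsum("eq,eqd,qa->ead", self.wdet, self.Xqp[..., :2],
                        self.Nvol, optimize=True)
        np.add.at(Xw, conn, WXx)
        rows = []
        sections = getattr(mesh, "tether_sections", [])
        if not sections:
            for comp in (0, 1):
                r = np.zeros(3 * n)
                r[comp::3] = w_nodal
                rows.append(r)
        r = np.zeros(3 * n)
        r[1::3] = Xw[:, 0]      # +X_x u_y
        r[0::3] = -Xw[:, 1]     # -X_y u_x
        rows.append(r)
        # perivascular tethering: zero volume-weighted mean displacement
        # of each interior cross-section (the global translation rows are
        # then redundant and omitted above); the consistent nodal weights
        # make the constraint force a smooth traction
        for sec in sections:
            sec = np.asarray(sec)
            wsec = w_nodal[sec]
            wsec = wsec / wsec.sum()
            for comp in (0, 1, 2):
                r = np.zeros(3 * n)
                r[3 * sec + comp] = wsec
                rows.append(r)
        self.C_rigid = np.stack(rows)[:, self.udof >= 0]   # (n_c, nu)
        self.n_c = self.C_rigid.shape[0]
        self.ndof = self.ic + self.n_c
        self.domain_volume = float(self.wdet.sum())
        self._patterns()

    def _patterns(self) -> None:
        e30 = self.edofs
        p4 = self.pdof_of_corner
        rows_uu = np.repeat(e30, 30, axis=1).ravel()
        cols_uu = np.tile(e30, (1, 30)).ravel()
        rows_up = np.repeat(e30, 4, axis=1).ravel()
        cols_up = np.tile(p4, (1, 30)).ravel()
        self._iK = np.concatenate([rows_uu, rows_up, cols_up])
        self._jK = np.concatenate([cols_uu, cols_up, rows_up])
        f18 = self.fdofs
        self._iS = np.repeat(f18, 18, axis=1).ravel()
        self._jS = np.tile(f18, (1, 18)).ravel()

    def _setup_kernel_data(self) -> None:
        fr = self.frame.vectors
        if self.is_lv:
            m: LVMaterial = self.material
            self._prm = np.array(
                [m.C, m.b_ff, m.b_xx, m.b_fx, m.T_max, m.Ca0, m.Ca0_max,
                 m.B, m.l_0, m.t_0, m.m, m.b, m.l_r]
            )
            self._dirs = np.ascontiguousarray(
                np.stack([fr["f"], fr["s"], fr["n"]], axis=2)
            )
            act = self.frame.activation_scale
            self._act = np.ascontiguousarray(
                act if act is not None else np.ones(self.wdet.shape)
            )
        else:
            m: AortaMaterial = self.material
            sm = m.S_m if self.active else 0.0
            self._prm = np.concatenate(
                [[m.c1, m.c2, m.c3, m.c4, m.c5, m.phi_e, m.phi_m, sm,
                  m.lam_M, m.lam_0], m.phi_k]
            )
            self._dirs = np.ascontiguousarray(
                np.stack([fr["e1"], fr["e2"], fr["e3"], fr["e4"]], axis=2)
            )
            self._act = np.ones(self.wdet.shape)

    # ------------------------------------------------------------------
    # element blocks (kernel and reference implementations)
    # ------------------------------------------------------------------

    def _kappa(self, t: float) -> float:
        """Tension-scaled volumetric stabilization stiffness (kPa)."""
        if not self.is_lv or self.kappa_act == 0.0:
            return self.kappa_stab
        from .materials import active_tension

        T_ref = float(active_tension(t, self.material.l_r, self.material))
        return self.kappa_stab + self.kappa_act * T_ref

    def _element_blocks(self, u, pfull, t: float, want_K: bool):
        """Per-element residual/tangent blocks, or None on inversion or
        material overflow."""
        if not self.use_kernels:
            return self._element_blocks_py(u, pfull, t, want_K)
        from ._kernels import assemble_elements

        u_e = np.ascontiguousarray(u[self.mesh.tets])
        p_e = np.ascontiguousarray(pfull[self.pdof_of_corner - self.nu])
        E = u_e.shape[0]
        Ru = np.empty((E, 30))
        Rp = np.empty((E, 4))
        J = np.empty(self.wdet.shape)
        kE = E if want_K else 1
        Kuu = np.empty((kE, 30, 30))
        Kup = np.empty((kE, 30, 4))
        ok = assemble_elements(
            u_e, p_e, self.dNdX, self.wdet, self.Np, self._dirs, self._prm,
            float(t), self.is_lv, self._act, self._kappa(t), want_K,
            Ru, Rp, J, Kuu, Kup,
        )
        if not ok:
            return None
        return Ru, Rp, J, (Kuu if want_K else None), (Kup if want_K else None)

    def _deformation(self, u: np.ndarray):
        ue = u[self.mesh.tets]
        F = np.einsum("eai,eqaI->eqiI", ue, self.dNdX, optimize=True)
        F += np.eye(3)
        return F

    def _material_response(self, F, t: float, tangent: bool):
        fr = self.frame.vectors
        if self.is_lv:
            S, C4 = lv_passive_response(
                F, fr["f"], fr["s"], fr["n"], self.material, tangent=tangent
            )
            Sa, C4a = lv_active_response(F, fr["f"], self.material, t,
                                         tangent=tangent)
            act = self._act[..., None, None]
            S = S + act * Sa
            if tangent:
                C4 = C4 + act[..., None, None] * C4a
            return S, C4
        return aorta_response(F, fr, self.material, active=self.active,
                              tangent=tangent)

    def _element_blocks_py(self, u, pfull, t: float, want_K: bool):
        F = self._deformation(u)
        J = np.linalg.det(F)
        if np.any(J <= 0) or not np.all(np.isfinite(J)):
            return None
        try:
            S, C4 = self._material_response(F, t, tangent=want_K)
        except MaterialOverflow:
            return None
        Finv = np.linalg.inv(F)
        FiT = np.swapaxes(Finv, -1, -2)
        pq = np.einsum("qc,ec->eq", self.Np, pfull[self.pdof_of_corner - self.nu],
                       optimize=True)
        peff = pq - self._kappa(t) * (J - 1.0)
        P1 = np.einsum("eqiK,eqKI->eqiI", F, S, optimize=True)
        P1 -= (peff * J)[..., None, None] * FiT
        Ru = np.einsum("eq,eqiI,eqaI->eai", self.wdet, P1, self.dNdX,
                       optimize=True).reshape(-1, 30)
        Rp = -np.einsum("eq,qc,eq->ec", self.wdet, self.Np, J - 1.0,
                        optimize=True)
        if not want_K:
            return Ru, Rp, J, None, None
        A4 = np.einsum("eqiK,eqKIJN,eqjN->eqiIjJ", F, C4, F, optimize=True)
        A4 += np.einsum("ij,eqIJ->eqiIjJ", np.eye(3), S, optimize=True)
        A4 -= (peff * J)[..., None, None, None, None] * (
            np.einsum("eqiI,eqjJ->eqiIjJ", FiT, FiT, optimize=True)
            - np.einsum("eqiJ,eqjI->eqiIjJ", FiT, FiT, optimize=True)
        )
        A4 += (self._kappa(t) * J**2)[..., None, None, None, None] * np.einsum(
            "eqiI,eqjJ->eqiIjJ", FiT, FiT, optimize=True
        )
        tmp = np.einsum("eq,eqaI,eqiIjJ->eqaijJ", self.wdet, self.dNdX, A4,
                        optimize=True)
        Kuu = np.einsum("eqaijJ,eqbJ->eaibj", tmp, self.dNdX,
                        optimize=True).reshape(-1, 30, 30)
        Kup = -np.einsum("eq,eqiI,eqaI,qc->eaic", self.wdet * J, FiT,
                         self.dNdX, self.Np, optimize=True).reshape(-1, 30, 4)
        return Ru, Rp, J, Kuu, Kup

    # ------------------------------------------------------------------
    # cavity volume functional
    # ------------------------------------------------------------------

    def _cap_area(self, xdef: np.ndarray, cap) -> float:
        return cap_area(xdef, cap, self.Mseg)

    def _surface_fields(self, xdef: np.ndarray):
        """Position and tangent fields at the inner-surface quadrature
        points: x, dx/dxi, dx/deta with shapes (F, Q, 3)."""
        x = xdef[self.faces]
        A = np.tensordot(self.Ns, x, axes=(1, 1)).swapaxes(0, 1)
        B = np.tensordot(self.dNs[:, :, 0], x, axes=(1, 1)).swapaxes(0, 1)
        Cc = np.tensordot(self.dNs[:, :, 1], x, axes=(1, 1)).swapaxes(0, 1)
        return A, B, Cc

    def _cavity_volume(self, u: np.ndarray, fields=None) -> float:
        xdef = self.mesh.nodes + u
        A, B, Cc = fields if fields is not None else self._surface_fields(xdef)
        V = -(1.0 / 3.0) * float(
            (self.ws[None, :] * np.einsum("fqd,fqd->fq", A, np.cross(B, Cc),
                                          optimize=False)).sum())
        for cap in self.mesh.caps:
            V += (1.0 / 3.0) * cap.outward_sign * cap.z * cap.ring_sign \
                * self._cap_area(xdef, cap)
        return V

    def _volume_gradient(self, u: np.ndarray):
        """dV/du (reduced vector) and the face fields reused by the
        follower-load Hessian and the volume evaluation."""
        xdef = self.mesh.nodes + u
        A, B, Cc = self._surface_fields(xdef)
        # eps_djk B_j C_k = (BxC)_d etc.; contract the quadrature axis
        g = np.einsum("qb,fqd->fbd", self._wNs, np.cross(B, Cc), optimize=False)
        g += np.einsum("qb,fqd->fbd", self._wdX, np.cross(Cc, A), optimize=False)
        g += np.einsum("qb,fqd->fbd", self._wdY, np.cross(A, B), optimize=False)
        g *= -(1.0 / 3.0)
        dofs = self.fdofs.ravel()
        ok = dofs >= 0
        grad = np.bincount(dofs[ok], weights=g.reshape(-1)[ok],
                           minlength=self.nu)
        for cap in self.mesh.caps:
            fac = (1.0 / 3.0) * cap.outward_sign * cap.z * cap.ring_sign
            xs = xdef[cap.segments][..., 0]
            ys = xdef[cap.segments][..., 1]
            dAx = ys @ self.Mseg.T
            dAy = xs @ self.Mseg
            for comp, dA in ((0, dAx), (1, dAy)):
                dofs_c = self.udof[3 * cap.segments + comp]
                okc = dofs_c >= 0
                grad += np.bincount(dofs_c[okc], weights=fac * dA[okc],
                                    minlength=self.nu)
        return grad, (A, B, Cc)

    def _volume_hessian_blocks(self, fields):
        """d2V/du2 on the inner-surface face pattern, (F,18,18)."""
        A, B, Cc = fields
        Ns, dX, dY, w = self.Ns, self.dNs[:, :, 0], self.dNs[:, :, 1], self.ws
        H = np.einsum("q,qb,qc,dek,fqk->fbdce", w, Ns, dX, _EPS3, Cc, optimize=True)
        H += np.einsum("q,qb,qc,dje,fqj->fbdce", w, Ns, dY, _EPS3, B, optimize=True)
        H += np.einsum("q,qb,qc,edk,fqk->fbdce", w, dX, Ns, _EPS3, Cc, optimize=True)
        H += np.einsum("q,qb,qc,ide,fqi->fbdce", w, dX, dY, _EPS3, A, optimize=True)
        H += np.einsum("q,qb,qc,ejd,fqj->fbdce", w, dY, Ns, _EPS3, B, optimize=True)
        H += np.einsum("q,qb,qc,ied,fqi->fbdce", w, dY, dX, _EPS3, A, optimize=True)
        H *= -(1.0 / 3.0)
        return H.reshape(-1, 18, 18)

    # ------------------------------------------------------------------
    # residual and Jacobian
    # ------------------------------------------------------------------

    def _unpack(self, x: np.ndarray):
        u = np.zeros((self.mesh.n_nodes, 3))
        free = self.udof >= 0
        u.reshape(-1)[free] = x[: self.nu]
        pfull = x[self.nu : self.nu + self.npr]
        return u, pfull, x[self.iP], x[self.ic :]

    def _pack(self, state: FEState) -> np.ndarray:
        x = np.zeros(self.ndof)
        free = self.udof >= 0
        x[: self.nu] = state.u.reshape(-1)[free]
        x[self.nu : self.nu + self.npr] = state.p
        x[self.iP] = state.P_cav
        x[self.ic :] = state.c_rigid
        return x

    def initial_state(self) -> FEState:
        return FEState(
            u=np.zeros((self.mesh.n_nodes, 3)),
            p=np.zeros(self.npr),
            P_cav=0.0,
            c_rigid=np.zeros(self.n_c),
            V_cav=getattr(self, "V_ref", 0.0),
        )

    def _residual(self, x: np.ndarray, V_target, P_target, t: float):
        u, pfull, Pcav, crig = self._unpack(x)
        blocks = self._element_blocks(u, pfull, t, want_K=False)
        if blocks is None:
            return None, None
        Ru_e, Rp_e, _J, _, _ = blocks
        dofs = self.edofs.ravel()
        ok = dofs >= 0
        R = np.bincount(dofs[ok], weights=Ru_e.reshape(-1)[ok],
                        minlength=self.ndof)
        R += np.bincount(self.pdof_of_corner.ravel(), weights=Rp_e.ravel(),
                         minlength=self.ndof)
        g, fields = self._volume_gradient(u)
        V = self._cavity_volume(u, fields)
        R[: self.nu] -= Pcav * g
        if V_target is not None:
            R[self.iP] = -(V - V_target)
        else:
            R[self.iP] = Pcav - P_target
        R[: self.nu] -= self.C_rigid.T @ crig
        R[self.ic :] = -(self.C_rigid @ x[: self.nu])
        # residual tolerance scale: magnitude of the internal/load forces
        # before cancellation (not the warm-start defect)
        fscale = np.linalg.norm(Ru_e) + abs(Pcav) * np.linalg.norm(g)
        return R, (g, fields, V, fscale)

    def _jacobian(self, x: np.ndarray, kin, V_target, t: float):
        g, fields = kin[0], kin[1]
        u, pfull, Pcav, _c = self._unpack(x)
        blocks = self._element_blocks(u, pfull, t, want_K=True)
        if blocks is None:
            return None
        _Ru, _Rp, _J, Kuu, Kup = blocks
        dataK = np.concatenate([Kuu.ravel(), Kup.ravel(), Kup.ravel()])
        Hs = -Pcav * self._volume_hessian_blocks(fields)
        rows = np.concatenate([self._iK, self._iS])
        cols = np.concatenate([self._jK, self._jS])
        data = np.concatenate([dataK, Hs.ravel()])
        ok = (rows >= 0) & (cols >= 0)
        K = sp.coo_matrix(
            (data[ok], (rows[ok], cols[ok])), shape=(self.ndof, self.ndof)
        ).tocsr()

        iP, ic, nu = self.iP, self.ic, self.nu
        idx = np.arange(nu)
        brows = [idx]
        bcols = [np.full(nu, iP)]
        bdata = [-g]
        if V_target is not None:
            brows += [np.full(nu, iP)]
            bcols += [idx]
            bdata += [-g]
        else:
            brows += [np.array([iP])]
            bcols += [np.array([iP])]
            bdata += [np.array([1.0])]
        for r in range(self.n_c):
            brows += [np.full(nu, ic + r), idx]
            bcols += [idx, np.full(nu, ic + r)]
            bdata += [-self.C_rigid[r], -self.C_rigid[r]]
        # follower-load stiffness of the planar end caps
        for cap in self.mesh.caps:
            fac = -Pcav * (1.0 / 3.0) * cap.outward_sign * cap.z * cap.ring_sign
            xdofs = self.udof[3 * cap.segments + 0]
            ydofs = self.udof[3 * cap.segments + 1]
            Hxy = fac * np.broadcast_to(self.Mseg, (cap.segments.shape[0], 3, 3))
            rr = np.repeat(xdofs, 3, axis=1).ravel()
            cc = np.tile(ydofs, (1, 3)).ravel()
            dd = Hxy.reshape(-1)
            okx = (rr >= 0) & (cc >= 0)
            brows += [rr[okx], cc[okx]]
            bcols += [cc[okx], rr[okx]]
            bdata += [dd[okx], dd[okx]]
        B = sp.coo_matrix(
            (np.concatenate(bdata), (np.concatenate(brows), np.concatenate(bcols))),
            shape=(self.ndof, self.ndof),
        ).tocsr()
        return (K + B).tocsc()

    # ------------------------------------------------------------------
    # Newton solve
    # ------------------------------------------------------------------

    def _newton(self, x, V_target, P_target, t, reuse_lu):
        R, kin = self._residual(x, V_target, P_target, t)
        if R is None:
            return None, 0
        tol = max(self.rtol * max(kin[3], np.linalg.norm(R)), 1e-12)
        iters = 0
        if np.linalg.norm(R) < tol:
            return (x, kin), iters
        # chord iterations with the cached factorization; only improving
        # steps are kept
        if reuse_lu and self._lu is not None:
            rprev = np.linalg.norm(R)
            for _ in range(self.n_chord):
                dx = self._lu.solve(-R)
                xn = x + dx
                Rn, kinn = self._residual(xn, V_target, P_target, t)
                if Rn is None:
                    break
                rn = np.linalg.norm(Rn)
                if not np.isfinite(rn) or rn >= rprev:
                    break
                x, R, kin, rprev = xn, Rn, kinn, rn
                iters += 1
                if rn < tol:
                    return (x, kin), iters
        # full Newton with residual-norm line search
        for _ in range(self.max_iter):
            K = self._jacobian(x, kin, V_target, t)
            if K is None:
                return None, iters
            try:
                self._lu = spla.splu(K, permc_spec="MMD_AT_PLUS_A")
            except RuntimeError:
                self._lu = None
                return None, iters
            dx = self._lu.solve(-R)
            if not np.all(np.isfinite(dx)):
                return None, iters
            lam, best = 1.0, None
            r0 = np.linalg.norm(R)
            Rn = None
            for _ls in range(8):
                xn = x + lam * dx
                Rn, kinn = self._residual(xn, V_target, P_target, t)
                if Rn is not None and np.linalg.norm(Rn) < (1.0 - 0.1 * lam) * r0 + tol:
                    best = (xn, Rn, kinn)
                    break
                lam *= 0.5
            if best is None:
                if Rn is None:
                    return None, iters
                best = (xn, Rn, kinn)
            x, R, kin = best
            iters += 1
            if np.linalg.norm(R) < tol:
                return (x, kin), iters
        return None, iters

    def solve(
        self,
        V_target: float | None = None,
        t: float = 0.0,
        state: FEState | None = None,
        P_target: float | None = None,
        max_bisect: int | None = None,
    ) -> FEState:
        """Solve at prescribed cavity volume (``V_target``, ml) or at
        prescribed cavity pressure (``P_target``, kPa).

        ``t`` is the activation time within the cycle (ms); ``state``
        warm-starts Newton and anchors the load continuation.  Returns the
        converged :class:`FEState`, whose ``P_cav`` is the cavity pressure
        (the chamber's pressure-volume relation f(V))."""
        if (V_target is None) == (P_target is None):
            raise ValueError("specify exactly one of V_target / P_target")
        if V_target is not None and V_target <= 0:
            raise ValueError("target cavity volume must be positive")
        state = state or self.initial_state()
        x0 = self._pack(state)
        start = state.V_cav if V_target is not None else state.P_cav
        goal = V_target if V_target is not None else P_target
        # activation continuation path; across a cycle wrap the activation
        # is not interpolated (tension is small on both sides of the wrap)
        t_start = state.t_act if self.is_lv and t >= state.t_act else t

        result, iters = self._newton(
            x0, V_target, P_target, t, reuse_lu=True)
        total_iters = iters
        if max_bisect is None:
            max_bisect = self.max_bisect
        if result is None:
            nsub = 2
            while nsub <= 2**max_bisect:
                x = x0.copy()
                res = None
                okall = True
                for istep in range(1, nsub + 1):
                    frac = istep / nsub
                    tgt = start + (goal - start) * frac
                    tt = t_start + (t - t_start) * frac
                    res, iters = self._newton(
                        x,
                        tgt if V_target is not None else None,
                        tgt if P_target is not None else None,
                        tt,
                        reuse_lu=False,
                    )
                    total_iters += iters
                    if res is None:
                        okall = False
                        break
                    x = res[0]
                if okall:
                    result = res
                    break
                nsub *= 2
            if result is None:
                raise ChamberSolveError(
                    f"chamber solve failed at load {goal:.6g} "
                    f"(start {start:.6g})", last_volume=start)
        x, kin = result
        u, pfull, Pcav, crig = self._unpack(x)
        V = kin[2]
        new = FEState(u=u, p=pfull, P_cav=float(Pcav), c_rigid=crig,
                      V_cav=float(V), t_act=float(t), converged=True,
                      newton_iters=total_iters)
        if V_target is not None and abs(V - V_target) > 1e-6 * max(V_target, 1.0):
            raise ChamberSolveError(
                f"volume constraint violated: {V:.8g} vs {V_target:.8g}")
        return new

    # ------------------------------------------------------------------
    # post-processing
    # ------------------------------------------------------------------

    def strain_energy(self, state: FEState) -> float:
        """Total stored strain energy (kPa cm^3), passive + tone terms."""
        F = self._deformation(state.u)
        fr = self.frame.vectors
        if self.is_lv:
            W = lv_passive_energy(F, fr["f"], fr["s"], fr["n"], self.material)
        else:
            W = aorta_energy(F, fr, self.material, active=self.active)
        return float((self.wdet * W).sum())

    def stress_field(self, state: FEState, t: float = 0.0) -> np.ndarray:
        """Cauchy stress (kPa) at every volume quadrature point, (E,Q,3,3)."""
        F = self._deformation(state.u)
        J = np.linalg.det(F)
        S, _ = self._material_response(F, t, tangent=False)
        sig = np.einsum("eqiI,eqIJ,eqjJ->eqij", F, S, F,
                        optimize=True) / J[..., None, None]
        pq = np.einsum("qc,ec->eq", self.Np,
                       state.p[self.pdof_of_corner - self.nu], optimize=True)
        sig -= pq[..., None, None] * np.eye(3)
        return sig

    def jacobian_field(self, state: FEState) -> np.ndarray:
        """det F at quadrature points, (E,Q)."""
        return np.linalg.det(self._deformation(state.u))

    def tissue_volume(self, state: FEState) -> float:
        """Current (deformed) tissue volume, ml."""
        return float((self.wdet * self.jacobian_field(state)).sum())
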