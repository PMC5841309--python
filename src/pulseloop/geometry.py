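"""Idealized chamber geometries and microstructure.

Two meshed chambers are produced, both as 10-node quadratic tetrahedra with
labeled boundary patches:

* left ventricle: truncated (half) prolate ellipsoid shell, base in the
  plane z = 0, apex pointing in -z;
* aorta: swept annular tube -- straight ascending segment, circular arch
  bending through 180 degrees in the x-z plane, straight descending
  segment -- with constant wall thickness and a linear inner-radius taper
  starting at mid-arch.  A straight tapered tube (frustum) variant is used
  for verification against closed-form solutions.

Meshes are built on a structured (circumferential x axial x transmural)
grid of hexahedral cells, each split into six tetrahedra with the
Freudenthal (Kuhn) template, which tiles the grid conformingly, including
across the periodic seam.  Mid-edge nodes are placed on the exact
parametric surfaces, so curved boundaries are represented to quadratic
accuracy.

Material direction fields (the LV fiber/sheet/normal triad with a linear
transmural helix-angle rule, and the four aortic fiber families at
0/90/+-45 degrees to the vessel axis) are evaluated directly at quadrature
points from the analytic parametrization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np

from ._tet import TET_FACES, TET10_EDGES, tet10_shape, tet_quadrature

__all__ = [
    "LVGeometry",
    "AortaGeometry",
    "ChamberMesh",
    "FiberFrame",
    "build_lv_mesh",
    "build_aorta_mesh",
    "assign_lv_fibers",
    "assign_aorta_fiber_families",
    "lv_helix_angle",
]


# ---------------------------------------------------------------------------
# geometry descriptions (all lengths in cm)
# ---------------------------------------------------------------------------


@dataclass
class LVGeometry:
    """Truncated prolate-ellipsoid LV shell.

    ``r_endo``/``z_endo`` are the equatorial and long endocardial
    semi-axes, ``r_epi``/``z_epi`` the epicardial ones.  The base is cut at
    z = 0 (the equator), the apex points toward -z.
    """

    r_endo: float = 2.8
    z_endo: float = 5.8
    r_epi: float = 3.8
    z_epi: float = 6.6
    n_circ: int = 14
    n_long: int = 7
    n_trans: int = 2

    def __post_init__(self) -> None:
        if min(self.r_endo, self.z_endo) <= 0:
            raise ValueError("endocardial semi-axes must be positive")
        if self.r_epi <= self.r_endo or self.z_epi <= self.z_endo:
            raise ValueError("epicardial semi-axes must exceed endocardial ones")

    @property
    def cavity_volume(self) -> float:
        """Analytic unloaded cavity volume (2/3) pi a b c, in ml."""
        return 2.0 / 3.0 * np.pi * self.r_endo**2 * self.z_endo

    @property
    def wall_volume(self) -> float:
        return 2.0 / 3.0 * np.pi * (self.r_epi**2 * self.z_epi - self.r_endo**2 * self.z_endo)

    def point(self, theta, mu, s):
        """Map parametric (theta, mu, s) to cartesian coordinates."""
        theta, mu, s = np.broadcast_arrays(theta, mu, s)
        phi = 0.5 * np.pi * np.asarray(mu)
        a = self.r_endo + s * (self.r_epi - self.r_endo)
        c = self.z_endo + s * (self.z_epi - self.z_endo)
        cphi = np.cos(phi)
        return np.stack(
            [a * cphi * np.cos(theta), a * cphi * np.sin(theta), -c * np.sin(phi)],
            axis=-1,
        )


@dataclass
class AortaGeometry:
    """Swept-tube aorta: ascending segment, 180-degree arch, descending
    segment; uniform wall thickness; inner radius constant to mid-arch and
    linearly tapered after.  ``arch_radius=None`` gives a straight tapered
    tube along +z (taper over the whole length)."""

    r_inner: float = 0.93
    thickness: float = 0.31
    length_asc: float = 6.0
    arch_radius: float | None = 5.0
    length_desc: float = 30.0
    taper_ratio: float = 0.9
    # arclength over which the centerline curvature ramps in/out of the
    # arch (clothoid-like); a sharp curvature jump concentrates bending
    # stress at the junctions
    junction_smoothing: float = 4.0
    n_circ: int = 12
    n_axial: int = 8
    n_trans: int = 2

    def __post_init__(self) -> None:
        if self.thickness <= 0:
            raise ValueError("wall thickness must be positive")
        if not 0 < self.taper_ratio <= 1:
            raise ValueError("taper must shrink the diameter (0 < ratio <= 1)")
        if self.arch_radius is not None:
            if self.arch_radius <= self.r_inner + self.thickness:
                raise ValueError("arch radius too small: wall self-intersects")
            La = np.pi * self.arch_radius
            if not 0 <= self.junction_smoothing < 0.5 * La:
                raise ValueError("junction smoothing must be below half the "
                                 "arch length")

    @property
    def length(self) -> float:
        if self.arch_radius is None:
            return self.length_asc + self.length_desc
        return self.length_asc + np.pi * self.arch_radius + self.length_desc

    @property
    def taper_start(self) -> float:
        """Arclength at which the inner radius starts decreasing."""
        if self.arch_radius is None:
            return 0.0
        return self.length_asc + 0.5 * np.pi * self.arch_radius

    def inner_radius_at(self, ell):
        ell = np.asarray(ell, dtype=float)
        l0, L = self.taper_start, self.length
        frac = np.clip((ell - l0) / max(L - l0, 1e-30), 0.0, 1.0)
        return self.r_inner * (1.0 - (1.0 - self.taper_ratio) * frac)

    def _turn_angle(self, ell):
        """Tangent turn angle beta(ell) in the arch plane (0 at the root,
        pi past the arch).  Curvature is a trapezoidal profile: linear
        ramps of length ``junction_smoothing`` at both junctions and a
        constant plateau in between, with total turn pi."""
        L1, La = self.length_asc, np.pi * self.arch_radius
        Lt = self.junction_smoothing
        k0 = np.pi / (La - Lt) if La > Lt else np.pi / La
        s = np.clip(np.asarray(ell, dtype=float) - L1, 0.0, La)
        if Lt <= 0:
            return k0 * s
        beta = np.where(
            s < Lt,
            0.5 * k0 * s**2 / Lt,
            np.where(
                s < La - Lt,
                0.5 * k0 * Lt + k0 * (s - Lt),
                np.pi - 0.5 * k0 * (La - s) ** 2 / Lt,
            ),
        )
        return beta

    def _centerline_table(self):
        """Dense arclength table of the in-plane centerline coordinates."""
        tab = getattr(self, "_cl_tab", None)
        if tab is None:
            L1, La = self.length_asc, np.pi * self.arch_radius
            s = np.linspace(0.0, La, 4001)
            beta = self._turn_angle(L1 + s)
            dx = np.sin(beta)
            dz = np.cos(beta)
            h = s[1] - s[0]
            x = np.concatenate([[0.0], np.cumsum(0.5 * (dx[1:] + dx[:-1]) * h)])
            z = np.concatenate([[0.0], np.cumsum(0.5 * (dz[1:] + dz[:-1]) * h)])
            tab = (s, x, L1 + z)
            self._cl_tab = tab
        return tab

    def centerline(self, ell):
        """Centerline point, tangent and in-plane section direction at
        arclength ``ell``; returns (c, T, u2) with u1 = +y always."""
        ell = np.atleast_1d(np.asarray(ell, dtype=float))
        c = np.zeros(ell.shape + (3,))
        T = np.zeros_like(c)
        if self.arch_radius is None:
            c[..., 2] = ell
            T[..., 2] = 1.0
        else:
            L1, La = self.length_asc, np.pi * self.arch_radius
            beta = self._turn_angle(ell)
            T[..., 0] = np.sin(beta)
            T[..., 2] = np.cos(beta)
            seg1 = ell <= L1
            seg3 = ell >= L1 + La
            arch = ~(seg1 | seg3)
            c[seg1, 2] = ell[seg1]
            stab, xtab, ztab = self._centerline_table()
            sa = ell[arch] - L1
            c[arch, 0] = np.interp(sa, stab, xtab)
            c[arch, 2] = np.interp(sa, stab, ztab)
            x_end, z_end = xtab[-1], ztab[-1]
            c[seg3, 0] = x_end
            c[seg3, 2] = z_end - (ell[seg3] - L1 - La)
        # u2 = y x T (perpendicular section direction in the arch plane)
        yhat = np.array([0.0, 1.0, 0.0])
        u2 = np.cross(np.broadcast_to(yhat, T.shape), T)
        return c, T, u2

    def point(self, theta, v, s):
        """Map parametric (theta, axial fraction v, transmural s)."""
        theta, v, s = np.broadcast_arrays(
            np.asarray(theta, float), np.asarray(v, float), np.asarray(s, float)
        )
        ell = v * self.length
        c, _T, u2 = self.centerline(ell.ravel())
        c = c.reshape(ell.shape + (3,))
        u2 = u2.reshape(ell.shape + (3,))
        r = self.inner_radius_at(ell) + s * self.thickness
        nhat = np.cos(theta)[..., None] * u2
        nhat[..., 1] += np.sin(theta)
        return c + r[..., None] * nhat

    def lumen_volume(self) -> float:
        """Reference lumen volume by integrating the section area along the
        centerline (exact for constant sections by Pappus)."""
        from scipy.integrate import quad

        val, _ = quad(lambda l: np.pi * self.inner_radius_at(l) ** 2, 0.0, self.length,
                      limit=200)
        return float(val)


# ---------------------------------------------------------------------------
# mesh container
# ---------------------------------------------------------------------------


@dataclass
class Cap:
    """Planar lumen closure at a tube end (plane z = const)."""

    ring: np.ndarray          # fine-grid inner ring node ids, circumferential order
    z: float                  # plane height
    outward_sign: float       # +1 if the lumen-outward normal is +z
    segments: np.ndarray = None       # (n_seg, 3) quadratic ring segments
    ring_sign: float = 1.0    # orientation factor making the shoelace area positive


def _shoelace_operator() -> np.ndarray:
    """Antisymmetric operator M with A = sum_seg x^T M y for quadratic
    ring segments (shoelace area in the cap plane)."""
    from ._tet import line3_shape, line_quadrature

    xq, wq = line_quadrature(3)
    Nl, dNl = line3_shape(xq)
    K = np.einsum("q,qa,qb->ab", wq, Nl, dNl)
    return 0.5 * (K - K.T)


def cap_area(nodes_xy: np.ndarray, cap: "Cap", Mseg: np.ndarray | None = None) -> float:
    """Signed shoelace area of a cap ring from node coordinates (n, >=2)."""
    M = _shoelace_operator() if Mseg is None else Mseg
    xs = nodes_xy[cap.segments][..., 0]
    ys = nodes_xy[cap.segments][..., 1]
    return float(np.einsum("sa,ab,sb->", xs, M, ys))


@dataclass
class ChamberMesh:
    """Quadratic-tet chamber mesh with labeled surfaces.

    ``surfaces`` maps label -> (F, 6) arrays of quadratic triangles whose
    corner ordering gives outward (domain-exterior) normals.  ``node_ijk``
    holds the structured fine-grid index of every node; ``node_param`` the
    parametric (theta, mu-or-v, s) coordinates.
    """

    chamber: str
    nodes: np.ndarray
    tets: np.ndarray
    surfaces: dict[str, np.ndarray]
    node_ijk: np.ndarray
    node_param: np.ndarray
    index_map: np.ndarray
    geom: LVGeometry | AortaGeometry
    caps: list[Cap] = field(default_factory=list)
    tether_sections: list = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_cells(self) -> int:
        return self.tets.shape[0]

    @property
    def vertex_ids(self) -> np.ndarray:
        return np.unique(self.tets[:, :4])

    def constrained_nodes(self) -> np.ndarray:
        """Nodes whose normal (z) displacement is pinned: the LV base ring
        plane, or both aortic end planes."""
        j = self.node_ijk[:, 1]
        if self.chamber == "lv":
            return np.nonzero(j == 0)[0]
        jmax = self.index_map.shape[1] - 1
        return np.nonzero((j == 0) | (j == jmax))[0]

    def min_scaled_jacobian(self) -> float:
        """Minimum detJ at the volume quadrature points, scaled per element
        by its maximum; positive for valid meshes."""
        pts, _ = tet_quadrature(4)
        _, dN = tet10_shape(pts)
        X = self.nodes[self.tets]                       # (E,10,3)
        J = np.einsum("qam,ead->eqdm", dN, X)           # dX_d/dxi_m
        det = np.linalg.det(np.swapaxes(J, -1, -2))
        return float((det.min(axis=1) / det.max(axis=1)).min())


# ---------------------------------------------------------------------------
# structured Freudenthal meshing
# ---------------------------------------------------------------------------

_KUHN_PERMS = [(0, 1, 2), (0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0)]


def _kuhn_corner_offsets() -> list[np.ndarray]:
    out = []
    for perm in _KUHN_PERMS:
        v = np.zeros((4, 3), dtype=int)
        v[1] = v[0].copy()
        v[1][perm[0]] = 1
        v[2] = v[1].copy()
        v[2][perm[1]] = 1
        v[3] = (1, 1, 1)
        out.append(v)
    return out


_KUHN_TETS = _kuhn_corner_offsets()


def _build_structured(
    chamber: str,
    geom,
    n_circ: int,
    n_ax: int,
    n_trans: int,
    param_of_index,
    collapse_apex: bool,
):
    """Shared LV/aorta builder on a periodic-theta structured grid."""
    NI, NJ, NK = 2 * n_circ, 2 * n_ax, 2 * n_trans

    # --- fine-grid nodes, with the apex column deduplicated ----------------
    index_map = -np.ones((NI, NJ + 1, NK + 1), dtype=int)
    ids_ijk: list[tuple[int, int, int]] = []

    def nid(i: int, j: int, k: int) -> int:
        i = i % NI
        if collapse_apex and j == NJ:
            i = 0
        if index_map[i, j, k] < 0:
            index_map[i, j, k] = len(ids_ijk)
            ids_ijk.append((i, j, k))
        return index_map[i, j, k]

    # --- tets --------------------------------------------------------------
    corner_sets = []
    for ci in range(n_circ):
        for cj in range(n_ax):
            for ck in range(n_trans):
                base = np.array([2 * ci, 2 * cj, 2 * ck])
                for offs in _KUHN_TETS:
                    corners = base + 2 * offs  # unwrapped fine indices
                    ids = [nid(*c) for c in corners]
                    if len(set(ids)) < 4:
                        continue  # collapsed at the apex
                    corner_sets.append((ids, corners))

    # node coordinates
    node_ijk = np.array(ids_ijk, dtype=int)
    theta, ax, s = param_of_index(node_ijk[:, 0], node_ijk[:, 1], node_ijk[:, 2])
    node_param = np.stack([theta, ax, s], axis=1)
    nodes = geom.point(theta, ax, s)

    # orient (corner order with positive volume), then attach mid-edge nodes
    tets = np.empty((len(corner_sets), 10), dtype=int)
    for e, (ids, corners) in enumerate(corner_sets):
        X = nodes[ids]
        vol6 = np.linalg.det(X[1:] - X[0])
        if vol6 < 0:
            ids = [ids[0], ids[2], ids[1], ids[3]]
            corners = corners[[0, 2, 1, 3]]
        tets[e, :4] = ids
        for m, (a, b) in enumerate(TET10_EDGES):
            mid = (corners[a] + corners[b]) // 2
            tets[e, 4 + m] = nid(*mid)

    # nid() may have appended nodes (edge midpoints) after the array was
    # sized -- rebuild coordinate arrays to cover them all
    if len(ids_ijk) > node_ijk.shape[0]:
        node_ijk = np.array(ids_ijk, dtype=int)
        theta, ax, s = param_of_index(node_ijk[:, 0], node_ijk[:, 1], node_ijk[:, 2])
        node_param = np.stack([theta, ax, s], axis=1)
        nodes = geom.point(theta, ax, s)

    mesh = ChamberMesh(
        chamber=chamber,
        nodes=np.asarray(nodes, dtype=float),
        tets=tets,
        surfaces={},
        node_ijk=node_ijk,
        node_param=node_param,
        index_map=index_map,
        geom=geom,
    )
    _extract_surfaces(mesh, NJ, NK, collapse_apex)

    msj = mesh.min_scaled_jacobian()
    if msj <= 0.0:
        raise RuntimeError(f"inverted element in {chamber} mesh (min scaled J={msj:.3g})")
    return mesh


def _extract_surfaces(mesh: ChamberMesh, NJ: int, NK: int, lv: bool) -> None:
    """Find boundary faces (appearing once) and label them by patch."""
    tets = mesh.tets
    facemap: dict[tuple[int, ...], tuple[int, ...] | None] = {}
    # local mid-node index for each corner pair
    edge_mid = {}
    for m, (a, b) in enumerate(TET10_EDGES):
        edge_mid[(a, b)] = 4 + m
        edge_mid[(b, a)] = 4 + m
    for conn in tets:
        for f in TET_FACES:
            tri = (conn[f[0]], conn[f[1]], conn[f[2]])
            mids = (
                conn[edge_mid[(f[0], f[1])]],
                conn[edge_mid[(f[1], f[2])]],
                conn[edge_mid[(f[2], f[0])]],
            )
            key = tuple(sorted(tri))
            if key in facemap:
                facemap[key] = None  # interior
            else:
                facemap[key] = tri + mids
    boundary = [v for v in facemap.values() if v is not None]

    j_of = mesh.node_ijk[:, 1]
    k_of = mesh.node_ijk[:, 2]
    labels: dict[str, list] = (
        {"inner": [], "outer": [], "base": []}
        if lv
        else {"inner": [], "outer": [], "end_proximal": [], "end_distal": []}
    )
    for face in boundary:
        ks = k_of[list(face)]
        js = j_of[list(face)]
        if np.all(ks == 0):
            labels["inner"].append(face)
        elif np.all(ks == NK):
            labels["outer"].append(face)
        elif np.all(js == 0):
            labels["base" if lv else "end_proximal"].append(face)
        elif not lv and np.all(js == NJ):
            labels["end_distal"].append(face)
        else:  # pragma: no cover - structural invariant
            raise RuntimeError("unclassifiable boundary face")
    mesh.surfaces = {k: np.array(v, dtype=int).reshape(-1, 6) for k, v in labels.items()}


# ---------------------------------------------------------------------------
# public mesh builders
# ---------------------------------------------------------------------------


def build_lv_mesh(geom: LVGeometry | None = None, resolution: float = 1.0) -> ChamberMesh:
    """Mesh the half-prolate-ellipsoid LV shell.

    ``resolution`` scales the default cell counts (values > 1 refine).
    """
    geom = geom or LVGeometry()
    nc = max(4, round(geom.n_circ * resolution))
    nl = max(2, round(geom.n_long * resolution))
    nt = max(1, round(geom.n_trans * resolution))

    def param(i, j, k):
        theta = 2.0 * np.pi * i / (2 * nc)
        mu = j / (2 * nl)
        s = k / (2 * nt)
        return theta, mu, s

    return _build_structured("lv", geom, nc, nl, nt, param, collapse_apex=True)


def build_aorta_mesh(geom: AortaGeometry | None = None, resolution: float = 1.0) -> ChamberMesh:
    """Mesh the swept-tube aorta (or straight frustum if no arch)."""
    geom = geom or AortaGeometry()
    nc = max(4, round(geom.n_circ * resolution))
    na = max(2, round(geom.n_axial * resolution))
    nt = max(1, round(geom.n_trans * resolution))

    def param(i, j, k):
        theta = 2.0 * np.pi * i / (2 * nc)
        v = j / (2 * na)
        s = k / (2 * nt)
        return theta, v, s

    mesh = _build_structured("aorta", geom, nc, na, nt, param, collapse_apex=False)

    # lumen end caps: planar rings in z = const planes
    _c, T0, _ = geom.centerline(np.array([0.0]))
    _c, T1, _ = geom.centerline(np.array([geom.length]))
    # Perivascular tethering: in situ the aorta is anchored along its
    # length (spine, intercostal and supra-aortic branches).  Constrain
    # the mean displacement of every interior cross-section (one
    # multiplier triple per section), which freezes the centerline --
    # otherwise the pressurized U-bend balloons axially (Bourdon effect)
    # -- while leaving radial distension free.
    for j in range(1, 2 * na):
        mesh.tether_sections.append(mesh.index_map[:, j, :].ravel().copy())
    Mseg = _shoelace_operator()
    for j, T in ((0, -T0[0]), (2 * na, T1[0])):
        if abs(abs(T[2]) - 1.0) > 1e-12:  # pragma: no cover
            raise RuntimeError("tube end plane is not horizontal")
        ring = mesh.index_map[:, j, 0].copy()
        zcap = float(mesh.nodes[ring, 2].mean())
        segs = np.array(
            [
                (ring[2 * t], ring[(2 * t + 2) % len(ring)], ring[2 * t + 1])
                for t in range(len(ring) // 2)
            ],
            dtype=int,
        )
        cap = Cap(ring=ring, z=zcap, outward_sign=float(np.sign(T[2]) or 1.0),
                  segments=segs)
        cap.ring_sign = 1.0 if cap_area(mesh.nodes, cap, Mseg) >= 0 else -1.0
        mesh.caps.append(cap)
    return mesh


# ---------------------------------------------------------------------------
# fiber/microstructure fields
# ---------------------------------------------------------------------------


@dataclass
class FiberFrame:
    """Material direction fields sampled at element quadrature points.

    For the LV the keys are ``f``, ``s``, ``n`` (fiber, sheet, sheet
    normal); for the aorta ``e1``..``e4`` (longitudinal, circumferential,
    +-45-degree collagen families; smooth muscle is aligned with ``e2``)
    plus ``radial``.
    Each entry has shape (n_elements, n_qp, 3).
    """

    kind: str
    vectors: dict[str, np.ndarray]
    qp_points: np.ndarray  # reference coordinates used for sampling
    activation_scale: np.ndarray | None = None  # (E, Q) active-stress taper

    def __getitem__(self, key: str) -> np.ndarray:
        return self.vectors[key]


def lv_helix_angle(s, angle_endo: float = 60.0, angle_epi: float = -60.0):
    """Helix angle (degrees) at transmural coordinate s in [0, 1]."""
    s = np.asarray(s, dtype=float)
    return angle_endo * (1.0 - s) + angle_epi * s


def _qp_fields(mesh: ChamberMesh, points: np.ndarray):
    """Physical coordinates and interpolated (axial, transmural) parametric
    coordinates at the given reference points, for every element."""
    N, _ = tet10_shape(points)
    conn = mesh.tets
    x = np.einsum("qa,ead->eqd", N, mesh.nodes[conn])
    ax = np.einsum("qa,ea->eq", N, mesh.node_param[conn, 1])
    s = np.einsum("qa,ea->eq", N, mesh.node_param[conn, 2])
    return x, ax, s


def assign_lv_fibers(
    mesh: ChamberMesh,
    angle_endo: float = 60.0,
    angle_epi: float = -60.0,
    points: np.ndarray | None = None,
    apex_blend: float | None = None,
) -> FiberFrame:
    """Rule-based myofiber triad with a linear transmural helix-angle
    variation (endocardium ``angle_endo`` to epicardium ``angle_epi``).

    Within a cap of cylindrical radius ``apex_blend`` (default: 30% of the
    endocardial radius) the fiber direction is blended smoothly toward the
    local longitudinal direction.  This is the standard rule-based-fiber
    regularization of the apex: the circumferential direction degenerates
    on the axis, and purely circumferential tension at a vanishing radius
    would crush the apex elements.
    """
    if mesh.chamber != "lv":
        raise ValueError("mesh is not tagged as LV")
    if points is None:
        points, _ = tet_quadrature(4)
    geom: LVGeometry = mesh.geom
    if apex_blend is None:
        apex_blend = 0.3 * geom.r_endo
    x, mu, s = _qp_fields(mesh, points)
    theta = np.arctan2(x[..., 1], x[..., 0])
    phi = 0.5 * np.pi * mu

    e_c = np.stack([-np.sin(theta), np.cos(theta), np.zeros_like(theta)], axis=-1)
    a = geom.r_endo + s * (geom.r_epi - geom.r_endo)
    c = geom.z_endo + s * (geom.z_epi - geom.z_endo)
    x_mu = np.stack(
        [
            -a * np.sin(phi) * np.cos(theta),
            -a * np.sin(phi) * np.sin(theta),
            -c * np.cos(phi),
        ],
        axis=-1,
    )
    e_l = x_mu / np.linalg.norm(x_mu, axis=-1, keepdims=True)
    e_t = np.cross(e_c, e_l)

    alpha = np.deg2rad(lv_helix_angle(s, angle_endo, angle_epi))
    e_f = np.cos(alpha)[..., None] * e_c + np.sin(alpha)[..., None] * e_l
    act = np.ones_like(s)
    if apex_blend > 0:
        rho = np.hypot(x[..., 0], x[..., 1])
        beta = np.clip(rho / apex_blend, 0.0, 1.0)
        beta = beta * beta * (3.0 - 2.0 * beta)        # smoothstep
        e_f = beta[..., None] * e_f + (1.0 - beta[..., None]) * e_l
        e_f = e_f / np.linalg.norm(e_f, axis=-1, keepdims=True)
        act = beta                                     # taper tension in the cap
    e_s = e_t
    # re-orthonormalize after blending
    e_s = e_s - np.einsum("...d,...d->...", e_s, e_f,
                          optimize=True)[..., None] * e_f
    e_s = e_s / np.linalg.norm(e_s, axis=-1, keepdims=True)
    e_n = np.cross(e_f, e_s)
    return FiberFrame("lv", {"f": e_f, "s": e_s, "n": e_n}, points,
                      activation_scale=act)


def assign_aorta_fiber_families(
    mesh: ChamberMesh, points: np.ndarray | None = None
) -> FiberFrame:
    """Four-fiber-family directions: e1 longitudinal (centerline tangent),
    e2 circumferential, e3/e4 at +-45 degrees to the axis in the tangent
    plane.  Smooth muscle shares e2."""
    if mesh.chamber != "aorta":
        raise ValueError("mesh is not tagged as aorta")
    if points is None:
        points, _ = tet_quadrature(4)
    geom: AortaGeometry = mesh.geom
    x, v, _s = _qp_fields(mesh, points)
    ell = v * geom.length
    c, T, _u2 = geom.centerline(ell.ravel())
    shape = ell.shape
    c = c.reshape(shape + (3,))
    T = T.reshape(shape + (3,))
    d = x - c
    # remove the axial component of the centerline offset: interpolated
    # position and interpolated arclength are only consistent to the mesh
    # resolution inside strongly curved (arch) elements
    d = d - np.einsum("...d,...d->...", d, T, optimize=True)[..., None] * T
    nrm = np.linalg.norm(d, axis=-1, keepdims=True)
    if np.any(nrm < 1e-12):  # pragma: no cover
        bad = np.argwhere(nrm[..., 0] < 1e-12)[0]
        raise RuntimeError(f"centerline projection failed at element {bad[0]}")
    nhat = d / nrm
    e1 = T
    e2 = np.cross(T, nhat)
    rt2 = 1.0 / np.sqrt(2.0)
    e3 = rt2 * (e1 + e2)
    e4 = rt2 * (e1 - e2)
    return FiberFrame(
        "aorta", {"e1": e1, "e2": e2, "e3": e3, "e4": e4, "radial": nhat}, points
    )
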