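"""Reference-element tables for 10-node tetrahedra, 6-node triangles and
3-node line segments (all quadratic Lagrange, VTK node ordering).

Everything here is expressed on the reference simplex; physical-space
quantities (Jacobians, integration weights) are produced by the callers.
"""

from __future__ import annotations

import numpy as np

# VTK_QUADRATIC_TETRA edge ordering: (0,1) (1,2) (2,0) (0,3) (1,3) (2,3)
TET10_EDGES = ((0, 1), (1, 2), (2, 0), (0, 3), (1, 3), (2, 3))
# VTK_QUADRATIC_TRIANGLE edge ordering: (0,1) (1,2) (2,0)
TRI6_EDGES = ((0, 1), (1, 2), (2, 0))

# Faces of a positively oriented tet, ordered so the face normal points out
# of the element.  Entries are corner-local indices.
TET_FACES = ((0, 2, 1), (0, 1, 3), (1, 2, 3), (0, 3, 2))


def tet10_shape(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Shape functions and reference gradients of the 10-node tet.

    Parameters
    ----------
    points : (Q, 3) array of reference coordinates (xi, eta, zeta).

    Returns
    -------
    N : (Q, 10), dN : (Q, 10, 3)
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    xi, eta, zeta = pts[:, 0], pts[:, 1], pts[:, 2]
    lam = np.stack([1.0 - xi - eta - zeta, xi, eta, zeta], axis=1)  # (Q,4)
    dlam = np.array(
        [[-1.0, -1.0, -1.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]]
    )  # (4,3)
    Q = pts.shape[0]
    N = np.empty((Q, 10))
    dN = np.empty((Q, 10, 3))
    for a in range(4):
        N[:, a] = lam[:, a] * (2.0 * lam[:, a] - 1.0)
        dN[:, a, :] = (4.0 * lam[:, a] - 1.0)[:, None] * dlam[a]
    for e, (a, b) in enumerate(TET10_EDGES):
        N[:, 4 + e] = 4.0 * lam[:, a] * lam[:, b]
        dN[:, 4 + e, :] = 4.0 * (
            lam[:, a][:, None] * dlam[b] + lam[:, b][:, None] * dlam[a]
        )
    return N, dN


def tri6_shape(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Shape functions / reference gradients of the 6-node triangle."""
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    xi, eta = pts[:, 0], pts[:, 1]
    lam = np.stack([1.0 - xi - eta, xi, eta], axis=1)
    dlam = np.array([[-1.0, -1.0], [1.0, 0.0], [0.0, 1.0]])
    Q = pts.shape[0]
    N = np.empty((Q, 6))
    dN = np.empty((Q, 6, 2))
    for a in range(3):
        N[:, a] = lam[:, a] * (2.0 * lam[:, a] - 1.0)
        dN[:, a, :] = (4.0 * lam[:, a] - 1.0)[:, None] * dlam[a]
    for e, (a, b) in enumerate(TRI6_EDGES):
        N[:, 3 + e] = 4.0 * lam[:, a] * lam[:, b]
        dN[:, 3 + e, :] = 4.0 * (
            lam[:, a][:, None] * dlam[b] + lam[:, b][:, None] * dlam[a]
        )
    return N, dN


def line3_shape(xi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Quadratic segment with nodes at xi = 0, 1, 1/2 (VTK ordering)."""
    xi = np.asarray(xi, dtype=float).ravel()
    N = np.stack(
        [2.0 * (xi - 0.5) * (xi - 1.0), 2.0 * xi * (xi - 0.5), 4.0 * xi * (1.0 - xi)],
        axis=1,
    )
    dN = np.stack([4.0 * xi - 3.0, 4.0 * xi - 1.0, 4.0 - 8.0 * xi], axis=1)
    return N, dN


def tet_quadrature(degree: int = 4) -> tuple[np.ndarray, np.ndarray]:
    """Symmetric Keast quadrature on the reference tet (weights sum to 1/6)."""
    if degree <= 2:
        a, b = 0.5854101966249685, 0.1381966011250105
        pts = np.array(
            [[b, b, b], [a, b, b], [b, a, b], [b, b, a]]
        )
        w = np.full(4, 0.25 / 6.0)
        return pts, w
    if degree <= 4:
        # 11-point Keast rule, degree 4
        pts = [(0.25, 0.25, 0.25)]
        w = [-74.0 / 5625.0]
        a, b = 1.0 / 14.0, 11.0 / 14.0
        for p in _perms4((b, a, a, a)):
            pts.append(p)
            w.append(343.0 / 45000.0)
        c, d = 0.3994035761667992, 0.1005964238332008
        for p in _perms4((c, c, d, d)):
            pts.append(p)
            w.append(28.0 / 1125.0)
        return np.array(pts), np.array(w)
    raise ValueError(f"no tet rule of degree {degree}")


def _perms4(bary: tuple[float, ...]) -> list[tuple[float, float, float]]:
    """Distinct permutations of a barycentric quadruple, as (xi,eta,zeta)."""
    seen = set()
    out = []
    from itertools import permutations

    for p in permutations(bary):
        if p not in seen:
            seen.add(p)
            out.append((p[1], p[2], p[3]))  # lam0 implicit
    return out


def tri_quadrature(degree: int = 5) -> tuple[np.ndarray, np.ndarray]:
    """Symmetric rule on the reference triangle (weights sum to 1/2)."""
    if degree <= 2:
        pts = np.array([[1 / 6, 1 / 6], [2 / 3, 1 / 6], [1 / 6, 2 / 3]])
        w = np.full(3, 1.0 / 6.0)
        return pts, w
    # 7-point degree-5 rule
    a1, w1 = 0.0597158717897698, 0.1323941527885062
    a2, w2 = 0.7974269853530873, 0.1259391805448271
    pts = [(1 / 3, 1 / 3)]
    w = [0.225]
    for a, ww in ((a1, w1), (a2, w2)):
        b = (1.0 - a) / 2.0
        pts += [(a, b), (b, a), (b, b)]
        w += [ww] * 3
    return np.array(pts), 0.5 * np.array(w)


def line_quadrature(npts: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """Gauss-Legendre rule on [0, 1]."""
    x, w = np.polynomial.legendre.leggauss(npts)
    return 0.5 * (x + 1.0), 0.5 * w
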