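"""Finite-element family definitions: shape functions, quadrature, facets.

Supported families
------------------
``tri3``   linear triangle (2D, constant strain)
``quad4``  bilinear quadrilateral (2D, 2x2 Gauss)
``quad8``  serendipity quadratic quadrilateral (2D, 3x3 Gauss)
``tet4``   linear tetrahedron (3D, constant strain)
``hex8``   trilinear hexahedron (3D, 2x2x2 Gauss)

Shape-function routines return ``N`` of shape (nnodes,) and ``dN`` of shape
(nnodes, dim) in natural coordinates.
"""

from __future__ import annotations

import numpy as np

_G = 1.0 / np.sqrt(3.0)
_G3 = np.sqrt(0.6)
_W3 = np.array([5.0, 8.0, 5.0]) / 9.0


def _tri3(xi):
    r, s = xi
    N = np.array([1 - r - s, r, s])
    dN = np.array([[-1.0, -1.0], [1.0, 0.0], [0.0, 1.0]])
    return N, dN


def _tet4(xi):
    r, s, t = xi
    N = np.array([1 - r - s - t, r, s, t])
    dN = np.array(
        [[-1.0, -1.0, -1.0], [1.0, 0, 0], [0, 1.0, 0], [0, 0, 1.0]]
    )
    return N, dN


_Q4_XI = np.array([[-1, -1], [1, -1], [1, 1], [-1, 1]], dtype=float)


def _quad4(xi):
    r, s = xi
    N = 0.25 * (1 + _Q4_XI[:, 0] * r) * (1 + _Q4_XI[:, 1] * s)
    dN = np.empty((4, 2))
    dN[:, 0] = 0.25 * _Q4_XI[:, 0] * (1 + _Q4_XI[:, 1] * s)
    dN[:, 1] = 0.25 * _Q4_XI[:, 1] * (1 + _Q4_XI[:, 0] * r)
    return N, dN


def _quad8(xi):
    r, s = xi
    rc, sc = _Q4_XI[:, 0], _Q4_XI[:, 1]
    N = np.empty(8)
    dN = np.empty((8, 2))
    # corners
    N[:4] = 0.25 * (1 + rc * r) * (1 + sc * s) * (rc * r + sc * s - 1)
    dN[:4, 0] = 0.25 * rc * (1 + sc * s) * (2 * rc * r + sc * s)
    dN[:4, 1] = 0.25 * sc * (1 + rc * r) * (rc * r + 2 * sc * s)
    # midsides: 4 (s=-1), 5 (r=+1), 6 (s=+1), 7 (r=-1)
    N[4] = 0.5 * (1 - r * r) * (1 - s)
    dN[4] = [-r * (1 - s), -0.5 * (1 - r * r)]
    N[5] = 0.5 * (1 + r) * (1 - s * s)
    dN[5] = [0.5 * (1 - s * s), -s * (1 + r)]
    N[6] = 0.5 * (1 - r * r) * (1 + s)
    dN[6] = [-r * (1 + s), 0.5 * (1 - r * r)]
    N[7] = 0.5 * (1 - r) * (1 - s * s)
    dN[7] = [-0.5 * (1 - s * s), -s * (1 - r)]
    return N, dN


_H8_XI = np.array(
    [
        [-1, -1, -1], [1, -1, -1], [1, 1, -1], [-1, 1, -1],
        [-1, -1, 1], [1, -1, 1], [1, 1, 1], [-1, 1, 1],
    ],
    dtype=float,
)


def _hex8(xi):
    r, s, t = xi
    a = _H8_XI
    N = 0.125 * (1 + a[:, 0] * r) * (1 + a[:, 1] * s) * (1 + a[:, 2] * t)
    dN = np.empty((8, 3))
    dN[:, 0] = 0.125 * a[:, 0] * (1 + a[:, 1] * s) * (1 + a[:, 2] * t)
    dN[:, 1] = 0.125 * a[:, 1] * (1 + a[:, 0] * r) * (1 + a[:, 2] * t)
    dN[:, 2] = 0.125 * a[:, 2] * (1 + a[:, 0] * r) * (1 + a[:, 1] * s)
    return N, dN


def _gauss_2d(n):
    if n == 2:
        pts = [(x, y) for y in (-_G, _G) for x in (-_G, _G)]
        wts = [1.0] * 4
    else:
        pts = [(x, y) for y in (-_G3, 0, _G3) for x in (-_G3, 0, _G3)]
        wts = [_W3[i] * _W3[j] for j in range(3) for i in range(3)]
    return np.array(pts), np.array(wts)


def _gauss_3d():
    pts = [(x, y, z) for z in (-_G, _G) for y in (-_G, _G) for x in (-_G, _G)]
    return np.array(pts), np.ones(8)


class Family:
    def __init__(self, name, dim, nnodes, shape_fn, gauss_pts, gauss_wts,
                 facets, vtk_type, reduced_pt=None):
        self.name = name
        self.dim = dim
        self.nnodes = nnodes
        self.shape_fn = shape_fn
        self.gauss_pts = gauss_pts
        self.gauss_wts = gauss_wts
        self.facets = facets
        self.vtk_type = vtk_type
        self.reduced_pt = reduced_pt  # single point for selective-reduced integration


FAMILIES: dict[str, Family] = {
    "tri3": Family(
        "tri3", 2, 3, _tri3,
        np.array([[1 / 3, 1 / 3]]), np.array([0.5]),
        [(0, 1), (1, 2), (2, 0)], 5,
    ),
    "quad4": Family(
        "quad4", 2, 4, _quad4, *_gauss_2d(2),
        facets=[(0, 1), (1, 2), (2, 3), (3, 0)], vtk_type=9,
        reduced_pt=np.array([0.0, 0.0]),
    ),
    "quad8": Family(
        "quad8", 2, 8, _quad8, *_gauss_2d(3),
        facets=[(0, 1, 4), (1, 2, 5), (2, 3, 6), (3, 0, 7)], vtk_type=23,
    ),
    "tet4": Family(
        "tet4", 3, 4, _tet4,
        np.array([[0.25, 0.25, 0.25]]), np.array([1 / 6]),
        [(0, 2, 1), (0, 1, 3), (1, 2, 3), (0, 3, 2)], 10,
    ),
    "hex8": Family(
        "hex8", 3, 8, _hex8, *_gauss_3d(),
        facets=[(0, 3, 2, 1), (4, 5, 6, 7), (0, 1, 5, 4),
                (1, 2, 6, 5), (2, 3, 7, 6), (3, 0, 4, 7)], vtk_type=12,
        reduced_pt=np.array([0.0, 0.0, 0.0]),
    ),
}


def shape_all_gauss(family: Family):
    """(ngp, nnodes) shape values and (ngp, nnodes, dim) natural gradients."""
    Ns, dNs = [], []
    for xi in family.gauss_pts:
        N, dN = family.shape_fn(xi)
        Ns.append(N)
        dNs.append(dN)
    return np.array(Ns), np.array(dNs)


def element_measures(nodes: np.ndarray, elements: np.ndarray, family_name: str) -> np.ndarray:
    """Area (2D) or volume (3D) of each element, signed-by-orientation made
    explicit: returns the signed measure (positive for correctly oriented
    elements)."""
    fam = FAMILIES[family_name]
    coords = nodes[elements]  # (nel, nn, dim)
    total = np.zeros(len(elements))
    _, dNs = shape_all_gauss(fam)
    for w, dN in zip(fam.gauss_wts, dNs):
        J = np.einsum("ni,enj->eij", dN, coords)  # dx_j/dxi_i
        total += w * np.linalg.det(J)
    return total


def edge_lengths(nodes: np.ndarray, elements: np.ndarray, family_name: str) -> np.ndarray:
    """Min corner-edge length per element (simplex edges; quad/hex facet edges)."""
    fam = FAMILIES[family_name]
    coords = nodes[elements]
    if family_name in ("tri3", "tet4"):
        n = fam.nnodes
        pairs = [(a, b) for a in range(n) for b in range(a + 1, n)]
    elif family_name in ("quad4", "quad8"):
        pairs = [(0, 1), (1, 2), (2, 3), (3, 0)]
    else:  # hex8
        pairs = [(0, 1), (1, 2), (2, 3), (3, 0), (4, 5), (5, 6), (6, 7), (7, 4),
                 (0, 4), (1, 5), (2, 6), (3, 7)]
    d = np.stack(
        [np.linalg.norm(coords[:, a] - coords[:, b], axis=1) for a, b in pairs]
    )
    return d.min(axis=0)
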