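"""Linear-elastic forward solver (2D plane stress / 3D) with SIMP material.

Element stiffness follows the density parameterization ``E_k = rho_k**p * E0``
with isotropic linear elasticity: plane stress in 2D, the full isotropic law
in 3D.  Dirichlet data may prescribe individual displacement components
(NaN marks a free component).  The solver condenses prescribed DOFs and
factorizes the free-free block with sparse LU; the factorization is reused
for adjoint solves during inversion.

Under pure-Dirichlet loading the solution is invariant to a uniform scaling
of ``E0``: only relative stiffness is identifiable, which is why a nominal
baseline modulus (default 500 Pa) is acceptable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .elements import FAMILIES, shape_all_gauss
from .meshing import FEMesh


class SolverError(RuntimeError):
    pass


@dataclass
class MaterialField:
    """Per-element density with SIMP modulus scaling ``E_k = rho_k**p * E0``.

    Parameters
    ----------
    rho : ndarray (n_elements,)
        Relative densities, ``rho_min < rho_k <= 1``.
    rho_min : float
        Lower density bound keeping the stiffness matrix definite.
    penal : float
        SIMP exponent p; the elastography workflow uses p = 1 (modulus
        linear in density; no 0/1 penalization).
    E0 : float
        Baseline Young's modulus in Pa (arbitrary under pure-Dirichlet data).
    nu : float
        Poisson's ratio (default 0.49: nearly incompressible tissue).
    """

    rho: np.ndarray
    rho_min: float = 0.01
    penal: float = 1.0
    E0: float = 500.0
    nu: float = 0.49

    def __post_init__(self):
        self.rho = np.asarray(self.rho, dtype=float)
        if not (0 < self.rho_min < 1):
            raise ValueError("rho_min must be in (0, 1)")
        if np.any(self.rho < self.rho_min - 1e-12) or np.any(self.rho > 1 + 1e-12):
            raise ValueError("rho must lie in [rho_min, 1]")
        if self.penal < 1:
            raise ValueError("penal must be >= 1")
        if not (0 <= self.nu < 0.5):
            raise ValueError("nu must be in [0, 0.5)")
        if self.E0 <= 0:
            raise ValueError("E0 must be positive")

    def youngs(self) -> np.ndarray:
        """Element Young's moduli E_k in Pa."""
        return self.rho ** self.penal * self.E0

    @classmethod
    def uniform(cls, n_elements: int, rho: float = 0.5, **kw) -> "MaterialField":
        return cls(rho=np.full(n_elements, float(rho)), **kw)


@dataclass
class DirichletBC:
    """Prescribed nodal displacements (mm); NaN leaves a component free."""

    nodes: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.nodes = np.asarray(self.nodes, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or len(self.values) != len(self.nodes):
            raise ValueError("values must be (n_nodes, dim)")
        if len(np.unique(self.nodes)) != len(self.nodes):
            raise ValueError("duplicate nodes in boundary condition")
        if np.any(np.isinf(self.values)):
            raise ValueError("boundary values must be finite (or NaN for free)")

    @property
    def dim(self) -> int:
        return self.values.shape[1]

    def dof_arrays(self, n_nodes: int):
        """Boolean prescribed-mask and value vector over all ``n_nodes*dim`` DOFs."""
        dim = self.dim
        prescribed = np.zeros(n_nodes * dim, dtype=bool)
        vals = np.zeros(n_nodes * dim)
        for c in range(dim):
            sel = np.isfinite(self.values[:, c])
            dofs = self.nodes[sel] * dim + c
            prescribed[dofs] = True
            vals[dofs] = self.values[sel, c]
        return prescribed, vals

    @classmethod
    def from_dict(cls, d: dict) -> "DirichletBC":
        nodes = np.array(sorted(d.keys()), dtype=np.int64)
        values = np.array([d[n] for n in nodes], dtype=float)
        return cls(nodes, values)

    def to_json(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        doc = {int(n): [None if not np.isfinite(v) else float(v) for v in row]
               for n, row in zip(self.nodes, self.values)}
        path.write_text(json.dumps(doc, indent=1))
        return path

    @classmethod
    def from_json(cls, path) -> "DirichletBC":
        doc = json.loads(Path(path).read_text())
        d = {int(k): [np.nan if v is None else v for v in row] for k, row in doc.items()}
        return cls.from_dict(d)


@dataclass
class ForwardSolution:
    """Nodal displacements (mm) plus solver diagnostics."""

    displacements: np.ndarray
    residual_norm: float
    n_free: int
    condition_estimate: float


def _dmatrix(nu: float, dim: int) -> np.ndarray:
    """Isotropic constitutive matrix for E = 1: plane stress (2D) / full 3D."""
    if dim == 2:
        return (1.0 / (1 - nu**2)) * np.array(
            [[1, nu, 0], [nu, 1, 0], [0, 0, (1 - nu) / 2]], dtype=float
        )
    lam = nu / ((1 + nu) * (1 - 2 * nu))
    mu = 1.0 / (2 * (1 + nu))
    D = np.zeros((6, 6))
    D[:3, :3] = lam
    D[np.arange(3), np.arange(3)] += 2 * mu
    D[3:, 3:] = np.eye(3) * mu
    return D


def _bmatrix(dNdx: np.ndarray) -> np.ndarray:
    """Strain-displacement matrices from spatial gradients (nel, nn, dim)."""
    nel, nn, dim = dNdx.shape
    if dim == 2:
        B = np.zeros((nel, 3, 2 * nn))
        B[:, 0, 0::2] = dNdx[:, :, 0]
        B[:, 1, 1::2] = dNdx[:, :, 1]
        B[:, 2, 0::2] = dNdx[:, :, 1]
        B[:, 2, 1::2] = dNdx[:, :, 0]
    else:
        B = np.zeros((nel, 6, 3 * nn))
        B[:, 0, 0::3] = dNdx[:, :, 0]
        B[:, 1, 1::3] = dNdx[:, :, 1]
        B[:, 2, 2::3] = dNdx[:, :, 2]
        B[:, 3, 0::3] = dNdx[:, :, 1]
        B[:, 3, 1::3] = dNdx[:, :, 0]
        B[:, 4, 1::3] = dNdx[:, :, 2]
        B[:, 4, 2::3] = dNdx[:, :, 1]
        B[:, 5, 0::3] = dNdx[:, :, 2]
        B[:, 5, 2::3] = dNdx[:, :, 0]
    return B


def element_stiffness_matrices(
    mesh: FEMesh, nu: float, thickness: float = 1.0, sri: bool = False
) -> np.ndarray:
    """Unit-modulus (E = 1) element stiffness matrices, shape (nel, ndof_e, ndof_e).

    Gauss quadrature exact for each family; with ``sri=True`` (quad4/hex8
    only) the volumetric part of the constitutive law is integrated at the
    element center to relax locking near incompressibility.

    Raises
    ------
    SolverError
        If any element has a non-positive Jacobian (inverted/degenerate).
    """
    fam = FAMILIES[mesh.family]
    dim = fam.dim
    coords = mesh.nodes[mesh.elements]
    D = _dmatrix(nu, dim)
    if sri and fam.reduced_pt is not None:
        m = np.zeros(D.shape[0])
        m[:dim] = 1.0
        # volumetric projector: D_vol = (m D m / (m.m)^2) * m m^T
        kvol = float(m @ D @ m) / dim**2
        D_vol = kvol * np.outer(m, m)
        D_dev = D - D_vol
    else:
        D_vol = None
        D_dev = D
    ndofe = fam.nnodes * dim
    Ke = np.zeros((mesh.n_elements, ndofe, ndofe))
    _, dNs = shape_all_gauss(fam)
    for w, dNxi in zip(fam.gauss_wts, dNs):
        J = np.einsum("ni,enj->eij", dNxi, coords)
        detJ = np.linalg.det(J)
        if np.any(detJ <= 0):
            bad = int(np.argmax(detJ <= 0))
            raise SolverError(f"element {bad} has non-positive Jacobian (det={detJ[bad]:.3g})")
        dNdx = np.linalg.solve(J[:, None, :, :], dNxi[None, :, :, None])[..., 0]
        B = _bmatrix(dNdx)
        Ke += (w * detJ)[:, None, None] * np.einsum("eki,kl,elj->eij", B, D_dev, B)
    if D_vol is not None:
        w_total = fam.gauss_wts.sum()
        dNxi = fam.shape_fn(fam.reduced_pt)[1]
        J = np.einsum("ni,enj->eij", dNxi, coords)
        detJ = np.linalg.det(J)
        dNdx = np.linalg.solve(J[:, None, :, :], dNxi[None, :, :, None])[..., 0]
        B = _bmatrix(dNdx)
        Ke += (w_total * detJ)[:, None, None] * np.einsum("eki,kl,elj->eij", B, D_vol, B)
    if dim == 2:
        Ke *= thickness
    # enforce exact symmetry
    return 0.5 * (Ke + Ke.transpose(0, 2, 1))


def element_stiffness(mesh: FEMesh, material: MaterialField, index: int,
                      thickness: float = 1.0, sri: bool = False) -> np.ndarray:
    """Stiffness matrix of one element with its SIMP-scaled modulus."""
    sub = FEMesh(mesh.nodes, mesh.elements[index:index + 1], mesh.family,
                 boundary_nodes=mesh.boundary_nodes)
    Ke0 = element_stiffness_matrices(sub, material.nu, thickness, sri)[0]
    return material.youngs()[index] * Ke0


class CachedSolver:
    """Assembly/factorization cache for repeated solves on one mesh + BC pattern.

    Precomputes unit-modulus element matrices and the sparse index structure
    of the condensed free-free and free-prescribed blocks, so that each new
    density vector only requires a data-array rescale and one LU
    factorization.
    """

    def __init__(self, mesh: FEMesh, nu: float, prescribed: np.ndarray,
                 thickness: float = 1.0, sri: bool = False):
        fam = FAMILIES[mesh.family]
        dim = fam.dim
        self.mesh = mesh
        self.dim = dim
        self.Ke0 = element_stiffness_matrices(mesh, nu, thickness, sri)
        conn = mesh.elements
        edof = (conn[:, :, None] * dim + np.arange(dim)[None, None, :]).reshape(
            mesh.n_elements, -1
        )
        self.edof = edof
        ndofe = edof.shape[1]
        rows = np.repeat(edof, ndofe, axis=1).ravel()
        cols = np.tile(edof, (1, ndofe)).ravel()
        self.entry_element = np.repeat(np.arange(mesh.n_elements), ndofe * ndofe)
        prescribed = np.asarray(prescribed, dtype=bool)
        if not prescribed.any():
            raise SolverError("no prescribed DOFs: system is singular (rigid modes)")
        self.prescribed = prescribed
        self.free = ~prescribed
        self.n_free = int(self.free.sum())
        new_index = -np.ones(len(prescribed), dtype=np.int64)
        new_index[self.free] = np.arange(self.n_free)
        presc_index = -np.ones(len(prescribed), dtype=np.int64)
        presc_index[prescribed] = np.arange(int(prescribed.sum()))
        rf, cf = self.free[rows], self.free[cols]
        self._ff = np.nonzero(rf & cf)[0]
        self._fp = np.nonzero(rf & ~cf)[0]
        self._ff_rc = (new_index[rows[self._ff]], new_index[cols[self._ff]])
        self._fp_rc = (new_index[rows[self._fp]], presc_index[cols[self._fp]])
        self.n_presc = int(prescribed.sum())

    def _data(self, E: np.ndarray) -> np.ndarray:
        return (E[:, None, None] * self.Ke0).ravel()

    def factorize(self, E: np.ndarray):
        data = self._data(E)
        Kff = sp.csc_matrix(
            (data[self._ff], self._ff_rc), shape=(self.n_free, self.n_free)
        )
        Kfp = sp.csc_matrix(
            (data[self._fp], self._fp_rc), shape=(self.n_free, self.n_presc)
        )
        try:
            lu = splu(Kff)
        except RuntimeError as e:  # pragma: no cover - singular systems
            raise SolverError(f"free-DOF system could not be factorized: {e}") from e
        return lu, Kff, Kfp

    def solve(self, E: np.ndarray, presc_values: np.ndarray):
        """Solve for the full DOF vector; returns (u_flat, lu, diagnostics)."""
        lu, Kff, Kfp = self.factorize(E)
        up = presc_values[self.prescribed]
        rhs = -Kfp @ up
        uf = lu.solve(rhs)
        resid = float(np.linalg.norm(Kff @ uf - rhs))
        u = np.empty(len(self.prescribed))
        u[self.free] = uf
        u[self.prescribed] = up
        d = Kff.diagonal()
        cond = float(d.max() / max(d.min(), 1e-300))
        return u, lu, {"residual_norm": resid, "condition_estimate": cond}


def solve_forward(
    mesh: FEMesh,
    material: MaterialField,
    bc: DirichletBC,
    thickness: float = 1.0,
    sri: bool = False,
    solver: CachedSolver | None = None,
) -> ForwardSolution:
    """Solve the Dirichlet problem; prescribed DOFs are reproduced exactly."""
    if len(material.rho) != mesh.n_elements:
        raise ValueError("material has wrong number of elements")
    prescribed, vals = bc.dof_arrays(mesh.n_nodes)
    if solver is None:
        solver = CachedSolver(mesh, material.nu, prescribed, thickness, sri)
    u, _, diag = solver.solve(material.youngs(), vals)
    return ForwardSolution(
        displacements=u.reshape(mesh.n_nodes, mesh.dimension),
        residual_norm=diag["residual_norm"],
        n_free=solver.n_free,
        condition_estimate=diag["condition_estimate"],
    )


def indentation_protocol(
    mesh: FEMesh,
    depth_fraction: float,
    indenter_width: float | None = None,
    axis: int | None = None,
) -> DirichletBC:
    """Indentation loading preset used to generate phantom displacements.

    The bottom face (minimum coordinate along the loading axis) is fully
    constrained; the top face — or the indenter-contact subset of it when
    ``indenter_width`` is given — is displaced ``depth_fraction *
    thickness`` downward with zero lateral motion (stick contact).  Lateral
    boundary nodes are left free.  The inversion variant instead prescribes
    measured displacements on all boundary nodes (see
    :func:`fdelast.inverse.bc_from_measured`).
    """
    if not (0 <= depth_fraction < 0.5):
        raise ValueError("depth_fraction must be in [0, 0.5)")
    dim = mesh.dimension
    if axis is None:
        axis = dim - 1
    coord = mesh.nodes[:, axis]
    lo, hi = coord.min(), coord.max()
    thickness = hi - lo
    tol = 1e-6 * max(thickness, 1.0)
    bottom = np.nonzero(coord <= lo + tol)[0]
    top = np.nonzero(coord >= hi - tol)[0]
    if indenter_width is not None:
        lateral = [a for a in range(dim) if a != axis]
        center = mesh.nodes[:, lateral].mean(axis=0)
        r = np.linalg.norm(mesh.nodes[np.ix_(top, lateral)] - center, axis=1)
        top = top[r <= indenter_width / 2 + tol]
    nodes = np.concatenate([bottom, top])
    values = np.zeros((len(nodes), dim))
    values[len(bottom):, axis] = -depth_fraction * thickness
    return DirichletBC(nodes, values)
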