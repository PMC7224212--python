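"""Finite-element meshes from pixel/voxel masks and grid<->mesh transfer.

Rectangular (all-true) masks become structured quadrilateral/hexahedral
meshes; irregular masks are meshed by Delaunay triangulation of the masked
pixel centers with degenerate/outside simplices culled.  Boundary nodes are
the nodes on facets owned by exactly one element.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .elements import FAMILIES, edge_lengths, element_measures
from .fields import DisplacementField


class MeshError(ValueError):
    pass


@dataclass
class FEMesh:
    """Unstructured finite-element mesh.

    nodes : (nn, dim) physical coordinates in mm
    elements : (nel, k) connectivity (family-dependent node count)
    family : one of 'tri3', 'quad4', 'quad8', 'tet4', 'hex8'
    """

    nodes: np.ndarray
    elements: np.ndarray
    family: str
    boundary_nodes: np.ndarray = None

    def __post_init__(self):
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.elements = np.asarray(self.elements, dtype=np.int64)
        fam = FAMILIES[self.family]
        if self.nodes.shape[1] != fam.dim:
            raise MeshError("node dimension does not match family")
        if self.elements.shape[1] != fam.nnodes:
            raise MeshError("connectivity width does not match family")
        if self.elements.min(initial=0) < 0 or self.elements.max(initial=-1) >= len(self.nodes):
            raise MeshError("connectivity indices out of range")
        if self.boundary_nodes is None:
            self.boundary_nodes = self._find_boundary_nodes()
        self.boundary_nodes = np.asarray(self.boundary_nodes, dtype=np.int64)
        self._cache = {}

    # -- derived geometry ---------------------------------------------------
    @property
    def dimension(self) -> int:
        return self.nodes.shape[1]

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    @property
    def centroids(self) -> np.ndarray:
        if "centroids" not in self._cache:
            self._cache["centroids"] = self.nodes[self.elements].mean(axis=1)
        return self._cache["centroids"]

    @property
    def measures(self) -> np.ndarray:
        """Element areas (2D) / volumes (3D)."""
        if "measures" not in self._cache:
            self._cache["measures"] = element_measures(self.nodes, self.elements, self.family)
        return self._cache["measures"]

    @property
    def typical_edge(self) -> float:
        if "edge" not in self._cache:
            self._cache["edge"] = float(
                np.median(edge_lengths(self.nodes, self.elements, self.family))
            )
        return self._cache["edge"]

    def facet_counts(self):
        """(facet key -> number of owning elements); keys are sorted node tuples."""
        fam = FAMILIES[self.family]
        counts: dict[tuple, int] = {}
        for f in fam.facets:
            for row in self.elements[:, list(f)]:
                key = tuple(sorted(row.tolist()))
                counts[key] = counts.get(key, 0) + 1
        return counts

    def _find_boundary_nodes(self) -> np.ndarray:
        nodes = set()
        for key, c in self.facet_counts().items():
            if c == 1:
                nodes.update(key)
        return np.array(sorted(nodes), dtype=np.int64)

    @property
    def interior_nodes(self) -> np.ndarray:
        mask = np.ones(self.n_nodes, dtype=bool)
        mask[self.boundary_nodes] = False
        return np.nonzero(mask)[0]


@dataclass
class GridMeshMap:
    """Interpolation maps between the imaging grid and a mesh.

    forward: per-node multilinear stencil over pixel centers (flat pixel
    indices + weights summing to 1) with a flag for nodes whose stencil
    touches unmasked pixels; inverse: per masked pixel, the containing
    element and the shape-function weights of its nodes at the pixel center.
    """

    grid_shape: tuple[int, ...]
    stencil_idx: np.ndarray      # (nn, 2**dim) flat pixel indices
    stencil_w: np.ndarray        # (nn, 2**dim) weights, rows sum to 1
    node_outside: np.ndarray     # (nn,) bool: stencil touches unmasked pixels
    pixel_element: np.ndarray    # flat (npix,) element index or -1
    pixel_shape_w: np.ndarray    # (npix, nnodes_per_elem) shape values


# ---------------------------------------------------------------------------
# mesh construction


def _structured_mesh(origin, extent, n_el, family: str) -> FEMesh:
    dim = len(n_el)
    axes = [origin[a] + np.linspace(0.0, extent[a], n_el[a] + 1) for a in range(dim)]
    grids = np.meshgrid(*axes, indexing="ij")
    nodes = np.stack([g.ravel() for g in grids], axis=1)
    nshape = tuple(n + 1 for n in n_el)

    def nid(*idx):
        return np.ravel_multi_index(idx, nshape)

    if dim == 2:
        nx, ny = n_el
        i, j = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
        i, j = i.ravel(), j.ravel()
        quad = np.stack([nid(i, j), nid(i + 1, j), nid(i + 1, j + 1), nid(i, j + 1)], axis=1)
        if family == "quad4":
            return FEMesh(nodes, quad, "quad4")
        if family == "quad8":
            # append mid-edge nodes: horizontal (along x) then vertical edges
            hx = np.stack(
                np.meshgrid(
                    origin[0] + (np.arange(nx) + 0.5) * extent[0] / nx,
                    axes[1], indexing="ij",
                ), axis=-1,
            ).reshape(-1, 2)
            vy = np.stack(
                np.meshgrid(
                    axes[0],
                    origin[1] + (np.arange(ny) + 0.5) * extent[1] / ny,
                    indexing="ij",
                ), axis=-1,
            ).reshape(-1, 2)
            nh0 = len(nodes)
            nv0 = nh0 + len(hx)
            allnodes = np.vstack([nodes, hx, vy])

            def hid(i_, j_):  # mid node of edge ((i,j)-(i+1,j)), j in 0..ny
                return nh0 + np.ravel_multi_index((i_, j_), (nx, ny + 1))

            def vid(i_, j_):  # mid node of edge ((i,j)-(i,j+1)), i in 0..nx
                return nv0 + np.ravel_multi_index((i_, j_), (nx + 1, ny))

            conn = np.stack(
                [
                    nid(i, j), nid(i + 1, j), nid(i + 1, j + 1), nid(i, j + 1),
                    hid(i, j), vid(i + 1, j), hid(i, j + 1), vid(i, j),
                ],
                axis=1,
            )
            return FEMesh(allnodes, conn, "quad8")
        raise MeshError(f"family {family!r} unsupported for structured 2D meshes")
    else:
        nx, ny, nz = n_el
        if family != "hex8":
            raise MeshError(f"family {family!r} unsupported for structured 3D meshes")
        i, j, k = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
        i, j, k = i.ravel(), j.ravel(), k.ravel()
        conn = np.stack(
            [
                nid(i, j, k), nid(i + 1, j, k), nid(i + 1, j + 1, k), nid(i, j + 1, k),
                nid(i, j, k + 1), nid(i + 1, j, k + 1), nid(i + 1, j + 1, k + 1),
                nid(i, j + 1, k + 1),
            ],
            axis=1,
        )
        return FEMesh(nodes, conn, "hex8")


def _cull_and_build(nodes, elems, mask, spacing, origin, pitch, family, min_feature_mm):
    """Orient, apply the minimum-feature/degeneracy/outside-mask culls, reindex."""
    meas = element_measures(nodes, elems, family)
    neg = meas < 0
    if np.any(neg):
        elems[neg, 0], elems[neg, 1] = elems[neg, 1].copy(), elems[neg, 0].copy()
        meas = np.abs(meas)
    keep = np.ones(len(elems), dtype=bool)
    med = np.median(meas[meas > 0]) if np.any(meas > 0) else 1.0
    keep &= meas > 1e-9 * med
    # minimum-feature edge rule, capped below the point pitch so regular
    # grids finer than the threshold are untouched
    thr = min(min_feature_mm, 0.9 * pitch)
    keep &= edge_lengths(nodes, elems, family) >= thr
    cent = nodes[elems].mean(axis=1)
    idx = np.round((cent - np.asarray(origin)) / np.asarray(spacing)).astype(int)
    inb = np.all((idx >= 0) & (idx < np.array(mask.shape)), axis=1)
    inmask = np.zeros(len(elems), dtype=bool)
    inmask[inb] = mask[tuple(idx[inb].T)]
    keep &= inmask
    elems = elems[keep]
    if len(elems) == 0:
        raise MeshError("all simplices culled; mask too small or thin for meshing")
    used = np.unique(elems)
    remap = -np.ones(len(nodes), dtype=np.int64)
    remap[used] = np.arange(len(used))
    return FEMesh(nodes[used], remap[elems], family)


# Kuhn (main-diagonal) decomposition of the unit cube into six tetrahedra;
# conforming across neighbouring cells when every cell uses the same diagonal.
_CUBE_TETS = [(0, 1, 2, 6), (0, 2, 3, 6), (0, 3, 7, 6),
              (0, 7, 4, 6), (0, 4, 5, 6), (0, 5, 1, 6)]


def _lattice_simplex_mesh(mask, spacing, origin, pitch, family, min_feature_mm):
    """Simplicial mesh of the masked pixel lattice.

    Pixel centers are the nodes; every grid cell whose corners are all
    masked is split into two triangles (2D) or six tetrahedra (3D) along a
    fixed diagonal — a Delaunay triangulation of the lattice points that,
    unlike a generic Delaunay of the (degenerate, cospherical) grid, is
    conforming and free of sliver simplices.
    """
    dim = mask.ndim
    step = max(1, int(round(pitch / float(np.min(spacing)))))
    sub = mask[tuple(slice(None, None, step) for _ in range(dim))]
    nshape = sub.shape
    spacing_s = np.asarray(spacing, dtype=float) * step
    pts = np.stack(np.nonzero(np.ones(nshape, dtype=bool)), axis=1) * spacing_s + origin
    nid = np.arange(int(np.prod(nshape))).reshape(nshape)
    if dim == 2:
        cells = sub[:-1, :-1] & sub[1:, :-1] & sub[1:, 1:] & sub[:-1, 1:]
        i, j = np.nonzero(cells)
        c = [nid[i, j], nid[i + 1, j], nid[i + 1, j + 1], nid[i, j + 1]]
        elems = np.concatenate([
            np.stack([c[0], c[1], c[2]], axis=1),
            np.stack([c[0], c[2], c[3]], axis=1),
        ])
    else:
        cells = (sub[:-1, :-1, :-1] & sub[1:, :-1, :-1] & sub[1:, 1:, :-1]
                 & sub[:-1, 1:, :-1] & sub[:-1, :-1, 1:] & sub[1:, :-1, 1:]
                 & sub[1:, 1:, 1:] & sub[:-1, 1:, 1:])
        i, j, k = np.nonzero(cells)
        v = [nid[i, j, k], nid[i + 1, j, k], nid[i + 1, j + 1, k], nid[i, j + 1, k],
             nid[i, j, k + 1], nid[i + 1, j, k + 1], nid[i + 1, j + 1, k + 1],
             nid[i, j + 1, k + 1]]
        elems = np.concatenate([
            np.stack([v[a], v[b], v[c_], v[d]], axis=1) for a, b, c_, d in _CUBE_TETS
        ])
    if len(elems) == 0:
        raise MeshError("mask contains no complete lattice cell to mesh")
    return _cull_and_build(pts, elems, mask, spacing, origin, pitch, family,
                           min_feature_mm)


def _lattice_cell_mesh(mask, spacing, origin, pitch, family, min_feature_mm):
    """Pixel-aligned quadrilateral/hexahedral mesh of an irregular mask:
    one element per grid cell whose corners are all masked."""
    dim = mask.ndim
    step = max(1, int(round(pitch / float(np.min(spacing)))))
    sub = mask[tuple(slice(None, None, step) for _ in range(dim))]
    nshape = sub.shape
    spacing_s = np.asarray(spacing, dtype=float) * step
    pts = np.stack(np.nonzero(np.ones(nshape, dtype=bool)), axis=1) * spacing_s + origin
    nid = np.arange(int(np.prod(nshape))).reshape(nshape)
    if dim == 2:
        cells = sub[:-1, :-1] & sub[1:, :-1] & sub[1:, 1:] & sub[:-1, 1:]
        i, j = np.nonzero(cells)
        elems = np.stack([nid[i, j], nid[i + 1, j], nid[i + 1, j + 1], nid[i, j + 1]],
                         axis=1)
    else:
        cells = (sub[:-1, :-1, :-1] & sub[1:, :-1, :-1] & sub[1:, 1:, :-1]
                 & sub[:-1, 1:, :-1] & sub[:-1, :-1, 1:] & sub[1:, :-1, 1:]
                 & sub[1:, 1:, 1:] & sub[:-1, 1:, 1:])
        i, j, k = np.nonzero(cells)
        elems = np.stack(
            [nid[i, j, k], nid[i + 1, j, k], nid[i + 1, j + 1, k], nid[i, j + 1, k],
             nid[i, j, k + 1], nid[i + 1, j, k + 1], nid[i + 1, j + 1, k + 1],
             nid[i, j + 1, k + 1]], axis=1)
    if len(elems) == 0:
        raise MeshError("mask contains no complete lattice cell to mesh")
    return _cull_and_build(pts, elems, mask, spacing, origin, pitch, family,
                           min_feature_mm)


def mesh_from_mask(
    mask: np.ndarray,
    spacing,
    origin=0.0,
    target_element_size: float | None = None,
    family: str | None = None,
    min_feature_mm: float = 0.5,
) -> FEMesh:
    """Build a mesh whose domain is the masked pixel region.

    Rectangular (all-true) masks give a structured quad4/quad8 (2D) or hex8
    (3D) lattice with ``round(extent / target_element_size)`` elements per
    axis; irregular masks give a tri3/tet4 simplicial mesh connecting the
    masked pixel centers (the fixed-diagonal Delaunay triangulation of the
    lattice).  Simplices with non-positive measure, with an edge shorter
    than the minimum-feature threshold, or centered outside the mask are
    culled.

    Raises
    ------
    MeshError
        Empty or disconnected masks (the error lists component sizes).
    """
    mask = np.asarray(mask, dtype=bool)
    dim = mask.ndim
    spacing_t = np.atleast_1d(np.asarray(spacing, dtype=float))
    if spacing_t.size == 1:
        spacing_t = np.full(dim, spacing_t[0])
    origin_t = np.atleast_1d(np.asarray(origin, dtype=float))
    if origin_t.size == 1:
        origin_t = np.full(dim, origin_t[0])
    if not mask.any():
        raise MeshError("mask is empty")
    labels, n_comp = ndimage.label(mask)
    if n_comp > 1:
        sizes = ndimage.sum_labels(mask, labels, index=range(1, n_comp + 1))
        raise MeshError(
            f"mask has {n_comp} disconnected components (sizes "
            f"{[int(s) for s in sizes]}); mesh one component at a time"
        )
    if target_element_size is None:
        target_element_size = float(spacing_t.max())
    if target_element_size < spacing_t.min() - 1e-12:
        raise MeshError("target_element_size must be >= pixel spacing")

    if mask.all():
        fam = family or ("quad4" if dim == 2 else "hex8")
        extent = (np.array(mask.shape) - 1) * spacing_t
        n_el = np.maximum(1, np.round(extent / target_element_size)).astype(int)
        return _structured_mesh(origin_t, extent, tuple(n_el), fam)

    fam = family or ("tri3" if dim == 2 else "tet4")
    pitch = float(target_element_size)
    if fam in ("quad4", "hex8"):
        return _lattice_cell_mesh(mask, spacing_t, origin_t, pitch, fam, min_feature_mm)
    if fam not in ("tri3", "tet4"):
        raise MeshError(f"irregular masks support tri3/tet4/quad4/hex8, got {fam!r}")
    return _lattice_simplex_mesh(mask, spacing_t, origin_t, pitch, fam, min_feature_mm)


# ---------------------------------------------------------------------------
# grid <-> mesh maps


def _forward_stencil(mesh: FEMesh, shape, spacing, origin, mask):
    dim = mesh.dimension
    spacing = np.asarray(spacing, dtype=float)
    origin = np.asarray(origin, dtype=float)
    f = (mesh.nodes - origin) / spacing
    i0 = np.floor(f).astype(int)
    i0 = np.clip(i0, 0, np.array(shape) - 2)
    frac = np.clip(f - i0, 0.0, 1.0)
    corners = np.stack(np.meshgrid(*([np.array([0, 1])] * dim), indexing="ij"), axis=-1)
    corners = corners.reshape(-1, dim)  # (2**dim, dim)
    idx = i0[:, None, :] + corners[None, :, :]
    w = np.prod(np.where(corners[None, :, :] == 1, frac[:, None, :], 1 - frac[:, None, :]), axis=2)
    flat = np.ravel_multi_index(tuple(idx[..., a] for a in range(dim)), shape)
    touches_unmasked = ~mask.ravel()[flat].all(axis=1)
    return flat, w, touches_unmasked


def _inverse_map(mesh: FEMesh, shape, spacing, origin, mask):
    dim = mesh.dimension
    fam = FAMILIES[mesh.family]
    spacing = np.asarray(spacing, dtype=float)
    origin = np.asarray(origin, dtype=float)
    grids = np.meshgrid(*[origin[a] + spacing[a] * np.arange(shape[a]) for a in range(dim)],
                        indexing="ij")
    pix = np.stack([g.ravel() for g in grids], axis=1)
    npix = len(pix)
    elem_of = -np.ones(npix, dtype=np.int64)
    sw = np.zeros((npix, fam.nnodes))
    masked = mask.ravel()
    if mesh.family in ("tri3", "tet4"):
        tree = cKDTree(mesh.centroids)
        kmax = min(30, mesh.n_elements)
        _, cand = tree.query(pix, k=kmax)
        cand = np.atleast_2d(cand)
        pending = masked.copy()
        X = mesh.nodes[mesh.elements]  # (nel, nn, dim)
        for r in range(kmax):
            if not pending.any():
                break
            rows = np.nonzero(pending)[0]
            e = cand[rows, r]
            x0 = X[e, 0]
            T = np.transpose(X[e, 1:], (0, 2, 1)) - x0[:, :, None]  # (m, dim, dim)
            lam = np.linalg.solve(T, (pix[rows] - x0)[:, :, None])[:, :, 0]
            lam0 = 1.0 - lam.sum(axis=1)
            bc = np.concatenate([lam0[:, None], lam], axis=1)
            ok = np.all(bc >= -1e-9, axis=1)
            good = rows[ok]
            elem_of[good] = e[ok]
            sw[good] = bc[ok]
            pending[good] = False
        if pending.any():
            # snap stragglers (pixels on culled slivers) to the nearest element
            rows = np.nonzero(pending)[0]
            e = cand[rows, 0]
            x0 = X[e, 0]
            T = np.transpose(X[e, 1:], (0, 2, 1)) - x0[:, :, None]
            lam = np.linalg.solve(T, (pix[rows] - x0)[:, :, None])[:, :, 0]
            bc = np.concatenate([(1 - lam.sum(axis=1))[:, None], lam], axis=1)
            bc = np.clip(bc, 0.0, None)
            bc /= bc.sum(axis=1, keepdims=True)
            elem_of[rows] = e
            sw[rows] = bc
    else:
        # axis-aligned quad/hex cells: candidate search over centroids, then
        # the natural coordinate from the element's min/diag corners
        tree = cKDTree(mesh.centroids)
        kmax = min(8, mesh.n_elements)
        _, cand = tree.query(pix, k=kmax)
        cand = np.atleast_2d(cand)
        diag_node = 2 if dim == 2 else 6
        X0 = mesh.nodes[mesh.elements[:, 0]]
        Xd = mesh.nodes[mesh.elements[:, diag_node]]
        pending = masked.copy()
        for r in range(kmax):
            if not pending.any():
                break
            rows = np.nonzero(pending)[0]
            e = cand[rows, r]
            xi = 2.0 * (pix[rows] - X0[e]) / (Xd[e] - X0[e]) - 1.0
            ok = np.all(np.abs(xi) <= 1 + 1e-9, axis=1)
            good = rows[ok]
            for row, ee, x in zip(good, e[ok], xi[ok]):
                sw[row] = fam.shape_fn(np.clip(x, -1, 1))[0]
                elem_of[row] = ee
            pending[good] = False
    elem_of[~masked] = -1
    return elem_of, sw


def grid_mesh_map(mesh: FEMesh, field: DisplacementField) -> GridMeshMap:
    """Build the forward (grid->node) and inverse (pixel->element) maps."""
    flat, w, outside = _forward_stencil(mesh, field.shape, field.spacing, field.origin, field.mask)
    elem_of, sw = _inverse_map(mesh, field.shape, field.spacing, field.origin, field.mask)
    return GridMeshMap(
        grid_shape=field.shape,
        stencil_idx=flat,
        stencil_w=w,
        node_outside=outside,
        pixel_element=elem_of,
        pixel_shape_w=sw,
    )


def interpolate_to_mesh(
    field: DisplacementField, mesh: FEMesh, gmap: GridMeshMap | None = None
):
    """Multilinear interpolation of each displacement component to mesh nodes.

    Nodes whose stencil touches unmasked pixels take the value of the nearest
    masked pixel and are flagged.  Returns ``(values, flagged)`` with
    ``values`` of shape (n_nodes, dim).

    Raises
    ------
    MeshError
        If any node lies farther than one element size from a masked pixel.
    """
    if gmap is None:
        gmap = grid_mesh_map(mesh, field)
    dim = field.dim
    spacing = np.asarray(field.spacing)
    # nearest-masked fill for pixels outside the mask
    if field.mask.all():
        filled = field.components
        nearest_idx = None
    else:
        dist, nearest = ndimage.distance_transform_edt(
            ~field.mask, sampling=field.spacing, return_indices=True
        )
        fill_tuple = tuple(nearest[a] for a in range(dim))
        filled = np.stack([field.components[c][fill_tuple] for c in range(dim)])
        nearest_idx = fill_tuple
    vals = np.stack(
        [
            (filled[c].ravel()[gmap.stencil_idx] * gmap.stencil_w).sum(axis=1)
            for c in range(dim)
        ],
        axis=1,
    )
    flagged = gmap.node_outside.copy()
    if flagged.any() and not field.mask.all():
        # flagged nodes: nearest-masked-pixel value; error if too far
        masked_pts = field.pixel_coords()[field.mask.ravel()]
        tree = cKDTree(masked_pts)
        d, j = tree.query(mesh.nodes[flagged])
        if np.any(d > mesh.typical_edge * (1 + 1e-6) * np.sqrt(mesh.dimension)):
            raise MeshError("mesh node farther than one element size from any masked pixel")
        masked_vals = np.stack(
            [field.components[c][field.mask] for c in range(dim)], axis=1
        )
        vals[flagged] = masked_vals[j]
    return vals, flagged


def sample_nodal_to_grid(
    mesh: FEMesh,
    nodal: np.ndarray,
    field_like: DisplacementField,
    gmap: GridMeshMap | None = None,
) -> np.ndarray:
    """Evaluate nodal data at masked pixel centers via the inverse map.

    ``nodal`` is (nn,) or (nn, m); returns grids of shape (*grid,) or
    (m, *grid) with zeros outside the mask.
    """
    if gmap is None:
        gmap = grid_mesh_map(mesh, field_like)
    nodal = np.asarray(nodal, dtype=float)
    squeeze = nodal.ndim == 1
    if squeeze:
        nodal = nodal[:, None]
    m = nodal.shape[1]
    npix = int(np.prod(gmap.grid_shape))
    out = np.zeros((m, npix))
    sel = gmap.pixel_element >= 0
    conn = mesh.elements[gmap.pixel_element[sel]]  # (ns, nn_e)
    w = gmap.pixel_shape_w[sel]
    for c in range(m):
        out[c, sel] = (nodal[conn, c] * w).sum(axis=1)
    out = out.reshape((m,) + tuple(gmap.grid_shape))
    return out[0] if squeeze else out


def crop_artifact_margin(field: DisplacementField, margin_pixels: int) -> DisplacementField:
    """Erode the mask by ``margin_pixels`` to drop edge-artifact pixels.

    The new mask rim becomes the boundary where measured displacements are
    prescribed during inversion of the partial model.
    """
    if margin_pixels < 0:
        raise ValueError("margin_pixels must be >= 0")
    out = field.copy()
    if margin_pixels == 0:
        return out
    struct = np.ones((3,) * field.mask.ndim, dtype=bool)
    eroded = ndimage.binary_erosion(field.mask, structure=struct, iterations=margin_pixels)
    if not eroded.any():
        raise MeshError("margin erodes the mask to nothing")
    out.mask = eroded
    return out


# ---------------------------------------------------------------------------
# VTK legacy ASCII export/import


def write_vtk(path, mesh: FEMesh, point_data: dict | None = None,
              cell_data: dict | None = None) -> Path:
    """Write the mesh (+ data arrays) as a legacy-ASCII VTK unstructured grid."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fam = FAMILIES[mesh.family]
    pts3 = np.zeros((mesh.n_nodes, 3))
    pts3[:, : mesh.dimension] = mesh.nodes
    lines = [
        "# vtk DataFile Version 3.0",
        "fdelast unstructured grid",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {mesh.n_nodes} double",
    ]
    lines += [" ".join(f"{v:.10g}" for v in p) for p in pts3]
    k = fam.nnodes
    lines.append(f"CELLS {mesh.n_elements} {mesh.n_elements * (k + 1)}")
    lines += [f"{k} " + " ".join(map(str, row)) for row in mesh.elements]
    lines.append(f"CELL_TYPES {mesh.n_elements}")
    lines += [str(fam.vtk_type)] * mesh.n_elements

    def emit(data: dict, count: int, tag: str):
        lines.append(f"{tag} {count}")
        for name, arr in data.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim == 1:
                lines.append(f"SCALARS {name} double 1")
                lines.append("LOOKUP_TABLE default")
                lines.extend(f"{v:.10g}" for v in arr)
            else:
                v3 = np.zeros((len(arr), 3))
                v3[:, : arr.shape[1]] = arr
                lines.append(f"VECTORS {name} double")
                lines.extend(" ".join(f"{x:.10g}" for x in row) for row in v3)

    if point_data:
        emit(point_data, mesh.n_nodes, "POINT_DATA")
    if cell_data:
        emit(cell_data, mesh.n_elements, "CELL_DATA")
    path.write_text("\n".join(lines) + "\n")
    return path


_VTK_FAMILY = {5: "tri3", 9: "quad4", 23: "quad8", 10: "tet4", 12: "hex8"}


def read_vtk(path):
    """Read a legacy-ASCII VTK unstructured grid written by :func:`write_vtk`.

    Returns ``(mesh, point_data, cell_data)``.
    """
    lines = Path(path).read_text().splitlines()
    i = 0

    def seek(prefix):
        nonlocal i
        while not lines[i].startswith(prefix):
            i += 1
        return lines[i]

    nn = int(seek("POINTS").split()[1])
    pts = np.array([[float(x) for x in lines[i + 1 + r].split()] for r in range(nn)])
    i += nn
    nel = int(seek("CELLS").split()[1])
    conn = [list(map(int, lines[i + 1 + r].split()))[1:] for r in range(nel)]
    i += nel
    seek("CELL_TYPES")
    vtk_type = int(lines[i + 1])
    i += nel
    family = _VTK_FAMILY[vtk_type]
    dim = FAMILIES[family].dim
    mesh = FEMesh(pts[:, :dim], np.array(conn), family)

    point_data, cell_data = {}, {}
    count = None
    target = None
    while i < len(lines):
        t = lines[i]
        if t.startswith("POINT_DATA"):
            count, target = nn, point_data
            i += 1
        elif t.startswith("CELL_DATA"):
            count, target = nel, cell_data
            i += 1
        elif t.startswith("SCALARS") and target is not None:
            name = t.split()[1]
            target[name] = np.array(
                [float(lines[i + 2 + r]) for r in range(count)]
            )
            i += 2 + count
        elif t.startswith("VECTORS") and target is not None:
            name = t.split()[1]
            vals = np.array(
                [[float(x) for x in lines[i + 1 + r].split()] for r in range(count)]
            )
            target[name] = vals[:, :dim]
            i += 1 + count
        else:
            i += 1
    return mesh, point_data, cell_data
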