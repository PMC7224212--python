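"""Synthetic validation phantoms: ground-truth stiffness patterns + loading.

Every phantom is defined parametrically (geometry, stiffness pattern,
indentation loading, pixel resolution), rasterized to per-element truth by
element-centroid membership, forward-solved under its loading preset, and
resampled to the imaging grid — optionally with Gaussian displacement noise
at the experimental level.  The stiffest region has true relative density
1 by construction (``rho_true = E / max(E)``).

Named cases (:func:`end_to_end_case`):

``bilayer2d``          6x6 mm square, 1000 Pa top over 500 Pa bottom,
                       0.15 mm elements, 15% indentation (plane stress).
``inclusions2d``       500 Pa background with stiff 1000 and 1500 Pa
                       circular inclusions.
``gradient_fissure2d`` background stiffness ramping 500 -> 1000 Pa bottom to
                       top with a soft (200 Pa) slender fissure-like
                       inclusion reaching the loaded surface.
``cylinder3d``         two-layer cylinder (radius 5 mm, height 6 mm, top
                       third at twice the bottom modulus: 2:1 ratio).
``homogeneous``        uniform 500 Pa null case.

Inclusion positions/sizes are package defaults (documented here); the 2D
cases mirror the dualMRI validation resolution of 150 um.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fem import DirichletBC, MaterialField, indentation_protocol, solve_forward
from .fields import DisplacementField, NoiseSpec, add_noise
from .meshing import FEMesh, GridMeshMap, grid_mesh_map, mesh_from_mask, sample_nodal_to_grid


@dataclass
class Rectangle:
    width: float
    height: float

    def __post_init__(self):
        if self.width <= 0 or self.height <= 0:
            raise ValueError("rectangle dimensions must be positive")


@dataclass
class Cylinder:
    radius: float
    height: float

    def __post_init__(self):
        if self.radius <= 0 or self.height <= 0:
            raise ValueError("cylinder dimensions must be positive")


@dataclass
class Bilayer:
    """Two horizontal layers; ``top_fraction`` of the thickness is the top."""

    E_top: float = 1000.0
    E_bottom: float = 500.0
    top_fraction: float = 0.5

    def __post_init__(self):
        if self.E_top <= 0 or self.E_bottom <= 0:
            raise ValueError("moduli must be positive")
        if not (0 < self.top_fraction < 1):
            raise ValueError("top_fraction must be in (0, 1)")


@dataclass
class Inclusions:
    """Circular (2D) inclusions on a homogeneous background.

    ``circles`` is a list of ``(center, radius, modulus)``.
    """

    E_background: float
    circles: list

    def __post_init__(self):
        if self.E_background <= 0:
            raise ValueError("moduli must be positive")
        for _, r, E in self.circles:
            if E <= 0 or r < 0:
                raise ValueError("inclusion radius must be >= 0 and modulus > 0")


@dataclass
class GradientInclusion:
    """Linear bottom-to-top stiffness ramp with a soft polygonal inclusion."""

    E_low: float
    E_high: float
    polygon: np.ndarray
    E_inclusion: float

    def __post_init__(self):
        if min(self.E_low, self.E_high, self.E_inclusion) <= 0:
            raise ValueError("moduli must be positive")
        self.polygon = np.asarray(self.polygon, dtype=float)


@dataclass
class Homogeneous:
    E: float = 500.0

    def __post_init__(self):
        if self.E <= 0:
            raise ValueError("modulus must be positive")


@dataclass
class PhantomSpec:
    """Parametric ground-truth phantom: geometry, pattern, loading, resolution."""

    geometry: object
    pattern: object
    depth_fraction: float = 0.15
    resolution: float = 0.15
    indenter_width: float | None = None
    nu: float = 0.49

    def __post_init__(self):
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if not (0 <= self.depth_fraction < 0.5):
            raise ValueError("depth_fraction must be in [0, 0.5)")


@dataclass
class PhantomData:
    """Packaged phantom fixture: inputs plus the exact truth and BCs used."""

    spec: PhantomSpec
    mesh: FEMesh
    gmap: GridMeshMap
    truth_rho: np.ndarray
    labels: np.ndarray
    label_names: dict
    bc: DirichletBC
    ideal_field: DisplacementField
    field: DisplacementField
    solution: np.ndarray  # nodal displacements (nn, dim)

    @property
    def truth_normalized(self) -> np.ndarray:
        from .inverse import normalize_relative_stiffness

        return normalize_relative_stiffness(self.truth_rho, self.mesh.measures)

    def write(self, outdir):
        """Write displacements (NIfTI + text), truth VTK, and BC JSON."""
        from pathlib import Path

        from .io import save_displacement_nifti, save_displacement_text
        from .meshing import write_vtk

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        save_displacement_nifti(self.field, outdir / "displacement")
        save_displacement_text(self.field, outdir / "displacement")
        write_vtk(outdir / "truth.vtk", self.mesh,
                  cell_data={"rho_true": self.truth_rho,
                             "label": self.labels.astype(float)})
        self.bc.to_json(outdir / "bc.json")
        return outdir


def _truth_modulus(spec: PhantomSpec, centroids: np.ndarray):
    """Element-centroid modulus (Pa) and region labels for a phantom pattern."""
    pat = spec.pattern
    n = len(centroids)
    axis = centroids.shape[1] - 1
    z = centroids[:, axis]
    lo, hi = z.min(), z.max()
    names: dict[int, str] = {}
    if isinstance(pat, Homogeneous):
        return np.full(n, pat.E), np.zeros(n, dtype=int), {0: "body"}
    if isinstance(pat, Bilayer):
        # layer boundary in absolute phantom coordinates (loading axis runs
        # from 0 to the geometry height), so cropped meshes label correctly
        cut = (1.0 - pat.top_fraction) * _thickness(spec)
        top = z >= cut - 1e-12
        E = np.where(top, pat.E_top, pat.E_bottom)
        labels = top.astype(int)
        return E, labels, {0: "bottom", 1: "top"}
    if isinstance(pat, Inclusions):
        E = np.full(n, pat.E_background)
        labels = np.zeros(n, dtype=int)
        names = {0: "background"}
        for i, (center, r, Einc) in enumerate(pat.circles, start=1):
            if r <= 0:
                names[i] = f"inclusion{i}"
                continue
            d = np.linalg.norm(centroids[:, :2] - np.asarray(center), axis=1)
            inside = d <= r
            E[inside] = Einc
            labels[inside] = i
            names[i] = f"inclusion{i}"
        return E, labels, names
    if isinstance(pat, GradientInclusion):
        from matplotlib.path import Path as MplPath

        span = max(hi - lo, 1e-12)
        E = pat.E_low + (pat.E_high - pat.E_low) * (z - lo) / span
        labels = np.zeros(n, dtype=int)
        inside = MplPath(pat.polygon).contains_points(centroids[:, :2])
        E[inside] = pat.E_inclusion
        labels[inside] = 1
        return E, labels, {0: "background", 1: "inclusion"}
    raise ValueError(f"unknown pattern {type(pat).__name__}")


def _thickness(spec: PhantomSpec) -> float:
    g = spec.geometry
    return g.height


def build_grid_and_mesh(spec: PhantomSpec):
    """Pixel grid (mask, spacing, origin) and mesh with nodes at pixel centers."""
    res = spec.resolution
    g = spec.geometry
    if isinstance(g, Rectangle):
        nx = int(round(g.width / res))
        ny = int(round(g.height / res))
        mask = np.ones((nx + 1, ny + 1), dtype=bool)
        origin = (0.0, 0.0)
        mesh = mesh_from_mask(mask, res, origin, target_element_size=res)
    elif isinstance(g, Cylinder):
        nr = int(round(2 * g.radius / res))
        nz = int(round(g.height / res))
        origin = (-g.radius, -g.radius, 0.0)
        ax = origin[0] + res * np.arange(nr + 1)
        X, Y = np.meshgrid(ax, ax, indexing="ij")
        disk = X**2 + Y**2 <= g.radius**2 + 1e-9
        mask = np.repeat(disk[:, :, None], nz + 1, axis=2)
        # brick elements: markedly better conditioned near incompressibility
        # than linear tets (which lock at nu=0.49 and blur identifiability)
        mesh = mesh_from_mask(mask, res, origin, target_element_size=res,
                              family="hex8")
    else:
        raise ValueError(f"unknown geometry {type(g).__name__}")
    return mask, res, origin, mesh


def rasterize_truth(spec: PhantomSpec, mesh: FEMesh | None = None):
    """Element-wise true relative density (``E / max(E)``) and region labels."""
    if mesh is None:
        mesh = build_grid_and_mesh(spec)[3]
    E, labels, names = _truth_modulus(spec, mesh.centroids)
    return E / E.max(), labels, names


def generate_displacements(spec: PhantomSpec, noise: NoiseSpec | None = None
                           ) -> PhantomData:
    """Forward-solve the phantom under its indentation preset and package the
    displacement field (plus truth, labels, BCs and the grid/mesh maps).

    The generation preset fixes the bottom face, indents the top face by
    ``depth_fraction`` of the thickness, and leaves lateral boundaries free;
    generated fields therefore satisfy the prescribed BCs exactly at
    boundary pixels.  Noise (if any) is added per ``NoiseSpec`` — boundary
    pixels included by default, matching the experimental condition.
    """
    mask, res, origin, mesh = build_grid_and_mesh(spec)
    E, labels, names = _truth_modulus(spec, mesh.centroids)
    rho_true = E / E.max()
    material = MaterialField(rho=rho_true, rho_min=min(0.01, rho_true.min() / 2),
                             E0=float(E.max()), nu=spec.nu)
    bc = indentation_protocol(mesh, spec.depth_fraction, spec.indenter_width)
    sol = solve_forward(mesh, material, bc)
    template = DisplacementField(
        components=np.zeros((mesh.dimension,) + mask.shape),
        spacing=res, origin=origin, mask=mask,
    )
    gmap = grid_mesh_map(mesh, template)
    comps = sample_nodal_to_grid(mesh, sol.displacements, template, gmap)
    ideal = DisplacementField(components=comps, spacing=res, origin=origin, mask=mask)
    noisy = add_noise(ideal, noise) if noise is not None and noise.sigma > 0 else ideal
    return PhantomData(
        spec=spec, mesh=mesh, gmap=gmap, truth_rho=rho_true, labels=labels,
        label_names=names, bc=bc, ideal_field=ideal, field=noisy,
        solution=sol.displacements,
    )


_CASES = ("bilayer2d", "inclusions2d", "gradient_fissure2d", "cylinder3d",
          "homogeneous")


def end_to_end_case(
    name: str,
    resolution: float | None = None,
    noise_sigma: float = 0.0,
    seed: int = 7,
) -> PhantomData:
    """Deterministic packaged fixture for a named validation case.

    ``resolution`` overrides the default pixel/element size (0.15 mm for the
    2D cases, 0.6 mm for the 3D cylinder).  ``noise_sigma`` is in mm; the
    same spec + seed always reproduces the bundle bit-for-bit.
    """
    if name == "bilayer2d":
        spec = PhantomSpec(Rectangle(6.0, 6.0), Bilayer(1000.0, 500.0, 0.5),
                           resolution=resolution or 0.15)
    elif name == "inclusions2d":
        spec = PhantomSpec(
            Rectangle(6.0, 6.0),
            Inclusions(500.0, [((1.8, 4.2), 0.8, 1000.0),
                               ((4.2, 2.1), 0.8, 1500.0)]),
            resolution=resolution or 0.15,
        )
    elif name == "gradient_fissure2d":
        polygon = np.array([[2.8, 3.0], [3.2, 3.0], [3.2, 6.0], [2.8, 6.0]])
        spec = PhantomSpec(
            Rectangle(6.0, 6.0),
            GradientInclusion(500.0, 1000.0, polygon, 200.0),
            resolution=resolution or 0.15,
        )
    elif name == "cylinder3d":
        spec = PhantomSpec(Cylinder(5.0, 6.0), Bilayer(1000.0, 500.0, 1.0 / 3.0),
                           resolution=resolution or 0.6)
    elif name == "homogeneous":
        spec = PhantomSpec(Rectangle(6.0, 6.0), Homogeneous(500.0),
                           resolution=resolution or 0.15)
    else:
        raise ValueError(f"unknown case {name!r}; choose from {_CASES}")
    noise = NoiseSpec(noise_sigma, seed=seed) if noise_sigma > 0 else None
    return generate_displacements(spec, noise)
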