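"""Displacement and phase fields on regular pixel/voxel grids.

Containers and pre-processing for displacement-encoded (DENSE) MRI data:
conversion of phase maps to displacements, phase unwrapping, robust LOWESS
and mask-normalized Gaussian smoothing, and Gaussian noise injection.

Conventions
-----------
Grids are indexed ``[i, j(, k)]`` where index ``i`` runs along the x axis,
``j`` along y and ``k`` along z; the physical coordinate of pixel
``(0, 0[, 0])`` is ``origin`` and pixel centers sit at
``origin + index * spacing``.  All displacements are carried in millimetres;
phase is in radians.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage


class InvalidEncodingError(ValueError):
    """Requested displacement decoding on an axis with no net encoding gradient."""


def _as_tuple(x, dim: int) -> tuple[float, ...]:
    arr = np.atleast_1d(np.asarray(x, dtype=float))
    if arr.size == 1:
        arr = np.full(dim, float(arr[0]))
    if arr.size != dim:
        raise ValueError(f"expected {dim} values, got {arr.size}")
    return tuple(float(v) for v in arr)


def _check_grid(name: str, arr: np.ndarray, shape: tuple[int, ...]) -> None:
    if arr.shape != shape:
        raise ValueError(f"{name} has shape {arr.shape}, expected {shape}")


@dataclass
class DisplacementField:
    """Vector displacement field (mm) on a regular grid with a tissue mask.

    Parameters
    ----------
    components : ndarray, shape (dim, \\*grid)
        Per-axis displacement grids in mm; ``components[0]`` is the
        x-displacement.
    spacing : float or sequence of float
        Pixel size per axis in mm (strictly positive).
    origin : float or sequence of float, optional
        Physical coordinate of pixel (0, 0[, 0]) in mm.  Default 0.
    mask : bool ndarray, optional
        Tissue mask; default all-true.
    weights : ndarray, optional
        Non-negative per-pixel weights used to down-vote unreliable nodes in
        the inverse objective.  Default 1 everywhere.
    uncertainty : ndarray, optional
        Per-component, per-pixel 1-sigma-level uncertainty of the stored
        values in mm (set by the smoothers); consumed by the inverse module
        to weight nodes and to set its discrepancy stopping floor.
    """

    components: np.ndarray
    spacing: tuple[float, ...]
    origin: tuple[float, ...] = None
    mask: np.ndarray = None
    weights: np.ndarray = None
    uncertainty: np.ndarray = None

    def __post_init__(self):
        self.components = np.asarray(self.components, dtype=float)
        if self.components.ndim not in (3, 4):
            raise ValueError("components must have shape (dim, *grid) with a 2D or 3D grid")
        dim = self.components.shape[0]
        shape = self.components.shape[1:]
        if dim != len(shape):
            raise ValueError(
                f"{dim} components for a {len(shape)}-dimensional grid; expected {len(shape)}"
            )
        self.spacing = _as_tuple(self.spacing, dim)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")
        self.origin = _as_tuple(0.0 if self.origin is None else self.origin, dim)
        if self.mask is None:
            self.mask = np.ones(shape, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        _check_grid("mask", self.mask, shape)
        if self.weights is None:
            self.weights = np.ones(shape, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        _check_grid("weights", self.weights, shape)
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")
        if not np.all(np.isfinite(self.components[:, self.mask])):
            raise ValueError("components must be finite inside the mask")
        if self.uncertainty is not None:
            self.uncertainty = np.asarray(self.uncertainty, dtype=float)
            _check_grid("uncertainty", self.uncertainty, self.components.shape)
            if np.any(self.uncertainty[:, self.mask] < 0):
                raise ValueError("uncertainty must be non-negative")

    @property
    def dim(self) -> int:
        return self.components.shape[0]

    @property
    def shape(self) -> tuple[int, ...]:
        return self.components.shape[1:]

    def axis_coords(self) -> list[np.ndarray]:
        """Physical center coordinate of each pixel along each axis (mm)."""
        return [
            self.origin[a] + self.spacing[a] * np.arange(n)
            for a, n in enumerate(self.shape)
        ]

    def pixel_coords(self) -> np.ndarray:
        """Physical coordinates of all pixel centers, shape (npix, dim)."""
        grids = np.meshgrid(*self.axis_coords(), indexing="ij")
        return np.stack([g.ravel() for g in grids], axis=1)

    def copy(self) -> "DisplacementField":
        return replace(
            self,
            components=self.components.copy(),
            mask=self.mask.copy(),
            weights=self.weights.copy(),
            uncertainty=None if self.uncertainty is None else self.uncertainty.copy(),
        )


@dataclass
class PhaseField:
    """Scalar phase map (radians), possibly wrapped to (-pi, pi]."""

    phase: np.ndarray
    spacing: tuple[float, ...]
    origin: tuple[float, ...] = None
    mask: np.ndarray = None

    def __post_init__(self):
        self.phase = np.asarray(self.phase, dtype=float)
        dim = self.phase.ndim
        if dim not in (2, 3):
            raise ValueError("phase grid must be 2D or 3D")
        self.spacing = _as_tuple(self.spacing, dim)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")
        self.origin = _as_tuple(0.0 if self.origin is None else self.origin, dim)
        if self.mask is None:
            self.mask = np.ones(self.phase.shape, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        _check_grid("mask", self.mask, self.phase.shape)
        if not np.all(np.isfinite(self.phase[self.mask])):
            raise ValueError("phase must be finite inside the mask")

    @property
    def dim(self) -> int:
        return self.phase.ndim


@dataclass
class PhaseEncodingSpec:
    """Displacement-encoding parameters of the DENSE phase contrast.

    Phase accumulates as ``dphi = gamma * t_enc * (G_de - G_ref) * dx`` per
    encoded axis, with everything in SI; decoded displacements are returned
    in mm.

    Parameters
    ----------
    gyromagnetic_ratio : float
        gamma_H in rad s^-1 T^-1 (proton: 2.675e8).
    encoding_duration : float
        t_enc in seconds.
    encoding_gradient, reference_gradient : sequence of float
        G_de and G'_de per axis in T m^-1; the reference gradient removes
        phase contributions common to both acquisitions.
    """

    gyromagnetic_ratio: float
    encoding_duration: float
    encoding_gradient: tuple[float, ...]
    reference_gradient: tuple[float, ...]

    def __post_init__(self):
        if self.gyromagnetic_ratio <= 0:
            raise ValueError("gyromagnetic_ratio must be positive")
        if self.encoding_duration <= 0:
            raise ValueError("encoding_duration must be positive")
        self.encoding_gradient = tuple(float(g) for g in np.atleast_1d(self.encoding_gradient))
        self.reference_gradient = tuple(float(g) for g in np.atleast_1d(self.reference_gradient))
        if len(self.encoding_gradient) != len(self.reference_gradient):
            raise ValueError("gradient tuples must have equal length")

    def delta_gradient(self, axis: int) -> float:
        return self.encoding_gradient[axis] - self.reference_gradient[axis]


@dataclass
class NoiseSpec:
    """Additive Gaussian displacement noise model.

    sigma is the per-component standard deviation in mm.  When
    ``apply_to_boundary`` is true (the experimental condition), the one-pixel
    rim of the mask is perturbed as well as the interior.
    """

    sigma: float
    seed: int = 0
    apply_to_boundary: bool = True

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")


# ---------------------------------------------------------------------------
# operations


def decode_displacement(phase: PhaseField, enc: PhaseEncodingSpec, axis: int) -> np.ndarray:
    """Convert an (unwrapped) phase map to one displacement component in mm.

    ``dx = dphi / (gamma_H * t_enc * (G_de - G'_de))`` evaluated per pixel in
    SI units (metres) and converted to mm.

    Raises
    ------
    InvalidEncodingError
        If the net encoding gradient on ``axis`` is zero.
    """
    dg = enc.delta_gradient(axis)
    scale = enc.gyromagnetic_ratio * enc.encoding_duration * dg
    if scale == 0.0 or not np.isfinite(scale):
        raise InvalidEncodingError(f"axis {axis} has zero net encoding gradient")
    return phase.phase / scale * 1e3  # m -> mm


def encode_phase(component_mm: np.ndarray, enc: PhaseEncodingSpec, axis: int) -> np.ndarray:
    """Synthesize the (unwrapped) phase a displacement component would produce."""
    dg = enc.delta_gradient(axis)
    scale = enc.gyromagnetic_ratio * enc.encoding_duration * dg
    if scale == 0.0:
        raise InvalidEncodingError(f"axis {axis} has zero net encoding gradient")
    return np.asarray(component_mm, dtype=float) * 1e-3 * scale


def wrap_phase(phase: np.ndarray) -> np.ndarray:
    """Wrap phase into (-pi, pi]."""
    return np.pi - np.mod(np.pi - np.asarray(phase, dtype=float), 2.0 * np.pi)


def unwrap_phase(phase: PhaseField) -> PhaseField:
    """Unwrap a wrapped phase map over its mask.

    Uses the quality-guided flood-fill unwrapper (2D/3D), then snaps the
    result so the output differs from the input by exact integer multiples
    of 2*pi at every pixel.  Disconnected mask components are unwrapped
    independently (their mutual 2*pi offset is unidentifiable) with a
    warning.
    """
    from skimage.restoration import unwrap_phase as _sk_unwrap

    n_comp = ndimage.label(phase.mask)[1]
    if n_comp > 1:
        warnings.warn(
            f"mask has {n_comp} disconnected components; each is unwrapped "
            "independently (relative 2*pi offsets are unidentifiable)",
            stacklevel=2,
        )
    marr = np.ma.array(phase.phase, mask=~phase.mask)
    out = np.ma.filled(_sk_unwrap(marr), 0.0)
    # enforce exact congruence with the input
    k = np.round((out - phase.phase) / (2.0 * np.pi))
    out = phase.phase + 2.0 * np.pi * k
    out = np.where(phase.mask, out, phase.phase)
    return replace(phase, phase=out)


def _connected_regions(mask: np.ndarray):
    labels, n = ndimage.label(mask, structure=ndimage.generate_binary_structure(mask.ndim, mask.ndim))
    return labels, n


def smooth_lowess(
    field: DisplacementField,
    window_pixels: int = 150,
    robust: bool = True,
    n_robust_iters: int = 3,
    estimate_uncertainty: bool = True,
) -> DisplacementField:
    """Robust LOWESS smoothing of each displacement component.

    At each masked pixel a weighted linear fit over its ``window_pixels``
    nearest masked neighbours (tricube distance weights) gives the smoothed
    value.  With ``robust=True`` the fit is re-weighted ``n_robust_iters``
    times by the bisquare of the residuals ("least absolute residuals"
    behaviour: outliers such as single-pixel spikes are suppressed).  The
    window is the k-nearest-pixel span within each mask-connected region;
    pixels outside the mask never enter a fit.

    With ``estimate_uncertainty`` the returned field carries a per-pixel
    error estimate of the smoothed values: the plug-in curvature bias of the
    local linear fit (difference to a local quadratic refit) plus twice the
    fit's noise standard deviation ``sigma * ||L_i||`` (the smoother is
    linear in the data given its final robust weights; sigma is the robust
    residual SD).  The inverse module uses this map for node weighting and
    its discrepancy stopping rule.
    """
    from scipy.spatial import cKDTree

    if window_pixels < 3:
        raise ValueError("window_pixels must be >= 3")
    out = field.copy()
    unc = np.zeros_like(field.components) if estimate_uncertainty else None
    coords_all = field.pixel_coords().reshape(*field.shape, field.dim)
    labels, n_regions = _connected_regions(field.mask)
    for r in range(1, n_regions + 1):
        sel = labels == r
        n = int(sel.sum())
        k = min(window_pixels, n)
        if k < window_pixels:
            warnings.warn(
                f"LOWESS window {window_pixels} exceeds region size {n}; "
                "shrinking to the region",
                stacklevel=2,
            )
        if n < 3:
            continue
        pts = coords_all[sel]  # (n, dim)
        tree = cKDTree(pts)
        dist, idx = tree.query(pts, k=k)
        dmax = dist[:, -1:].copy()
        dmax[dmax == 0] = 1.0
        w = (1.0 - np.clip(dist / dmax, 0.0, 1.0) ** 3) ** 3  # tricube
        w = np.maximum(w, 1e-12)
        # local design: intercept + centered coordinates
        rel = pts[idx] - pts[:, None, :]  # (n, k, dim)
        X = np.concatenate([np.ones((n, k, 1)), rel], axis=2)  # (n, k, p)
        p = X.shape[2]
        if estimate_uncertainty:
            # quadratic terms for the plug-in bias estimate
            sq = [rel[..., a] * rel[..., b]
                  for a in range(field.dim) for b in range(a, field.dim)]
            X2 = np.concatenate([X, np.stack(sq, axis=2)], axis=2)
            p2 = X2.shape[2]
        for c in range(field.dim):
            y = field.components[c][sel]
            yn = y[idx]  # (n, k)
            delta = np.ones(n)
            n_iter = 1 + (n_robust_iters if robust else 0)
            fit = y.copy()
            W = w
            A = None
            for it in range(n_iter):
                W = w * delta[idx]
                A = np.einsum("nkp,nk,nkq->npq", X, W, X)
                A += 1e-12 * np.eye(p)
                b = np.einsum("nkp,nk,nk->np", X, W, yn)
                beta = np.linalg.solve(A, b[..., None])[..., 0]
                fit = beta[:, 0]  # value at the center pixel
                if it < n_iter - 1:
                    resid = y - fit
                    s = 6.0 * np.median(np.abs(resid))
                    if s <= 0:
                        delta = (resid == 0).astype(float)
                    else:
                        delta = np.clip(1.0 - (resid / s) ** 2, 0.0, None) ** 2
            out.components[c][sel] = fit
            if estimate_uncertainty:
                if k <= p2:
                    unc[c][sel] = 0.0
                    continue
                A2 = np.einsum("nkp,nk,nkq->npq", X2, W, X2) + 1e-10 * np.eye(p2)
                b2 = np.einsum("nkp,nk,nk->np", X2, W, yn)
                fit2 = np.linalg.solve(A2, b2[..., None])[..., 0][:, 0]
                # row norms of the (linear) smoothing operator
                e1 = np.zeros((n, p, 1))
                e1[:, 0, 0] = 1.0
                v = np.linalg.solve(A, e1)[..., 0]  # (n, p)
                Lw = np.einsum("np,nkp->nk", v, X) * W
                lnorm = np.sqrt((Lw**2).sum(axis=1))
                resid = y - fit
                sigma = 1.4826 * np.median(np.abs(resid - np.median(resid)))
                unc[c][sel] = np.abs(fit2 - fit) + 2.0 * sigma * lnorm
    out.uncertainty = unc
    return out


def smooth_gaussian(field: DisplacementField, sigma_pixels: float,
                    estimate_uncertainty: bool = True) -> DisplacementField:
    """Mask-normalized Gaussian smoothing of each component.

    The kernel is renormalized over masked pixels only, so values outside the
    mask never leak in; near thin mask edges this still flattens genuine
    gradients (the known edge bias of Gaussian smoothing on masked fields).

    With ``estimate_uncertainty`` the result carries a per-pixel error
    estimate analogous to the LOWESS one: a scale-halving bias estimate
    (difference to smoothing at ``sigma/sqrt(2)``) plus twice the fit noise
    SD (robust residual SD attenuated by the kernel's l2 norm).
    """
    if sigma_pixels <= 0:
        raise ValueError("sigma_pixels must be positive")
    out = field.copy()
    m = field.mask.astype(float)

    def masked_smooth(arr, s):
        den = ndimage.gaussian_filter(m, s)
        num = ndimage.gaussian_filter(arr * m, s)
        vals = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
        return np.where(field.mask, vals, arr)

    unc = np.zeros_like(field.components) if estimate_uncertainty else None
    for c in range(field.dim):
        sm = masked_smooth(field.components[c], sigma_pixels)
        out.components[c] = sm
        if estimate_uncertainty:
            sm_half = masked_smooth(field.components[c], sigma_pixels / np.sqrt(2.0))
            resid = (field.components[c] - sm)[field.mask]
            sigma_n = 1.4826 * np.median(np.abs(resid - np.median(resid)))
            # l2 norm of an isotropic Gaussian kernel in d dimensions
            l2 = (4.0 * np.pi * sigma_pixels**2) ** (-field.dim / 4.0)
            unc[c] = np.abs(sm - sm_half) + 2.0 * sigma_n * l2
            unc[c][~field.mask] = 0.0
    out.uncertainty = unc
    return out


def boundary_pixels(mask: np.ndarray) -> np.ndarray:
    """One-pixel rim of the mask (masked pixels touching the outside)."""
    struct = np.ones((3,) * mask.ndim, dtype=bool)
    return mask & ~ndimage.binary_erosion(mask, structure=struct)


def add_noise(field: DisplacementField, noise: NoiseSpec) -> DisplacementField:
    """Add i.i.d. zero-mean Gaussian noise to each component at masked pixels.

    Boundary (rim) pixels are perturbed iff ``noise.apply_to_boundary``.
    Reproducible bit-for-bit under a fixed seed.
    """
    out = field.copy()
    if noise.sigma == 0:
        return out
    rng = np.random.default_rng(noise.seed)
    target = field.mask.copy()
    if not noise.apply_to_boundary:
        target &= ~boundary_pixels(field.mask)
    draws = rng.normal(0.0, noise.sigma, size=(field.dim,) + field.shape)
    for c in range(field.dim):
        out.components[c][target] += draws[c][target]
    return out
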