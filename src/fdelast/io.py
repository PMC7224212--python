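"""File import/export for fields, encoding sidecars and boundary conditions.

Displacement fields travel either as one NIfTI volume per component (the
affine carries spacing and origin) or as delimited-text maps (one file per
component, row-major in the ``[i, j(, k)]`` index convention, axis order
x, y[, z]).  Encoding and noise parameters ride in JSON sidecars.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .fields import DisplacementField, NoiseSpec, PhaseEncodingSpec

_COMP_SUFFIX = ("dx", "dy", "dz")


def save_displacement_nifti(field: DisplacementField, prefix: str | Path) -> list[Path]:
    """Write one ``<prefix>_dx.nii`` / ``_dy.nii`` [/ ``_dz.nii``] volume per
    component plus ``<prefix>_mask.nii``; returns the written paths."""
    import nibabel as nib

    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    affine = np.eye(4)
    for a, s in enumerate(field.spacing):
        affine[a, a] = s
        affine[a, 3] = field.origin[a]
    paths = []
    for c in range(field.dim):
        p = prefix.parent / f"{prefix.name}_{_COMP_SUFFIX[c]}.nii"
        nib.save(nib.Nifti1Image(field.components[c].astype(np.float64), affine), p)
        paths.append(p)
    pm = prefix.parent / f"{prefix.name}_mask.nii"
    nib.save(nib.Nifti1Image(field.mask.astype(np.uint8), affine), pm)
    paths.append(pm)
    return paths


def load_displacement_nifti(prefix: str | Path, dim: int | None = None) -> DisplacementField:
    """Load a field written by :func:`save_displacement_nifti`."""
    import nibabel as nib

    prefix = Path(prefix)
    comps = []
    for suffix in _COMP_SUFFIX:
        p = prefix.parent / f"{prefix.name}_{suffix}.nii"
        if p.exists():
            comps.append(nib.load(p))
        elif dim is None or len(comps) < dim:
            if suffix == "dz" and len(comps) == 2 and dim is None:
                break
            if len(comps) < 2 or (dim is not None and len(comps) < dim):
                raise FileNotFoundError(p)
            break
    img0 = comps[0]
    affine = img0.affine
    spacing = tuple(float(affine[a, a]) for a in range(len(comps)))
    origin = tuple(float(affine[a, 3]) for a in range(len(comps)))
    data = np.stack([np.asanyarray(im.dataobj, dtype=float) for im in comps])
    pm = prefix.parent / f"{prefix.name}_mask.nii"
    mask = np.asanyarray(nib.load(pm).dataobj).astype(bool) if pm.exists() else None
    return DisplacementField(components=data, spacing=spacing, origin=origin, mask=mask)


def save_displacement_text(field: DisplacementField, prefix: str | Path) -> list[Path]:
    """Write each component (and the mask) as a delimited-text map.

    2D grids are written directly; 3D grids are flattened row-major with the
    grid shape recorded in the header.  Header lines document the axis order
    and geometry.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    header = (
        f"axis order (x, y{', z' if field.dim == 3 else ''}); pixel (0,0) at "
        f"origin; coords = origin + index*spacing\n"
        f"shape={','.join(map(str, field.shape))} "
        f"spacing={','.join(f'{s:g}' for s in field.spacing)} "
        f"origin={','.join(f'{o:g}' for o in field.origin)} units=mm"
    )
    paths = []
    arrays = [field.components[c] for c in range(field.dim)] + [field.mask.astype(int)]
    names = list(_COMP_SUFFIX[: field.dim]) + ["mask"]
    for name, arr in zip(names, arrays):
        p = prefix.parent / f"{prefix.name}_{name}.txt"
        np.savetxt(p, arr.reshape(arr.shape[0], -1), header=header)
        paths.append(p)
    return paths


def load_displacement_text(prefix: str | Path) -> DisplacementField:
    prefix = Path(prefix)
    first = prefix.parent / f"{prefix.name}_dx.txt"
    meta = {}
    with open(first) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            for token in line[1:].split():
                if "=" in token:
                    k, v = token.split("=", 1)
                    meta[k] = v
    shape = tuple(int(s) for s in meta["shape"].split(","))
    spacing = tuple(float(s) for s in meta["spacing"].split(","))
    origin = tuple(float(s) for s in meta["origin"].split(","))
    comps = []
    for suffix in _COMP_SUFFIX[: len(shape)]:
        p = prefix.parent / f"{prefix.name}_{suffix}.txt"
        comps.append(np.loadtxt(p).reshape(shape))
    pm = prefix.parent / f"{prefix.name}_mask.txt"
    mask = np.loadtxt(pm).reshape(shape).astype(bool) if pm.exists() else None
    return DisplacementField(
        components=np.stack(comps), spacing=spacing, origin=origin, mask=mask
    )


def save_sidecar(path: str | Path, enc: PhaseEncodingSpec | None = None,
                 noise: NoiseSpec | None = None) -> Path:
    """JSON sidecar for encoding / noise parameters."""
    doc = {}
    if enc is not None:
        doc["encoding"] = {
            "gyromagnetic_ratio": enc.gyromagnetic_ratio,
            "encoding_duration": enc.encoding_duration,
            "encoding_gradient": list(enc.encoding_gradient),
            "reference_gradient": list(enc.reference_gradient),
        }
    if noise is not None:
        doc["noise"] = {
            "sigma": noise.sigma,
            "seed": noise.seed,
            "apply_to_boundary": noise.apply_to_boundary,
        }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(doc, indent=2))
    return path


def load_sidecar(path: str | Path):
    """Load a sidecar; returns (PhaseEncodingSpec | None, NoiseSpec | None)."""
    doc = json.loads(Path(path).read_text())
    enc = noise = None
    if "encoding" in doc:
        e = doc["encoding"]
        enc = PhaseEncodingSpec(
            gyromagnetic_ratio=e["gyromagnetic_ratio"],
            encoding_duration=e["encoding_duration"],
            encoding_gradient=tuple(e["encoding_gradient"]),
            reference_gradient=tuple(e["reference_gradient"]),
        )
    if "noise" in doc:
        n = doc["noise"]
        noise = NoiseSpec(sigma=n["sigma"], seed=n["seed"],
                          apply_to_boundary=n["apply_to_boundary"])
    return enc, noise
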