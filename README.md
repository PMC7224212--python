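# fdelast — finite-deformation MRI elastography by topology optimization

`fdelast` reconstructs spatial maps of **relative stiffness** in stiff soft
tissues (articular cartilage, hydrogels, silicone biomaterials) from imaged
finite-deformation displacement fields.  Conventional magnetic-resonance
elastography relies on high-frequency shear waves that dissipate in stiff
tissue; this package instead takes the displacement fields produced by
low-frequency, physiological-magnitude cyclic loading (e.g. DENSE
displacement-encoded MRI during indentation) and solves the inverse
elasticity problem by iterative finite-element topology optimization.

It is aimed at researchers in musculoskeletal imaging and biomaterials who
have (or want to simulate) pixel/voxel displacement maps and need
quantitative stiffness contrast — layer ratios, inclusions, gradients — in
2D slices or 3D volumes.

## The method

Each finite element `k` carries a design density `ρ_k` that scales an
isotropic linear-elastic modulus (SIMP parameterization with exponent
`p = 1`, i.e. un-penalized):

```
E_k = ρ_k^p · E⁰ ,      0 < ρ_min < ρ_k ≤ 1
```

Measured displacements are prescribed on **all boundary nodes** (Dirichlet
data) and the densities are updated to minimize the worst weighted misfit
over internal nodes `P_i`:

```
F  =  min  max_i  w_i · | Δx_exp(P_i) − Δx_sim(P_i) |
```

Gradients of a smooth p-norm surrogate of `F` come from one adjoint solve
per iteration, are regularized by a cone-shaped sensitivity filter, and
drive either a move-limited MMA-style update (noisy data) or a
bound-constrained quasi-Newton descent (clean data).  Because
pure-displacement boundary data determine stiffness only up to a
multiplicative constant, maps are reported normalized to a mean relative
stiffness of 0.5 and as region-mean ratios.

The pre-processing chain covers the rest of the imaging pipeline: phase →
displacement conversion (`Δφ = γ_H t_enc (G_de − G′_de) Δx`), quality-guided
phase unwrapping, robust LOWESS (or mask-normalized Gaussian) smoothing with
per-pixel uncertainty estimates, noise injection for simulation studies,
mesh building from binary masks, and Monte-Carlo / Cotter sensitivity
evaluation of the whole workflow.

## Worked example

Reconstruct a synthetic 6 × 6 mm bilayer phantom (1000 Pa over 500 Pa,
bottom fixed, top indented by 15% of the thickness, plane stress, ν = 0.49):

```python
from fdelast.phantoms import end_to_end_case
from fdelast.inverse import InverseProblem

case = end_to_end_case("bilayer2d", resolution=0.3)   # 20x20 elements
res = InverseProblem.from_field(case.ideal_field, mesh=case.mesh,
                                gmap=case.gmap).fit()
print(res.summary())
means, ratios = res.region_ratio(case.labels)
print(f"top:bottom ratio = {ratios[(1, 0)]:.2f}")
```

prints

```
Relative-stiffness inversion
============================================================
elements                    400
nodes                       441
element family              quad4
target nodes                361
Poisson ratio               0.49
SIMP exponent p             1.0
baseline modulus E0 (Pa)    500.0
iterations                  122
converged                   True
rejected trial steps        0
objective max|du| (mm)      0.00141162
surrogate p-norm (mm)       0.00187471
relative stiffness mean     0.5 (normalized to 0.5)
relative stiffness range    [0.2945, 0.7679]
============================================================
top:bottom ratio = 1.97
```

The worst displacement mismatch fell from the initial homogeneous guess to
1.4 µm, and the recovered layer-mean ratio 1.97 matches the true 2:1
stiffness contrast; the normalized map ranges over [0.29, 0.77] around the
mean-0.5 convention.

The same objects drive real data: load displacement components with
`fdelast.io.load_displacement_nifti` (or the delimited-text reader), smooth
with `fdelast.fields.smooth_lowess`, and fit.  A command-line interface
wraps the common runs:

```
fdelast phantom    --case bilayer2d --noise 0.1 --seed 7 --out ph/
fdelast invert     --displacement ph/displacement --out inv/
fdelast montecarlo --case bilayer2d --sigma 0.1 --n 100 --seed 1 --out mc/
fdelast cotter     --out cotter/
```

Every run writes a JSON log of its settings, seed and objective history.

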