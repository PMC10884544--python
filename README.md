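# b0dti

Simulation and analysis toolkit for quantifying how diffusion-tensor MRI
measures (MD, AD, RD, FA) depend on the white-matter fibre orientation θ
relative to the scanner's main magnetic field **B₀**, when the underlying
driver is orientation-dependent transverse relaxation in the extra-axonal
compartment.

## Who this is for

Diffusion-MRI methods researchers who want to (i) predict the size and sign
of θ-dependence injected into DTI measures by compartmental T2 anisotropy,
(ii) test analysis pipelines (pooled single-fibre-voxel statistics,
along-tract tractometry with two head orientations) on fully synthetic
cohorts with known ground truth, and (iii) study how Rician noise and
fibre dispersion mask or distort those effects.

## The model

A white-matter voxel is a stick + zeppelin with a common fibre axis **n**:

```
S(b, g, TE) = f · exp(−R₂ᵢₐ TE) · exp(−b Dᵢₐ(g))
            + (1−f) · exp(−R₂ₑₐ(θ) TE) · exp(−b Dₑₐ(g)),
D(g) = D⊥ + (g·n)² (D∥ − D⊥)
```

with axonal signal fraction `f`, stick diffusivity `Dᵢₐ,∥ = 2.6 μm²/ms`
(zero perpendicular), zeppelin `Dₑₐ,∥ = 2.0`, `Dₑₐ,⊥ = 0.4 μm²/ms`,
intra-axonal rate `R₂ᵢₐ = 12 s⁻¹` and an extra-axonal rate that depends on
the fibre angle θ to B₀:

```
R₂ₑₐ(θ) = 17.4 + 2.4 · sin⁴θ   [s⁻¹]
```

Because the compartments relax at different, θ-dependent rates, the
T2-weighting of the compartments — and hence every apparent diffusion
measure — inherits an orientation dependence. In the low-b limit the
apparent diffusion coefficient is the T2-weighted mixture

```
ADC(TE, θ) = [f Dᵢ e^(−R₂ᵢₐTE) + (1−f) Dₑ e^(−R₂ₑₐ(θ)TE)]
           / [f e^(−R₂ᵢₐTE) + (1−f) e^(−R₂ₑₐ(θ)TE)].
```

Orientation anisotropy of any measure F is quantified by the representation
`F(θ) = A + B·sin⁴θ` (coefficient B = anisotropy magnitude, with AIC-based
selection against the isotropic `F = A` and an 85% confidence-interval rule
on B), and non-parametrically by 1°-binning plus a count-weighted cubic
smoothing spline whose signed range is the anisotropy magnitude. A dipolar
alternative `R₂(θ) ∝ (3cos²θ − 1)²`, vanishing at the magic angle 54.7°, is
available for the intra-axonal compartment.

The package also contains: Rician noise generation, diffusion-tensor
estimation by iterative weighted linear least squares (IWLLS) per echo
time, a synthetic cohort generator (subjects → tracts → along-tract
segments → single-fibre voxels, imaged in a default and an 18°-tilted head
orientation with B₀ and gradient directions fixed in the scanner frame),
and three pipelines: a simulation grid over axonal fraction × echo time,
the pooled single-fibre-voxel analysis, and the segment-wise
default-vs-tilted tractometry comparison fitted through the origin,
`Δmeasure = B · Δsin⁴θ`.

## Worked example

```python
import numpy as np
import b0dti

# recover the extra-axonal relaxation parameters from the rate curve
theta = np.arange(91.0)
rates = b0dti.relaxation_rate(b0dti.RelaxationModel("sin4", 17.4, 2.4), theta)
print(b0dti.fit_sin4(theta, rates).summary())
```

```
Anisotropy fit: F(theta) = A + B sin^4(theta)
  n obs          : 91
  A (offset)     : 17.4  (se 4.27e-16)
  B (anisotropy) : 2.4  (se 8.13e-16)
  85% CI of B    : [2.4, 2.4]
  AIC iso / aniso: -19.384 / -6091.904
  selected       : anisotropic  (dAIC of rejected form 6072.52, support: none)
```

The fit recovers the generating offset A = 17.4 s⁻¹ and anisotropy
B = 2.4 s⁻¹ exactly, and the anisotropic representation is selected with
essentially no support for the isotropic alternative.

```python
# anisotropy of the four tensor measures, analytic condition, f = 0.4, TE = 54 ms
grid = b0dti.run_simulation_grid(
    f_list=(0.4,), te_list=(54.0,), conditions=("analytic",), seed=1
)
print(grid[["measure", "a_hat", "b_hat", "selected"]].to_string(index=False))
```

```
measure    a_hat     b_hat    selected
     md 0.901896 -0.002158 anisotropic
     ad 2.282936  0.019421 anisotropic
     rd 0.211376 -0.012947 anisotropic
     fa 0.899737  0.007378 anisotropic
```

AD and FA increase with θ (B > 0) while RD decreases (B < 0): lying
perpendicular to B₀ the extra-axonal water relaxes faster, so at nonzero TE
the voxel looks more stick-like. MD's coefficient is small and can change
sign with `f` and TE. `|B|` grows with echo time (compare
`te_list=(54., 130.)`).

A command-line surface wraps the pipelines:

```bash
b0dti simulate-grid --config cfg.yaml --out out/   # B over (f, TE) grid
b0dti make-cohort   --config cfg.yaml --out out/   # synthetic cohort + signals
b0dti pooled        --config cfg.yaml --out out/   # pooled SFP-voxel analysis
b0dti tractometry   --config cfg.yaml --out out/   # default-vs-tilted segments
```

where `cfg.yaml` needs at least a `seed:` entry; every other key has a
documented default (see `b0dti.config`). All outputs are tidy CSV plus a
provenance log (package version, config hash, seed).

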