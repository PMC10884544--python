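# Methods

## Signal model

A single-fibre white-matter voxel is modelled as two non-exchanging,
axially symmetric compartments sharing a fibre axis **n**: a stick
(intra-axonal, perpendicular diffusivity zero) and a zeppelin
(extra-axonal). The normalised diffusion-relaxation signal is

    S(b, g, TE) = f e^(−R2_ia TE) e^(−b D_ia(g)) + (1−f) e^(−R2_ea(θ) TE) e^(−b D_ea(g)),

with the projected diffusivity `D(g) = D⊥ + (g·n)² (D∥ − D⊥)`. Units
follow diffusion-MRI convention: b in s/mm², D in μm²/ms (dimensionless
exponent `b·D·10⁻³`), TE in ms, rates in 1/s. The angle θ between the
fibre and B₀ is always the folded axis angle `arccos|n·b̂₀| ∈ [0°, 90°]`
(fibres are antipodally symmetric).

Transverse relaxation may depend on θ per compartment:

* `constant` — R2 independent of orientation (intra-axonal default,
  R2_ia = 12 s⁻¹);
* `sin4` — `R2(θ) = R2_iso + R2_aniso sin⁴θ` (extra-axonal default,
  17.4 + 2.4 sin⁴θ s⁻¹), the empirical form for myelinated white matter;
* `dipolar` — `R2(θ) = R2_iso + R2_aniso (3cos²θ − 1)²`, the residual
  dipolar-coupling form that vanishes at the magic angle
  `arccos(1/√3) ≈ 54.7°`; available as an intra-axonal option, off by
  default.

Because the compartments carry different θ-dependent T2 weights, every
apparent diffusion measure inherits an orientation dependence. In the
low-b limit the ADC is the T2-weighted mixture of the projected
compartment diffusivities (the first-order coefficient of the Maclaurin
expansion of ln S in b); AD and RD are the parallel/perpendicular ADCs,
MD = (AD + 2RD)/3, and FA is computed from the eigenvalue triple
(AD, RD, RD). At TE = 0 the weighting is flat and the orientation
dependence vanishes — θ enters only through relaxation.

Reference tissue parameters: f = 0.4, [D_ia,∥, D_ea,∥, D_ea,⊥] =
[2.6, 2, 0.4] μm²/ms. The simulation grid varies
f ∈ {0.1, 0.3, 0.5, 0.7, 0.9} and TE ∈ {54, 75, 100, 130} ms; the exact
echo-time set of the emulated acquisition being unavailable, this grid
spans the 54–130 ms range used by multi-TE spin-echo protocols and is
configurable.

## Fibre dispersion

Dispersed voxels integrate the coherent signal over sub-fibre orientations
n′ ~ Watson(n, κ); each sub-compartment sees its own angle θ′ to B₀ in the
relaxation rates and its own gradient projection. The integral is
evaluated by a deterministic product quadrature: Gauss–Legendre nodes
mapped through the inverse CDF of the Watson marginal in cos α (the
probability-domain transform keeps the rule accurate from κ = 0 to the
near-delta limit) × a midpoint rule in azimuth; default 48 × 24 = 1152
nodes, minimum 8 × 8 enforced. A rejection-sampling Monte-Carlo average is
kept in the tests as an independent oracle, never in the main path.
Concentration can be specified directly as κ; a converter to/from the
orientation-dispersion index `OD = (2/π) arctan(1/κ)` is provided (the
grid's dispersed condition uses κ = 16). Verified limits: κ = 10⁶ matches
the coherent signal within 10⁻⁴; κ = 0 is rotation invariant within 10⁻⁶;
κ = 16 agrees with a 10⁶-sample Monte-Carlo mean within 3 standard errors.

## Noise and tensor estimation

Rician noise is the magnitude of a complex Gaussian perturbation,
`√((S+ε₁)² + ε₂²)`, with σ defined by the SNR on the b = 0, TE = 0 signal
(default SNR 100, σ = 0.01 for the normalised model).

Diffusion tensors are fitted per echo time by iterative weighted linear
least squares on the 7-parameter log-linear model
`ln S = ln S0 − Σ bᵢⱼ Dᵢⱼ`: ordinary least squares on log-signals to
initialise, then weighted least squares with weights equal to the squared
model-predicted signals, iterated until the maximum parameter change is
below 10⁻⁶ of the parameter scale (max 10 iterations; the scale-relative
criterion avoids false non-convergence on exactly-zero off-diagonal
elements). Nonpositive signals are clipped to 10⁻¹⁰ × S0 before the log
and counted. No positivity constraint is imposed on the tensor; negative
eigenvalues are flagged, not repaired. Scalars: MD = mean eigenvalue,
AD = λ₁, RD = (λ₂+λ₃)/2, FA from the standard eigenvalue-dispersion
formula; θ is the folded angle between the principal eigenvector and B₀.
On noiseless mono-exponential data the fit is exact to machine precision;
on model-misspecified data (the two-compartment signal) it converges to
the root of its estimating equation `Xᵀ diag(S_pred²)(y − Xβ) = 0`, which
differs from a signal-domain nonlinear fit at second order in the
residuals (~10⁻⁴ μm²/ms for the reference parameters) — the tests verify
both statements at their respective scales.

The default acquisition used by the simulations is a two-shell scheme,
b ∈ {750, 1500} s/mm² with 30 directions per shell plus 3 b = 0 rows per
TE, directions from a golden-spiral hemisphere set polished by
electrostatic repulsion and shared across echo times (fixed in the scanner
frame); pulse timings Δ = 22 ms, δ = 8 ms are metadata. Schemes round-trip
through FSL-dialect bval/bvec files plus a TE sidecar column; gradient
norms within 1% of unity are renormalised on read, larger deviations are
rejected.

## Anisotropy statistics

**sin⁴θ representation.** `F(θ) = A + B sin⁴θ` is fitted by (weighted)
least squares; the 85% confidence interval of B uses the t-distribution
with n−2 degrees of freedom. Model selection against the isotropic
`F = A` uses the least-squares AIC `n ln(RSS/n) + 2k` (k = mean parameters
+ 1 for the variance; the +1 cancels in differences; no small-sample
correction). The anisotropic representation is selected only jointly: its
AIC is minimal, the isotropic ΔAIC exceeds 2, and the 85% CI of B excludes
zero. ΔAIC support bands: ≤ 2 substantial, 4–7 considerably less, ≥ 10
none. A slope below 10⁻¹² of the data scale is treated as numerically zero
(perfect-fit AIC arithmetic on constant data would otherwise select a
rounding residue). Under the joint rule the type-I error on
θ-independent Gaussian data is below 15% (measured ≈ 5% over 1000 seeded
repeats).

**Binning + smoothing spline.** Voxel values are binned in 1°-wide
half-open bins [k, k+1) over [0°, 90°] (θ = 90° folds into the last bin);
each non-empty bin reports the mean angle, mean value and count, the
reported bin centre being the in-bin mean angle rather than the geometric
centre. A cubic smoothing spline is fitted to the bin means weighted by
bin counts, the penalty chosen by generalised cross-validation
(`scipy.interpolate.make_smoothing_spline`; the results record the
criterion and the weighted bin RSS — the GCV-selected penalty itself is
internal to scipy). Since the folded angle makes any orientation-dependent
measure an even function at 0° and 90°, the binned data are reflected
across both boundaries before fitting, which removes the boundary bias
cubic splines otherwise show at the extrema. The anisotropy magnitude is
the signed range of the curve over the observed angles: negative when the
curve's minimum falls below its value at the smallest observed angle, with
a 1%-of-range tie-break so monotone increasing curves are not sign-flipped
by numerical wiggle. On noiseless `A + B sin⁴θ` data the recovered
magnitude is within ~5·10⁻⁵·B of B. The variance contribution of
anisotropy is `(std_iso − std_aniso)/std_iso`, the fractional drop in
across-voxel standard deviation when the fitted curve (re-centred at its
mean) is subtracted; both standard deviations are reported so alternative
definitions can be derived. A minimum of 10 non-empty bins is required.

## Synthetic cohort

The generator emulates a tiltable-coil study: the same anatomy imaged in a
default (0°) and a tilted head orientation (default 18° about the
left–right scanner x-axis). The head rotation rotates the fibre
orientations only; B₀ and the gradient directions stay fixed in the
scanner frame, so tilting re-samples θ without changing the anatomy.

Hierarchy: subjects → tracts → along-tract segments → single-fibre voxels
(defaults 2 × 5 × 10 × 8). Tract directions are drawn isotropically
(folded-θ density ∝ sin θ) or from a user θ-histogram; voxels scatter
about their segment direction with ~5° tangent-plane Gaussian spread
(mimicking the fanning that motivates end-segment exclusion in
tractometry); per-voxel tissue parameters get independent multiplicative
truncated-Gaussian jitter (CV 5%, clipped at ±3 CV and to the parameter
bounds) around the reference values, standing in for micro-anatomical
variability. All draws are deterministic given the config seed; cohort and
signal tables are byte-identical across runs.

What the generator does **not** emulate: image space and partial-volume
mixing, crossing fibres (all voxels are single-fibre by construction —
the single-fibre selection step of real pipelines is out of scope),
EPI/susceptibility artifacts, spatially varying coil sensitivity or SNR
changes with head position, and gradient nonlinearity. Passing tests on
this cohort therefore validate the estimation and statistics chain under
the stated signal model, not robustness to those real-data effects.

## Pipelines

* **Simulation grid** — per (condition, f, TE) cell the measure-versus-θ
  relation is built (analytically on a 1° grid, or from fitted tensors of
  simulated voxels with θ spread uniformly over [0°, 90°] and random
  azimuths — a fixed azimuth per θ would alias the direction-set-dependent
  estimation bias into a systematic pseudo-trend in θ), then the sin⁴θ fit
  and selection are applied. Default 1000 simulated voxels per noisy cell,
  applied as one pooled fit per cell.
* **Pooled analysis** — all single-fibre voxels from all subjects and both
  head orientations are pooled; per measure × TE both the spline route
  (magnitude, variance contribution) and the sin⁴θ route (A, B, selection)
  are reported, using the fitted θ from the tensor chain, as an in vivo
  pipeline would.
* **Tractometry** — segment means per head orientation of each measure and
  of sin⁴θ; the outer-most 20% of segments per tract (10% from each end;
  a config flag switches to 20% per end) and segments with 3 or fewer
  voxels are excluded; the change across orientations is fitted through
  the origin, `Δmeasure = B Δsin⁴θ` (an intercept variant exists for
  sensitivity analysis), with a star where `AIC_iso − AIC_aniso > 2` and
  the fractional std reduction after removing the fitted term. A zero tilt
  makes the regressor degenerate; the cell is flagged, not fitted.

On noiseless, jitter-free cohorts the pooled sin⁴θ fit, the spline
magnitude and the tractometry slope agree in sign for all four measures at
every TE, with AD and FA positive and RD negative; MD's anisotropy is an
order of magnitude smaller (≈ −0.002 μm²/ms at f = 0.4) and its sign is
not resolvable at SNR 100 with the default 800-voxel cohort — expected,
since the model predicts MD sign flips across (f, TE). Setting
R2_aniso = 0 nullifies anisotropy in all pipelines: exactly in the
analytic grid, and with the isotropic representation selected in ≥ 95% of
noisy cells.

## Problem sizes and determinism

The test suite and the acceptance script run on desk-scale problems: 1°
analytic grids (91 points), 100–1000 simulated voxels per noisy cell,
cohorts of order 10²–10³ voxels, Monte-Carlo oracles of 2·10⁵–10⁶ draws.
Every stochastic step takes an explicit seed (numpy `default_rng`); fixed
seeds reproduce all tables bit-for-bit. The per-voxel IWLLS is vectorised
across voxels, so the full default cohort (6400 tensor fits) completes in
seconds.

## Known limitations

* The sin⁴θ representation is an approximation even for the analytic
  two-compartment ADC; A and B are descriptive coefficients, not model
  parameters, except when the data are generated by the sin⁴ form itself.
* The AIC/CI selection rule is calibrated for independent observations;
  pooled voxels within a subject/tract are correlated, so selection on
  real-style cohorts is anti-conservative to an unquantified degree.
* Fitted θ and fitted measures share estimation noise, which induces a
  small spurious association under the null; at SNR 100 it stays within
  the selection rule's error budget but grows at lower SNR.
* Exchange between compartments, higher-order (kurtosis) b-terms, and
  susceptibility-gradient cross-terms are outside the signal model.
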