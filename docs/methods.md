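# Methods

This note documents the models implemented in `microrelax`, the study
conditions encoded in the synthetic-data generator, and the numerical and
design choices that shape the results the test suite and
`scripts/acceptance.py` compute.

## Signal models

All models describe the magnitude of a gradient-echo signal at echo time
TE (seconds) as a product of four factors: an amplitude S0, a microscopic
decay term, a nanoscale term exp(−R2,nano·TE), and a caller-supplied
macroscopic attenuation F_macro(TE) (default 1; the voxel-spread-function
correction that produces it is upstream of this package).

The microscopic term is controlled by two parameters: Ω², the variance of
the Larmor angular-frequency offsets the magnetic inclusions induce across
the voxel (rad²/s²), and R2,micro*, the long-time relaxation rate (s⁻¹).
Every nonexponential model obeys

* short times (TE ≪ t_c): ln S ≈ −Ω²·TE²/2,
* long times (TE ≫ t_c):  d ln S/dTE → −R2,micro*,

with t_c = R2,micro*/Ω². The three implemented forms differ in how they
interpolate between these limits (κ = Ω²/R2,micro*):

| model | microscopic exponent |
|---|---|
| Padé | −(Ω²TE²/2) / (1 + κTE/2) |
| Anderson–Weiss | −(R2,micro\*²/Ω²)·(κTE + e^(−κTE) − 1) |
| Jensen–Chandra | −(R2,micro\*²/Ω²)·(κTE + 1 − √(1 + 2κTE)) |

The Padé form is a model-free rational interpolation; Anderson–Weiss
follows from Gaussian phase accumulation with an exponential frequency
autocorrelation; Jensen–Chandra from the autocorrelation implied by free
Gaussian diffusion around spherical perturbers.  The Jensen–Chandra
square-root term approaches the exponential asymptote only as 1/√(κTE),
so over a 20 ms echo window its fitted R2,micro* systematically exceeds
the apparent decay rate of the data — the package's tests pin this
direction (JC > AW on identical AW-generated data).  The exponential
reference model is S0·exp(−R2*·TE) with R2* = R2,micro* + R2,nano.

These closed forms are enforced by asymptote tests (short-time curvature
to 10⁻³ relative, long-time slope, mutual collapse to the exponential at
Ω² → 0) rather than trusted as transcription; the small-argument branches
use `expm1`/series guards so the Gaussian limit is accurate to machine
precision.

## Preprocessing

* **Harmonization.** Repetitions are mapped voxel-wise onto the first by
  ordinary least squares of an affine model (scale + offset over the echo
  dimension); repetition 1 is the fixed reference.  An affine model is the
  minimal one that removes receive-field scaling and baseline offsets
  between repetitions.
* **MP-PCA denoising.** Sliding 5×5×5 patches; for each patch the echo-
  direction covariance eigenvalues are tested against the Marchenko–Pastur
  bulk edge (width 4σ²√((N−p)/M) for the trailing N−p eigenvalues of an
  M×N patch matrix); components under the edge are zeroed and their mean
  eigenvalue is the local noise variance.  Overlapping patch estimates are
  averaged.  Input is magnitude data (the generator produces magnitudes);
  at the SNR of interest (≈ 50) the magnitude noise is Gaussian to good
  approximation, which is the regime the estimator assumes.
* **Rician floor.** Background intensities are fitted by maximum
  likelihood (`scipy.stats.rice`, location fixed at 0, method-of-moments
  start); the noncentrality ν is subtracted from all echoes as a single
  global scalar.  ν is weakly identified when the true floor is zero — the
  tests assert only that it stays well below σ in that case.
* **SNR** is signal over the per-voxel noise SD map, per echo; zero-σ
  voxels are reported as infinite and excluded from summaries.

## Fitting

Trust-region-reflective least squares (`scipy.optimize.least_squares`)
with box bounds: R2,micro* ∈ [1, 80] s⁻¹ (start 20), Ω² ∈ [100, 4·10⁴]
rad²/s² for Padé/AW and [100, 8·10⁴] for JC (start 10⁴), R2* ∈ [0, 80]
(start 20), S0 ∈ [10, 2000] (start 500).  R2,nano is never free — a
gradient-echo protocol cannot separate it from R2,micro* — and defaults to
10 s⁻¹ (8 and 12 s⁻¹ are the sensitivity-analysis alternates).  Residuals
are unweighted magnitudes over all echoes; tolerances 10⁻⁸ on parameters
and cost; a fit touching a bound is flagged, not retried.

Goodness of fit: MSE = RSS/n in signal units² (meaningful on the S0 ≈
10–2000 intensity scale), and AIC = n·ln(RSS/n) + 2k with k counting free
parameters including S0 (k = 2 exponential, 3 nonexponential).  Only AIC
*differences* between models on the same curve are interpreted.  QC
excludes voxels with MSE > 15 (spurious effects, e.g. physiological
noise) or t_c < 0.5 ms (transition finished before it is detectable); the
MSE threshold is calibrated for denoised data — raw single-repetition
noise at SNR 50 sits far above it.

Two non-obvious behaviours, both covered by tests:

* A pure exponential decay fitted with a nonexponential model drives Ω²
  to its **upper** bound: a transition completed before the first echo is
  the family's way of expressing "no observable Gaussian phase".  (At the
  lower bound the decay would be a nearly flat Gaussian.)
* Nesting of the exponential inside the nonexponential family is
  approximate, not exact, because Ω² is capped: mimicking an exponential
  at the Ω² bound leaves an RMS residual of 0.02–0.21% of S0 depending on
  the model, so under noise the nonexponential MSE can exceed the
  exponential one by a fraction of a percent on individual draws.

## Microstructure inversion

With γ = 2.675·10⁸ rad/s/T and B0 = 3 T (package constants, overridable),
a dilute suspension of spheres with susceptibility difference Δχ (SI) and
volume fraction ζ gives Ω² = (4/45)·ζ(1−ζ)·(γB0Δχ)².  The forward model
keeps the (1−ζ) factor; the inversions use the dilute approximation
ζ(1−ζ) ≈ ζ (error < 4% for ζ < 0.04) so that they are exact algebraic
inverses of the approximate forward maps:

* SDR: R2,micro* = λ_SDR·ζ·γB0Δχ with λ_SDR = 2π/(9√3) ≈ 0.4031, so
  γB0Δχ = (45/4)·λ_SDR·Ω²/R2,micro* and ζ = (4/45)·R2,micro*²/(λ_SDR²Ω²).
* DNR: R2,micro* = λ_DNR·ζ·(γB0Δχ)²·τ with λ_DNR = 16/75 ≈ 0.2133; only
  τ = (4/45)·R2,micro*/(λ_DNR·Ω²) is identifiable, and the implied radius
  is r = √(6Dτ) with D = 1 µm²/ms.

ζ ≥ 1 is flagged nonphysical rather than silently returned.  The
dimensionless dephasing α = τ·δΩ_s (δΩ_s = γB0Δχ/3) separates the
regimes; the rate ratio R2,DNR/R2,SDR = α·λ_DNR/λ_SDR ≈ α/2.

Iron conversion: Δχ = ρ·χ_eff·Fe with ρ = 1.05 g/cm³ and χ_eff = 2.98
ppm·m³/kg for neuromelanin-bound iron.  Units resolve so that 1 ppm of
susceptibility corresponds to ≈ 0.32 mg iron per g tissue; equivalently
the per-concentration slopes are 3.3 ppb/(µg/g) for neuromelanin and 1.3
for ferritin (used when converting iron maps to susceptibility maps).
These are the only readings consistent with the worked value
2.4 ppm ↔ 0.77 mg/g, and they are applied uniformly.

Regional comparison uses the Kruskal–Wallis omnibus test, pairwise
Mann–Whitney p-values with and without Tukey-HSD adjustment, and Cliff's
delta by its defining dominance count (computed via ranks, verified
against the O(n²) count); the significance default is α = 0.01.

## Microscopic simulator

* **Inclusion maps.** Non-overlapping spheres placed uniformly at random
  with periodic geometry until the target ζ is reached (±1 sphere);
  realized ζ is recorded.  Defaults emulate nigral histology: ≈ 15 µm
  cluster radius, 300–1000 µg/g iron (≈ 1–3.3 ppm via the neuromelanin
  slope) over a diffuse background, on grids of order 100–440 µm with
  µm-scale pitch.  A loader accepts external (histology-derived)
  susceptibility maps as NIfTI/NPZ.
* **Dipole field.** ω = γB0·F⁻¹[(1/3 − k_z²/|k|²)·F[χ − ⟨χ⟩]], B0 along
  z, k = 0 term zeroed (the Lorentz-sphere reference is absorbed into the
  removed mean).  Verified against the analytic external field of a
  sphere, (Δχ/3)γB0(R/r)³(3cos²θ−1), to a few percent, and against the
  suspension variance formula to within 15% — the key consistency between
  the simulator and the inversion algebra.
* **Signals.** Static dephasing: S(TE) = |⟨e^(−iωTE)⟩| over grid points.
  Monte Carlo: walkers start uniformly at random, take Gaussian steps with
  per-axis variance 2D·dt (default dt = 0.1 ms), wrap periodically, accrue
  phase ω(position)·dt with nearest-neighbour field lookup (trilinear
  behind a flag), and the signal is the magnitude of the ensemble mean of
  e^(−iφ) with its standard error.  All randomness flows from one seeded
  generator; echo times are snapped to the step grid with a warning.
  Desk-scale default is 10⁵ walkers on grids up to ≈ 128³ (the study-scale
  10⁶ walkers/50 ms runs are reached by raising `n_walkers`).  Nanoscale
  relaxation is applied as a scalar exp(−R2,nano·TE) factor to simulated
  decays, not re-derived from the iron chemistry.
* **Diffusion regimes.** With D → 0 the Monte Carlo signal reproduces the
  static-dephasing signal within sampling error.  For small inclusions
  (α ≪ 1) diffusion averages the field and the long-TE Monte Carlo rate
  falls well below the static rate (motional narrowing); the packaged
  tests use 2 µm spheres where the effect is order-of-magnitude.  For
  large/strong inclusions (α ≫ 1) the two rates coincide within noise, so
  the narrowing direction is asserted only where diffusion matters.
* **Fit protocol for simulated decays.** The exponential model is fitted
  on TE > 10 ms only (its asymptotic regime) and the Padé model on all
  echoes; because those are different echo subsets, the package also
  reports the tail fit's residual evaluated on *all* echoes, which is the
  quantity that exposes the short-TE Gaussian phase the exponential
  misses.

## Synthetic datasets and experiments

The generator encodes the study conditions: 16 echoes from TE = 1.25 ms
with 1.2 ms spacing, three repetitions carrying affine perturbations
(scales 0.95–1.05, offsets ±5 signal units; repetition 1 is the
reference), per-voxel Padé ground truth with R2,micro* ∈ [10, 30] s⁻¹,
Ω² ∈ [0.4, 1.5]·10⁴ rad²/s² and S0 ∈ [450, 550] (so the fit bounds and
the MSE threshold apply on the intended scale), R2,nano = 10 s⁻¹, and
Rician noise — the magnitude of a complex-Gaussian perturbation — with σ
set by the target first-echo SNR (default 50, inside the 47–63 range
typical of subcortical data at the first echo).

Ground-truth parameter maps are spatially correlated Gaussian random
fields rescaled to the ranges above (correlation length 1 voxel,
`spatial_smoothness=0` for independent draws).  Real parameter maps are
spatially organized, and the patch-based MP-PCA step relies on exactly
that structure; spatially white parameter maps would put the denoiser
outside its operating assumptions and inflate the apparent Ω² bias by a
factor ≈ 2.  What the experiments emulate is therefore the estimator
pipeline on realistic-looking data; what they do not emulate is real
anatomy, physiological noise, macroscopic field gradients, motion, or the
embedding of synthetic voxels inside a measured brain volume — so passing
bounds here demonstrate estimator behaviour under the stated noise model,
not in-vivo performance.

The **noise-propagation experiment** fixes one ground truth, generates 10
independently re-noised datasets, runs concatenation → MP-PCA →
harmonization → Padé fitting on each, and summarises per-voxel bias (mean
deviation across repeats) and variability (SD across repeats) in percent
of truth, with Ω² stratified by t_c relative to the first echo time
(below it the Gaussian phase is unobservable and Ω² errors inflate
severely; the exclusion threshold 0.5 ms and the stratification threshold
TE₁ = 1.25 ms are both exposed in configuration).  The default problem
size is 8³ = 512 voxels — large enough that the reported medians are
stable across seeds.  No Rician-floor subtraction is applied here: the
synthetic volume has no background region to estimate it from, and at
SNR 50 the floor is far below the smallest signals.

The **R2,nano sensitivity experiment** refits one noisy dataset
(generated at R2,nano = 10 s⁻¹) with the fixed rate forced to 8 and
12 s⁻¹ and reports median percent changes; lowering the assumed nanoscale
rate pushes decay into the Gaussian term (Ω² up ≈ 20%, R2,micro* up
≈ 9% at mid-range parameters), and raising it mirrors the changes with
inverted sign.

## Known limitations

* Magnitude-domain MP-PCA only; complex-valued denoising (which avoids
  the Rician floor entirely) is not implemented.
* The dilute-suspension inversion breaks down as ζ grows (flagged at
  ζ ≥ 1, approximation error rises from ≈ 4% at ζ ≈ 0.04); no
  intermediate-dephasing interpolation between SDR and DNR is provided.
* The Monte Carlo walker ignores membranes, restriction and exchange, and
  uses nearest-neighbour field lookup by default; fields are periodic by
  construction.
* Published values that derive from post-mortem histological maps or
  in vivo cohorts (specific field widths, regional medians, MSE ratios,
  absolute AIC levels) are not reproduced at desk scale; the simulator's
  loader accepts such maps when users have them, and the package covers
  the corresponding claims at the level of directions and invariants.
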