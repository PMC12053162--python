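# microrelax

Nonexponential transverse (R2\*) relaxometry of magnetic microstructure in
multi-echo gradient-echo MRI.

## The problem

In iron-rich brain tissue — substantia nigra, globus pallidus, putamen,
caudate, thalamus — the gradient-echo signal does not decay exponentially.
Microscopic magnetic inclusions (chiefly iron-loaded cells such as
neuromelanin-pigmented dopaminergic neurons) perturb the local Larmor
frequency; at short echo times the log-signal is *quadratic* with curvature
set by the frequency variance Ω² (rad²/s²), and only at longer echo times
does it become linear with rate R2,micro\* (s⁻¹).  The transition happens
around the characteristic time t_c = R2,micro\*/Ω² (a few milliseconds).
Fitting both regimes instead of a single exponential yields two independent
handles on the tissue, which can be inverted to microscopic inclusion
properties — their susceptibility Δχ and volume fraction ζ in the static
dephasing regime (SDR), or the diffusion correlation time τ and inclusion
radius r = √(6Dτ) in the diffusion narrowing regime (DNR).

`microrelax` implements this analysis end to end for people working on
quantitative MRI of brain iron:

* **Signal models** (`microrelax.models`) — exponential decay plus three
  nonexponential forms sharing the asymptotes
  ln S ≈ −Ω²TE²/2 (TE ≪ t_c) and ln S ≈ −R2,micro\*·TE (TE ≫ t_c):
  a Padé (rational) interpolation, the Anderson–Weiss model (exponential
  frequency autocorrelation) and the Jensen–Chandra model (autocorrelation
  from free Gaussian diffusion, with its slow √TE approach to the
  exponential asymptote).  All carry a fixed nanoscale rate R2,nano and an
  optional per-echo macroscopic attenuation F_macro.
* **Preprocessing** (`microrelax.preprocessing`) — per-voxel affine
  harmonization of repetitions, Marchenko–Pastur PCA denoising with noise
  maps, Rician noise-floor estimation/subtraction, SNR maps.
* **Fitting** (`microrelax.fitting`) — a statsmodels-style
  `TransverseDecayModel` whose `fit()` returns `DecayFitResults` with
  parameters, MSE, AIC, t_c, QC flags and a `summary()` table; voxel-wise
  `fit_volume`, `compare_models`, and MSE/AIC-based model selection.
* **Microstructure** (`microrelax.microstructure`) — exact algebraic
  SDR/DNR inversions, susceptibility ↔ iron-concentration conversion,
  Kruskal–Wallis / Tukey / Cliff's-delta regional comparison.
* **Microscopic simulator** (`microrelax.simulator`) — synthetic sphere
  suspensions or loaded susceptibility maps → dipole-kernel frequency
  fields → static-dephasing and Monte Carlo diffusion signals, with the
  Padé/exponential fits used to quantify the nonexponential behaviour.
* **Synthetic data** (`microrelax.synthetic`) — in-vivo-like multi-echo
  datasets with known ground truth, plus the noise-propagation and
  R2,nano-sensitivity experiments.
* **CLI** (`microrelax` command) — `fit`, `invert`, `synth`, `noise-prop`,
  `r2nano-sens`, `simulate-mc`, `report`.

## Worked example

Fit a substantia-nigra-like decay (three concatenated repetitions of 16
echoes, TE = 1.25–19.25 ms; residual noise at the level left by MP-PCA
denoising) and invert the estimates:

```python
import numpy as np
from microrelax import (EchoSchedule, RelaxationParams, TransverseDecayModel,
                        eval_anderson_weiss, sdr_invert, dnr_invert,
                        iron_from_chi)

sched = EchoSchedule.default(n_repetitions=3)
truth = RelaxationParams(S0=500, R2_micro=23, Omega2=0.85e4, R2_nano=10)
rng = np.random.default_rng(0)
clean = eval_anderson_weiss(truth, sched)
signal = np.hypot(clean + rng.normal(0, 2.5, 48), rng.normal(0, 2.5, 48))

res = TransverseDecayModel(signal, sched).fit()
print(res.summary())
sdr = sdr_invert(res.params.R2_micro, res.params.Omega2)
dnr = dnr_invert(res.params.R2_micro, res.params.Omega2)
print(f"SDR: delta_chi = {sdr.delta_chi:.2f} ppm, zeta = {sdr.zeta:.3f}")
print(f"     Fe(neuromelanin) = {iron_from_chi(sdr.delta_chi):.2f} mg/g")
print(f"DNR: tau = {dnr.tau*1e3:.2f} ms, radius = {dnr.radius:.2f} um")
```

prints

```
Transverse decay fit
============================================
model:        pade
n echoes:     48
S0:               500.7330
R2_micro*:         25.1478 s^-1
Omega^2:        10263.2320 rad^2/s^2
R2_nano:           10.0000 s^-1 (fixed)
R2* (total):       35.1478 s^-1
t_c:                2.4503 ms
MSE:                4.8533
AIC:               81.8233
converged:    True   bounds hit: False
QC:           pass ('ok',)
SDR: delta_chi = 2.31 ppm, zeta = 0.034
     Fe(neuromelanin) = 0.74 mg/g
DNR: tau = 1.02 ms, radius = 2.48 um
```

Reading the numbers: the voxel transitions from Gaussian to exponential
decay at t_c ≈ 2.5 ms, inside the echo window, so both Ω² and R2,micro\*
are identifiable.  Under static dephasing the decay is consistent with
inclusions of Δχ ≈ 2.3 ppm occupying ≈ 3.4% of the voxel — an
intracellular iron concentration of ≈ 0.74 mg/g if the iron is bound to
neuromelanin.  Under diffusion narrowing the same pair instead implies
field structures of radius ≈ 2.5 µm.  The QC line applies the exclusion
rules (mean squared residual ≤ 15, t_c ≥ 0.5 ms).

The same analysis runs on NIfTI volumes from the shell:

```bash
microrelax synth --out data --seed 3 --grid 5
microrelax fit data/rep1.nii.gz data/rep2.nii.gz data/rep3.nii.gz --out fits
microrelax invert --r2-micro-map fits/pade_R2_micro.nii.gz \
    --omega2-map fits/pade_Omega2.nii.gz --out inclusions --regime SDR
```

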