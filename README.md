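# sandimri

Cortical-microstructure analysis for multi-shell diffusion MRI: the
three-compartment SANDI model of the direction-averaged gray-matter
signal, a random-forest inversion, DTI/DKI scalar metrics, partial-volume
ROI aggregation, and the cohort statistics that relate regional
microstructure to age and normalized volume. A synthetic-cohort
generator emulates a 72-subject adult-lifespan study so the entire
pipeline runs, and is validated, without any scanner data.

It is written for diffusion-MRI methods researchers who want a tested,
reproducible reference for powder-averaged gray-matter modelling on
strong-gradient (Connectome-class) acquisitions, and for anyone who
needs the surrounding statistical battery (partial Pearson correlations
with covariates, Benjamini–Hochberg FDR, ANCOVA with post hoc t-tests,
Fisher r-to-z, quadratic age trends) in one place.

## The model

The spherical-mean (powder-averaged) signal at diffusion weighting *b*,
normalized by the *b*=0 signal, is modelled as three non-exchanging
compartments:

    S(b)/S0 = f_in·A_in(b; D_in) + f_is·A_is(b; r_s, D_is) + f_ec·A_ec(b; D_ec)

with T2-weighted signal fractions on the simplex `f_in + f_is + f_ec = 1`:

- **Neurites** — impermeable zero-radius sticks with parallel
  diffusivity `D_in`; powder average `A_in = √(π/(4bD_in))·erf(√(bD_in))`.
- **Somas** — impermeable spheres of apparent radius `r_s` with
  intrinsic diffusivity `D_is` (fixed at 3 μm²/ms); PGSE attenuation
  from the Gaussian-phase-distribution (Murday–Cotts) series with
  eigenvalues from the roots of d/dx[j₁(x)] = 0.
- **Extracellular space** — isotropic Gaussian pool,
  `A_ec = exp(−b·D_ec)`.

The acquisition is the 8-shell Connectome protocol (b = 0.05–6 ms/μm²,
Δ = 19 ms, δ = 8 ms, 32 or 64 directions per shell, interspersed b=0).
Inversion follows the published recipe: simulate 10⁵ parameter
combinations uniformly within the fitting priors, add Rician noise at
σ = 1/SNR, and train a random-forest regressor (200 trees) mapping the
8 shell means to the five free parameters; `f_ec` comes from the simplex
constraint. A Monte-Carlo random-walk simulator (reflecting sphere, PGSE
phase accrual) serves as the independent oracle for the sphere signal.

## Worked example

```python
import numpy as np
from sandimri import SANDIParams, sandi_signal, fisher_z_compare
from sandimri.protocol import CONNECTOME_SHELLS, b_to_gradient

p = SANDIParams.from_free(f_in=0.3, f_is=0.3, r_s=8.0, D_in=2.0, D_ec=1.0)
print(np.round(sandi_signal(p).values, 4))
# [0.9639 0.7795 0.5815 0.3903 0.2561 0.1745 0.1229 0.0963]
print(round(b_to_gradient(6.0, delta=8.0, Delta=19.0), 1))
# 283.2        (mT/m needed for the b=6 shell; scanner limit is 300)
z, pval = fisher_z_compare(-0.69, 72, -0.31, 72)
print(round(z, 2), round(pval, 3))
# 3.1 0.002    (occipital: microstructure-age beats volume-age)
```

The signal vector is the normalized spherical mean at the 8 shells: it
decays from ~0.96 at b=0.05 to ~0.10 at b=6, where the extracellular
pool is fully suppressed and sticks plus somas dominate. The Fisher
comparison shows a soma-fraction–age correlation of −0.69 is
significantly stronger than a volume–age correlation of −0.31 at n=72.

## The analysis

Numbered drivers under `analysis/` rerun the study stages and write
their tables to `results/`:

1. `01_protocol_and_forward_model.py` — builds the protocol, tabulates
   shells and gradient amplitudes, and validates the sphere series
   against the Monte-Carlo walker.
2. `02_noise_propagation.py` — 1000-draw parameter-recovery experiment
   at SNR 10¹⁰ and 50 (bias / RMSE / correlation per parameter).
3. `03_synthetic_cohort_study.py` — full synthetic study: demographics
   (33/21/18 subjects, 40 F), age-dependent ground truths, directional
   signal synthesis with Rician noise, forest inversion, ROI tables,
   correlation/ANCOVA/trend statistics, and a planted-vs-recovered
   recovery report.
4. `04_worked_examples.py` — the summary-statistics examples above.

A caveat the recovery report makes explicit: at these pulse timings the
soma compartment's powder-averaged attenuation is mono-exponential in b,
so it competes with the extracellular ball and the soma parameters are
only weakly identifiable; recovered effect sizes for `f_is`, `r_s`,
`D_in` are attenuated relative to the planted ones. See
`docs/methods.md` for the quantitative analysis.

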