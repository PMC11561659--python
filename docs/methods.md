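# Methods

## Signal model

The direction-averaged (spherical-mean) diffusion signal in gray matter
is modelled as three non-exchanging compartments — sticks (neurites),
impermeable spheres (somas), and an isotropic Gaussian pool
(extracellular space):

    S(b)/S0 = f_in·A_in(bD_in) + f_is·A_is(b; r_s, D_is) + f_ec·exp(−b·D_ec),
    f_in + f_is + f_ec = 1.

Units throughout: b in ms/μm² (1 ms/μm² = 1000 s/mm²), diffusivities in
μm²/ms, radii in μm, times in ms. File readers convert FSL-style
s/mm² b-values automatically (any value above 50 implies s/mm²).

**Stick.** `A_in = √(π/(4bD_in))·erf(√(bD_in))`, the closed-form powder
average of `exp(−bD_in cos²θ)`. Below `bD_in = 10⁻⁶` a 3-term Taylor
series replaces the 0/0 expression. Validated against numerical
averaging over 10⁴ quasi-uniform directions (agreement < 10⁻³; in
practice ~10⁻⁸ with the Fibonacci lattice).

**Sphere.** Gaussian-phase-distribution (Murday–Cotts) series for a
rectangular PGSE pair, with eigenvalue constants μ_m from the roots of
d/dx[j₁(x)] = 0 (first root 2.0816) and α_m = μ_m/r_s. The gradient
factor is derived from b via the PGSE relation b = γ²g²δ²(Δ−δ/3), which
inside the series reduces to (γg)² = b/(δ²(Δ−δ/3)) in 1/(μm²·ms²) —
no unit conversions enter. The series is truncated at 30 roots with a
convergence guard (last term below 10⁻⁶ of the sum); terms decay fast
for these timings. Intra-soma diffusivity D_is is fixed at 3 μm²/ms and
exposed in configuration.

**Validity of the sphere approximation.** The package ships an
independent Monte-Carlo oracle (`sandimri.mc`): walkers uniformly
seeded in an impermeable sphere, Gaussian steps with radial-mirror
reflection, PGSE phase accrual, signal = ⟨cos φ⟩. The walker is itself
validated against `exp(−bD)` in the free-diffusion limit (< 0.7%
absolute at b ≤ 2) and converges in step count. Against this oracle the
GPD series agrees to ≤ 0.2% at r_s = 3 μm and ≤ 1.7% at r_s = 5 μm
across all 8 shells, and to ≤ 2% for every radius at b ≤ 0.8. At
r_s ≥ 8 μm on the strongest shells the series overestimates the signal
by up to ~0.04 absolute (over 100% relative on near-zero signals): the
b = 6 shell needs g ≈ 283 mT/m, which pushes the gradient length
(D/γg)^(1/3) ≈ 3.4 μm below the radius — outside the Gaussian-phase
regime. We keep the GPD form because it is the standard SANDI kernel;
the validation table (`analysis/01`, `results/forward_validation.csv`)
quantifies where it is trustworthy.

## Inversion

Training labels are drawn uniformly in the fitting priors —
D_ec, D_in ∈ [0.25, 3] μm²/ms, r_s ∈ [1, 12] μm, f_in, f_is ∈ [0, 1] —
with rejection resampling of draws violating f_in + f_is ≤ 1 so f_ec is
a proper fraction; features are the 8 noise-corrupted shell means (b=0
is excluded: identically 1). A multi-output random forest (default 200
trees, 10⁵ samples; other tree hyperparameters at library defaults) maps
features to the five free parameters; labels are scaled to the unit cube
during training so the variance-based split criterion weighs all outputs
equally (r_s spans 1–12 while fractions span 0–1), and predictions are
un-scaled on the way out. Because forest predictions average in-range
labels, estimates cannot leave the prior box. `f_ec = 1 − f_in − f_is`
at prediction, clipped to [0,1] with a flag. The model object stores its
priors, training σ, protocol fingerprint (shell b-values, δ, Δ), and
seed; prediction refuses data whose fingerprint differs.

**Identifiability.** At fixed (δ, Δ) the GPD sphere attenuation is
exactly `exp(−b·D_eff(r_s))` — mono-exponential in b — so the soma
compartment is formally a second ball. D_eff rises from ~0 at 1 μm to
1.07 μm²/ms at 12 μm and overlaps the extracellular prior, making
(f_is, r_s) vs (f_ec, D_ec) quasi-degenerate wherever D_eff ≈ D_ec.
Quantitatively, training signals within 0.003 (Euclidean, 8 shells) of
each other span an f_is range comparable to the prior itself, and the
unconstrained Cramér–Rao bound for f_is at a cortex-like operating point
exceeds the parameter's plausible biological range by two orders of
magnitude at realistic noise. Practical consequences, all visible in the
shipped experiments: noise-free forest recovery of f_is correlates only
weakly with truth; recovered effect sizes for f_is, r_s, D_in in the
synthetic cohort are attenuated relative to planted ones; and f_ec's
recovered age-trend can flip sign because it is the simplex complement
of an exaggerated f_in. Short gradient pulses (smaller δ) shrink D_eff
and would restore separability; with this protocol the degeneracy is a
property of the experiment, not of the fitting code.

## Noise

Magnitude (Rician) noise: `S_n = √((S+N_r)² + N_i²)` with N_r, N_i ~
Normal(0, σ²), σ = 1/SNR of b=0. SNR 10¹⁰ is represented exactly as
σ = 10⁻¹⁰ rather than σ = 0. σ can be estimated from ≥ 3 b=0 replicates
(per-voxel SD/mean, median over the mask) or supplied directly. The
noise-propagation experiment draws 1000 parameter sets from narrow
prior-interior ranges (D_ec ∈ [0.5, 1.5], D_in ∈ [1, 2], r_s ∈ [5, 11],
f_in, f_is ∈ [0.1, 0.5]), reuses the same draws at both SNR levels
(paired comparison via seed substreams), and reports bias, RMSE and
Pearson correlation per parameter. For the noise-ablation comparison one
regressor — trained noise-free — is evaluated at both SNRs, so the
contrast isolates the effect of measurement noise; training at the
matching σ per level is available but confounds estimator change with
noise change.

## DTI / DKI

DTI (FA, MD, AD, RD) uses only the b = {0, 0.8} subset and DKI (AK, RK,
MK plus the tensor scalars) the b = {0, 0.8, 1.5, 2.4, 3.45} subset; the
b = 0.05 shell is excluded by default (configurable). Both fits are
two-pass weighted linear least squares on the log signal, with weights
equal to squared predicted signals from the first (OLS) pass. The DKI
design fits `ln S = ln S0 − b·D(n) + (b²/6)·V(n)` with V = MD²·W;
W is recovered after MD. Apparent kurtosis along n is MD²W(n)/D(n)²;
AK is taken along the principal eigenvector, RK averages 64 directions
on the perpendicular circle, MK averages 256 quasi-uniform directions
(validated by exact self-recovery on cumulant-generated signals, so the
numerical average introduces no error on the model class). No positivity
constraints; unfittable voxels (non-positive signals, rank deficiency)
are flagged, never clamped.

## Regions and volumes

ROI means include only voxels with partial-volume weight strictly
greater than 0.5 and a valid fit flag, unweighted by default (a
weighted-mean option exists). Region volume is the plain weight sum
times voxel volume — every fractional voxel contributes, with no
threshold — normalized by the intracranial volume. The two conventions
are deliberately different and separately tested.

## Statistics

- Partial Pearson correlation: correlate OLS residuals of x and y on
  the covariates (sex coded F=0/M=1; optionally a free-water-fraction
  column); p from t = r√((n−2−k)/(1−r²)). Invariant to the binary
  coding of sex.
- FDR: Benjamini–Hochberg step-up, applied within one results table
  (one metric set × region set × target) by default; a global family is
  available.
- Group comparison: ANCOVA F from the residual-sum-of-squares ratio of
  group-dummies+sex vs sex-only OLS models; post hoc Student's
  (equal-variance) t for the three pairs with BH-FDR; Welch optional.
- Fisher r-to-z compares correlation *strengths*:
  z = (atanh|r₁| − atanh|r₂|)/√(1/(n₁−3) + 1/(n₂−3)), sign positive when
  the first is stronger. The independent-samples formula is the default
  even when the two correlations share a variable; a Steiger-style
  dependent variant is provided but non-default.
- Age trends: nested linear/quadratic OLS with R²; peak age −β₁/(2β₂)
  reported only for concave fits with the vertex inside the observed
  age range.
- Normality screening: one-sample KS against Normal(mean̂, sd̂) without
  the Lilliefors small-sample correction — flagged as a screening
  statistic only.
- Age groups: young ≤ 34, middle 35–54, older ≥ 55 years.

## Synthetic cohort

The generator emulates a 72-subject cross-sectional study: three groups
of 33/21/18 subjects with truncated-normal ages (25.5 ± 3.6 in [19,34],
44.3 ± 6.6 in [35,54], 67.1 ± 7.7 in [55,85]) and fixed sex counts
(18/13/9 female). Per region, each SANDI metric follows
`intercept + slope·age (+ quad·age²) + Normal(0, σ_res)`, with σ_res
solved from the realized age SD so the expected correlation with age
hits a target: σ_res = |slope|·sd(age)·√(1/r² − 1). Default cortex
targets carry the sign structure of an aging cortex — f_is −0.75,
r_s −0.44, D_in −0.25 declining; f_in +0.33, D_ec +0.46 rising; f_ec
derived from the simplex and rising because the f_is decline dominates —
and a second "null" region has zero slopes throughout as the negative
control. Normalized region volume declines with age (target −0.74).
Trajectory intercepts and slopes are fixture values chosen inside the
fitting priors, not measurements; out-of-bounds residuals are redrawn.
A per-subject free-water fraction (target age-r +0.5) is emitted for the
optional-covariate analysis path.

Signals are synthesized directionally: per record a random stick
orientation, per protocol volume the stick/sphere/ball mixture, Rician
noise at σ = 1/SNR (default SNR 50) added to every directional signal
*before* shell averaging, and normalization by the mean of the noisy b=0
volumes — reproducing the small Rician floor and the √N noise reduction
that in vivo spherical means carry. At SNR → ∞ the shell mean equals the
discrete 32/64-direction average, which differs from the analytic powder
average by up to ~5·10⁻³ (finite-direction error), not by zero.

What the generator does **not** emulate: anatomical geometry and
partial-volume structure at the voxel level (region summaries are
simulated at the record level; voxel-grid code paths are tested with
separate synthetic weight maps), compartmental T2 differences, exchange,
orientation dispersion of the signal across a voxel beyond a single
stick orientation, and scanner artifacts. Passing tests therefore
validate the estimation and statistics chain under the model's own
assumptions, not the biological accuracy of SANDI in tissue.

## Problem sizes and numerical choices

The shipped experiments run on one CPU in minutes: forest training at
2·10⁴ samples / 50 trees for the recovery experiments (the in-vivo-scale
default of 10⁵ / 200 is available through the same functions), 1000
noise-propagation draws, 10⁵ walkers × 10³ steps per radius for the
Monte-Carlo oracle, and 20 cohort replicates for the seed-coverage
checks. Master seeds expand into independent substreams
(`numpy.random.SeedSequence`) per stage, so every table is reproducible
from one integer and parameter draws are shared across paired arms.
Shell grouping uses a 0.049 ms/μm² tolerance and rejects order-dependent
(ambiguous) clusterings; voxels with non-positive b=0 means are flagged
unfittable and excluded from ROI means.

## Known limitations

- The soma/extracellular degeneracy described above is the dominant
  error source for f_is, r_s and D_in at this protocol; treat those
  maps as prior-regularized, attenuated estimates.
- The GPD sphere kernel is unreliable at r_s ≥ 8 μm on the b ≥ 2.4
  shells (localization regime); the Monte-Carlo module is the reference
  there.
- KS normality p-values without the Lilliefors correction are
  conservative screens, not exact tests.
- The ANCOVA power for a 1-SD shift in the smallest group at n =
  (33, 21, 18) is ≈ 0.89, so single-study non-significance of a real
  group effect of that size is expected in ~1 run in 9.
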