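# Methods

`dietmri` re-implements, as a tested pipeline, a longitudinal
multiparametric MRI and HRMAS workflow for diet-intervention studies in
mouse brain. Because the original animal data are not redistributable, the
package ships a first-class synthetic-data module that generates every
input with known ground truth, and all validation is phrased as recovery of
that ground truth. This note records the models, the defaults and why, the
numerical choices, and what the synthetic conditions do and do not show
about real data.

## Signal models and map fitting

Each quantitative acquisition follows a closed-form single-compartment
model per voxel:

* T2 relaxometry: S(TE) = S0 · exp(−TE/T2), 50 echo times log-spaced on
  12–600 ms (the acquisition is specified only by its open range and
  count; log spacing samples the decay efficiently and is the package's
  default, overridable).
* Diffusion: S(b) = S0 · exp(−b·D) with b in s/mm² and ADC reported in
  μm²/s, so the exponent is b·ADC·10⁻⁶ (1 μm²/s = 10⁻⁶ mm²/s). Nine
  b-values evenly spaced on 200–2000 s/mm² (male protocol) or
  {300, 750, 1200} s/mm² (female protocol); when three orthogonal gradient
  directions are present the signals are arithmetically averaged before
  fitting (geometric mean available in config — whether the original
  program averaged signals or fitted per direction is not recoverable).
* Magnetization transfer: MTR = (S0 − S_MT)/S0 · 100 from the
  saturation-off/on pair; b-value arithmetic follows
  b = γ²δ²G²(Δ − δ/3) with γ the proton gyromagnetic ratio.

Fitting uses a weighted log-linear least-squares initializer (exact on
noise-free data) refined by a damped, bounded Gauss–Newton iteration on the
exponential model (relative tolerance 10⁻⁸, 200 iterations). The refinement
matters under magnitude (Rician) noise, where the log transform alone is
biased. Fitting bounds (1 ≤ T2 ≤ 2000 ms, 0 ≤ ADC ≤ 4000 μm²/s) are
deliberately wider than the retention filters so that filtering happens
once, at the ROI stage. Voxels that fail to converge, land on a rate bound
(e.g. a constant series, T2 → ∞), or have non-positive amplitude are
flagged invalid and carried as NaN; a flat diffusion series is the one
deliberate exception (ADC = 0 is representable and is removed later by the
strict 0 < ADC filter).

## ROI extraction and filtering

Manual per-animal ROI delineation is replaced by a deterministic geometric
template with the protocol voxel counts: hypothalamus 7×10 rectangle
(70 voxels), hippocampus two 5×6 blocks (2×30), nucleus accumbens two
40-voxel ovals, infralimbic area a 20-voxel circle. Oval and circular masks
take exactly the n closest grid voxels in the elliptic metric with a
deterministic tie-break, so realized counts match the contract exactly and
masks are reproducible. Voxel values then pass strict retention filters
(30 < T2 < 80 ms, 0 < ADC < 1200 μm²/s, MTR > 0) that remove CSF-containing
voxels and artifacts, are averaged per ROI and animal, and per-ROI means
outside [Q1 − 1.5·IQR, Q3 + 1.5·IQR] within each diet × day × region group
are discarded. Quartiles use linear interpolation between order statistics
(the common spreadsheet/statistics default; the convention is exposed
because it changes small-sample fences), and groups with fewer than four
observations skip outlier removal — fences on so few points are
meaningless.

## Longitudinal mixed models

Per-ROI means are log-transformed and fitted to a nine-model chain
B → A → AT → ATrs → ATrsD → ATrsD.TA → ATrsD.TA.DT → ATrsD.TA.DT.DA →
ATrsD.TA.DT.DA.DAT, each adding one fixed term (area, categorical time,
diet and their interactions) or, at the "rs" step, a per-mouse random slope
in day rescaled to [0, 1]. All models share the random structure: a random
intercept per mouse, a random intercept per area nested within mouse, and
AR(1) correlation among residuals of successive time points within each
mouse × area series (indexed by time-point rank, not calendar day, so the
correlation structure describes successive measurements). An alternative
reading — the random slope at the mouse × area level — is possible from the
protocol description; the mouse-level slope is the default because the
"rs" models are described as subject-dependent time variation.

The fitter profiles the fixed effects (GLS) and the residual scale out of
the Gaussian likelihood, leaving a 3–4-parameter Nelder–Mead optimization
over log variance ratios and arctanh φ (tolerances 10⁻⁶/10⁻⁸, one restart
on non-convergence). Balanced designs share a single per-mouse covariance
factorization, which keeps a full-ladder fit under a few seconds at study
size. The implementation is cross-checked in the test suite against
nlme::lme (nested intercepts, diagonal random slope, corAR1) on identical
data: log-likelihood, AIC and φ agree to ~10⁻².

Model comparison uses ML (REML likelihoods are not comparable across
different fixed-effect structures) with AIC = −2·logLik + 2k, k counting
fixed coefficients plus variance parameters, matching nlme's convention;
ties within 10⁻⁶ go to the simpler model, and non-converged fits are
excluded with a logged reason. The chain is examined as specified — not all
subsets — and exactly interpolated (noise-free) responses short-circuit the
variance optimization, whose surface is then unbounded. The selected model
is refit by REML for all reported coefficients, Type III Wald chi-square
tests (valid under the sum-to-zero contrasts used throughout), and
day-versus-baseline contrasts. Each diet × region family of four contrasts
is Dunnett-adjusted via the joint multivariate normal rectangle probability
of the four statistics with correlation taken from the fitted covariance
(the large residual df make the normal and t references indistinguishable
here; the test suite verifies agreement with a 10⁵-draw max-|z| Monte-Carlo
oracle to < 0.005). Diagnostics report whitened (Cholesky-standardized)
residuals, which are i.i.d. standard normal under a correctly specified
model, with a Shapiro–Wilk summary.

Literature spellings of the interaction models vary (TA vs AT order); the
package canonicalizes to the "TA" order and accepts the alternates as
aliases.

## HRMAS quantification

Spectra are modelled as non-negative linear combinations of unit-area
metabolite basis spectra plus an order-2 polynomial baseline (BVLS).
The synthetic basis uses Gaussian peak mixtures at textbook chemical
shifts for 21 metabolite/lipid signals; real basis line shapes are not
recoverable, which is immaterial for validating the fitting machinery.
The per-metabolite precision estimate, sd_percent = 100·SE/amount with the
noise variance estimated from the basis's signal-free ppm window, is a
covariance-based relative standard error standing in for an LCModel-style
%SD; its role — a quality filter at ≤ 20 (boundary inclusive) — is
preserved. Amounts are reported as ratios to total creatine (Cr+PCr),
together with the conventional composite sums; ratios are invariant to
global spectrum scaling.

Per-metabolite group comparisons fit diet + area with and without their
interaction, with a mouse random intercept (at one observation per
mouse × area the nested area-within-mouse intercept is confounded with the
residual, so the "area/mouse" structure collapses to the mouse intercept);
these ordinary mixed fits use statsmodels MixedLM. A likelihood-ratio test
between the ML fits at α = 0.05 decides the interaction; the chosen model
is refit by REML. Wald chi-square statistics per term are referenced
against an F distribution with classical containment denominator df
(between-mouse terms against the mouse count, within-mouse terms against
the residual observations) — with 16 mice the asymptotic chi-square
reference is visibly liberal, and the containment correction restores
near-nominal Type I error, as the calibration tests verify. When the
interaction is retained, per-area diet contrasts are Bonferroni-adjusted
over the four areas (the correction for these post-hocs is not otherwise
specified).

## Power analysis

Sample-size reasoning uses the classical repeated-measures noncentral-F
formulation with λ = f²·N·m·ε/(1−ρ), numerator df (m−1)ε for within designs
and (g−1)(m−1)ε for within-between interactions, denominator df
(N−g)(m−1)ε, ε = 1 (sphericity) by default. The alternative convention
with a correlation-adjusted effect size is selectable, since sample-size
tools support both. The three study scenarios are built in
(f = 0.35/0.25/0.15, m = 5/5/20, ρ = 0.8). The target power behind the
study's printed per-scenario sizes is not stated; the package defaults to
0.80 (configurable), and at a target of 0.95 the three scenarios solve to
exactly 8, 7 and 8 subjects per group with consensus 8 — the printed
values — which the acceptance script recomputes. A seeded Monte-Carlo of
the actual repeated-measures F test (compound-symmetric data with unit
total variance, subject variance ρ) provides the independent check; the
analytic and simulated powers are constructed on the same noncentrality
convention and agree within Monte-Carlo error.

## Synthetic study conditions

Defaults mirror the study design: two diets (SD/HFD), 8 mice per
sex × diet group, days {0, 7, 14, 28, 70}, four regions. The cohort
generator draws log-scale responses X·β + mouse intercept +
area-within-mouse intercept + mouse slope·s(day) + AR(1) residual and
exponentiates; default variance components (σ_mouse = 0.05,
σ_area = 0.04, σ_slope = 0.03, σ_residual = 0.05 on the log scale,
ρ_AR = 0.3) correspond to ~4–8% coefficients of variation, the scale of
between-animal spread typical for regional T2/ADC/MTR means, with a ~10%
default diet effect. The digital phantom embeds the four template ROIs in
an elliptical other-brain background with a two-voxel CSF rim whose truth
values (T2 150 ms, ADC 2500 μm²/s, MTR 0) fall outside every retention
filter, so CSF removal is genuinely exercised. Image noise is Rician by
default (magnitude MRI physics), Gaussian retained for analytic tests.

Monte-Carlo problem sizes are chosen to keep each check's sampling error
well inside its decision band at desk scale: 50 replicates for selection
consistency, 500 for null calibration, 200 for interval coverage,
10⁴ draws for power and noise-distribution checks; calibration cohorts use
study-sized groups on a reduced grid (2 regions × 3 days).

What passing these conditions does not show: the phantoms are geometric
stand-ins without anatomy, partial-volume gradients, motion, or coil
inhomogeneity; the cohort model is exactly the fitted model class (no
misspecification stress beyond the ladder's own submodels); spectra carry
neither lineshape distortion nor baseline structure beyond low-order
polynomials. Results on real data depend on those factors and on manual
ROI placement, which the template deliberately replaces.

## Known limitations

No multi-exponential, IVIM/kurtosis or diffusion-tensor models; no motion
correction or registration; the model ladder examines the specified chain
rather than all term subsets; no Bayesian or GEE alternatives; no absolute
(molar) metabolite quantification, phase/eddy-current correction or spline
baselines; the power module covers only the repeated-measures families
above.
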