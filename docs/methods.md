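# Methods

## Signal model and T1 mapping

All signals follow the steady-state spoiled-gradient-echo (SPGR / T1-FFE)
equation

    S = M0 · sin(θ) · (1 − E1) / (1 − cos(θ) · E1),   E1 = exp(−TR/T1),

with the effective flip angle θ = b1 · α, where b1 is the transmit-field
scale (actual/nominal flip ratio, 1.0 = nominal). Pre-contrast T1 and M0 are
estimated from images at ≥ 2 flip angles by the linearised DESPOT1 fit
(y = S/sinθ on x = S/tanθ; slope = E1). The linearised fit is closed-form and
vectorises over the volume; for three noiseless angles it is exact, and for
three-point VFA data a nonlinear refinement adds little. Voxels whose slope
falls outside (0, 1) — no signal, pure noise, or physically impossible E1 —
are flagged invalid and excluded downstream; values are never clamped,
because clamping silently biases regional means.

## Concentration conversion

The dynamic series is converted frame by frame. An effective M0 is anchored
per voxel so the SPGR model reproduces the measured pre-bolus baseline
(mean of the frames before the injection dynamic) at R1 = 1/T1_pre; each
frame is then inverted for E1(t) and

    C(t) = (R1(t) − R1_pre) / r1.

Frames whose magnitude meets the SPGR saturation ceiling M0·sinθ are not
invertible; they become NaN and are counted per voxel (a voxel with any such
frame in the fit window is excluded from the kinetic fit, with reason
recorded). Signal below baseline converts to negative concentration, which
is retained — clipping at zero would bias the low-leakage estimates this
application lives on — and counted as a QC flag. Echo-time (T2*) decay is
neglected, the standard approximation for T1-weighted DCE at low agent
concentration.

The plasma input function is taken from a sagittal-sinus ROI: each ROI voxel
is converted to blood concentration, averaged per frame, and divided by
(1 − Hct). Conversion precedes averaging because the signal equation is
nonlinear: averaging heterogeneous baseline signals first would bias the
curve. Kinetic quantities use minutes; acquisition metadata stay in
seconds/milliseconds and are converted at this boundary.

## Patlak estimation

Assuming unidirectional transport of gadolinium from plasma to the
extravascular extracellular space over the scan duration,

    C_t(t) = v_p · C_p(t) + K^trans · ∫₀ᵗ C_p(τ) dτ.

Both parameters are estimated per voxel by no-intercept ordinary least
squares with regressors C_p(t) and its running trapezoid integral, over a
window from the injection dynamic to the end of the series (configurable).
This is algebraically identical to the classical graphical (divided) Patlak
form on noiseless data but avoids amplifying noise by dividing by C_p.
C_p is zeroed before the bolus dynamic prior to integration — pre-bolus
samples are measurement noise, not tracer. Estimates are not constrained or
clipped; implausibility is handled at the subject level by a declared,
overridable QC rule (fail when the masked median v_p falls outside (0, 0.1]
or > 10% of voxels have v_p > 1). Bolus arrival is taken from the known
injection dynamic (the 8th frame in the default protocol) rather than
estimated per voxel.

## Default parameters

| Parameter | Default | Why |
| --- | --- | --- |
| r1 (relaxivity) | 3.5 s⁻¹ mM⁻¹ | typical of gadoterate at 3 T; config-overridable; estimates scale as 1/r1 |
| Hematocrit | 0.42 | population-typical; recorded with every VIF for provenance |
| Dynamics / spacing | 160 at 7.6 s | ~20 min acquisition, bolus on dynamic 8 (7 baseline frames) |
| VFA flips | 2°, 5°, 10° | three-point T1 mapping |
| Dynamic flip | 18° | above the Ernst angle for tissue T1 at this TR, maximising sensitivity to R1 change — the usual design choice for T1-weighted DCE; the exact protocol value is site-specific and configurable |
| TR | 5 ms | representative 3D T1-FFE value; configurable placeholder |
| Voxel size | 1.5 × 1.5 × 4 mm | acquisition geometry |
| Dose | 0.1 mmol/kg | standard single dose |
| QC thresholds | median v_p ∈ (0, 0.1], ≤ 10% of voxels v_p > 1 | declared and overridable; "non-physiological v_p" has no universal definition |
| Lesion threshold | 0.3, boundary-inclusive (≥) | probability cut for lesion binarisation; tie direction documented since toolbox conventions differ |
| Cluster rule | p < 0.001 one-sided, ≥ 50 voxels, 26-connectivity | corner-touching components merge; the one-sided maps are computed in both directions |

## The synthetic input function

The phantom's whole-blood curve is an exponential sum after onset,
C_b(t) = dose · Σ aᵢ exp(−mᵢ(t − t₀)). The default is three terms: the two
Weinmann-type distribution/washout terms (3.99 and 4.78 kg/L at 0.144 and
0.0111 min⁻¹) plus a fast first-pass term (21 kg/L at 1.5 min⁻¹) giving a
realistic ~5 mM plasma peak after a 0.1 mmol/kg bolus. Both features matter
for testing: the washout tail carries the integral that identifies K^trans,
and the first-pass peak is what makes v_p identifiable at all — a
washout-only curve renders v_p nearly unestimable, which no measured
sagittal-sinus curve does. Bolus dispersion is not modelled.

## What the phantom does and does not emulate

The phantom generates VFA stacks, a B1 field, truth maps and a 4D dynamic
series by running the forward physics above on piecewise-constant tissue
classes (white matter, grey matter, lesion, blood), with optional Gaussian
or Rician magnitude noise at per-voxel σ = baseline signal / SNR (Rician is
the physically appropriate default for magnitude MRI). Tissue concentration
uses the discrete-time uptake model on the acquisition grid — the same
trapezoid rule the fit uses — so that noiseless round-trip tests isolate
estimator error from quadrature error. Not simulated: head motion, scanner
drift, bolus dispersion, water-exchange effects (which bias v_p downward in
vivo), T2* effects, partial volume at tissue boundaries, and multi-site
differences. Passing round-trip and calibration tests therefore demonstrates
the correctness and statistical behaviour of the estimation chain, not
robustness to those real-world effects.

## The synthetic cohort

The cohort generator emulates a three-group study (healthy controls CN,
cerebrovascular-disease controls CP, patients PD; default sizes 31/15/49)
with regional K^trans and v_p means per group, a between-subject random
offset per metric and within-subject regional noise. Default regional means
sit in the published low-leakage range (K^trans of order 10⁻³ min⁻¹, v_p of
order 10⁻²), with K^trans elevated in PD mainly in substantia nigra,
normal-appearing white matter, lesions and posterior cortex, and v_p
slightly lower in CP. Covariates (age, gender, MoCA, LEDD, UPDRS, cube-root
WML volume) follow group-specific distributions centred on the study
population's printed summary statistics. `CohortDesign.null()` removes all
group differences for calibration experiments; `with_group_shift()` adds a
uniform shift in units of the between-subject SD for power/recovery
experiments.

## Statistics

**Repeated-measures ANOVA.** Group (between-subject) and region
(within-subject) with subject as the random blocking factor, implemented as
the exact split-plot decomposition via model comparisons: the
between-subject stratum is an OLS on subject means (group plus optional
age/gender/cube-root-WML covariates, drop-one F tests against the
subject-within-group mean square); region and group:region are tested
against the subject-by-region residual. For complete-data random-intercept
designs these F tests coincide with those of a linear mixed model with
Satterthwaite denominator df, while being exact and fast enough for
500-replicate calibration runs. Post hoc pairwise Welch t-tests on subject
means carry Bonferroni correction over the three group pairs
(p_corrected = min(1, 3·p_raw)); per-region uncorrected tests are also
emitted.

**Clinical mixed model.** Within the patient group, regional values are
modelled with fixed effects region, MoCA, LEDD, UPDRS (mean-centred) and
their region interactions, and a random subject intercept (REML via
statsmodels MixedLM). Per-term Wald F tests use between-within (containment)
denominator df — scores constant within subject against the between-subject
residual df, region terms against the within-subject residual df — which
matches Satterthwaite for balanced random-intercept designs. When the
subject variance collapses to the boundary the model degenerates to OLS and
the fixed-effects covariance is used, with a logged warning. Rows with
missing scores are dropped and counted; a constant score is dropped from the
model with a warning.

**Voxelwise comparison.** Welch's unequal-variance t with
Welch–Satterthwaite df per voxel (per-voxel n where data are missing),
Gaussian smoothing with FWHM in mm (σ = FWHM/2√(2 ln 2) per axis in voxel
units, reflective boundaries so constant fields are preserved), one-sided
supra-threshold clustering, and cluster-extent FWE control by permutation of
group labels: the null distribution of the maximum supra-threshold cluster
extent, corrected p = (1 + #{perm max ≥ observed})/(n_perm + 1), with exact
enumeration when fewer distinct label assignments exist than requested
permutations. Permutation replaces random-field theory deliberately: it is
distribution-free, needs no smoothness estimation, and is exact at any
sample size; the acceptance surface is calibration of the error rate, not
equivalence with a parametric implementation.

**Demographics.** Welch t-tests for continuous variables (consistent with
the unequal-variance choice made voxelwise; plain Student's t is a special
case whose pooled-variance assumption we have no reason to grant) and
two-sided Fisher exact tests for categorical ones, over all three group
pairs.

## Numerical and measurement choices

- Degenerate fits (zero signal, E1 outside (0,1), C_p ≡ 0) yield flags or
  NaN plus reason counts — never silent zeros.
- Masked-out and unfitted voxels carry NaN; regional means average valid
  voxels only and report the valid count.
- Trapezoid quadrature is used consistently for ∫C_p in both the phantom
  and the estimator; against the closed-form antiderivative of the default
  input function it agrees to < 0.5% at the 7.6 s sampling interval.
- Calibration problem sizes: ANOVA type-I error uses 500 null cohorts of
  3 × 15 subjects × 8 regions; cluster-FWE calibration uses 500 null
  replicates of 10 + 10 smoothed-noise maps on 16 × 16 × 8 grids with 199
  permutations; these sizes give Monte-Carlo standard errors of ~1
  percentage point on a 5% rate.
- The noise-performance benchmark (Rician SNR 20, K^trans 3×10⁻³ min⁻¹,
  v_p 0.02) reports medians over 20 000 simulated voxels: the v_p median
  sits near 9.7%, close enough to the 10% design bound that a 1000-voxel
  estimate (MC spread ≈ ±0.4 points) straddles it by chance; 20 000 voxels
  shrink the estimator error an order of magnitude below the margin being
  judged.
- All simulations are reproducible bit-for-bit under a fixed seed;
  per-component seeds are derived from one root seed.

## Known limitations

- The Patlak model ignores backflux; over ~20 min acquisitions with intact
  or subtly leaky BBB this is the standard operating regime, but K^trans is
  protocol-dependent and not comparable across very different durations.
- v_p from this model inherits the usual water-exchange underestimation in
  vivo; the phantom does not emulate that effect.
- The VIF is taken as measured (no partial-volume or inflow correction);
  the phantom's blood compartment is pure blood, which is optimistic.
- Motion correction, spatial normalisation, lesion segmentation and atlas
  construction are out of scope: masks, lesion probability maps and ROIs
  are inputs.
- The B1 map is an input; its own estimation errors propagate into T1 and
  hence concentration scale.
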