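# Methods

`oximc` simulates reflectance pulse oximetry on a layered skin model and
uses the simulated data to build and evaluate skin-tone-corrected SpO2
calibration models. This note documents the model, its parameters, the
numerical choices, and what the synthetic conditions do and do not show
about real measurements.

## The skin model

Skin is modelled as six laterally homogeneous plane-parallel layers:
epidermis, capillary loops, upper vascular plexus, reticular dermis, deep
vascular plexus and subcutis. Each layer carries volume fractions of
melanin (epidermis only), blood, water and fat, a thickness d (mm), a
refractive index n and a mean vessel diameter vd (mm). The bundled default
table is:

| layer            | Cm        | Cb    | Cw   | Cf   | d (mm) | n    | vd (mm) | pulsatile |
|------------------|-----------|-------|------|------|--------|------|---------|-----------|
| epidermis        | 0.01-0.43 | 0     | 0.20 | 0    | 0.1    | 1.33 | 0       | no        |
| capillary loops  | 0         | 0.04  | 0.65 | 0.17 | 0.15   | 1.37 | 0.01    | yes       |
| upper plexus     | 0         | 0.02  | 0.65 | 0.17 | 0.08   | 1.40 | 0.02    | yes       |
| reticular dermis | 0         | 0.004 | 0.65 | 0.17 | 1.2    | 1.40 | 0.02    | no        |
| deep plexus      | 0         | 0.04  | 0.65 | 0.17 | 0.5    | 1.40 | 0.04    | yes       |
| subcutis         | 0         | 0.03  | 0.05 | 0.90 | 5.0    | 1.44 | 0.05    | no        |

The melanin volume fraction f_m is the simulation's proxy for skin tone:
0.01 represents light skin, 0.43 very dark skin.

### Absorption

Layer absorption is the volume-fraction-weighted sum of chromophore
spectra, mu_a = sum_i f_i mu_a_i, in mm^-1. The epidermis uses

    mu_a_EP = f_m mu_a_mel + f_w mu_a_water + (1 - f_m - f_w) B(lambda),
    B(lambda) = 0.122 + 42.65 exp(-(lambda - 154)/66.2),

with the baseline constants read in mm^-1 (layer geometry is in mm; a
`baseline_unit="cm"` switch divides them by 10, since the literature also
quotes a cm^-1 variant of this baseline at one fifth the amplitude).
Dermal and subcutaneous layers use water, fat and the same residual
baseline; blood enters through the pulsatile terms below.

The bundled chromophore tables are anchor transcriptions of standard
compendia (hemoglobin extinction converted to whole blood at 150 g/L and
molecular weight 64,500; pure-water and fat absorption) and a melanin
power law 6.6e11 lambda^-3.33 cm^-1, resampled by piecewise-linear
interpolation onto a 1 nm grid over 400-1000 nm; queries outside that
range are rejected rather than extrapolated. Each file records its
provenance string. These are approximate stand-ins for the literature
curves: absolute reflectance values inherit their uncertainty, though the
structural features that drive pulse oximetry (red/NIR Hb-HbO2 contrast,
the ~800 nm isosbestic crossing, the steep melanin slope) are faithful.

### Vessel self-shielding

Blood is confined to vessels, so a voxel-homogeneous blood fraction
overstates absorption ("pigment packaging"). The effective diastolic blood
fraction is f_b(d) = f_b * S with

    S(x) = 1 / (1 + 1.007 (x/2)^1.228),  x = mu_a_blood * vd,

which tends to 1 for thin vessels or weak absorption and falls
monotonically otherwise. Whole-blood absorption interpolates linearly in
saturation: mu_a_blood = (1 - SaO2) mu_a_Hb + SaO2 mu_a_HbO2.

### Pulsation

During systole the arterial blood volume in the pulsatile layers (the
three vascular plexus layers by default) rises by the pulsatile constant
p = 0.5: f_b(s) = (1 + p) f_b(d). The accompanying layer expansion
(expansion factor E = 0.79) can be realised two ways, selected by
`systole_geometry`:

* `"equivalent"` (default): geometry fixed, mu_a = f_b(s) mu_a_blood +
  mu_a_baseline, mu_s unchanged. Expansion dilutes the conserved species
  (baseline absorbers, scatterers) by E while the layer thickens by 1/E,
  so their optical depths mu*d are unchanged — the fixed-geometry slab
  realises exactly those optical depths. Only the blood optical depth
  grows, by (1+p).
* `"expand"`: thickness d/E, mu_a and mu_s both diluted by E — the
  literal expanded geometry with the same optical depths.

The two are first-order equivalent in optical depth, but not in lateral
spreading: in `"expand"`, photons traverse geometrically longer paths and
exit at larger radii, which at this probe's near-zero source-detector
separation changes the detected signal by several percent regardless of
blood — an artifact of realising a volumetric expansion as purely vertical
thickening, and it almost completely masks the SaO2 dependence of the
ratio of ratios. The `"equivalent"` realisation keeps the classic R-SaO2
relationship (R ~ 2 at 50% SaO2 falling to ~ 0.3 at 100% for light skin)
and additionally lets paired diastole/systole runs share identical photon
trajectories (see Variance reduction). The epidermis contains no blood and
is phase-invariant.

### Scattering and anisotropy

Reduced scattering follows a power law with curvature C1 and an offset
C2 = 400^(C1-1) that pins mu_s'(400 nm) = mu_s0 * 577/400 independent of
C1:

    mu_s'(lambda) = mu_s0 (577 / lambda^C1) C2,  C1 = 0.5.

The epidermis steepens and brightens with melanin through calibration
functions alpha(f_m) = 1 + (f_m - 0.01) k_alpha (k_alpha = 22/3) and
beta(f_m) = 1 + (f_m - 0.01) * 20 applied as C1_EP = alpha * C1 and
C2_EP = beta * 400^(C1_EP - 1); both reduce to the global law at
f_m = 0.01. Scattering scale factors mu_s0 default to 3.3 (epidermis),
2.5 (dermal layers) and 1.8 mm^-1 (subcutis), chosen so that
mu_s = mu_s'/(1 - g) lands in the tens of mm^-1 typical of skin.
Anisotropy uses an affine model g(lambda) = 0.62 + 0.00029 lambda clipped
to [0, 0.99], per layer overridable. k_alpha, mu_s0 and g(lambda) are the
least constrained constants in the model (the sources only plot them);
they are config switches, and the absolute error metrics downstream are
sensitive to them (see Limitations).

## Monte Carlo transport

Photons are launched uniformly over a source disk (radius 0.2 mm,
normal incidence) concentric with a detector disk (radius 0.0667 mm) on
the top surface, emulating a fiber reflectance probe; the domain is bounded
laterally at 3 mm radius and in depth at 8 mm. Specular loss at the
ambient/epidermis interface is deducted analytically per photon. Transport
is weighted-photon with continuous absorption: free paths are sampled
against mu_s only, and the weight decays by exp(-mu_a l) along every
segment, deposited into depth bins split exactly at bin crossings.
Scattering angles sample the Henyey-Greenstein phase function with the
layer's g; internal boundaries apply Snell refraction with unpolarised
Fresnel reflection probabilities and exact total internal reflection.
Photons exiting the top surface are tallied as probe-detected if their
exit radius is within the detector, otherwise as diffuse reflectance;
bottom exits are transmittance, lateral exits side escape. Russian
roulette (threshold 1e-4, survival 0.1) terminates low weights with
exchange bookkeeping against the absorbed tally, so for every run

    specular + detected + diffuse + transmitted + side + absorbed = 1

holds to ~1e-13 (machine accumulation), not just in expectation. A
scatter-free slab degenerates to exact Beer-Lambert attenuation with zero
variance.

The RNG is xorshift128+, seeded per photon via splitmix64 from the run
seed, with substreams derived per run (wavelength, grid cell) from the
master seed through `numpy.random.SeedSequence`. Identical configuration
and seed reproduce results bit for bit.

### Variance reduction for AC/DC

The PPG observable AC/DC = (Rd - Rs)/Rd is a small difference of two
reflectances (1e-4 to 4e-3 here), far below the absolute MC noise of
independent desk-scale runs. Two choices make it measurable at 1e5
photons: (i) the diastole and systole runs of a pair share their seed, and
(ii) with absorption weighting and the `"equivalent"` systole geometry,
mu_s, g and the geometry are identical between the phases, so the paired
trajectories coincide photon by photon and only the absorption weights
differ. The AC/DC estimate then comes from weight ratios along shared
paths and its noise is roughly an order of magnitude below the
per-reflectance noise. This pairing is the principal desk-scale deviation
from brute-force independent high-photon runs, which would need ~1e8
photons for the same precision.

## From reflectance to the SaO2-R dataset

The sweep grid spans f_m = 0.01 to 0.43 (43 values at 0.01 steps by
default; 9 evenly spaced values in the reduced desk grid) and SaO2 = 0.50
to 1.00 (11 values; 6 reduced), at 655 and 940 nm, both phases — 1892
runs for the full grid, 216 reduced. AC/DC versus melanin is smoothed at
each (wavelength, SaO2) by A exp(B m) + C, fitted by *relative* (1/|y|
weighted) least squares: AC/DC spans one to two decades over the melanin
range, and unweighted fitting tracks only the bright light-skin points,
overshooting the dark-skin tail that dominates the high-melanin ratio of
ratios. Initialisation is A = first value, B = -1, C = last value; nearly
constant data falls back to a constant, non-convergence to raw
pass-through with a warning. R = AC/DC(655)/AC/DC(940) is computed from
the smoothed values by default (raw columns are kept alongside).

## Calibration models

The conventional mapping SpO2 = b R + c (linear) or a R^2 + b R + c
(quadratic) is fitted on the minimum-melanin slice only — deliberately
reproducing light-skin-heavy calibration practice — and evaluated over the
whole grid; the error map |SaO2 - SpO2| * 100 (percentage points) exposes
the skin-tone bias. The corrected candidate zoo comprises 25 forms:
melanin polynomials (cubic, quadratic or linear in m) added to one, two or
all three quadratic coefficient slots, a shared-coefficient variant (the
same melanin polynomial added to every slot, implemented as an equality
constraint, i.e. one design-matrix column per power), and vertex-form
variants alpha (R - h + P(m))^2 + k + Q(m). All non-vertex forms are
linear in their coefficients and solved by exact least squares on the full
grid (unweighted SpO2 residuals); vertex forms use Levenberg-Marquardt
from 8 deterministic starts derived from the conventional quadratic fit
(alpha = a, h = -b/2a, k = c - b^2/4a, perturbed in h and scaled in
alpha). Nesting therefore holds exactly: adding melanin terms never
increases in-sample loss.

Agreement is summarised by Bland-Altman statistics (bias = mean of
predicted - truth, 95% limits of agreement = bias +/- 1.96 sample SD) and
by the average and maximum of the absolute error map. Melanin-estimation
sensitivity re-evaluates a fitted model at m + delta and reports the added
error, with the largest tolerable |delta| under a configurable bound
(default 4 percentage points).

## Synthetic surfaces

For calibration testing without photon transport, any candidate model with
coefficients is inverted numerically: for each grid cell, SpO2(R, m) =
SaO2 is solved for R by bisection to 1e-12 after a monotonicity check on
the bracket (default (1e-9, 6)); optional Gaussian noise (sigma on R)
is seeded and reproducible. The emitted table is column-compatible with
the Monte Carlo dataset (AC/DC placeholders use a flat 5% NIR pulse).
These surfaces have exactly the generating model's geometry and
uncorrelated noise — unlike MC data they contain no structural
model-mismatch, which is why parameter recovery on them is exact.

## Problem sizes and runtime

Desk-scale defaults are chosen for a single CPU: 1e5 photons per run
(~1-2 s each), the reduced 9 x 6 grid (216 paired runs, ~5-6 min), and
1e3-5e4 photons in unit tests. The full 43 x 11 grid at 1e8 photons is the
brute-force reference configuration and is out of desk scope; all
quantitative desk results are therefore "scaled down" and carry MC noise
of a few percent in R at high melanin.

## What the tests show, and limitations

* The transport engine is verified against closed forms (Beer-Lambert,
  Fresnel, analytic absorption profiles), an independently coded naive
  photon loop, energy closure and 1/sqrt(N) convergence. These validate
  the mechanics, not the tissue parameters.
* The calibration layer is verified by exact parameter recovery on
  synthetic surfaces (noise-free to 1e-6; <5% relative at sigma = 0.001)
  and by structural properties on MC data (bias grows with melanin under
  light-skin calibration; corrected fits remove the trend).
* The headline *absolute* error metrics depend strongly on the
  under-constrained optical constants (melanin spectrum steepness,
  k_alpha, mu_s0, g). With the defaults here, the melanin-induced R
  shift is steeper (factor ~10 between f_m 0.01 and 0.43) than the ~4.5x
  implied by published corrected-model coefficients, so the residual
  errors of the low-order corrected models come out several times larger
  than the reference values, while the conventional-model bias magnitude
  (~50 points max) and the model-quality ordering (more melanin terms ->
  lower error; the b-slot placement best among 4-coefficient forms) are
  reproduced. Conclusions should be read at the level of orderings and
  trends, not absolute percentages.
* Real skin adds lateral heterogeneity, appendages, probe pressure
  effects, motion, and physiological variation in every parameter held
  fixed here; none are modelled.
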