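# Methods

This note documents the models, conventions and numerical choices behind
`radgem`, and what the synthetic-data generator does and does not emulate.

## Tumour volumes and growth curves

Calliper triples (length, width, height in mm) are converted to volume with
the standard calliper-ellipsoid convention

    V = (π/6) · l · w · h,

i.e. an ellipsoid whose semi-axes are half the measured dimensions. The
relative tumour volume (RTV) is V(t)/V(0), with day 0 the start of
treatment; a missing day-0 baseline is a configuration error, and missed
visits are propagated as gaps, never interpolated.

Group curves are arithmetic means with SEM over the animals still measured
on each nominal visit day (shrinking-n follow-up); the SEM of a
single-animal arm is defined as 0 so curves stay plottable. Each arm's
per-day ratio to the untreated control arm is the ratio of group-mean RTVs;
the control's own ratio is identically 1. Days are taken as nominal
schedule days — off-schedule visits are not binned or aligned, so input
tables must already carry nominal days.

## Progression and progression-free survival

Progression is scored per animal from its RTV trace: the first
post-baseline day with RTV strictly greater than 1, counted at or after
the day of minimal RTV. The nadir condition operationalises "after the
initial treatment response": a transient early excursion above baseline
that is followed by regression does not count, while for monotonically
growing tumours (nadir at day 0) progression is simply the first visit
above baseline — typically the first visit for untreated animals. An
animal killed before progressing is scored as an event at its kill day;
this treats humane-endpoint kills as progressions, which is a deliberate,
conservative choice (the alternative — censoring regressing animals at
kill — is not exposed because kill criteria are themselves
tumour-burden-driven). All other animals are censored at the end of
follow-up.

Progression-free survival uses the product-limit (Kaplan–Meier) estimator,
implemented directly: at each distinct event time t the curve is
multiplied by (1 − d_t/n_t) with n_t the number still at risk. Ties
between events and censorings are resolved events-first (censored-at-t
animals remain in the risk set at t). The median time to progression is
the smallest step time at which the curve falls to 0.5 or below; if the
curve never reaches 0.5 the median is reported as undefined rather than
extrapolated. No confidence intervals are attached to the curves.

## Internal dosimetry

The mean absorbed dose follows the MIRD formalism,
D = Ã · ΣᵢEᵢYᵢ · φ / M. With a time-activity *concentration* as input
(MBq/g), the mass cancels and the chain is:

1. Fit C(t) = C₀·e^(−λt) to the concentration data. The default fit is
   ordinary least squares on ln C vs t, which weights relative errors
   equally — appropriate for multiplicative (lognormal) measurement noise;
   a nonlinear least-squares variant is available for sensitivity checks.
   A non-decaying fit (λ ≤ 0) is an error, since the integral below would
   diverge.
2. Integrate analytically from injection (t = 0) to infinity: Ã = C₀/λ.
   The fitted curve is extrapolated back to t = 0 even when the first
   sample is later.
3. Convert: dose [Gy] = Ã [MBq·h/g] × 3.6×10⁹ decays/(MBq·h) × E [keV]
   × 1.602×10⁻¹⁶ J/keV × 10³ g/kg × φ.

Defaults model the beta-only contribution of ¹⁷⁷Lu (E = 147.9 keV,
φ = 1); photon cross-dose and voxel-level dosimetry are out of scope.
Inputs in %IA/g are converted to MBq/g via the injected activity before
fitting. Animal drug doses in mg/kg are converted to human-equivalent
mg/m² by body-surface-area scaling with a Km factor (3 for mouse), so
60 mg/kg ↦ 180 mg/m².

## Bliss-independence interaction

Per measurement day, on group-mean RTVs: the fractional response of an arm
is F = 1 − RTV_arm/RTV_control; two monotherapies predict the additive
combination response F_add = F_rad + F_gem − F_rad·F_gem (equivalently
1 − (1−F_rad)(1−F_gem)), and the predicted-additive RTV is
(1 − F_add)·RTV_control. The observed combination fraction is classified
synergistic / additive / antagonistic according to whether it lies above,
within, or below a tolerance band around F_add.

Two choices deserve comment:

* **Tolerance.** Exact equality of F_obs and F_add is measure-zero on any
  real data, so the strict three-way comparison (the function default,
  tolerance 0) always returns synergistic or antagonistic in practice. The
  pipeline default is a tolerance of 0.05, roughly three standard errors
  of F_obs − F_add for group means at study-scale arm sizes with 15%
  calliper noise; it is a classification band, not a statistical test, and
  no inferential procedure on F_obs vs F_add is provided.
* **Out-of-range fractions.** F < 0 (arm growing faster than control) or
  F > 1 breaks the probabilistic reading of Bliss independence; such
  values are passed through unclamped with a warning so the breakage is
  surfaced, not hidden.

## Group statistics

Per measurement day: a classical fixed-effects one-way ANOVA across all
arms (F = MS_between/MS_within) and all pairwise two-sided t-tests.
Pooled-variance Student's t is the default; a Welch option exists because
treated-arm variances can differ substantially. The Bonferroni–Holm
step-down adjustment (sort ascending, adjᵢ = min(1, max_{j≤i}(m−j+1)p⁽ʲ⁾))
is applied to the pairwise family. The default family is all pairwise
comparisons at one day, matching per-day reporting; an option widens the
family to all days × all pairs, which is the right choice when the claim
under test spans the whole follow-up (the null-study check in the test
suite uses it). ANOVA omnibus p-values are reported unadjusted. These
procedures are implemented from first principles; SciPy supplies only the
F and t tail probabilities.

## Quantitative IHC

Sections are analysed inside a hand-drawn tumour ROI polygon (pixel-centre
coordinates, origin top-left, x right / y down, 0-based). Colour
classification runs in HSV with precedence background → fold → positive →
counterstain:

* background/cracks: near-white (saturation < 0.10 and value > 0.85);
* folds: over-dark (value < 0.28);
* Ki67-positive: DAB brown (hue ≤ 0.14, saturation ≥ 0.35);
* MT collagen-positive: blue (hue 0.50–0.78, saturation ≥ 0.30);
* MT necrosis candidate: the pale, eosin-dominant class
  (saturation 0.10–0.38, value ≥ 0.70).

All thresholds are user-overridable; the shipped defaults are calibrated
against the synthetic renderer below and are a starting point for the
manual, pathologist-approved calibration that real slides require. The
necrotic/viable partition of the MT section applies morphological closing
(disk radius 2 px) to the pale class and discards connected regions below
a minimum area (default 2000 µm², a few cell diameters); the remainder is
viable. Quantification is area-based throughout: Ki67 positivity is the
positive area fraction of *viable* tumour only, MT positivity the fraction
of the whole artefact-free tumour area.

The MT-derived viable mask is transferred to the Ki67 section through a
least-squares landmark transform fitted to user-supplied control points.
Similarity (rigid + isotropic scale) is the default model — adjacent 4-µm
sections of the same block justify it — with affine available; collinear
points raise a rank error. Masks are resampled nearest-neighbour so they
stay binary; pixels mapping from outside the source frame are unlabelled.

## Synthetic data generator

**Growth.** Per animal,

    V(t) = V0 · v_gem(t) · [ f_s·ι · e^(g·t) + (1 − f_s·ι) · e^(−d·t) ] · ε(t)

with baseline V0 lognormal (mean 570 mm³, SD 406 mm³), control growth rate
g = 0.042 d⁻¹ (doubling ≈ 16.5 d, RTV ≈ 3.5 at day 30), a radiation
surviving fraction f_s whose complement regresses at d = 0.12 d⁻¹, a drug
factor v_gem(t) that accumulates a growth-rate multiplier during the
dosing window (days 0–13), and lognormal mean-1 measurement noise ε with
CV 0.15. The drug factor multiplies *both* compartments (the drug acts on
all tumour cells); a consequence worth stating explicitly is that with
interaction multiplier ι = 1 the combination arm satisfies
RTV_combo/RTV_ctrl = (RTV_rad/RTV_ctrl)·(RTV_gem/RTV_ctrl) identically, so
independent effects are exactly Bliss-additive in the noiseless mean and ι
is a clean dial for injecting synergy (ι < 1) or antagonism (ι > 1). Had
the drug factor been applied to the surviving compartment only, the
regression term would break this identity by up to ~0.08 in F even without
noise, making "independent" arms classify as antagonistic — the
two-compartment form above was chosen to keep the independence null exact.

The two-compartment shape is a stand-in producing the qualitative
radiotherapy pattern (nadir near day 13, regrowth at the control rate),
not a mechanistic radiobiological model. Calibrated presets put the
drug-arm ratio-to-control near 0.5 after the dosing window
(gem_multiplier = −0.36, i.e. mild net regression while dosing) and the
radiotherapy nadir near 0.6 (f_s = 0.25). Volumes are re-expressed as
calliper triples by inverting the ellipsoid product with bounded
anisotropy jitter, so volume round-trips exactly when noise is off. Kill
rules: an absolute volume cap (default 2500 mm³, standing in for "tumour
exceeds 10% of body weight" at ~25 g and unit density) and an optional
per-day toxicity hazard.

What the generator does *not* emulate: delayed onset of the radiation
response (the model nadirs too early relative to a real fractionated
response), inter-animal heterogeneity in treatment sensitivity, drug PK,
or correlated calliper errors. Passing tests therefore demonstrate that
the analysis chain recovers known ground truth under these idealised
kinetics — not that the kinetics themselves describe real xenografts.

**Tracer washout** is mono-exponential with lognormal noise.

**Section pairs.** An elliptical tissue region with one necrotic disc,
thin near-white cracks and dark elliptical folds is rendered on the MT
raster; the Ki67 raster is the same label map pushed through a known
similarity transform (nearest-neighbour), with four landmark pairs
returned as control points. Positive pixels are drawn to hit the
configured fractions exactly on the rendered rasters (collagen over all
artefact-free tissue; Ki67 positivity over viable tissue), and per-pixel
colour jitter (±4 of 255) keeps classes inside their threshold boxes. The
canvas is a downsampled overview (default 4 µm/px on a 384² default
canvas) rather than a native 0.25 µm/px scan, so physical-area parameters
such as the necrosis minimum region stay meaningful on a small raster.
Real-slide phenomena not rendered: stain intensity gradients, nuclear
texture, out-of-focus regions, capsule, and non-rigid section distortion
(the embedded transform is exactly similarity, which is also why
registration residuals in tests are at machine precision).

All generators are pure functions of (config, seed); the pipeline derives
per-module substream seeds from the single run seed by hashing the module
name, so outputs are byte-identical across repeated runs.

## Validation problem sizes

The test suite and the acceptance script use: 500 replicate washout fits
(CV 5%, 6 time points) for decay-constant recovery; 200 animals/arm for
effect-size and interaction-classification checks (group-mean SEM ≈ 1%);
1000 null replicates for type-I-error calibration of ANOVA and t;
exhaustive enumeration of all ≤ 6-observation event/censor configurations
(with ties) against a brute-force product-limit oracle; 1000 random
p-value families against an independent Holm construction; and 256²
section pairs across planted fraction grids. These sizes were chosen to
make Monte-Carlo noise small relative to the tolerances being checked
while keeping the default suite fast.

## Known limitations

* The pipeline analyses nominal visit days; real studies with ragged
  visit times need upstream alignment.
* The progression rule depends only on RTV and kill records; it cannot
  represent non-tumour deaths as competing risks.
* The dose chain assumes a single mono-exponential phase; biphasic washout
  will bias Ã (use the nls option and inspect residuals).
* Colour thresholds are calibrated to the synthetic palette; real slides
  require manual recalibration, and stain-separation alternatives to HSV
  thresholding are not implemented.
* The Bliss evaluation uses group means per day, so animal-level
  uncertainty in the synergy call is not propagated.
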