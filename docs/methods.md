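# Methods

## Spectral model

Widefield multispectral reflectance is converted to hemoglobin concentration
changes with the modified Beer–Lambert law.  For each wavelength band λ the
attenuation change relative to a baseline window is

    ΔA(λ, t, x, y) = −ln( R(λ, t, x, y) / R₀(λ, x, y) )
                   = [ ε_HbO(λ)·Δ[HbO] + ε_HbR(λ)·Δ[HbR] ]·L(λ)

where R₀ is the per-pixel mean intensity over a leading baseline window
(default the first 30 s of a recording, truncated to end before the first
pre-stimulus window), ε are molar extinction coefficients (1/(µM·cm)) and
L(λ) the effective, scattering-lengthened photon pathlength (cm).  With the
four bands used (494, 560, 575, 595 nm) the two-chromophore system is
overdetermined and is solved per pixel and frame by ordinary least squares;
Δ[HbT] = Δ[HbO] + Δ[HbR] by definition, and the implementation guarantees
this identity elementwise.

Assumptions and defaults:

- **Extinction coefficients** are band-center values from standard compiled
  hemoglobin absorption spectra.  The filter bandwidths (±20/±5/±14/±5 nm)
  are carried in the configuration but no band-averaging is applied.
- **Pathlengths** depend on baseline oxygen saturation, so the table is keyed
  by tissue class: "tissue" assumes 80% saturation (whisker region,
  parenchyma), "artery" 90%.  Baseline total hemoglobin is taken as 100 µM,
  so the resting split is 80/20 µM (tissue) or 90/10 µM (artery).  The
  shipped pathlength values are documented defaults, overridable via YAML.
  Because the synthetic forward model and the inversion share one table, the
  round-trip tests establish correctness of the algebra, not the absolute
  tissue realism of the table — which this package does not claim.
- The artery class changes only L(λ); the extinction weighting is
  saturation-independent in this model.
- Intensities must be strictly positive; non-positive values raise rather
  than clamp, so generator noise is truncated instead of silently masked.
- The unmixing design matrix is rejected when its condition number exceeds
  1e8 (configurable).

## Evoked-response maps and ROIs

The spatial response map is the trial-averaged difference between the mean
Δ[HbT] in a post-onset window and the pre-stimulus baseline window, per
pixel, standardized by the spatial mean and SD of the difference map.  If
the spatial SD is below 1e−12 an all-zero map is returned instead of
dividing by ~0.  Doubling the response amplitude leaves the z-map unchanged.

The whisker-barrel ROI is the set of "active" pixels with z > k (default
k = 1.5, SD taken over the entire map), reduced to the **largest 8-connected
component**, with ties broken in favour of the component containing the
global maximum.  The single-region reduction reflects the intent of finding
*the* region with the largest HbT increase; the connectivity choice is a
documented convention.

Artery/vein/parenchyma sub-ROIs are suggestions, not decisions: within the
whisker mask the pixel time series are decomposed by PCA (components below
1% of the leading singular value are ignored as numerical noise), the
component most correlated with a boxcar stimulus regressor is taken as the
stimulus-locked vascular signal, and the artery candidate is the top decile
of pixels by loading on it (restricted to positively responding pixels).
The vein candidate is the top decile of remaining pixels by HbR washout
depth; parenchyma is the rest of the whisker mask.  The three masks are
disjoint by construction.  Decile cutoffs are configuration; manually drawn
masks override any candidate exactly and are recorded as such in the mask
provenance, which is how the same vessel is kept across sessions of one
animal.

## Trials, locomotion, metrics

Trials span [onset−5 s, onset+20 s) for 2-s stimulations and
[onset−10 s, onset+60 s) for 16-s, half-open windows, 0-based frames;
trials whose window leaves the recording are dropped with a warning.  Each
trial's hemodynamic traces are re-zeroed by the mean of its pre-onset
segment.  Locomotion is resampled to the imaging clock by linear
interpolation before windowing.

Locomotion classification uses two windows — pre = [onset−4 s, onset) and
stim = [onset, offset+4 s) — and the 2×2 grid of "any (debounced) movement
in the window":

| pre | stim | category |
|-----|------|----------|
| no  | no   | 1 (rest) |
| yes | no   | 2        |
| no  | yes  | 3 (starts at onset) |
| yes | yes  | 4        |

This grid is the only reading under which the four categories are exhaustive
and mutually exclusive.  The movement threshold defaults to 0 (the sensor
emits zeros at rest and positive integers when moving); runs of moving
samples shorter than 0.125 s are ignored as sensor jitter (configurable).

Per-trial metrics are computed on the window from stimulus onset to 5 s past
onset (2-s protocol) or 20 s past onset (16-s), endpoints inclusive:
trapezoidal AUC (µM·s; a.u.·s for locomotion) and the maximum value.  The
main analysis uses the category-1 (rest) and category-3 (locomotion at
onset) subsets only.  For locomotion-ranking analyses, trials are ranked by
locomotion AUC ascending within each animal×session (stratification
configurable, pooled ranking available), and the bottom/top floor(0.2·n)
trials are flagged, ties broken by trial id.

## Group statistics

Trial metrics are compared across disease groups with a linear mixed model
carrying a random intercept per animal (REML).  Because group varies only
between animals, its error stratum is the animal level: the overall test and
the Tukey-adjusted pairwise contrasts use the between-animal mean square
with n_animals − n_groups denominator df.  On balanced data this is exactly
the test that Satterthwaite df reduce to; it avoids the small-sample
conservatism that REML variance truncation induces in naive Wald tests
(verified by simulation: type-I error within the binomial CI of 0.05 at 8
animals).  Variance components are reported from the REML fit; a failed or
boundary REML fit is flagged without invalidating the stratum test.  A
constant response yields a flagged degenerate result.

Trend analyses (metric vs trial number) report per-group Pearson r and a
two-stage OLS comparison: an interaction F-test for slope homogeneity,
followed — when slopes are homogeneous at α = 0.05 — by an intercept
(group offset) test.  Per-animal behavioral metrics pass a Shapiro–Wilk
gate on residuals (α = 0.05): one-way ANOVA with Tukey post hoc when
normal, Kruskal–Wallis otherwise.  Significance is fixed at p ≤ 0.05
throughout.

## Behavior (novel object recognition)

Exploration is scored per frame when the nose point is closer than 2 cm to
the object's **boundary** (not its center, so the rule is independent of
object size) and not inside the object footprint (climbing proxy).  Up to
10% of frames may lack coordinates and are filled by linear interpolation;
more raises an error.  The preference index is 100·t_novel/(t_novel +
t_familiar), undefined at zero total exploration.  Inclusion requires both
training objects explored ≥ 20 s (boundary inclusive).  Distance traveled is
the sum of centroid step lengths; mean velocity divides by session duration.

## Histology

Amyloid burden (% area) follows the pixel-count formula

    100 · (A + CAA_reclassified + CAA_added) / (T + A + CAA_reclassified)

in which manually *added* CAA pixels enter the numerator only — the formula
is implemented verbatim, asymmetry included.  Pixel classes come from
color-deconvolution thresholding (DAB optical density above 0.15 is
amyloid; remaining hematoxylin OD above 0.05 is tissue; the rest is
ignored); every class can be replaced by external masks, which models the
manual CAA reclassification workflow.  The thresholds stand in for a trained
pixel classifier and are not claimed to match it.

Plaque burden (% area) converts the aortic-arch image to 8-bit gray by the
standard luminance weights and counts pixels strictly below gray level 150
inside the hand-drawn arch polygon (lipid stain is dark); the polygon is
rasterized by the pixel-center rule, and content outside it cannot affect
the result.  Whether the original thresholding was < or ≤ 150 is not
recoverable; strict < is this package's documented convention.

## Synthetic data generator

The generator emulates, with machine-readable ground truth:

- **Stimulus-evoked hemodynamics**: a gamma-variate kernel (unit peak at
  2.8 s, shape 3) convolved with the stimulus boxcar; the 2-s response then
  peaks ≈3.9 s after onset, inside the 3.3–4.6 s range reported for awake
  whisker stimulation.  Spatially the response is a central Gaussian blob
  with an "artery" stripe (1.5× amplitude) and a "vein" stripe (doubled,
  0.5-s-delayed HbR washout).  HbO/HbR split: Δ[HbO] = 1.3·Δ[HbT],
  Δ[HbR] = −0.3·Δ[HbT] by default.
- **Reflectance rendering**: the exact inverse of the unmixing model, with
  optional multiplicative Gaussian noise truncated at 4σ (σ ≤ 0.2) so
  intensities stay positive.  σ = 0 gives exact round trips.
- **Locomotion**: Poisson bout onsets, lognormal durations, integer
  magnitudes; plus a deterministic scheduler that places bouts to realize a
  requested category per trial.
- **Cohorts**: four groups (WT/AD/ATH/MIX), 30 trials per 2-s session (15
  for 16-s), 32 Hz.  Default planted effect: ATH rest-response peak 1.5 µM
  vs 2.0 µM elsewhere (−25%).  Trial-level amplitude SD 0.25 µM and
  animal-level SD 0.08 µM were fixed by an a-priori power analysis of the
  reference design (8 animals × 30 trials, −25% deficit: analytic power
  0.85 for the animal-stratum test) and are plausible for trial-averaged
  awake imaging.  Behavioural model: when locomotion is concurrent with the
  stimulation (categories 3/4) the response is a shared locomotion-coupled
  amplitude (3 µM) identical across groups, so planted deficits appear only
  in rest trials — the rest/locomotion contrast the classification stage
  exists to expose.  A slow locomotion-coupled baseline component
  (0.05 µM/a.u., Gaussian-smoothed) is added to all groups.
- **Histology**: stain masks are smoothed-noise fields thresholded at the
  quantile that yields a pixel-exact planted fraction, rendered through the
  inverse stain-deconvolution transform (DAB) or as dark pixels on a light
  arch (Oil Red O).
- **NOR tracks**: alternating wander/visit bouts; each visit chooses the
  novel object with probability p and parks the nose 0.3–1.5 cm off the
  boundary, so the expected preference index converges to 100p.

What the generator does **not** emulate: photon transport and wavelength-
dependent scattering beyond the shared pathlength table, vessel morphology,
breathing/heartbeat artifacts, slow drifts, motion artifacts in imaging or
tracking, and realistic plaque morphology.  Passing tests therefore
establish the correctness of the analysis algebra and decision rules under
the stated statistical structure, not robustness to all real-data artifacts.

## Problem sizes and numerical choices

Tests run the full-scale spectral round trip at 64×64 px, 4 wavelengths,
60 s at 32 Hz; other imaging tests use 32×32 or 16×16 grids at reduced frame
rates, which exercise identical code paths.  The power and calibration
simulations use 200 replicates (planted effect, trace-level cohorts of
8 animals × 30 trials) and 500 replicates (null, metric-level draws of the
same structure); these sizes give binomial standard errors of ~2.5% and
~1%, adequate for the 0.8-power and α-calibration assertions.  Seconds are
the canonical time unit; windows are half-open except metric windows
(endpoints inclusive); frame indices are 0-based.  The z-map SD guard is
1e−12; the dhbt = dhbo + dhbr identity is enforced at 1e−9.

## Known limitations

- Absolute concentration scaling inherits the uncertainty of the default
  pathlength table; only relative/round-trip behaviour is validated.
- The vessel-ROI suggestion is a heuristic aid; analyses of specific vessels
  should use the manual-override path.
- The animal-stratum group test is exact for (near-)balanced designs;
  heavily unbalanced cohorts would warrant a dedicated Satterthwaite
  implementation.
- The DAB threshold classifier is a deterministic stand-in for a trained
  pixel classifier and will not match its boundary behaviour on real slides.
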