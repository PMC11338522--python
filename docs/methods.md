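# Methods

## Scope and design

The package separates three concerns: a forward model of the imaging
experiments (`synth`), the quantifiers that operate on images and tables
(`contact`, `intensity`, `frap`, `morpho`), and orchestration/statistics
(`pipeline`, `cli`). The quantifiers never see ground truth; the forward
model never calls the quantifiers. Every claim the test suite makes is a
parameter-recovery claim: simulate with known truth, quantify blind,
compare.

## Scene model

An axon segment is a straight cylinder of length L (default 30–40 µm) and
caliber `width_nm` (460–600 nm, the scale of developing axons), observed in
2D projection along the optical axis. One ER tubule of radius
`er_tubule_radius_nm` runs along the cylinder; its centerline meanders
laterally as a sum of three random-phase sinusoids (wavelengths 6–20 µm,
total amplitude 0.9 of the available headroom between tubule + binding
shell and the axon wall). The meander is a deliberate departure from a
perfectly straight, centered ridge: a straightened segment with a straight
tubule is mirror-symmetric, which would make the flipped-channel null
identical to the unflipped measurement and remove exactly the control the
estimator depends on. The amplitude/wavelength ranges are simulator
conventions, not anatomical claims; multiple tubules are supported
(`n_tubules`), one is the default, matching the few-long-tubules morphology
of axonal ER.

Ribosome-like puncta live in 3D. A punctum flagged *bound* sits at radial
distance `r_tubule + U(0, bind_distance_nm)` from the tubule centerline at a
uniform azimuth, hence within the binding distance of the tubule surface by
construction (with `bind_distance = 0` the limiting case puts it exactly on
the surface). Unbound puncta are uniform in the cylinder; when
`bind_distance > 0` they are rejection-sampled out of the binding shell so
the two classes are geometrically distinct and the ground-truth bound
fraction is identifiable. With `bind_distance = 0` no exclusion is applied —
that configuration produces genuinely uniform puncta and is what the
flip-null calibration tests use. Exactly `round(bound_fraction * n_puncta)`
puncta are bound. Amplitudes are lognormal with a configurable coefficient
of variation (default 0.25–0.3), mean 1.

The 3D-to-2D projection is what makes the contact geometry realistic: a
punctum bound anywhere on the tubule circumference projects to a lateral
offset of at most `r + bind`, most of the azimuthal mass projecting close
to the centerline, and unbound puncta in front of or behind the tubule
project onto it. A purely 2D placement model understates the overlap badly.

## Rendering

The ideal emitter map is the projected tubule (chord length
`2 sqrt(r^2 - d^2)` at lateral distance `d`) plus bilinearly deposited
puncta, convolved with an isotropic Gaussian PSF of the stated FWHM
(kernel truncated at 4 sigma, < 0.01% mass loss), scaled by `photon_scale`,
offset by a constant `background_level` (photons/pixel), then passed
through Poisson shot noise, additive Gaussian read noise, and a clip at
zero. The grid adds a 2.5 x FWHM margin on all sides; pixel centers sit at
`(i + 0.5) * pixel_size_nm`, thresholding is strict (`>`), and localization
histograms use half-open, origin-anchored bins. Rendering refuses
`pixel_size_nm > psf_fwhm_nm` (undersampling).

In noiseless mode total intensity equals `photon_scale * sum(amplitudes)`
up to kernel truncation; the test suite asserts this at 1%.

## Presets and the programmed effect sizes

`presets.yaml` (versioned) encodes one parameter set per experiment family.
The programmed effects are the quantity under test and are fixed:
condition-pair scale factors 0.71 / 0.70 / 0.63 (intensity or density
reductions of 29% / 30% / 37%), a 0.45 bound fraction at 30 nm binding
distance imaged at 60 nm FWHM / 20 nm pixels, and a 1.75-fold branch-window
density enrichment. Photon budgets, puncta densities, tubule radius and
axon caliber are free conventions: the imaging literature gives no values
for them, so they were chosen once at realistic magnitudes and so that the
contact preset's measured fraction falls in the experimentally reported
40–50% band and the estimators reach useful precision at the reported
sample sizes (n = 30 segments/group, 20 contact segments, 16 branched
segments). In particular the STED-like preset uses a 75 nm effective
tubule radius — an imaging-scale convention absorbing marker distribution
and residual blur, not a membrane-geometry claim — and 240 puncta per
30 µm segment (8/µm); the ribosome-density preset uses 500 puncta per
40 µm (12.5/µm) so that a density-based 37% reduction is estimated with
~1-point precision.

Condition pairs derive per-image streams by hashing
`(master_seed, group, index)` through `numpy.random.SeedSequence` spawn
keys, so groups are reproducible and extensible in parallel. Scenes are
unpaired across groups by default; `paired_geometry=True` re-uses control
geometry in the test group, which with noiseless rendering makes the
group-mean ratio exactly the scale factor (asserted in tests).

## Contact estimator choices

- Threshold: Otsu by default (parameter-free, reproducible), fixed-value
  override available. A constant image is a degenerate input, not a mask.
- The "enlarged" mask is the filled dilation (original ∪ ring), not the
  ring alone, so mask ⊂ enlarged and the two fractions are nested measures;
  the ring reading remains computable as their difference.
- A 5 nm enlargement is sub-pixel at any realistic pixel size; it rounds up
  to one pixel because a zero-pixel dilation would collapse the two
  reported measures into one.
- The flip mirrors the *ribosome* channel about the vertical midline
  (along-axon axis in straightened segments), leaving the ER mask and the
  axon's transverse intensity envelope untouched.
- Fractions are intensity proportions over the whole segment crop;
  background photons therefore dilute them, which is faithful to how the
  measurement behaves on real crops.

## Intensity measurements

Line profiles resample the image bilinearly at ~1-pixel arc steps with a
perpendicular band of `width_px` samples; the background is an explicit
rectangular ROI (the synthetic segments carry a border strip), because an
implicit background estimate would be unverifiable. Negative corrected
means are kept and flagged — truncation at zero would bias percent-change
estimates. Split-APEX expression correction divides streptavidin by
`V5 x HA` per cell *before* per-batch normalization to the control mean;
the functional form is a documented convention (the underlying protocol
description fixes neither order nor form), and cells with non-positive
expression signal are flagged and excluded rather than silently dropped.
Branch-versus-shaft quantification measures the inner 1.4 µm of each 2 µm
branch window and tiles shaft windows with a 1 µm guard so PSF bleed-over
(sigma ~106 nm at 250 nm FWHM) does not couple the two classes.

## FRAP

Normalization follows the standard anchor convention: background
subtraction, division by an unbleached same-cell reference rescaled to its
own prebleach mean (the acquisition-bleach correction; if no reference
exists the correction must be disabled explicitly), then an affine map
sending the mean of the three prebleach frames to 100% and the first
post-bleach frame to 0%. The anchors hold exactly for every curve by
construction and the output is invariant under positive affine rescaling
of the raw trace. Averaging requires a shared time grid — no resampling is
performed, so acquisition irregularities surface as errors instead of
being interpolated away. The simulator's recovery is a single exponential
with plateau `1 - depth + depth * recovery_fraction`; acquisition
bleaching multiplies both traces by `exp(-rate * frame)`.

## Sholl and kymographs

Sholl intersections are connected runs of foreground pixels along the
8-symmetric midpoint circle at each radius (pixels ordered by angle,
counted circularly), the standard neurite-crossing definition. Radii step
10 µm by default, up to the image diagonal unless capped. The morphology
simulator co-emits its exact segment list, from which an analytic oracle
counts circle–segment crossings (quadratic roots with `t` in `[0, 1)` so a
crossing at a shared tree vertex counts once; tangencies excluded).
Rasterized neurites are ~3 px thick — a 1-px skeleton can cross a
discretized circle without sharing a pixel. Radii whose circle passes
within a tolerance of a tree vertex or a segment's closest approach are
flagged ambiguous and excluded from oracle comparisons; across 20 random
trees the remaining radii agree with the oracle at ≥ 95% (asserted).

Kymographs resample each frame along the traced path (bilinear, 1-px
steps) and project across the band thickness with a maximum (mean
available), one column per frame, row 0 at the path start. Sample points
are symmetric in arc length, so reversing the path exactly row-reverses
the kymograph (asserted).

## Statistics

Group comparisons are plumbing, delegated to scipy: Mann-Whitney U for two
independent groups, a paired one-sided Wilcoxon for mask-versus-flipped
fractions, ANOVA/Dunnett available for multi-group designs. Reports embed
the seed and a SHA-256 config hash; identical config and seed reproduce
byte-identical report bodies.

## Problem sizes and runtime

Default validation sizes match the reported experiment scales: 30 segments
per group for condition pairs, 20 two-channel segments for the contact
band, 16 branched segments, 20-seed suites for calibration properties.
The full test suite runs in well under a minute on one CPU; the acceptance
script in a few seconds.

## Known limitations

The simulator is a 2D-projection model: no z-stacks, no depth-dependent
blur, no STED depletion or expansion-microscopy distortion physics, no
organelle dynamics, no localization fitting from raw frames (localization
tables are generated at the precision/blink level). Puncta are points, not
25 nm extended particles. The acquisition-bleach correction assumes a
valid same-cell reference region; the exponential-control-cell fallback is
the caller's responsibility. Condition-pair tests show estimator
correctness under this generative model — real images add tracing error,
heterogeneous background and optical aberrations that the recovery results
do not speak to.
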