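# Methods

## Profile extraction

An axis fragment is a polyline trace over one or more grayscale channels
of a chromosome-spread image, in `(row, col)` coordinates with pixel
centers at integers. The profile is sampled at unit steps of arc length
(linear interpolation between vertices; output length
`floor(total arc length) + 1`, indexed from 0). At each step the value is
the mean of `width_px` bilinear samples spaced one pixel apart along the
local normal, centered on the trace — the same averaging a wide ImageJ
line selection performs, without reproducing ImageJ internals
bit-for-bit. Width must be odd (default 5 px, chosen to span axis
thickness); a trace whose width-expanded footprint leaves the image is an
error rather than being clipped. Width-1 sampling along a grid-aligned
trace reduces to exact pixel lookup, and sampling is linear in the image;
both properties are tested.

Background is the mean intensity over the union of 2–3 polygonal nuclear
regions free of axes (overlapping pixels counted once) and is subtracted
per channel. Negative post-subtraction values are retained deliberately:
the per-fragment z-scoring later removes the mean anyway, and clipping
would bias it.

## Correlation statistic

Each fragment's channels are z-scored with the sample standard deviation
(divisor L−1). A consequence asserted throughout (rather than forcing
c(0) = 1): the auto-curve at lag 0 equals the mean over fragments of
(L_f − 1)/L_f exactly.

Two estimators are exposed:

* `fragment_mean` (default): average the per-fragment expected products
  ⟨s_i s_j⟩_f with equal weight per fragment. This is the primary
  definition; it keeps long fragments from dominating.
* `pooled`: average all products across fragments, implicitly weighting
  by pair count. Retained because classical time-series cross-correlation
  routines effectively pool; useful for sensitivity checks.

Lags are unsigned. Cross products at x > 0 include both orientations;
auto products use one orientation to avoid double-counting the identical
pair. Fragments shorter than x + 1 contribute nothing at lag x — no
padding, no exclusion of the whole fragment. Zero-variance fragments
cannot be z-scored and are excluded before curve computation with a
logged count. Missing values inside a fragment are not supported; the
importer splits fragments at position gaps instead and logs how many.

### Per-lag significance

The null hypothesis is zero correlation at the lag. The test is a
two-sided one-sample t-test whose sample unit is configurable:

* `product` (default for reported curves): pools individual products.
  With tens of thousands of products this reproduces the extremely small
  p-values that pooled testing yields, but products within a fragment are
  serially dependent (both channels are spatially smooth), so the test is
  anti-conservative. This caveat is documented rather than silently
  "fixed".
* `fragment_mean`: one sample per fragment. Fragments are the independent
  replicates, so this unit is properly calibrated; the Monte-Carlo
  calibration tests and the acceptance script use it.

A lag whose chosen sample has fewer than two values gets a NaN p-value
and is flagged degenerate; a zero-variance sample around a nonzero mean
reports p = 0 with the same flag. Condition contrasts
(`compare_conditions`) use Welch's two-sample t-test per shared lag with
Bonferroni and Benjamini–Hochberg columns; disjoint lag ranges are an
error and partially overlapping ranges compare on the intersection.

## Synthetic generator

The generator emulates the structure the statistic is designed to
detect, per fragment on a 1-D pixel grid (1 px = 65 nm):

1. platform channel: `clip(base + N(0, platform_noise_sd), 0, ∞)`
   smoothed with a Gaussian of `platform_smooth_sigma_px`;
2. foci: count ~ Poisson(`focus_rate_per_px` · L), positions uniform, or
   tilted by acceptance weight `exp(coupling · z)` with `z` the
   standardized pre-depletion platform (rejection sampling capped at
   1000 tries per focus, uniform fallback with a warning). Positive
   coupling attracts foci to platform peaks, negative to troughs;
3. focus channel: sum of Gaussians `focus_amp · exp(−(i−p)²/2σ_f²)`;
4. depletion: the platform is multiplied by
   `1 − d·exp(−(i−p)²/2σ_d²)` per focus — multiplicative, so intensity
   stays physically non-negative;
5. i.i.d. Gaussian measurement noise on both channels.

Defaults and rationale (arbitrary intensity units): `platform_base` 100,
`platform_noise_sd` 40 and `platform_smooth_sigma_px` 3 give a patchy
platform with a few-pixel grain; `focus_sigma_px` 3 makes the visible
focus extent span roughly 8–12 px, matching how recombinase foci appear
along axes at this pixel size; `depletion_sigma_px` 6 makes valleys about
twice as wide as foci; `focus_rate_per_px` 0.03 yields ~2 foci per
typical fragment; fragment lengths are uniform on 30–120 px (manual
traces of unsynapsed stretches); `noise_sd` 2 reflects residual noise of
a background-subtracted profile already averaged over a 5-px line width.
These are fixtures reproducing qualitative regimes, not fits to any
measured biology — no distributional information about real platform
texture or focus amplitudes was available, and no claim of estimating
biological parameters is made.

Presets name the regimes of interest: `wt_like` (d = 0.7, uniform
placement → strong negative g(0)), `atr_null_like` and
`irradiation_1h_like` (d = 0, uniform → null), `atr_atm_null_like`
(d = 0, coupling +0.5 → weak positive). Determinism: all randomness
flows through one `numpy.random.default_rng(seed)` (PCG64) per cohort;
identical parameters and seed give byte-identical fragments.

`render_image` paints fragments as straight horizontal single-pixel
lines, blurs with an isotropic Gaussian PSF and adds a constant
background. Because a traced fragment is a window on a continuous axis,
the painted signal is extended past both trace ends by edge replication
over the PSF support — otherwise blurring tapers the profile ends, an
artifact real traces along continuous axes do not show.

What the generator does *not* emulate: 2-D axis curvature and crossing
axes, spatially varying background, chromatic offsets between channels,
stage-dependent signal evolution, or any mechanistic feedback dynamics.
Passing Monte-Carlo tests therefore demonstrate that the statistic
detects (and stays null-calibrated about) the platform/focus/depletion
structure, not that real images satisfy these assumptions.

## Cohort statistics

Focus density is count per µm of axis. Intensity ratios are
background-corrected: (unsynapsed − background)/(synapsed − background).
The "likelihood ratio test" on category proportions is the 2×2 G-test of
independence, G = 2 Σ O ln(O/E), df = 1 — the standard reading when the
compared quantities are two proportions. Mann–Whitney U uses midranks
for ties; the exact null distribution when min(n) ≤ 8 without ties,
otherwise the normal approximation with tie and continuity correction
(the method used is recorded). All tests are two-sided.

## Numerical choices and problem sizes

* z-scoring uses two-pass mean removal to avoid cancellation residue on
  large intensity offsets; the centered/unit-sd invariant holds to 1e−9.
* Curve oracle equivalence (brute-force all-pairs double loop) is
  asserted to 1e−12 on small cohorts; t-test and G-test p-values are
  cross-checked against direct density integration / closed forms to
  1e−10; Mann–Whitney against exhaustive permutation enumeration.
* Monte-Carlo validations run 500-fragment cohorts over 20 seeds
  (10 paired seeds per level for the depth-rank check in the acceptance
  script, with common random numbers across levels so that rank
  differences at deep, near-saturated depletion are not drowned in
  between-seed variance). These sizes keep every check comfortably
  within a couple of minutes on one CPU while leaving wide margins on
  the tested thresholds.
* Default lag window is 0–20 px (0–1.3 µm), with an optional disjoint
  extra window (e.g. 40–43 px) emitted on request.

## Known limitations

* The ImageJ wide-line average is approximated by perpendicular unit
  spaced bilinear samples; sub-pixel differences from ImageJ's exact
  freehand-line averaging cannot be arbitrated (imported per-fragment
  tables bypass extraction entirely).
* The pooled-product t-test inherits serial dependence (above); treat
  its p-values as descriptive, the fragment-mean unit as inferential.
* The ROI reader decodes only the polygon/polyline/freehand vertex-list
  families (integer and sub-pixel), which is what axis tracing produces;
  composite and shape ROIs are out of scope.
* Proportions and focus-count medians reported for real genotypes can
  only be validated in distribution on synthetic cohorts, since per-cell
  counts behind published bar charts are not available as data.
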