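# Methods

This note records the models, numerical choices and study conditions behind
`chromacal`, and what the simulated results do and do not show about real
captures.

## Image formation and the sensor model

The simulator renders the linear spectral model

    f_c(x) = m(x) · Σ_λ s(λ, x) · e(λ) · ρ_c(λ) · Δλ

on a uniform wavelength grid, by default 380–730 nm in 10 nm steps
(36 bins). Integration is rectangle-rule summation; for the smooth curves
used here this is accurate to far better than the shot-noise floor, and it
is matched in the tests by an independently coded term-by-term oracle.
Illuminants add at the photon level, so a flash+ambient expectation is
exactly the sum of the single-source expectations — the additivity that
flash/no-flash subtraction relies on is built into the physics, and the test
suite asserts it to machine precision rather than assuming it.

Sensor noise is shot noise only: the expected photo-electron count per
photosite is the spectral response times exposure time, ISO scale and gain
(electrons per DN), and the realized count is a Poisson draw. Read noise and
dark current are omitted because the pipeline's quality metric models only
the Poisson term; ISO is a pure multiplicative scale. Digital numbers are
`round(count / gain) + black_level`, clipped to `[0, white_level]`
(defaults: black 64, white 4095, gain 1 e⁻/DN — a 12-bit sensor whose DN are
themselves Poisson distributed).

**Deterministic mode.** With noise disabled the simulator returns the
*unquantized* expectation as float DN. Quantizing noiseless output at 12 bits
would inject ~1e-4 relative error, swamping the closed-form properties the
noiseless mode exists to exhibit (exposure linearity, exact source
additivity, exact subtraction). Quantization is a property of stochastic
captures; the noiseless path trades physical completeness for exactness and
is used only where an analytic reference is wanted. Noiseless frames are
rounded to integers if exported to the 16-bit fixture format.

## Bundled spectra and synthetic devices

The CIE 1931 2° color-matching functions and the D50/D65 illuminant tables
(380–730 nm at 10 nm) are bundled as CSV; integrating a perfect reflector
under the bundled D50 gives xy = (0.34566, 0.35863), within 5e-4 of the
nominal D50 white point — the residual is 10 nm quadrature, not data error.

Everything else is synthetic and only claims statistical realism:

* **Phone sensitivities** are single Gaussian bands per channel (two
  parameter sets = two distinct devices). Gaussian bands are *not* linear
  combinations of the CIE observer, so these cameras violate the Luther
  condition, as real sensors do; their 3×3 mapping error is genuine
  metamerism.
* **The Luther fixture camera** uses non-negative invertible combinations of
  the observer curves. An exact linear RGB→XYZ map exists for it only when
  the calibration illumination matches the illuminant of the reference XYZ
  values (an illuminant change is not a linear map on tristimulus), so this
  camera carries a D50-shaped flash. In that limit the pipeline recovers
  training-patch chromaticity to machine precision (~3e-16 measured),
  demonstrating that the only systematic error in the pipeline is the
  physics it cannot remove.
* **Flash spectra**: a blue-pump-plus-phosphor white-LED shape and a
  three-band screen-backlight shape. **Ambient spectra**: the D65 table
  (daylight-like) and a synthetic triband fluorescent. None claims to match
  a specific real device or lamp.
* **Reflectances** come from low-dimensional smooth bases: a deterministic
  24-patch general card (18 chromatic via band/edge/notch primitives + 6
  neutrals), seeded random smooth spectra for held-out "scenes", and two
  yellow-card families (blue-absorbing cut-on edges; the test family adds a
  mid-green dip and red roll-off to emulate a second manufacturer). The two
  yellows cards are fixed artifacts of the custom-card study — like physical
  cards, they do not change between runs; run seeds vary only capture noise.

## Pipeline conventions

* Pixel coordinates are 0-based row-major; CFA patterns name the 2×2 tile
  left-to-right, top-to-bottom; ROI rectangles are (x0, y0, w, h), half-open.
* Demosaicing is bilinear via normalized convolution: sampled photosites
  pass through unchanged, edges average the available neighbours, and flat
  fields stay exactly flat. The algorithm is deliberately simple and
  deterministic so simulator closed forms survive it; it is isolated behind
  one function and swappable.
* Saturated photosites are flagged at linearization, dilated 3×3 through
  demosaicing, and excluded from ROI statistics; an ROI with >1% saturation
  warns, >10% is an error — the linear, shot-noise-limited model holds only
  in the sensor mid-range.
* Color uses ROI **medians** (robust to outliers and inter-frame motion);
  SSNR uses ROI **means** (matching its Poisson derivation). The SSNR
  averages the three demosaiced channel means into one scalar signal before
  applying the quadrature formula — demosaiced data weights channels
  equally, and a single scalar makes a clean gate. SSNR is computed on the
  black-level-subtracted raw DN scale, where the Poisson assumption is
  meaningful; it is not renormalized.
* A non-positive subtracted component raises rather than clamps: it means
  the flash did not dominate or the ambient changed between frames, both
  retake conditions.
* Grey-card intensity is per patch (mean green over the patch ROI),
  normalized to unit mean. Calibration additionally divides by the grey
  image's global mean green level, so the two divisions together equal raw
  grey division; this removes the calibration exposure scale and makes the
  fitted matrix itself exposure-time independent (verified to ~1e-16), not
  merely the chromaticities.
* Reference XYZ tables are normalized so a perfect reflector has Y = 1; the
  absolute XYZ scale is conventional since chromaticity cancels it.
* The least-squares fit uses `lstsq` (orthogonal decomposition); the
  normal-equations formula is kept as a test oracle only. Rank deficiency is
  an error; the design condition number and per-patch residuals are reported
  with every mapping.

## Evaluation procedures

**SSNR threshold.** Ground truth is the first of three zero-ambient
sessions; the repeatability baseline is the mean (+1 population SD; ddof=0
so a single session pair is well-defined) of same-patch rg distances across
all session pairs. The sweep holds the flash at ≈5% of sensor range and
steps a daylight-like ambient through ratios 0.3–15× the flash signal —
weak flash is what makes low SSNR reachable without saturating a 12-bit
sensor. The threshold is the smallest sample SSNR above which every sample
sits inside the ceiling (+∞ with a warning if none does); it equals an
exhaustive scan over candidate cutoffs by construction and by test. Under
these conditions the procedure returns thresholds of roughly 4–7 depending
on seed. The shipped field default of 3.4 comes from physical-device
experiments of this protocol; that the synthetic procedure returns a
different number is expected, since the threshold depends on ROI size,
sensor scale and the device's intrinsic baseline — the procedure, not the
number, is the reproducible object.

**CAMP.** "Average minimum xy separation" is the mean over permutations of
each accepted subset's minimum pairwise distance. Nearest-neighbour ties
break to the lowest patch index (measure zero for continuous data).
Uniqueness of subset permutations is enforced by hashing accepted index
sets, re-drawing on collision up to 50× the requested count, with a
stagnation cut-off (no new subset in max(200, n/5) consecutive draws) so
small subset spaces — d_min = 0 admits exactly one subset — terminate;
the evaluated permutation count is reported. Subsets below two points are
skipped and counted. 1000 permutations is the default and what curve-level
results use.

## Study conditions

Simulated cards use 32 px square patches (24-patch card → 128×192 frames)
with ROIs inset 6 px to avoid demosaic bleed across patch borders;
noise-statistics checks use a 100×100 flat field (10⁴ photosites, ≥500
expected electrons). Auto-exposure places the brightest noiseless patch at a
target fraction of the dynamic range (0.45 for measurement studies, 0.25
where exposure is doubled, 0.05 for the threshold sweep). These sizes keep
every study in the seconds range while leaving ROI statistics hundreds of
pixels per patch; all headline numbers are insensitive to modest changes in
them.

## What passing tests do and do not show

The simulator realizes exactly the assumptions the pipeline is built on —
linear sensors, additive sources, Poisson noise, static scenes. Passing
tests therefore validate the *processing*: that subtraction, gating,
calibration and chromaticity extraction are implemented correctly and
achieve their theoretical behaviour when the assumptions hold. They do not
validate the assumptions themselves on real hardware: sensor nonlinearity
near saturation, read noise at very low signal, flash spectral drift,
inter-frame motion and specular reflection are real-capture effects the
synthetic studies exclude by construction (motion robustness is partially
covered by the median-then-subtract design, but never exercised with actual
motion). Cross-device agreement figures (median xy distance ~0.003 for the
two Gaussian fixture phones) quantify the metamerism of *these* synthetic
sensors, not of any physical handset.

## Known limitations

* DNG ingestion requires the optional `rawpy` dependency and sidecar
  exposure metadata; all bundled workflows use the portable TIFF+JSON
  fixture format.
* No automatic card/patch localization: ROI layouts are explicit inputs.
* Only bilinear demosaicing is provided; advanced algorithms (AHD/VNG) and
  lens-shading metadata are out of scope.
* The output is chromaticity — one dimension is deliberately given up to
  gain exposure/shading invariance; applications needing full tristimulus
  must add an in-scene reference.
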