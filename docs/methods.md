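# Methods

## Model

The analysis object is a pair of co-registered 2-D grayscale signal maps,
one T1-weighted and one T2-weighted, with two disjoint ROIs: a tumor mask
and an adjacent-tissue mask.  The statistic is the tumor contrast

    TC = S_tu / S_ti

with `S_tu`, `S_ti` the arithmetic means of the pixel values under the two
masks.  TC is evaluated on four image variants — T1w, T2w, the pixelwise
difference T1w − T2w and the sum T1w + T2w — before and after contrast
agent injection (8 report rows).  Because the mean is linear, the ROI mean
of a difference image equals the difference of the ROI means, so the
phantom's contrast values follow in closed form from the compartment
baselines; the pixel pipeline is tested against that closed form.

A contrast agent is modeled as multiplicative fractional signal changes
per compartment and weighting: a fraction `f` scales the affected signal
by `1 + f`.  The three built-in idealized agents are perfectly targeted
(zero tissue fractions): T1-only (`f_t1w_tumor = +0.5`), T2-only
(`f_t2w_tumor = −0.5`) and dual (both).  The ±50% magnitude reflects the
contrast enhancement typically reported for agent injection in breast
cancer MRI.  Sequential application composes multiplicatively:
`(1+f)(1+g) − 1`.

## Phantom

The synthetic phantom is two nested homogeneous ellipses: tumor inside
normal adjacent tissue, background zero.  Defaults: 256×256 grid, tissue
ellipse semi-axes (100, 60), concentric tumor (30, 20), rotation 0,
baselines 100 au (T1w) and 70 au (T2w) equal across compartments so that
pre-injection TC = 1 in every variant.  Rasterization uses pixel centers
in 0-based coordinates: a pixel is inside iff
`(x′/a)² + (y′/b)² ≤ 1` in the ellipse's rotated frame.  The tissue ROI
is the annulus excluding tumor pixels, since tumor and adjacent tissue
are distinct signal sources.  Geometry is a free choice: any
containment-valid geometry yields identical noiseless ROI means, and a
test asserts this.

Noise is optional and off by default (`noise_sigma = 0`), because the
reference phantom results are exact only noiselessly.  Gaussian additive
noise is the default model (negative tails clipped at zero, as signal
magnitudes are non-negative); a Rician mode
(`|S + n₁ + i·n₂|`, `n₁, n₂ ~ N(0, σ)`) is available for magnitude-MRI
realism.  Rendering is seeded and bit-reproducible.

What the phantom does **not** emulate: anatomical texture, partial-volume
edges, uptake kinetics, cross-sequence intensity scaling, coil shading,
or motion.  Passing phantom tests therefore demonstrates the correctness
of the arithmetic and the post-processing claim under ideal conditions,
not performance on real acquisitions.

## Image arithmetic and bit depth

All quantitative work happens on the analog (float, arbitrary-unit)
representation or the lossless rounded 16-bit working format; conversion
to 8-bit (`clip` or min–max to [0, 255]) is a display export only.
Measuring after a min–max 8-bit rescale would destroy the exact
subtraction arithmetic (e.g. 150 − 35 = 115), so the pipeline never does
it.  Signed differences are kept signed internally (`keep_signed`
default) and clipped at zero only when leaving through an integer file
format.  PNG is the default export; JPEG is supported but discouraged
because lossy compression contaminates downstream measurement.  A
constant image under min–max conversion maps to all zeros by convention.

## In vivo worked example

The original mouse images are not publicly deposited; what is published
are the ROI mean signals per variant and phase.  Those means fully
determine TC, so the worked example builds one synthetic
piecewise-constant image per variant (tumor pixels = published S_tu,
tissue pixels = published S_ti) and runs it through the standard ROI
machinery.  The published difference/sum means are the study's own
measurements on its combined images and are *not* the arithmetic
difference/sum of the published T1w/T2w means (e.g. pre-injection tissue:
162.0 − 60.9 = 101.1, but 110.0 is reported) — plausibly due to display
rescaling before measurement — so each variant gets its own fixture
rather than being re-derived.  Two further printed inconsistencies are
documented and excluded from checks: the post-T2-agent T2w contrast is
printed as 0.47 although 35/70 = 0.50 (the dual-agent row prints 0.50
for the same signals), and the post-T1/post-T2 added-image signal rows
are not the sums of their weighted-image rows.  Likewise the published
"12%" subtraction improvement (1.24 → 1.56) is not derivable from the
printed values (the ratio gives ≈26%) and is not asserted anywhere.

One reported ratio, 216.0/138.0, prints as 1.56 though it rounds to 1.57;
whether the source truncated or measured at higher precision is unknown,
so comparisons use an absolute tolerance of 0.01.

## Physics layer

An optional forward model maps relaxation parameters to signals via the
idealized spin-echo equation `S = PD·(1 − exp(−TR/T1))·exp(−TE/T2)` with
presets TE 7 ms / TR 750 ms (T1w RARE) and TE 35 ms / TR 5000 ms (T2w
MESE).  An agent at concentration C adds to the rates:
`1/T1′ = 1/T1 + r1·C`, `1/T2′ = 1/T2 + r2·C`.  Here r1 and r2 are
relaxivities in the standard sense — slopes of rate versus concentration
— not the bare rates 1/T1, 1/T2 with which they are sometimes conflated.
The bundled NaDyF4/NaGdF4 values (r1 = 9.0×10⁵, r2 = 147.0×10⁵
mM⁻¹ s⁻¹) are per nanoparticle-molar concentration and are used with
concentrations in those same units rather than silently converted.
RARE echo-train and MESE multi-echo effects, flip angles and field
inhomogeneity are ignored: the layer exists to derive plausible effect
fractions, not to simulate a scanner.  `predicted_effect` closes the loop
to the phantom's fractional-change abstraction and a test verifies the
two routes agree.

## Numerical choices and edge cases

* TC is stored at full precision and displayed at two decimals; test
  comparisons use absolute tolerance 0.01.
* A zero tissue mean raises a dedicated undefined-contrast error (it
  signals a degenerate subtraction of identical tissue signals).
* Empty or overlapping masks, non-contained tumor ellipses, non-positive
  geometry and out-of-range integer values are rejected with distinct
  error types, each mapped to its own CLI exit code.
* Zero agent concentration short-circuits to the identity to keep the
  no-dose case bit-exact.
* The file-analysis path converts integer images to analog floats on
  load; cross-sequence intensity normalization is deliberately left to
  the user and raw values are subtracted as-is.

## Problem sizes

The default 256×256 phantom renders in milliseconds; the full test suite
and the reproduction script each run in a few seconds on one CPU.  Tests
mostly use a 64×64 phantom, which has identical noiseless ROI means by
the geometry-independence property above.

## Limitations

Single 2-D slice only (no DICOM/NIfTI, no 3-D), no registration, no
automated segmentation, no SNR-based metrics, n = 1 in the in vivo worked
example with no statistical inference.  Conclusions about real scanners
require real images through `run_image_analysis`.
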