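# Methods

## Threshold-sweep Minkowski functionals

The core statistic treats a grayscale pattern as a stack of excursion
sets. Given a normalised intensity field *I* ∈ [0,1] (high = marking), the
sweep places `n_levels = 80` thresholds evenly and *strictly inside* the
open interval between the in-mask minimum and maximum. Interior placement
avoids the degenerate all-foreground and all-background slices the closed
endpoints would contribute; a constant (degenerate) image yields a grid
strictly above the constant, so every slice is empty and all summaries are
zero rather than an error. Retention is strict (`I > t`), so a pixel
exactly at a threshold counts as background.

Per slice, three planar Minkowski functionals:

- **Area** *A(t)*: foreground pixel count.
- **Perimeter** *P(t)*: two estimators.
  - `crofton4` (default): the Crofton formula
    *P = (π/2)·E[I(θ)·d(θ)]* discretised over four directions
    (axes, spacing 1; diagonals, spacing √2/2; equal weights), where
    *I(θ)* is the number of foreground/background transitions along the
    grid lines of direction θ. Asymptotically exact for isotropic
    boundaries (a radius-25 digital disc measures within ~1.5% of 2πr)
    and ~5% low on axis-aligned squares — the standard anisotropy bias of
    4-direction Crofton estimators.
  - `boundary_edges`: the exact count of exposed 4-neighbour pixel edges
    (an n×n square gives exactly 4n). Used as the oracle in tests and
    available for analyses that prefer the exact digital length.
- **Euler characteristic** *χ(t)*: components minus holes via Gray's 2×2
  configuration counting, χ₈ = (Q₁ − Q₃ − 2Q_d)/4 with 8-connected
  foreground and 4-connected background (the consistent complementary
  pairing; the 4/8 pairing is available via `connectivity=4`). Verified
  exhaustively against an independent flood-fill labelling oracle.

Summaries are plain sums over the level grid — Σ(P²/A), ΣEuler, ΣP, ΣA —
since the grid is evenly spaced (a trapezoid option exists but is off by
default). Levels with *A = 0* contribute 0 to Σ(P²/A) so all specimens
share the same 80-point support. P²/A is dimensionless and
scale-invariant: 16 for any square under `boundary_edges`, 4π at the disc
minimum, and unbounded for elongated shapes — which is exactly why
Σ(P²/A) captures scribbles that marking-size statistics miss.

Out-of-ROI pixels are background. Foreground touching the ROI edge
therefore contributes perimeter along that edge; this is a measurement
artifact identical across specimens measured with the same ROI shape and
cancels in comparative analyses.

## Preprocessing

Images are min–max normalised within the ROI; RGB collapses to luminance
with fixed Rec. 709 weights (any fixed weighting preserves marking
geometry, and calibrated colour is out of scope). Photographs of dark
markings on light shells are inverted once (`1 − I`) into the
marking-intensity convention; inversion parity is tracked in metadata.
Noise suppression is a Gaussian blur with reflective boundaries (a padded
blur would create a dark frame that registers as spurious perimeter). The
smoothing scale is a free parameter: default σ = 2 px, chosen as the
smallest scale that suppresses single-pixel noise speckle (which otherwise
dominates χ through thousands of tiny components/holes) without erasing
3-px-wide strokes. Constant images are accepted and flagged degenerate so
batch runs do not abort.

## Synthetic egg generator

The generator provides ground truth where real photographs would be
needed. Scribbles integrate a bounded-curvature random heading
(wrapped-normal increments, default 0.25 rad per unit arc length, step
0.5 px, headings reflecting off the canvas margin) and dilate the path to
the stroke width (default 3 px, default length 120 px); this produces
smooth, rarely self-crossing strokes of predictable area (≈ length ×
width). Blotches are rotated ellipses of bounded axis ratio (default
≤ 1.6) parameterised by equivalent-circle radius. `match_area` solves the
closed-form radius √(total/(kπ)) and corrects iteratively for
digitisation until the blotch set matches a scribble set's total area
within 5% — mirroring experimental designs that compare marking *shape*
at fixed marking *quantity* (5 scribbles vs 10 area-matched blotches, the
counts used by the painting treatments). Eggs are composed as a smooth
low-frequency background (level 0.2 ± 0.05) plus markings at intensity
0.8 (composited with `max`, as paint covers rather than adds), Gaussian
pixel noise (σ = 0.02), and an elliptical ROI. Painting composites fresh
markings onto an existing egg at the marking intensity (the experimental
paint was colour-matched to natural pigment); `water` is the
handling-only identity control.

What the generator does *not* emulate: 3-D egg curvature and specular
shading, calibrated reflectance, camera noise statistics, and the spatial
statistics of real pigment deposition. Passing tests therefore
demonstrate correctness of the measurement chain and the *direction* of
scribble/blotch separation, not the published effect sizes on real eggs,
which require the archived image data.

## Traits and classification

The granularity-style traits are deliberately simplified, self-contained
analogues of the multi-scale toolbox traits used in the egg-pattern
literature (those recipes live in external MATLAB/ImageJ toolchains):
octave-band radial energies of the Fourier power spectrum (DC removed,
energies normalised to 1) give principal marking size (centre wavelength
of the peak band) and marking-size variation (entropy of band energies);
coverage is the foreground fraction at the median sweep level; contrast
is the in-mask intensity standard deviation; pole dispersion is the
normalised count asymmetry across the long-axis midline, with the axis a
required input since pole orientation is not inferable from pixels. A
`simplified_` column prefix is available to keep these from being
mistaken for the toolbox originals.

Classification is flexible discriminant analysis by optimal scoring:
regress the class-indicator matrix on the (standardised, optionally
degree-2 expanded) traits, eigendecompose the fitted cross-product for
the optimal scores, then whiten the discriminant variates in the pooled
within-class metric. Classification is nearest-centroid in that whitened
canonical space with a −2·log(prior) penalty, which for the linear basis
reproduces pooled-covariance LDA assignments exactly (verified on 100
random datasets against a closed-form oracle). Near-singular designs fail
with a message suggesting the ridge flag rather than returning garbage.
Trait importance is reported as absolute first-discriminant coefficients
on standardised traits, normalised to sum to 100% — a declared
convention, chosen because it is basis-independent and sums meaningfully.
Assignment rates can be resubstitution (default) or leave-one-out; the
scheme is always attached to the output since the two can differ
substantially on small samples.

## Receiver-response statistics

Rejection experiments are analysed as a binomial logistic regression of
outcome on treatment with Wald inference, fitted by IRLS. For the
saturated one-factor design the MLE has a closed form — coefficients are
cell log-odds differences, SEs are √(Σ 1/count) over the four cells
involved — and the IRLS fit is required (and tested) to match it to 1e-6.
Complete separation is detected from the cell table and flagged.
Published frequencies are converted back to integer counts by half-up
rounding of frequency × n, which inverts the rounding used when
proportions are printed as percentages. The reference level default is
`blotches` (alphabetically first, the convention of common GLM software);
with counts 11/17, 8/14, 8/13 this reproduces the full set of printed
Wald statistics, and the second dummy is water-vs-blotches. Before/after
manipulations are scored with the classical matched-pairs t-test
(df = n − 1, two-sided), with zero-variance differences flagged.

Wald p-values from ~44 Bernoulli trials are discrete and slightly
conservative: under a simulated null the type-I error at α = 0.05 stays
at or below nominal, but the p-value distribution is *not* exactly
uniform, so calibration is asserted as a bound on the false-positive
rate rather than a distributional uniformity test.

## Problem sizes and numerical choices

Synthetic studies default to a 120×160 px canvas (96×128 in the demo and
stochastic test batteries, 50 seeded replicates), sizes at which the
separation properties hold with wide margins while a full 80-level sweep
takes milliseconds. All generators are pure functions of (parameters,
seed) and every pipeline output can carry a JSON provenance sidecar with
the full configuration. Ties in nearest-centroid classification resolve
to the first class in sorted order (measure-zero for continuous traits);
the PCA component count is the smallest k whose cumulative explained
variance reaches the requested fraction, with a 1e-12 guard against
floating-point shortfalls at exactly 100%.

## Known limitations

- The Crofton perimeter is biased low for boundary directions aligned
  with the grid; comparative conclusions are unaffected (the bias is
  common to all specimens) but absolute perimeters of blocky shapes are
  better served by `boundary_edges`.
- Granularity traits are simplified stand-ins, not re-implementations of
  the published toolbox recipes; their values are not comparable across
  studies.
- The classifier supports any number of classes the optimal-scoring
  algebra allows, but has been exercised mainly at 2–3 classes.
- Published real-data results that depend on archived images and spectra
  (species assignment rates, real-egg coefficient rankings and t
  statistics, colour discriminability) are outside what synthetic data
  can validate; the package reproduces the response-experiment
  statistics, which are fully determined by printed frequencies and
  sample sizes.
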