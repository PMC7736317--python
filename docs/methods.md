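# Methods

## Overview

`qmpm` quantifies vascular function from intravital multiphoton
time-lapse imaging of an intravenously injected fluorescent tracer
(e.g. a 150-kDa TRITC dextran) in bone marrow. The pipeline is

1. **registration** — per-frame translational drift is estimated by
   windowed phase correlation and removed by Fourier-interpolated
   translation;
2. **segmentation** — each field is partitioned into blood (vascular
   lumen), tissue (extravascular marrow) and excluded (bone /
   background / out-of-field) compartments with Otsu thresholds;
3. **kinetics** — compartment-mean time–intensity curves are fitted
   with a two-compartment leakage model to yield the volume transfer
   constant `K_trans` (1/min), the fractional extravascular
   extracellular space `v_ec`, and the surface-normalised vascular
   permeability `K_trans / (S/V)` (um/min);
4. **vasculometry** — vessel skeletons give per-segment inner
   diameters and vessel density; fast time-lapses give intravascular
   cell velocities from centroid tracking of unlabeled-cell shadows.

A seeded synthetic-stack generator produces ground-truthed inputs so
each stage, and the pipeline end to end, is validated by parameter
recovery rather than by inspection.

## The kinetic model

With equal transport rate constants into and out of the tissue
compartment, tissue tracer concentration follows the Tofts form

    C_t(t) = K_trans * \int_0^t C_b(tau) * exp(-(K_trans / v_ec) * (t - tau)) dtau

where `C_b` is the blood curve measured from the segmented lumen —
used directly as the local input function, which is appropriate for
well-perfused tissue where local and arterial concentrations coincide.
Fluorescent intensity is taken as linear in concentration with an
unknown common gain; since the model is linear in `C_b`, the gain
cancels and `K_trans` and `v_ec` are invariant under rescaling both
curves (this scale invariance is property-tested). No hematocrit or
plasma-volume correction is applied: whole-lumen intensities are
fitted, and any such correction would only rescale `K_trans` by a
constant. An alternative literal parameterisation (equal rates applied
to raw intensities) reduces to the same two-parameter family under the
gain convention, so the Tofts form is the single implemented default.

### Numerical evaluation

The convolution is evaluated with the exact exponential recursion for
piecewise-linear inputs: over one interval with decay `x = k_ep * dt`,

    y_{i+1} = y_i e^{-x} + c_{i+1} * dt * phi1(x) - s_i * dt^2 * phi2(x)

with `phi1(x) = (1 - e^{-x})/x`, `phi2(x) = (1 - (1+x)e^{-x})/x^2` and
`s_i` the interval slope; both are switched to 4-term Taylor series for
`|x| < 1e-3` so the `k_ep -> 0` limit is seamless. On uniform grids the
recursion is executed as a first-order IIR filter. Against a constant
input the closed form `v_ec C0 (1 - e^{-k_ep t})` is matched to ~1e-13
relative, and against trapezoid quadrature of the continuous integrand
at dt = 1 ms to ~1e-11.

### Estimation

`TwoCompartmentModel.fit()` minimises the sum of squared residuals
between the measured and predicted tissue curves from bolus arrival
onward, by bounded trust-region least squares (`K_trans` in [0, 10]
1/min, `v_ec` in (1e-3, 1]) from a grid of at least 9 starts
(log-spaced `K_trans` x linear `v_ec`). Arrival is detected as the
first sample where the blood curve exceeds 10% of its peak. Tissue
curves on a different grid are linearly resampled onto the blood grid.

A fit is flagged **unidentifiable** when the tissue signal never
exceeds three pre-arrival noise standard deviations; the signal is
estimated with a boxcar smooth (width ≤ 11 samples) and the noise floor
scaled accordingly, so the decision concerns the underlying uptake, not
single noisy samples. Unidentifiable fits report `K_trans = 0` and
`v_ec = NaN`. An optional seeded residual bootstrap (200 replicates by
default when enabled, off otherwise) provides percentile confidence
intervals; the results object renders a statsmodels-style `summary()`.

Noisy measured blood curves may dip below zero; only a curve with no
positive signal at all is rejected ("no input function").

### Blood clearance

The post-peak blood curve is modelled as
`A1 exp(-lambda1 dt) + A2 exp(-lambda2 dt)` (`lambda1 >= lambda2 >= 0`).
The peak is located on a lightly smoothed curve so noise spikes on the
tail cannot masquerade as the bolus peak; amplitudes are initialised by
non-negative least squares on a grid of rate pairs (variable
projection) and all four parameters polished by bounded least squares,
keeping the best start. Fits that collapse to a single exponential
(vanishing amplitude or coinciding rates) are reported canonically as
`(A1, lambda1)` with `A2 = lambda2 = 0`. Monotonically rising data are
flagged `non_decaying` instead of fitted.

## Registration

Calvarium head-plate fixation leaves predominantly translational
residual motion, so a translation-only model is used. Frames are
Hann-apodised and correlated against a reference frame with subpixel
(upsampled-DFT, 1/100 px) peak refinement. Two correlation
normalisations are evaluated per frame — whitened phase correlation
(robust for structured scenes) and plain cross-correlation (robust for
strongly band-limited content) — and the candidate whose realigned
frame correlates better with the reference wins; that correlation is
the reported confidence. The preferred registration channel is an
intravascular blood-pool label when present (stable, anatomy-locked
contrast at every frame); otherwise the tracer channel is used with the
reference auto-selected as the highest-variance frame, because
pre-arrival tracer frames contain no anatomy, and late tracer frames
lose lumen/tissue contrast as the tracer equilibrates. Offsets of
frames with confidence below 0.2 are interpolated from confident
neighbours. Correction translates all channels of a frame by the
negated offset using Fourier interpolation (exact for translations);
pixels entering from outside the field are flagged invalid and excluded
from all downstream masks and curve extraction. Declared accuracy:
0.25 px for offsets up to 10 px at blood-curve SNR 20.

## Segmentation

Thresholds are recomputed per acquisition. `otsu_threshold` maximises
the between-class variance over every cut point of the histogram
(vectorised cumulative moments), breaking ties toward the smallest
threshold; it is property-tested against an exhaustive search. The
blood mask is the Otsu-thresholded time-mean of the blood-pool channel
when present, else of the tracer frames within 15 s after bolus
arrival, while extravascular signal is still near zero. Bone and
background can be split off by the lower threshold of a three-class
Otsu or supplied as a user mask; the tissue mask is the complement.
Masks are static over an acquisition — per-frame re-segmentation would
let tracer leakage grow the lumen mask over time.

Vascular surface area per volume uses the marching-squares perimeter of
the blood mask (sub-pixel contouring, less digitisation bias than
pixel-edge counting) times a nominal slab thickness, over the field
volume at the same thickness — the thickness cancels, leaving
perimeter / field area in 1/um. Stacks are 2D + time (single optical
plane): the kinetics are unchanged by this choice and the slab
convention keeps S/V in volumetric units.

## Vasculometry

Skeletons come from topology-preserving thinning; the mask is
edge-replicated by its maximal inscribed radius before thinning so
vessels crossing the field boundary do not retract, then cropped back.
Branch points (more than two skeleton neighbours) split the skeleton
into branch-to-branch segments — the counting unit for vessel density
(segments per blood + tissue area, in 1/mm^2). Per-pixel inner radius
is the Euclidean distance transform at the centerline; per-segment
diameter is twice the mean radius excluding pixels within one maximal
radius of any branch point (junction bias), and the field mean is
length-weighted.

Cell velocimetry tracks unlabeled-cell shadows: per frame, blobs inside
the lumen darker than 70% of the median lumen intensity are linked by
greedy nearest neighbour within a 20 um gate; tracks shorter than 3
points are dropped. The frame rate must keep the per-frame displacement
at or below about half the gate (at 4 mm/s this means ~2 ms frames).
Per-track speed is path length over elapsed time; per-vessel means are
track-duration-weighted (a cell whose trajectory fragments — e.g. by
wrapping at a field boundary — is not over-counted), and the field mean
averages over vessels. Tracks are assigned to the skeleton segment
nearest their median position, yielding per-vessel (velocity, diameter)
pairs.

## Synthetic data

The generator renders what a drifting, photon-limited detector would
see: vessels as tortuous tubes (lane-packed sinusoids, so disjointness
is guaranteed while both translation components stay observable for
registration), the tracer channel carrying the blood curve inside the
lumen and the tissue curve outside, an optional constant blood-pool
channel, cells as dark discs (7 um diameter, 80% contrast) translating
along centerlines, Fourier-shifted per-frame drift, and Poisson photon
noise plus Gaussian read noise applied last.

Default study conditions: 256 x 256 um field at 1 um/px, 1 Hz frames
for 10 min post-injection; four vessels with radii 5–25 um; bolus
arrival uniform in 6–12 s, linear rise over 3 s, biexponential
clearance with amplitudes 0.7/0.3 and rates 0.05 and 0.005 1/s;
`K_trans` = 0.05 1/min, `v_ec` = 0.30; photon gain 0.002 AU/count and
read noise 0.02 AU, giving blood-curve SNR ≈ 20 at peak. "SNR-20 curve
pairs" for recovery studies carry Gaussian noise with sd equal to each
curve's own peak divided by 20 — real extracted curves, being
compartment means over ~5e4 pixels, are considerably cleaner, so the
curve-level studies are the conservative case.

The clearance-fit validation samples the blood curve at 2 Hz: a
Cramér–Rao analysis at the default rates gives sd(lambda1)/lambda1 of
6.7% at 1 Hz (the fast component's half-life is ~14 s), so the expected
median recovery error of even an efficient estimator sits at the
declared 5% tolerance; at 2 Hz the expected median is ~3.2% and the
validation is properly powered. The kinetic pipeline itself keeps the
1 Hz default.

What the generator does **not** emulate: realistic vascular topology
(no bifurcating trees or anastomoses by default — junction handling is
tested on constructed Y-masks), pressure-driven hemodynamics or
Fåhræus effects, a point-spread function (compartment boundaries are
sharp, so segmentation Dice on synthetic stacks overstates what blurred
real data would give), depth attenuation, photobleaching, and axial
drift. Recovery results on synthetic stacks therefore validate the
estimators and their composition, not performance on degraded real
acquisitions.

## Degenerate inputs and tie-breaks

- Otsu ties: smallest qualifying threshold; single-occupied-bin
  histograms are rejected as degenerate.
- `v_ec = 0` with `K_trans > 0` is rejected as ill-posed; `K_trans = 0`
  yields an identically zero tissue curve.
- Empty blood mask: S/V returns 0 with a warning; segmentation raises
  "no vessels detected"; skeletonisation rejects empty masks.
- A stationary cell is invisible to time-mean segmentation (its shadow
  darkens every frame); the tracker itself handles it when given a mask
  that covers the cell.
- Increasing `K_trans` at fixed input and `v_ec` raises the tissue
  curve pointwise only for non-decaying inputs; with a decaying input
  the faster washout lowers the late tail, so the monotonicity property
  is asserted only where it holds.

## Problem sizes used in validation

Otsu equivalence: 1000 random histograms. Recovery: 50 seeded SNR-20
curve pairs with `K_trans` in [0.01, 0.2] 1/min and `v_ec` in
[0.1, 0.6]; 9 noiseless grid points. End-to-end: 10 rendered SNR-20
stacks (601 frames, 256 x 256 px, drift up to 5 px). Drift: 25 frames
with shifts up to 10 px. Morphometry: 8-vessel network with diameters
10–50 um; velocimetry at 1/2/4 mm/s, 40 frames at 2 ms. Clearance
fits: 100 seeded SNR-20 replicates at 2 Hz.

## Known limitations

- Translation-only registration; no rotation, scaling, non-rigid
  motion, or axial drift.
- The local input function is taken at face value; no arterial-input
  deconvolution and no plasma-volume (v_p) term.
- Diameter from the distance transform carries sub-pixel bias of order
  half a pixel; the declared tolerance is 2 px.
- Vessel "count" for density is the branch-to-branch skeleton segment;
  other counting conventions (e.g. connected components) would shift
  absolute densities.
- The greedy nearest-neighbour tracker is not a global assignment
  solver; at high cell densities identity switches are possible within
  the gate.
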