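# Methods

## Signal model and transform

A measured image or volume is modelled as `f(n) = I(n) + ε(n)` with
`ε ~ N(0, σ²)` additive white Gaussian noise. Denoising estimates `I` by
modifying the coefficients of an undecimated dyadic wavelet decomposition
of `f` and inverting.

The transform is a separable à trous filter bank. The analysis pair is the
quadratic-spline low-pass `h = [1, 3, 3, 1]/8` (DC gain 1) and the two-tap
first-difference high-pass `g = [1, −1]`; at level *j* both are dilated by
inserting `2^(j−1) − 1` zeros between taps, and nothing is decimated, so
every band retains the source shape and the decomposition commutes with
translations. The synthesis low-pass is the time-reversed `h`; the
synthesis high-pass `K` is solved at bank construction by exact polynomial
division of `1 − H(z)·H̃(z)` by `G(z)` (a six-tap filter), and the bank
constructor verifies the perfect-reconstruction identity `H·H̃ + G·K = δ`
numerically, refusing to build a broken bank.

Per level, bands are produced axis by axis: band *d* is the high-pass along
axis *d* of the signal already low-passed along axes 1..d−1 at that level.
This telescoped arrangement is what lets the per-axis identity collapse the
multi-dimensional inverse exactly; the alternative (low-passing along *all*
other axes) admits no exact FIR synthesis. Each level still yields exactly
D gradient-like bands, which is what the cross-scale modulus needs.

All accumulation is in float64 regardless of input dtype.

**Boundary handling.** The default is periodic (circular) indexing, under
which the forward/inverse round trip and shift equivariance are exact to
machine precision everywhere. Mirror (whole-sample reflection) extension is
available via `DenoiseConfig(boundary="mirror")` / `default_spline_bank("mirror")`;
it avoids wrap-around mixing of opposite tomogram edges but breaks the
reconstruction identity in a border zone whose width is the total dilated
filter support (≈ 24 pixels for three levels) — inside that margin the
round trip is again exact to 1e−8, as the test suite pins down. For
tomograms whose object of interest sits away from the frame edge (the
usual case) either mode is appropriate; the periodic default is chosen so
the library's contracts hold globally.

## Denoising strategies

* **w1 (direct soft thresholding).** One global λ for every detail band:
  an explicit `lam`, else the universal threshold σ√(2 ln N) with
  σ = `noise_sigma` when given and otherwise the standard deviation of the
  measured data itself. Soft (not hard) thresholding throughout the
  package: the hard rule's jump discontinuity produces abrupt artifacts at
  significant noise energy.
* **w2 (modified shrinkage, the flagship).** Levels in `zero_levels`
  (default {1}) are zeroed outright. Every remaining band `(j, d)` is
  soft-thresholded with λ = σ̂_j² / sd(W_j^d). σ̂_j is the robust median
  estimate Median(|W_j|)/0.6745 pooled over the D bands of level *j*
  (0.6745 is the 0.75 standard-normal quantile); the denominator is the
  plain sample SD of the band. A BayesShrink-style variant that first
  subtracts the noise variance from the band variance is available as
  `subtract_noise_variance=True` but is not the default — the plain-SD
  quotient is the definition this package implements. If a band's SD is
  zero the threshold is +∞ and the band is zeroed (a zero-variance band
  carries no signal); if every band ends up zeroed the filter warns and
  returns the pure approximation rather than erroring on a valid input.
  `threshold_mode="universal"` replaces the per-band quotient with the
  per-level universal threshold σ̂_j√(2 ln N).
* **w3 (spatially adaptive).** Bands at `modify_levels` (default {1}) are
  replaced by their moving-window mean over an odd `neighborhood` window
  (default 5, i.e. 5×5 or 5×5×5, chosen empirically), with mirror handling
  at band edges. Levels listed in `zero_levels` but not modified are
  zeroed; a level listed in both is averaged (modification wins), which
  keeps `DenoiseConfig(strategy="w3")` meaning "w3_1" rather than a pure
  zeroing.
* **w4 (cross-scale regularization).** Processing coarse-to-fine over
  `modify_levels` (default {1, 2}; the coarsest level has no coarser
  neighbor and is rejected), the level-*j* modulus
  `M_j = √(Σ_d (W_j^d)²)` is scaled pointwise by the [0, 1]-normalized,
  already-modified modulus of level *j*+1, and the result is projected
  back onto the per-axis components. The implementation fuses the
  modulus/unit-vector/projection chain into `W̃_j^d = M^norm_{j+1} · W_j^d`,
  which is algebraically identical wherever `M_j > 0` and removes the 0/0
  at zero modulus (the fused form is zero there, as the limit demands). If
  the coarser modulus is identically zero the fine level is zeroed with a
  warning — a blank coarser level means no structure to propagate.

For volumes, `denoise_image` applies the 3-D filter to the whole array;
`denoise_slices` applies the 2-D filter independently per slice (default
slicing axis 1, the y axis of a z-y-x volume — the orientation used when
filtering tilt images individually).

## Evaluation metrics

SNR is the centered sum of squares of the reference divided by the
squared-error sum; MSE the mean squared error; CCC the Pearson-form
correlation of the centered values. The reference mean inside the SNR
numerator is the scalar mask-mean (the only reading that makes the
numerator a variance). All means are computed within the mask; the default
simulation mask is the phantom support dilated by two voxels, restricting
evaluation to the object region. Degenerate cases are explicit: a constant
reference makes SNR/CCC undefined (error); a candidate identical to the
reference yields SNR = +∞ with a warning.

## Simulation harness

**Phantom.** A deterministic multi-primitive density phantom (default 64³):
a large ellipsoid body, three spheres of decreasing radius (6, 4, 2 voxels
at 64³) and increasing contrast, a thin vertical cylinder and a small box —
coarse and fine structure in one object, so both smoothing and detail
preservation are exercised. Voxel value is the sum of the intensities of
the primitives covering it. Geometry is a config object, not hard-coded;
primitives must lie inside the volume, and the defaults also sit inside
the cylinder inscribed about the tilt axis so projection loses no mass.
The exact phantom used in the original simulation study is not published;
this one is the package's own stand-in with the same role.

**Noise.** `add_noise_to_snr` draws i.i.d. Gaussian noise with
σ = √(Var(I)/s) for target SNR *s* (variance computed within the mask when
given), the variance-ratio convention matching the SNR metric. The default
target is 0.1, the noise level of a real cryo-tomogram. All draws come
from a seeded `numpy` Generator; identical seeds give identical arrays.

**Projection.** Single-axis tilt geometry: beam along z, tilt axis the
vertical y axis, so each y slice is an independent 2-D problem. The
per-angle in-plane rotation is materialized as a sparse matrix of bilinear
interpolation weights; projection is rotate-then-sum. Linear interpolation
conserves mass to well under 0.5 % for objects inside the inscribed
cylinder. Angles must lie strictly inside (−90°, 90°); the full-scale
design is [−70°, 70°] at 1° (141 views) and the desk-scale tests use
[−69°, 69°] at 3° (47 views), which keeps the whole reconstruction study
in tens of seconds on one core.

**Reconstruction.** WBP ramp-filters each projection along the axis
perpendicular to the tilt axis (frequency-domain `2|f|` filter) and
back-projects with the transpose of the projection matrix, scaled by
π/(2·n_angles). SIRT is the simultaneous additive scheme
`x ← x + λ·C·Aᵀ·R·(b − A·x)` with R and C the reciprocal row/column sums
of A (the normalization common in electron-tomography SIRT), default 15
iterations and relaxation 1.0 — declared defaults, since no canonical
values exist. Because back-projection is the exact matrix transpose of
projection, the adjoint identity ⟨Ax, y⟩ = ⟨x, Aᵀy⟩ holds to rounding, a
property the test suite checks directly. The residual norm is monitored
and SIRT stops early with a warning if it grows three iterations running.
No missing-wedge compensation is applied beyond the angular range itself.

## What the simulations do and do not show

The harness reproduces the *statistical* situation of cryo-ET — piecewise
homogeneous density, white Gaussian noise at SNR ≈ 0.1, a ±70° missing
wedge — and the relative orderings measured on it (modified shrinkage
beating the noisy input on all three metrics; zeroing only level 1 beating
deeper zeroing; SIRT beating WBP on noisy data; denoise-then-reconstruct
beating reconstruct-raw). It does not model the contrast transfer
function, dose-dependent damage, detector MTF, alignment errors, or the
structured (non-white) component of real cryo-ET noise, so absolute metric
values on real tomograms will differ; the orderings are the transferable
result.

## Numerical choices and limitations

* Perfect reconstruction, linearity and constant annihilation are enforced
  at 1e−8/1e−10/1e−12 respectively; the transform accumulates in double
  precision to make those reachable from float32 input.
* The even-count median uses the mean of the two central order statistics,
  so threshold values are deterministic and testable.
* MRC I/O is a self-contained MRC2014 implementation: reads little-endian
  modes 0/1/2/6, writes mode 2 (float32), round-trips voxel spacing
  through the cell dimensions, and rejects non-finite voxel values on
  read. TIFF single images go through `tifffile`.
* D > 3, decimated/orthogonal wavelets, other wavelet families, hard
  thresholding and learned denoisers are out of scope; fiducial alignment
  and GPU execution are not provided.
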