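# Methods

This note documents the models, numerical choices and limitations of the
package. Everything quantitative stated here is computed by the test suite
or by `scripts/acceptance.py`.

## Signal model and phantom

The digital phantom is a 2D neck-like slice: a background ellipse
(default T1 = 1200 ms, M0 = 1) containing circular flowing-blood vessels
(venous T1 defaults in the 1650–2000 ms range). Vessels are rasterized by
the pixel-center-in-circle rule; vessels may not overlap.

Two signal regimes are simulated per TI frame, both as real signed
longitudinal magnetization:

* **Vessels (inflow regime).** Provided ΔTI > THK/v (slice thickness over
  blood velocity; the simulator warns when violated), every excitation
  sees freshly refreshed, fully inverted spins, so the vessel carries the
  complete inversion-recovery curve M(TI) = M0·(1 − (1+ε)·e^(−TI/T1)) with
  ε the inversion efficiency (default 1; a Bloch-derived value from
  `prep_rf` can be plugged in).
* **Background (saturation regime).** Repeated 90° excitation every ΔTI
  plus the WET pre-saturation before the inversion hold static tissue at
  the saturation-recovery plateau M0·(1 − e^(−ΔTI/T1)) in all frames. An
  optional `exact_first_frame` mode instead models the first frame as
  recovery since a pre-saturation applied `presat_delay_ms` before the
  inversion; the delay is a parameter (default 150 ms) because the exact
  pre-saturation timing admits more than one reading, and the plateau is
  what the temporal sparsity of the reconstruction actually relies on.

The TI grid is 50 + 200·(k−1) ms. One shot measures 55 frames: 50
"acquired" TIs used for fitting plus 5 "appended" TIs (10 050–10 850 ms)
acquired only to support the reconstruction's temporal boundary.

Coil maps are smooth complex Gaussian lobes on a ring around the FOV with
coil-specific phase ramps (RSS variation < factor 3); a single coil means
uniform unit sensitivity. k-space noise is complex Gaussian, independent
across frames/coils/samples, with per-frame RNG substreams derived from
one seed (bit-reproducible). When no absolute σ is given, the default is
2% of the RMS of the last frame's noiseless k-space — a deliberately
simple, signal-relative definition of "realistic SNR" for this phantom.

What the generator does **not** emulate: pulsatile/partial inflow,
through-plane flow profiles, B1 transmit inhomogeneity, physiological
motion (motion is injected explicitly in registration tests), and
anatomical background texture. Consequences: registration on this phantom
has no real motion to find (the tests verify it is a no-op and that
injected known transforms are recovered), and segmentation faces no
partial-volume ambiguity beyond the rasterized vessel edge. Passing tests
demonstrate internal correctness of the chain, not in-vivo robustness.

## Trajectory and sampling

The spiral arm is a constant-angular-velocity Archimedean spiral whose
radial pitch is the Nyquist pitch (1 cycle/FOV) times the variable-density
reduction factor: 1 inside 15% of the Nyquist radius, 5 outside 50%,
linear in between. Gradient hardware (slew/amplitude) is deliberately not
modeled — it does not affect reconstruction correctness. The arm is
integrated as the separable ODE dk/dθ = R(k/kmax)/2π on a fine grid and
sampled uniformly in θ; the design refuses sample budgets whose
consecutive radial spacing would exceed the locally allowed pitch, naming
the offending radius band.

Angles are degrees, rotations counter-clockwise, k in cycles/FOV (Nyquist
radius = matrix/2), forward transform with negative exponent and centered
pixel indices — fixed conventions for bit-reproducibility.

Density compensation (not specified by the protocol) is analytic
|k|·dk/dθ (arc × revolution-gap Voronoi approximation) with a floor
sharing the innermost-revolution area, normalized so Σw = matrix². The
normalization makes the gridded point-spread-function peak ≈ 1 even
though the sampled disk misses the k-space square's corners; the tests
check a point source reconstructs at the right pixel within 5% amplitude
and that rim/center weight ratios match the annular-area oracle.

The acquisition's *effective acceleration* is reported as π·kmax² (unit
Nyquist cells in the sampled disk) divided by samples per arm: ≈ 5.3 for
the 180×180 protocol (4800 samples at 2.5 µs over 12 ms). No claim is
made to any other headline undersampling factor, whose definition is not
derivable from the sampling geometry alone.

## NUFFT

No NUFFT library is a dependency; the package implements Kaiser–Bessel
gridding: 2× oversampled FFT grid, width-6 kernel with Beatty's shape
parameter, and a precomputed scipy.sparse interpolation matrix per frame.
The adjoint is the conjugate transpose of the same matrix, so the
operator pair is *exactly* adjoint (tested to 1e−6 normalized, measured
~1e−15). Deapodization is the inverse DFT of the sampled kernel, which
makes the transform exact at integer grid frequencies (the kernel support
is open — keeping the nonzero I0 band-edge value would truncate integer
tap sets asymmetrically). Against direct DFT summation on 16×16 grids the
max relative error is ~1e−5 (required < 1e−3). The simulator uses a finer
gridding (3×, width 6) than the reconstruction so data are not generated
by the operator later inverted.

## Reconstruction

Cost: ‖k − S F I‖² + λ‖TV_TI I‖₁ with λ = 0.1, solved by Polak–Ribière
nonlinear conjugate gradient (restart on non-descent) with Armijo
backtracking, the ℓ1 smoothed as Σ√(|d|² + ε²), ε = 1e−6 on the
normalized scale. The initial line-search step is the exact minimizer of
the quadratic data term, which keeps the search scale-free. The objective
trace is recorded and must be non-increasing; the solver is deterministic.
Initialization is the density-compensated adjoint ("gridding") image.

**Scale conventions.** λ is dimensionless only relative to a fixed
normalization, which the cost function alone does not pin down: any
rescaling of the data term is equivalent to rescaling λ. Two conventions
are fixed: (1) images are normalized so the gridding image has unit 98th
percentile magnitude; (2) the data term is measured in the
density-compensated metric ‖√(w/N²)·(k − SFI)‖², under which Eᴴ W E ≈
identity and the fidelity behaves like an image-domain squared error of
order one — commensurate with the O(1) frame differences the TV term
penalizes, so λ = 0.1 meaningfully trades the two. (With an unweighted
data term the fidelity exceeds the TV term by ~6 orders of magnitude and
the regularizer — and with it the frame padding — would be inert.) The
weighting slightly de-whitens the noise model; this is the standard
trade-off of density-compensated/preconditioned SENSE formulations.

**Padding.** The measured 55 frames are padded to 59 by prepending
sign-inverted copies of frames 52–55 (trajectory angles carried over).
Reconstruction uses all 59; prepended/appended frames are dropped before
fitting. On the scaled-down study the 50-frame reconstruction of identical
data shows ~1.5× larger vessel-signal error at the first/last TIs than
the 59-frame reconstruction (acceptance report), reproducing the
boundary-artifact rationale qualitatively.

**Polarity.** The reconstruction is complex; a global phase (anchored on
the last, near-equilibrium frame) is removed and the real part is fitted.
A magnitude-fitting mode with exhaustive polarity restoration exists for
robustness checks.

**Off-resonance deblurring** is frequency-segmented: the series is
projected onto the trajectory, demodulated at n_bins (default 9)
frequencies spanning the B0 map's range, regridded, and combined by
per-pixel linear interpolation at the local offset. It corrects the
readout-time blur of an adequately sampled arm, not undersampling
aliasing, and is exactly the identity for a numerically zero B0 map.
Applied to an already-reconstructed image it can over-recover peak
amplitude by tens of percent (the reprojection is not in the measured
data's range); T1 fitting is scale-invariant, so this does not bias T1.

## Analysis

**Registration** chains consecutive-frame rigid transforms (translation +
rotation) estimated by regular-step descent — a fixed step per sweep,
halved when no axis move improves the metric — on a 20×20 mm² window
around the target vessel, with bilinear resampling and cumulative
composition to frame 1. The metric is the MSE after optimal global
intensity scaling (1 − normalized correlation²) on 1-px-pre-smoothed
magnitudes: consecutive IR frames differ in contrast, and plain MSE (or
unsmoothed interpolation) rewards spurious transforms. Three safeguards
handle the frames near the vessel's signal null, where the window is
featureless and undersampling streaks dominate: translation is estimated
before rotation (rotation about a circularly symmetric vessel is
unidentifiable and only accepted if it explains ≥25% of the remaining
mismatch); per-pair motion is bounded to ±3 px / ±5° (a 200 ms frame
interval cannot produce more rigid neck motion); and the pair falls back
to identity unless the estimate explains ≥75% of the window mismatch.
Known injected transforms are recovered to <0.2 px / <0.3°; real motion
occurring exactly at a signal-null frame would be missed — a limitation
shared with any intensity-driven registration of this series.

**Segmentation** grows the vessel ROI from a seed pixel: flood fill
(4-connectivity) of pixels ≥ 0.7 × the local peak, with peak and region
iterated to a fixed point. The threshold is stored in the ROI. The
default reference frame is the last acquired frame, where blood is near
equilibrium; the first frame (TI = 50 ms) also has high |signal| but its
sign is inverted, and mid-series frames pass through zero.

**T1 fitting** is Levenberg-style least squares of the three-parameter
model with multi-start T1 ∈ {300, 800, 1600, 2400} ms (covering pre- and
post-contrast regimes), bounds T1 ∈ [1, 10⁵] ms, and a linearized
(Jacobian) 95% confidence interval. Fits with CI width ≥ 100 ms are
flagged excluded. Non-convergence yields a flagged result, not an
exception. The fit is invariant to positive rescaling of the signal to
1e−9 relative.

**Method comparison** reports Pearson r, the least-squares line, and
Bland–Altman statistics with percent differences taken relative to the
pair mean and 1.96·SD limits of agreement.

## Problem sizes

The package defaults mirror the full protocol (FOV 180 mm, 1.0 mm
resolution, 4800-sample arms). The study exercised by the tests and the
acceptance script is a proportionally scaled miniature chosen as the
package's standard verification size: 96×96 matrix with 1360-sample arms,
preserving the protocol's per-frame effective acceleration
(π·48²/1360 = π·90²/4800 = 5.3), 4 coils, 2% relative k-space noise,
vessels of 4 mm radius at T1 ∈ {1650, 1850, 2000} ms. Under these
conditions reconstruction + fitting recovers each T1 within 1%
(acceptance report; the requirement is 5%), and the repeatability study
(two noise realizations, six vessels spanning 1550–2050 ms at 64×64)
gives r > 0.99 with |bias| < 1%. An acquisition at the same matrix but
with the full 4800-sample arm is nearly fully sampled (acceleration 1.5)
and would not probe the undersampled regime the method targets.

## Known limitations

* 2D single-slice only; no low-rank or model-based alternatives to
  temporal TV.
* The WET sub-pulse shape is rectangular (the vendor's optimized shape is
  proprietary); flip angles and durations follow the published train.
* The HS inversion plateau (|Mz/M0| ≥ 0.9) covers the central ~75% of the
  swept bandwidth; the inversion-band FWHM equals the nominal bandwidth.
  Quoting "inversion across the full bandwidth" is accurate only in the
  FWHM sense.
* CI estimation is linearized; for very low SNR the interval (and hence
  the exclusion rule) inherits the usual optimism of the Jacobian
  approximation.
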