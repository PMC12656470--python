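# Methods

This package registers a high-resolution visible image against a
low-resolution thermal/infrared image of the same scene (the FLIR C2 regime:
640×480 visible, 80×60 infrared, co-mounted optics). The two modalities
disagree in spectrum (contrast may reverse wholesale), dynamic range and
resolution, so intensity-based alignment is unreliable; the pipeline instead
registers *contour geometry*, which both sensors see.

## Pipeline

1. **Gabor contour map `F`.** The image is convolved with a bank of
   even-symmetric (cosine-carrier) Gabor kernels

   `G(x,y) = γ/(2πσ²) · exp(−(x_θ² + γ²y_θ²)/(2σ²)) · cos(2πf·x_θ)`,

   `x_θ = x cosθ + y sinθ`, `y_θ = −x sinθ + y cosθ`, over 8 orientations
   (θ = kπ/8) and scales σ ∈ {2, 4, 8} px with f = 1/(2σ), γ = 0.5,
   support = ⌈3σ⌉. The bank is reduced by **summation**. The sum of even
   Gabors over orientations behaves like one isotropic zero-DC band-pass
   operator, and linearity is what makes the next step work: the response to
   a step edge is odd about the edge, so its **zero crossing sits on the edge
   regardless of blur level**. (A signed max-magnitude reduction is available
   as `combine="signed_max"`, but being nonlinear it switches winning kernels
   exactly at response zero crossings; we measured contour displacements up
   to ~5 px in the blurred modality with it, versus ~1.4 px with the sum.)

   The infrared image is bicubically upsampled to the visible grid first
   (its native grid is too coarse for contour analysis), using the pure
   coordinate-scaling convention `out(p) = ir(p/r)` so the resolution ratio
   composes exactly into the reported transform. The IR side is analysed
   with a coarser bank (σ ∈ {8, 12}): upsampling imprints per-pixel sensor
   noise as ripple at exactly the resolution-ratio wavelength, which the
   fine bank scales would amplify.

2. **Ordinal map `S`.** `F` is convolved with a zero-sum "triple lobe"
   ordinal filter — a positive central Gaussian and negative flanking lobes
   (defaults: center at 0, flanks at ±3 px, all σ = 1 px, coefficients
   balanced so the discretized kernel sums to 0). In 2-D the flanks are
   realized isotropically as four quarter-weight Gaussians on the axes.
   The balanced kernel removes any residual DC and sharpens the band-pass
   response. Maps are normalized by their maximum magnitude (symmetric
   scaling into [−1, 1]; a plain min–max shift would move the zero level the
   contour stage depends on).

3. **Contours.** Default rule: trace the zero-crossing curves of `S`
   (sub-pixel, via iso-contours of the lightly smoothed map at level 0),
   gate them by gradient energy at the 98th percentile with a
   hysteresis split along each curve (runs above 0.4× the gate that contain
   at least one above-gate point), drop curves below 0.35× the strongest
   curve's mean energy (these are the sidelobe rings that flank every
   principal crossing), suppress near-duplicate curves, and resample chains
   to 1 px arc-length spacing. A magnitude rule (binarize |S|, skeletonize,
   chain-trace) is available for comparison. Chains shorter than 40 px are
   discarded.

4. **CSS keypoints.** Corners are curvature-scale-space features: local
   maxima of |κ|, κ = (x′y″ − y′x″)/(x′²+y′²)^{3/2}, on the chain smoothed
   at σ = 2 chain-steps, kept only if |κ| stays above the 0.05 px⁻¹
   threshold at σ = 4 and 6 (within a ±3-step window), thinned by
   non-maximum suppression (5-step separation), and localized to sub-step
   precision by a parabolic fit of the |κ| peak. Sub-step localization
   matters because an along-chain position error Δs rotates the bisector
   orientation by κ·Δs radians.

5. **Main orientation.** Each corner's orientation is the angular bisector
   of its two contour arms, `v = min(|L|,|R|)·(L/|L| + R/|R|)`, mapped to
   [0, 2π) by the piecewise arctangent (equivalent to atan2 mod 2π; the
   x = 0 boundary goes to π/2 or 3π/2 by continuity). Arms are taken
   **20 chain-steps** out on the smoothed chain: on a rounded corner the
   bisector is normal-dominated, and short arms (e.g. 5 steps) pick up
   κ·Δs orientation noise far beyond the 5° repeatability we need; long
   smoothed arms anchor the bisector in the corner's flanks (measured
   same-scene rotation repeatability: 37% of matched corners within 5° at
   arm 5, 80–88% at arm 20–30). Corners with anti-parallel arms (straight
   chains) have no stable bisector and are dropped.

6. **Descriptors (modified SIFT).** 4×4 spatial cells × 8 orientation bins
   over [0, π), accumulated in the keypoint's orientation frame with
   trilinear interpolation, clamped at 0.2, unit-normalized. Two
   modifications make it modality-robust: gradient orientations are folded
   modulo π (merging opposite directions — this is the 16→8 bin reduction,
   and makes the descriptor invariant to contrast reversal) and magnitudes
   are normalized per patch (99th percentile, clamped). Gradients are taken
   on the map smoothed by σ = 8 px, and patches are large (radii 24/32/48 px
   on the visible side, 32 px on the infrared side): the band-pass maps are
   oscillation-dominated at small scales and carry the discriminative
   *shape* information only at silhouette scale. The visible side is
   described at three radii (its scale content is richer); the infrared at
   one.

7. **Bilateral matching.** Mutual nearest neighbors in descriptor space;
   each keypoint appears in at most one match (best scale wins); equal
   distances break toward the lower index. The nearest/second-nearest ratio
   test is available but defaults to off (ratio 1.0): on scenes with
   repeated similar shapes the second-nearest distance is uninformative and
   the test starves the next stage, whose whole job is outlier rejection.

8. **RANSAC rough registration.** Seeded 2-point similarity hypotheses
   (closed form via the complex ratio), consensus at a 5 px reprojection
   tolerance, 2000 iterations, followed by local optimization: least-squares
   refit (Umeyama) on the consensus, re-evaluation of membership, iterated
   to a fixed point. The 5 px tolerance reflects the measured 2–4 px corner
   localization error across the 8× resolution gap. Fewer than two matches
   or fewer than four inliers is a flagged failure. Deterministic given the
   seed.

9. **Fine refinement.** For every inlier, the infrared map patch is warped
   through the current transform and correlated (|ZNCC|, absolute value
   because contrast reversal flips the band-pass response sign) against
   visible patches at every integer shift within a ±10 px window
   (template half-width 16 px, maps pre-smoothed by σ = 4 px); the visible
   location moves only to a strictly better shift, polished by parabolic
   sub-pixel interpolation; transform refit; two sweeps. Featureless or
   border-clipped patches stay unrefined.

   *Monotonicity guard.* The stage is reverted outright if the mean pair
   residual ends worse than both the rough residual and the inlier
   tolerance. The pair residual alone is **not** required to decrease: the
   visible and infrared corner detectors share a localization bias that
   cancels inside the rough residual, so correcting the visible side toward
   the true correspondence necessarily raises the pair residual even as the
   transform improves (measured: residual 1.9 → 3.0 px while ground-truth
   control-point error fell 3.9 → 0.9 px). On same-modality pairs with
   planted perturbations the refinement does strictly reduce error, and is
   tested so.

## Metrics

RMSE = √(Σ‖p_i − r_i‖²/N); precision = correct/total with a match correct
iff its distance to the reference is **≤ 5 px** (the boundary counts);
recall = correct/correspond, where "correspond features" is computed from
ground truth as the number of keypoints in one image whose true
corresponding location falls within the correct-match radius of a keypoint
in the other; accuracy = (TP+TN)/(TP+TN+FP+FN); orientation agreement
counts pairs with circular angle error **strictly below 5°** (the boundary
does not count). Zero denominators report the metric as absent, never 0.

## Synthetic pairs

The generator renders three large smooth silhouettes (Fourier-perturbed
ellipses, harmonics m ∈ {4..9} with amplitudes 0.10–0.20, base radius
0.55–0.8 of a grid cell) on a weakly textured background — a subject that
fills much of the frame, as a body does in an 80×60 thermal image; many
small shapes would put neighboring edges inside the coarse analysis
footprint, which is not the acquisition regime being emulated. The visible
rendering passes one of four illumination schedules (#1 darkest … #4
brightest; #3 is the identity; #4 uses γ = 0.55 so highlights saturate).
The infrared rendering applies a planted similarity (defaults: scale 1.05,
rotation 0.04 rad, translation (6, −4) px) on top of the 8× resolution
ratio, a reversed monotone intensity map ((1−v)^1.2), σ = 4 px blur, point
downsampling to 80×60, and additive Gaussian noise (σ = 0.01) on both
frames. All randomness flows from the single spec seed. Ground truth
carries the exact composite native-IR→visible similarity, control points on
the silhouette outlines (consistent to < 0.5 px by construction), and the
true curvature-maximum locations.

What the generator does *not* emulate: real thermal physics (emissivity,
internal body-temperature structure), photometric vignetting, motion blur,
occlusion, and the clutter and low-contrast texture of real barn imagery.
Passing the end-to-end checks therefore demonstrates that the pipeline
recovers geometry across resolution and contrast reversal under controlled
conditions — not field performance. In particular, the clean synthetic
silhouettes are friendlier to a plain raw-image edge baseline (Canny + the
same corner/orientation machinery, used by `orient-compare`) than real
low-light imagery is: the Gabor-ordinal representation yields more
keypoints in aggregate, but its cross-modal orientation-agreement margin
over that baseline is small and scene-dependent here.

## Numerical and protocol choices

- Convolutions are true convolutions (kernel flipped) with reflect padding;
  verified by impulse response.
- Coordinates: x = column, y = row, origin top-left, 0-based; angles
  counter-clockwise from +x with +y pointing down.
- All stages are deterministic given the configured seeds; RANSAC is the
  only randomized stage.
- Degenerate inputs (blank images, flat patches, straight-line corners,
  anti-parallel arms, zero bisectors) are dropped or flagged, never
  silently defaulted.
- Problem sizes used by the test suite and the acceptance script (one to
  two generated pairs per illumination level, 640×480/80×60 frames, ~40
  control points per pair, 2000 RANSAC iterations) were chosen to exercise
  the full acquisition regime while keeping a complete run in the order of
  a minute.

## Known limitations

- The transform family is similarity (+ an affine option would be a small
  extension); non-rigid deformation is out of scope.
- Contour extraction assumes the scene has extended, closed-ish contours;
  texture-only scenes yield few keypoints and a flagged failure.
- The fine stage searches integer shifts in a fixed window; displacements
  beyond ~10 px at the visible scale must be absorbed by the rough stage.
- Registration of pairs whose overlap is small or whose shapes are
  near-identical repeated objects can mismatch corresponding corners of
  different objects; RANSAC usually, but not always, rejects these.
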