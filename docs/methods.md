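# Methods

This note documents the models, parameter choices, and numerical decisions
behind `synkey`, in the spirit of a methods section: what is computed, under
which assumptions, and what the built-in simulation does and does not show.

## Kinematic preprocessing

Joint angles (degrees, ten joints in the canonical thumb→pinky, MCP-first
order) are differentiated by central differences with one-sided ends —
the simplest scheme consistent with sampled glove data; it is isolated in
`compute_velocity` so a spline or filtered derivative can be substituted.
No smoothing is applied by default; an optional centred moving average is
available in `segment_trial`.

Movement segmentation takes the peak as the maximum absolute velocity over
*all* joints jointly and keeps the span from the first to the last sample
where any joint reaches 5% of that peak.  A per-joint-peak variant
(`onset_mode="per_joint"`) is available; the global reading is the default
because it produces the single extraction window per trial that the
fixed-size representation requires.  Segmented trials are zero-padded at the
tail to L = 151 samples, the duration of the longest grasp in the reference
protocol (1.208 s at 125 Hz); the padded representation is what all later
stages consume.

## Synergy extraction

The velocity matrix V (one row per grasp, joint-major flattening) is
decomposed by the economy SVD *without mean-centering* — the decomposition
operates on raw velocities, and variance fractions are squared singular
values over their total.  A `center=True` option exists for comparison.
Sign indeterminacy is resolved by making each synergy's largest-magnitude
element positive; the paired left-singular column is flipped with it so the
reconstruction identity V ≈ U_S diag(λ) R_Sᵀ is preserved exactly.  Ties in
singular values are therefore reproducible given identical input order.

## Matching and verification

Per-joint similarity is the Pearson product-moment correlation over the full
padded 151 samples.  A profile with zero variance in the compared window
(possible because of zero padding) contributes 0 rather than NaN.  The entry
synergy may be shifted by up to ±20 samples (160 ms) with zero fill; ties
between shifts are broken toward the smaller |shift|, then the negative
shift, favouring the unshifted interpretation.  Template synergies are
paired greedily in rank order — each takes the best available entry synergy,
which is then removed from the pool; an optimal Hungarian assignment is
available as a comparison mode but is not the default behaviour.  Raw
correlations are matched (no absolute value): synergies are
sign-canonicalized upstream, and an `allow_sign_flip`-style analysis can be
built from the correlation tensor if needed.

Scores are expressed as percent of the configuration's maximum
(|mask| × |indices|), so thresholds are comparable across joint masks and
for one- or two-synergy keys; multi-synergy scores are averaged over the
indices before thresholding.  Acceptance is strict: score > T_m.

The chance baseline permutes eight contiguous time bins of each joint
profile (seven 20-sample bins and an 11-sample tail at L = 151),
independently per joint, and re-runs the identical pairing.

## Evaluation

FAR(t) = #(imposter scores > t)/#imposter and FRR(t) = #(authentic ≤ t)/
#authentic are evaluated over the sorted union of observed scores, their
midpoints, and sentinels beyond the extremes.  The EER is linearly
interpolated between the two thresholds bracketing the FAR/FRR sign change;
with perfectly separated scores it is exactly 0 and with identically
distributed scores exactly 50%.

Leave-one-object-out ranking re-extracts synergies per omission (entry sets
included, for symmetry) and attributes to each object the change in mean
imposter correlation caused by its presence: an object whose removal makes
imposters match *better* is the most discriminative and ranks first.  The
opposite attribution is reachable through `score_kind`.  Statistical testing
of configuration differences is deliberately out of scope; the sweep emits
means and standard deviations for downstream use.

## Virtual hand and gain selection

The glove does not measure finger DIP joints; the virtual hand couples them
anatomically as DIP = ⅔·PIP so the palm-crossing criterion is computable.
The thumb is held straight at its default abduction during posture
construction.  The range of motion is taken as the glove calibration range
−10°…90° (an assumption: the calibration range stands in for "normal range
of movement").

Forward kinematics uses a front-view projection: digits leave their bases
along fixed axes and flexion folds phalanges *out of the image plane*, so a
segment of length l with cumulative flexion θ advances l·cos θ along the
digit axis.  This matches what a fixed overhead camera sees — flexion
shortens the silhouette — keeps neighbouring fingers from colliding
laterally, and makes the palm-crossing criterion geometrically meaningful:
past 90° of cumulative flexion the DIP drops below the knuckle line.  The
gain is the largest value keeping every measured joint inside the ROM
(closed form), then decremented in 0.01 steps until no finger DIP crosses
the upper palm edge (strictly: a DIP exactly on the edge does not cross).
When postures feed the renderer, a clearance of one digit width is added to
the palm criterion, because a finger whose DIP merely touches the knuckle
line leaves no silhouette peak for the image analysis to detect — the same
failure the gain cap exists to prevent.

The default geometry is a stylized average adult hand (JSON-serializable):
a 100 × 110 mm palm with shallow V-notch webs between the digit bases,
digits of 45–67 mm with 12 mm width.  The palm is deep relative to the
digits so that the silhouette centroid sits well below the knuckle line,
as it does in wrist-cropped photographs; this keeps the normalized radial
profile in the realistic 1–3 range rather than amplifying measurement noise
through a small normalizer.

## Silhouette analysis

Segmentation keys out the background by an HSV hue window (green by
default), keeps the largest connected component, and fills holes.  A
continuous foreground-coverage map (from the red channel, which the keyed
background lacks) rides along with the binary mask; boundary operations use
its 0.5 level, recovering the subpixel edge position that binarization
discards.  The wrist is cropped at the narrowest row in the lower quarter of
the component, but only when a genuine neck exists (wider rows below);
otherwise the mask is treated as already cropped — this makes the crop
idempotent.  A fixed-row override is available.

The digit-edge region is the contiguous boundary arc in the upward
half-plane from the (coverage-weighted) centroid, with a 5° angular margin
excluding the near-horizontal palm sides.  The traced contour is Gaussian
smoothed at a scale-free world scale (3% of √area) so arc lengths do not
depend on the pixel grid, and both endpoints are refined to the exact
margin-angle crossings.  Centroid distances along the arc are resampled at
100 equal arc-length steps, *anchored at the valleys*: fingertip peaks and
the valleys between them are located on the dense polyline (valleys refined
by a parabolic fit), and each stretch between consecutive valleys is
sampled uniformly starting exactly at its valley.  Valleys are therefore
always sample points and the discrete finger split cannot straddle a valley
bottom.  Distances are divided by their minimum — the profile minimum is
exactly 1.0 — which makes the representation invariant to translation and
uniform scale while per-finger sample counts still shrink with flexion or
adduction, the sensitivity the error metric is designed to exploit.

Fingers are split at the valleys between the five most prominent peaks;
fewer than five detectable peaks raises a finger-detection error that
verification reports as a rejection with its reason.  The per-finger error
zero-pads the shorter sequence at the tail, so point-count differences
inflate the error by design; a resampling mode would remove that
sensitivity and is intentionally not the default.  Acceptance is strict:
total error < T_p.  Rotation is not corrected (the capture rig fixes hand
orientation); an optional principal-axis tilt check can reject rotated
images but is off by default.

## Synthetic data generator

The generator defines the study conditions under which the package is
exercised:

- **Subjects.**  Each subject owns k = 10 orthonormal smooth synergy bases
  (10 × 151): sums of 2–3 Gaussian velocity bumps per joint with seeded
  centres (15–125 samples), widths (6–18 samples), and random signs,
  QR-orthonormalized on the flattened vectors.  One randomly chosen joint of
  the first basis carries a wide envelope that keeps its speed above the 5%
  segmentation threshold across the window, so noiseless single-synergy
  trials survive segmentation untrimmed and the basis is exactly
  recoverable.  Random bump signs keep cross-subject synergy correlations
  low (mean |r| < 0.3), which is the identity structure the biometric tests
  require; real first synergies share more of a common hand-closing shape,
  so the simulation is an easier separation problem than real data — the
  tests demonstrate the machinery, not field performance.
- **Grasps.**  velocity = Σᵢ w_{o,i}·basisᵢ + white noise, with weights
  fixed per (subject, object) so repetitions differ only by noise.  Weight
  scales give synergy 1 a 0.54 share of the expected squared-weight total
  (the share the reference protocol attributes to the first synergy); the
  remainder is split evenly.  Amplitude 240 deg/s and a trial noise SD of
  4 deg/s give authentic sessions matched correlations in the 85–95% band.
- **Protocol.**  10 subjects, 25 objects over the six-type grasp taxonomy
  (four objects per type, five for hook), 3 repetitions (first = template),
  4 follow-up entry sessions for the first five subjects (drifted bases,
  drift 0.15), yielding 40 authentic and 180 imposter movement conditions,
  and 20/10 posture conditions per synergy.  Clone and jointly-orthogonal
  population modes support the end-point analyses (EER → 50% and → 0%).
- **Renderer.**  The hand is a shapely union of the palm polygon and
  capsule digits, rasterized by unbiased subpixel point sampling (4×
  supersampling) into an antialiased silhouette on the chroma-key
  background — edge positions are exact to well below a pixel at any
  resolution, as with a real camera's optics.  Authentic repeats jitter
  joint angles by 2°; imposter attempts render the victim's posture with
  4° jitter plus the imposter's own per-digit abduction habits (SD 3°).

## Problem sizes and tolerances

Default analyses operate at the reference protocol size (25 × 1510
matrices, 220 verification comparisons), which runs in seconds; the test
suite uses the same sizes with small fixed seed sets (10 seeds for
Monte-Carlo end points, 100 random instances for oracle-equivalence
checks).  Reconstruction identities are checked to 1e−8 relative, EER
against a brute-force sweep to 1e−6 absolute, orthonormality to 1e−10, and
generator-recovery correlations at |r| > 0.999.  Scale invariance of the
silhouette profile is held to a summed per-finger error of 0.25 between a
template and its double-resolution re-render; the residual comes from
pixel-level measurement noise and, occasionally, a one-sample change in a
finger's point count when a segment's length sits near a sampling-grid
boundary — the zero-padding metric makes such flips visible by design.

## Known limitations

- The simulator's white trial noise and smooth bump bases are a deliberate
  idealization; real glove data contain sensor drift, cross-talk, and
  subject fatigue that the generator does not model.  Passing tests show
  the procedures are implemented correctly, not that the reported operating
  points transfer to human populations.
- The virtual hand is planar (front view only); side views, abduction
  dynamics, and 3-D self-occlusion are out of scope.
- The image pipeline assumes the controlled capture rig: uniform keyed
  background, fixed orientation, no shadows.
- Dynamic time warping as an alternative comparator is not implemented.
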