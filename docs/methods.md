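# Methods

## The kinematic model

The right arm is modelled as a six-revolute serial chain anchored at the
sternoclavicular (SC) joint, point **O**:

* joints 1–2 (clavicle horizontal/vertical rotation) at O,
* joints 3–5 (shoulder roll/pitch/yaw) at the glenohumeral centre **S**,
* joint 6 (elbow flexion/extension) at the humeroulnar centre **E**,
* the end effector **EE** at the wrist (distal radioulnar) centre.

Classic (distal) Denavit–Hartenberg parameters describe the chain.  Only
three link constants are non-zero: the clavicle length `l2` (link length of
joint 2), the upper-arm length `d5` (link offset of joint 5) and the
forearm length `l6` (link length of joint 6); the twists alternate
(−π/2, π/2, −π/2, π/2, −π/2, 0).  The base frame sits at O with +X lateral
toward the instrumented arm, +Z superior and +Y completing a right-handed
frame — chosen so the anatomical branch rules below are literal coordinate
sign tests.  Angles are radians internally; degrees appear only at
reporting boundaries.  Defaults `l2 = 180 mm`, `d5 = 300 mm`, `l6 = 260 mm`
are plausible adult values; per-subject values can be measured from the
marker data as median inter-centre distances.

## Closed-form inverse kinematics

Given only the wrist pose (P, R):

1. **Elbow**: the forearm lies along the wrist x-axis, so
   `E = P − l6·R[:,0]`.
2. **Shoulder**: S satisfies three constraints — the sphere `|S| = l2`
   about O; the plane `R[:,2]·S = R[:,2]·E` (the upper arm is
   perpendicular to the wrist z-axis, a structural property of the chain);
   and the plane `E·S = β`, `β = (|OE|² − d5² + l2²)/2`, which encodes the
   law of cosines of triangle O-S-E (equivalently `|ES| = d5`).  The two
   planes intersect in a line that pierces the sphere in at most two
   points — a quadratic in the vertical coordinate `Zc`.
3. **Angles**: θ1 = atan2(Yc, Xc), θ2 = atan2(−Zc, C1·Xc + S1·Yc) from the
   spherical coordinates of S; θ3, θ4, θ5, θ6 follow sequentially by
   comparing elements of `T0k⁻¹·T06` (rigid-transform inverses, never
   general inversion) with the remaining chain.

### Branch selection

Both quadratic roots are *exact* solutions of the stage-1 constraints, so
anatomy must select: a feasible shoulder has the clavicle upward-oblique
(`Zc > 0`) and lateral to the SC origin (`Xc > 0`).  If neither root is
feasible the configuration is a "shoulder dislocation" and is rejected
(strict mode) or flagged NaN (streaming mode).  If exactly one root is
feasible — the regime the method is designed for — it is selected.  When
both are feasible the pose genuinely has two anatomically plausible arm
postures; the solver then prefers the root closest to a caller-supplied
reference (the previous frame, or the measured shoulder centroid in the
marker pipeline) and otherwise the less-elevated clavicle.  The selected
root is polished with a few Newton steps on the exact constraint system,
which restores full precision near root tangency.

θ4 and θ5 are each recoverable only up to π (their atan2 pairs carry
factors sin θ5 and cos θ6 of unknown sign).  The ≤4 candidate branch
combinations are enumerated, each pushed through the forward model, and
the candidate minimizing a mixed pose residual (position in mm plus
100 × geodesic rotation angle in rad) is accepted; on exact input the
winner closes to ~1e-12.  The geodesic angle uses the atan2 form, which
keeps full precision near zero.

### Singularities and conditioning

* `Xc = Yc = 0`: θ1 undefined (shoulder on the base z-axis).
* `sin θ4 = 0`: θ3 indeterminate (elbow on the joint-3 axis).
* `sin θ5 = 0`: wrist singularity, θ4 indeterminate.
* `cos θ6 ≈ 0`: the θ5 element pair degenerates; the solver falls back to
  the unambiguous (sin θ5, cos θ5) pair of the same relative transform.
* `|cos θ0| → 1` (O, S, E nearly collinear, arm close to full extension):
  the sphere-line intersection is tangent and the split of S about the
  O-E axis — hence θ1…θ3 — is ill-conditioned under measurement noise.
  The streaming pipeline flags frames with `|cos θ0| ≥ 0.995` as
  `near_singular` (NaN); during a typical abduction repetition this
  removes short mid-rise/mid-fall stretches, never the ROM extremes.

## Marker pipeline

Markers: SC (one), SH1–SH3 around the shoulder (centroid at S), EL1/EL2
and WR1/WR2 symmetric about E and EE.  Joint centres are the
centroid/midpoints of these clusters.  The base frame is re-anchored at
the SC marker per frame; its yaw comes from a calibration window (first
second): +X is the horizontal projection of the mean O→S direction, +Z
capture-world up.  A residual constant yaw error only offsets θ1 and
cancels in every ROM.  The wrist frame is built per frame as
x = unit(EE−E), z = unit(x×(S−E)), y = z×x, which coincides with the
chain's own wrist frame whenever elbow flexion is below 90°.

For measured (noisy) recordings the recommended configuration, used by the
CLI by default, is: zero-phase 4th-order Butterworth marker filtering with
a 3 Hz cutoff (≈six harmonics of the 0.5 Hz exercise repetition; raise for
faster movements, or disable for synthetic/noise-free data, where the
unfiltered pipeline reproduces ground-truth ROM to <1e-10 degrees);
root disambiguation against the measured shoulder centroid; and the
near-singular frame flag above.  With 1 mm isotropic marker noise these
choices keep the median per-joint ROM error below ~0.5°; without them,
branch hops at the tangency passes can corrupt θ1–θ3 by tens of degrees.

**ROM.**  Per joint, `global` mode is max − min of the unwrapped series;
`per_cycle` mode (the default, matching a protocol of ten averaged
repetitions) segments the recording at the negative-to-positive
zero crossings of the dominant joint's smoothed velocity and averages the
per-cycle max − min.  ROM is invariant to time shifts, uniform resampling
and constant offsets.  Composite ROM: θ2 + θ4 for abduction/adduction,
θ5 for external/internal rotation.

**Cohort statistics.**  Per sex and pooled: mean, *population* SD
(divisor n — the convention that reproduces every printed spread in the
reference tables, e.g. male heights 170/174/177/190/172 → SD 7.1), and
SEM = SD/√n.  Reporting rounds half away from zero to one decimal; full
precision is kept internally.  Two printed cells of the
external/internal table are inconsistent with their own per-subject rows
(the female θ5 mean, printed 106.0 vs computed 104.2, and the female
height SD/SEM, which duplicate the male row); the package reproduces the
per-subject computation and documents, rather than patches, the printed
values.

## Synthetic motion generator

Each repetition is a raised-cosine excursion `offset + amplitude·rc(u)`
per joint (`rc(u) = (1 − cos 2πu)/2`), C¹-smooth so the velocity vanishes
at cycle endpoints and cycle segmentation is unambiguous.  Defaults: 10
repetitions of 2 s at 50 Hz; amplitudes follow the measured average ROM
pattern of each exercise (abduction/adduction ≈ 24/15/39/129/57/23°,
external/internal ≈ 4/3/8/8/109/24° for θ1…θ6); offsets keep every sample
on the anatomically valid branch (θ2 < 0 throughout) and away from the
sin θ4/sin θ5/cos θ6 singularities.  Per-repetition variability scales the
whole pattern so the dominant joint's amplitude has SD
`amplitude_jitter_sd` (default 2°); marker noise is isotropic Gaussian
(default 0.5 mm, typical of optical capture).  A single seeded RNG per
run, with fixed substreams for profile jitter and marker noise, makes
outputs bit-for-bit reproducible.

What the generator does *not* emulate: soft-tissue artefact (markers
rigidly follow the segment frames), marker occlusion/mislabeling,
physiological coupling between θ2 and θ4 (scapulohumeral rhythm), and
plane drift across repetitions.  Passing tests therefore demonstrate
correctness of the kinematic computation and its noise behaviour, not
robustness to skin-motion artefact.

## Problem sizes used in tests and the acceptance script

Round-trip checks sample 1000 random unambiguous configurations;
oracle-equivalence checks 500 instances against a grid + least-squares
sphere search; synthetic recovery runs full 10-repetition recordings
(1001 frames), noiselessly for both exercises and at 1 mm noise over 50
seeds in the tests (20 in the acceptance script's summary).
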