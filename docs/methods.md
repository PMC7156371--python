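# Methods

This note records the models, conventions and parameter choices behind
chewgear, in the order data flow through the package, and what the passing
test suite does and does not establish about real recordings.

## Coordinate conventions

All positions are in mm. The anatomical frame is a right-handed triad
(AP, ML, SI): anteroposterior, mediolateral, superoinferior. The sagittal
plane is span(AP, SI), the coronal plane span(ML, SI). Angles reported from
planar projections are folded into [0°, 90°], the convention for pinnation;
folding makes results insensitive to marker labelling order.

## Preprocessing

Occluded-marker frames (blank CSV cells) are carried as NaN. Gaps of at
most 5 frames (33 ms at 150 frames/s) with valid endpoints are linearly
interpolated before filtering; longer gaps stay missing and exclude the
affected cycles. The rule is a declared convention of this package —
standard motion-capture practice, chosen to be short relative to the
fastest phase (FC ≈ 12 frames) so interpolation cannot manufacture
kinematic features.

Each marker coordinate is filtered independently with a zero-phase
(forward–backward) low-pass Butterworth filter, cutoff 30 Hz, order 4,
reflective edge padding of 3×order samples. The cutoff is the recording
convention this package targets; the order and padding are our choices —
4th order is standard for 150 fps kinematics, and the two-pass scheme
removes the phase lag that would otherwise bias phase-transition timing.
Filtering precedes registration (filter-then-register); with per-coordinate
linear filtering and rigid motion the residual this ordering introduces is
below 0.02 mm on the synthetic data. Note the filter rounds the
acceleration discontinuities of the synthetic trajectories by a few
hundredths of a mm, so "exact recovery" tests run on unfiltered paths while
end-to-end tests use tolerances at or above that scale.

## Registration and gape

Rigid transforms are fitted with the Kabsch/SVD solution of the orthogonal
Procrustes problem; reflections are corrected so det(R) = +1, and
configurations with fewer than three markers or collinear geometry raise
rather than silently degrade. Cranial-frame fixing registers each frame's
cranial cloud onto its reference-frame configuration (the first frame with
all eight bone markers trackable, overridable) and applies that transform to
every marker. Mandibular motion is then expressed as per-frame transforms
relative to the reference pose, which also animate the CT landmarks.

Gape distance is the Euclidean displacement of the anterior mandibular
marker from its maximum-occlusion position. When no occlusion frame is
supplied it is estimated from the anatomy of the movement: the closed-jaw
pose is the extreme of jaw elevation (teeth in contact, it cannot be
overshot), so the candidate is the frame maximising the marker's SI
coordinate, re-anchored once at the frame minimising displacement within
its gape trough. With 0.15 mm marker noise this reference is good to ~2
frames and ~0.15 mm, which sets the noise floor of minimum-gape timing.
Gape uses the filtered trajectories.

## Cycle segmentation and phase detection

Cycles run from one gape maximum to the next; maxima are peaks with
prominence ≥ 20% of the recording's gape range (rejecting within-chew
jitter), and partial cycles at the recording boundaries are discarded.

Phase boundaries come from jaw vertical acceleration, the second derivative
of gape. The published criterion this operationalises is not reproduced in
citable detail anywhere we know of, so the rule here is fixed and testable:
minimum gape is the SC/SO boundary; the FC/SC boundary is the dominant
acceleration *step* (high→low) between peak closing speed and minimum gape;
the SO/FO boundary the dominant upward step between minimum gape and peak
opening speed. The step is located with a difference-of-one-sided-means
edge detector (window 5 frames each side) on the acceleration, after a
5-frame centred moving average. Two properties motivated this estimator
over a plain argmax: under the low-pass filter's symmetric smearing of an
acceleration jump the argmax drifts toward the heavier side of the peak
(a systematic 2-frame bias in our experiments), whereas the step centre is
unbiased; and the one-sided-means score is insensitive to linear
acceleration trends within a phase, which keeps it accurate across
fast:slow duration ratios from 1:1 to 3:1. Ties resolve to the earliest
frame.

Standardisation to 50 frames uses linear interpolation (monotone, no
overshoot); velocities are always computed on the real-time series *before*
standardisation, because resampling distorts time and hence derivatives.

## Architecture variables and AGR

Fascicle length is ‖m2 − m1‖ (CMJ to superficial termination); whole-muscle
length is coronoid tip (animated CT landmark) to the superior-attachment
marker m3. Planar fascicle angles project the fascicle vector (m1→m2) and
the line-of-action reference (m1→m3) onto the sagittal and coronal planes;
the angle between projections is computed with atan2(|cross|, |dot|), which
is well conditioned near 0° and 90°. Whether intermediate-frame angles
should be strictly planar or 3-D is genuinely open; we fix planar
projections and expose the 3-D angle only in the generator's ground truth.

Velocities are central differences (one-sided at ends), shortening
negative. The per-food AGR route mirrors the analysis convention this
package targets: standardised velocity curves are averaged per food, each
average is LOESS-smoothed (local linear, tricube weights, 25% span — via
statsmodels' lowess with robustness iterations off), and AGR is the ratio
of smoothed muscle to fascicle velocity. A per-cycle route
(`per_cycle_agr`) is exposed for cycle-level statistics.

The ratio is singular where fascicle velocity crosses zero (minimum and
maximum gape). Frames with |fascicle velocity| below ε = 2% of the curve's
peak, or with velocities of opposite sign, are masked, and the masked
fraction is reported in the pipeline log rather than silently dropped.
Because every operator in the chain (filter, derivative, standardisation,
averaging, LOESS) is linear, proportional velocity series keep their exact
ratio, which is why the constant-pinnation mode is recovered to ~1e-5 end
to end and the varying-gear constant-thickness mode to well under 2%.

## Synthetic generator

The generator emits what the lab would record — noisy marker CSVs, CT
landmarks, a config — plus the hidden truth (gape, l(t), θ(t), L(t),
AGR(t), transition frames, rigid transforms). Key choices, fixed once as
the study conditions:

* **Sampling and noise**: 150 frames/s; iid Gaussian marker noise,
  σ = 0.15 mm (midpoint of the 0.1–0.2 mm precision typical of the
  technique); optional slow whole-scene rigid drift (0.5 mm, 0.5°),
  zero at the reference frame.
* **Gape cycles**: C¹ piecewise-cosine through FC/SC/SO/FO with velocity
  zero at junctions and acceleration jumps there, so the phase detector has
  an exact target. Defaults: 15 mm maximum gape (a moderate chew for a
  small primate), phase durations (12, 18, 18, 12) frames — a 2.5 Hz chew
  with fast phases shorter than slow ones. The handoff gape between fast
  and slow phases is 0.6·G·T_slow²/(T_fast²+T_slow²), which reduces to the
  conventional ~30% of max gape at equal durations and guarantees the
  fast-phase acceleration jump dominates at any duration ratio, keeping
  the junctions detectable across the whole grid.
* **Jaw**: rigid rotation about a fixed ML axis through a centre near the
  jaw joint; the chord relation 2r·sin(φ/2) = gape maps gape to rotation
  (≈ 19° at 15 mm gape with the default 45 mm marker radius).
* **Muscle**: line of action from a fixed superior attachment m3 to the
  moving coronoid tip; m1 rides the central tendon at fraction 0.5 of the
  belly; m2 sits at l(t) from m1 at pinnation θ(t), in the sagittal plane
  by default or tilted out of it by a configurable coronal angle.
  `TILT_SAGITTAL_TWICE_CORONAL` = atan(1/2) ≈ 26.6° makes the sagittal
  projection range ≈ 2× the coronal one under the default geometry (the
  small-angle analysis gives cot(tilt) for the ratio). Muscle belly at
  occlusion is 12 mm, stretching ~60% to maximum gape; θ_ref = 20° at
  occlusion. Both are within the anatomical range reported for primate
  jaw-elevator fascicles.
* **Study builder**: 3 subjects × 5 foods with per-food cycle counts
  (7,7,7,6,6) — 33 cycles per subject, 99 total, matching the target design
  of ~30–33 chewing cycles per animal. Mechanically challenging foods
  (popcorn, cashew) use the constant-pinnation (low-gear) mode, compliant
  foods (grape, marshmallow, apple) the constant-thickness (high-gear)
  mode; subjects differ in scale (±5%) and θ_ref (18/20/22°); per-cycle
  gape amplitude jitters by 5%.

What the generator does **not** emulate: soft-tissue artefact (markers ride
rigidly), marker occlusion statistics, tracking outliers, activation-
dependent gearing, series-elastic transients (the transmission factor k is
exposed but defaults to 1), bilateral asymmetry, or within-sequence food
breakdown. Passing tests therefore establish that the *computational chain*
is correct and noise-robust at the stated precision — not that these
biological effects are absent from real data.

## Statistics layer

Mixed models are fit by maximum likelihood with statsmodels' MixedLM:
random intercepts nested as cycle within food within subject (grouping
only, no random slopes — the design statement specifies grouping). The
cycle-level component is included automatically only when cycles have
repeated observations, where it is identifiable. Term significance uses
Wald chi-square tests on the fixed-effect blocks (ANOVA-style); variance
components pinned at zero flag the fit as singular. R²m and R²c are the
variance-ratio decomposition var_f/(var_f+Σvar_r+var_e) and
(var_f+Σvar_r)/(same), with var_f the variance of the fixed-effect
predictions and all random components summed. At the study's design size
(3 subjects, 5 foods, ~7 cycles per cell) simulation shows 95% Wald CI
coverage ≈ 0.95 and type-I error ≈ 5.5% at α = 0.05 — the mild Wald/ML
anti-conservatism is noted, and "sequential Bonferroni" is implemented as
Holm's step-down procedure, its standard referent. The paired timing test
is a two-sided one-sample t on per-cycle offsets (the upstream literature
does not name its test); with zero offset variance only descriptives are
returned. RMA regression is the closed form slope = sign(r)·sd(y)/sd(x).

## Numerical and degenerate-input policy

Tolerances: orthonormality and det checks at 1e-8; collinearity at a 1e-8
singular-value ratio; projected vectors under 1e-9 mm mask an angle frame;
ties in argmax/argmin resolve to the earliest frame. Degenerate inputs
(collinear clouds, < 3 markers, tendon-slack geometry, empty files, cutoff
at or above Nyquist, spans/windows too small for LOESS) raise immediately
with the offending frame, marker or cell named; masked data propagate as
NaN with explicit masks rather than being dropped.

## Problem sizes

Default test and acceptance runs use 4–8 cycles per recording, 15-recording
studies, 1000-transform registration batches, and 500-replicate model
calibrations; these sizes put Monte-Carlo error comfortably inside every
asserted tolerance while keeping the full suite in the low minutes on one
CPU.
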