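# Methods

## The assay and its discretization

A single fish swims in a cylindrical tank of diameter 18.5 cm placed inside
a striped drum of diameter 24 cm (stripe width 2 cm on the circumference; a
central obstacle may block short-cuts across the middle).  The session is
one acclimatization phase (default 30 s, drum at rest) followed by
`n_reversals + 1` rotation epochs (default 3 + 1 epochs of 30 s) at a drum
speed of 60 deg/s, alternating direction.  Epochs are half-open intervals
`[start, end)` in seconds from recording start, so every video frame
belongs to exactly one epoch; direction changes are treated as
instantaneous.  Positive angle is counter-clockwise viewed from above; all
direction signs are relative, so results are orientation-invariant.

The tank-to-drum annular gap is (24 − 18.5)/2 = 2.75 cm.  (A fish-to-pattern
distance quoted as 5.5 cm corresponds to the diameter difference; the
package reports the radial gap and makes no claim about chord measures.)

## Angular kinematics

Tracker output (frame or time, x, y; pixels with an explicit px→cm scale,
or centimetres) becomes an unwrapped angular position θ(t) about the arena
centre.  The centre defaults to the centroid of all valid samples — adequate
for a fish orbiting the arena, and overridable in the session config for
still or tethered-looking animals, where the centroid is a poor estimate.
Unwrapping assumes consecutive valid samples subtend < 180°, the standard
shortest-arc rule.

Tracking dropouts are flagged, never dropped.  Gaps ≤ `max_gap_s`
(default 1.0 s) are bridged by linear interpolation of unwrapped angle;
longer gaps split the track into independent segments rather than
fabricating motion.  Angular velocity ω is the central finite difference of
θ over t (one-sided at run ends), smoothed by a centred moving average
(default 0.5 s — enough to suppress tracker jitter at ~30 fps without
masking the 30 s epoch structure).  Differentiation runs additionally break
at every epoch boundary, so velocity estimates never mix samples across a
known stimulus discontinuity; this is what makes the lockstep-follower
check exact.  On the raw (unsmoothed) ω, trapezoidal integration recovers
θ(end) − θ(start) exactly on uniform grids.

## The four optomotor parameters

"The fish follows the stripes" is operationalized (the assay literature
leaves it qualitative): a sample is *following* iff the drum is rotating,
sign(ω) equals the drum direction, and |ω| ≥ 25 % of the drum speed; runs
shorter than 1 s are discarded as incidental drift.  All three constants
are configuration-exposed.  Then, per session:

* **Delay** — for each post-switch epoch, the start of the first bout
  *beginning in* that epoch minus the epoch start; epochs with no bout
  contribute the epoch length (cap).  The aggregate is the mean over
  post-switch epochs (a first-switch-only mode exists).  The rotation-onset
  epoch is excluded by default — the definition concerns reaction to a
  *reversal* — and can be opted in.  The cap keeps Delay finite and bounded
  for non-responding fish, matching how non-responders are plotted at
  invisible wavelengths.
* **Duration** — following time / total rotation time.  Acclimatization is
  excluded from the denominator: the test begins when rotation begins.
* **Angular velocity** — mean |ω| over the *whole* rotation phase, not only
  following samples.  A stimulus-blind but active fish must still show its
  locomotor speed (blind-control cohorts maintain angular velocity while
  never following); a following-only definition would make the parameter
  undefined exactly where it is diagnostic.
* **Distance** — Σᵢ dᵢ·Δθᵢ/360 over inter-sample intervals, where dᵢ is the
  drum direction of the epoch owning the interval's left endpoint.  Computed
  from raw unwrapped-angle increments (not smoothed ω), so it telescopes to
  the direction-weighted net angle per epoch exactly and is unaffected by
  smoothing; intervals inside unbridged gaps contribute nothing.  It may be
  negative (net swimming against the drum).

A session whose rotation phase has < 50 % valid samples is flagged
`qc_fail`; parameters are still reported.

## Statistics cascade

The analysis unit is a complete n fish × k wavelengths matrix of one
parameter (repeated measures: the same fish across wavelengths).

1. **Bartlett's test** gates on variance homogeneity across wavelengths at
   α = 0.05 (the gate level is an assumption, exposed as a parameter).  An
   undefined statistic (zero-variance column) falls through to the
   non-parametric branch.
2. **Parametric branch.**  Sphericity is tested by the likelihood-ratio
   criterion on the orthonormal-contrast covariance, W = det(S_c) /
   (tr(S_c)/(k−1))^(k−1), with the standard first-order chi-square
   approximation on k(k−1)/2 − 1 degrees of freedom (for single-group
   designs this is the Mauchly-type form of the multisample test; k = 2 is
   degenerate and returns p = 1; when n ≤ k−1 the covariance is singular,
   the test is flagged inestimable and the ε adjustment is applied
   unconditionally).  The omnibus is one-way repeated-measures ANOVA,
   F = MS_condition / MS_(condition×subject) on (k−1, (k−1)(n−1)) df; when
   sphericity is rejected, both df are multiplied by the Greenhouse–Geisser
   ε = tr(S_c)² / ((k−1)·tr(S_c²)), clamped to [1/(k−1), 1].  All-pairs
   comparisons are paired t-tests on within-fish differences — robust to
   sphericity violation, rather than pooled-error contrasts — under
   Shaffer's modified sequentially rejective Bonferroni procedure: step-i
   multiplier = the largest logically achievable number of true pairwise
   hypotheses after i−1 rejections, found by exhaustive enumeration of set
   partitions of the k levels ((3,1,1) for k = 3; (6,3,3,3,2,1) for k = 4);
   adjusted p is the running maximum of p₍ᵢ₎ × multiplierᵢ.
3. **Non-parametric branch.**  Steel–Dwass: each pair is midranked on its
   own pooled sample; t = (W − E[W])/√Var[W] with the exact tie-corrected
   permutation variance n_a·n_b/(N(N−1))·(Σr² − N(N+1)²/4); p =
   P(Q_k ≥ |t|·√2) under the infinite-df studentized range.  Steel
   (many-to-one): the same standardized statistic against the control
   column, referred to the maximum (absolute) component of an equicorrelated
   (ρ = ½) multivariate normal.  Both are implemented in their standard
   independent-samples form; their application to repeated measures is
   flagged in the output notes rather than silently accepted, since no
   repeated-measures variant of either procedure is standard.

The studentized-range and equicorrelated-max-normal tails are evaluated as
one-dimensional latent-normal integrals with Simpson's rule on a fixed
4001-point grid over ±8.5; absolute error is below 1e-6 (checked against
scipy's finite-df studentized range at df = 10⁷ and against bivariate-normal
rectangle probabilities).

Small-sample behaviour: with six fish per wavelength the rank statistics
are coarse lattices, and the asymptotic references make both rank
procedures *conservative* — the all-pairs familywise error at n = 6, k = 5
is bounded above by 10 × 2/924 ≈ 0.022 (each pair can only reject at its
two most extreme rank sums).  Calibration approaches the nominal 0.05 as n
grows.  The tests never err anti-conservative.

## Positivity rule and boundary estimation

Published positivity judgments in this assay combine all four parameters by
inspection; the package makes the rule explicit and reproducible, built on
Distance because it converges to zero exactly when vision is lost.  A
cohort at one wavelength is OMR *positive* iff (a) mean Distance exceeds a
zero band of 1.0 round and (b) an exact one-sided sign-flip permutation
test of Distance > 0 rejects at α = 0.05 (2ⁿ enumeration for n ≤ 16, so the
smallest attainable p with six fish is 1/64; cohorts smaller than five can
never be called positive by the test, and classification refuses n < 2).
The 1.0-round band is the scale of what a stimulus-blind random swimmer
accumulates over a 120 s rotation phase (simulated blind cohorts stay
within ±1 round almost surely); both constants are exposed.

The boundary estimate is the interval (last wavelength with everything
below it positive, next tested wavelength).  Non-monotone patterns — a
positive above a negative — are flagged and resolved conservatively to the
smallest consistent boundary.  The two-round planner refines a coarse
boundary: the fine grid covers one fine-step beyond each endpoint of the
coarse interval, snapped outward to step multiples and clipped to the
round-1 tested range (a 50 nm boundary of (800, 850) refined at 20 nm gives
780–880 nm).

The continuous alternative fits a decreasing three-parameter logistic
A / (1 + exp((λ − λ₅₀)/s)) to cohort mean Distance (normalized to the
shortest tested wavelength) by least squares.  The fit *refuses* — a
status, not a number — when fewer than four wavelengths are given, when no
decrease is detectable, or when the fitted midpoint is not bracketed by the
tested grid.  Decrease detectability uses the Wald 95 % CI of the inverse
slope when the fit is well-conditioned; for step-like transitions the slope
is unidentified (huge variance) even though the decrease is obvious, so the
check falls back to requiring the fitted drop across the grid to exceed
twice the residual RMS.

## Synthetic cohorts

The generator emulates the behavioural phenotypes the assay encounters, at
the study's design points (six fish per wavelength; coarse grid 700–1000 nm
step 50, fine grid 780–880 nm step 20; 30 fps sampling, a typical consumer
camera rate).

* **follower** — a two-state (idle/engaged) continuous-time Markov chain.
  At every drum reversal the chain resets to idle and an exponential
  reaction latency (mean 1 s) must elapse before re-engagement; the
  engagement rate (0.2 Hz) is multiplied by a logistic detection
  probability p(λ) = 1/(1 + exp((λ − λ₅₀)/s)); disengagement rate 0.3 Hz.
  Engaged, ω = direction × drum speed × gain (gain 1.0) plus attenuated
  noise; idle, ω is stationary AR(1) noise (sd 10 deg/s, correlation time
  1 s).  These rates give a fully-visible duty cycle of ≈ 0.4 and net
  distances of ≈ 6–8 rounds per session, the range real OMR-positive
  cohorts show at clearly visible wavelengths.  The psychometric width
  default s = 3 nm makes the behavioural collapse complete within about one
  fine-grid step, matching how sharply real cohorts drop between adjacent
  20 nm wavelengths.  The logistic is the minimal monotone sigmoid and is
  also what the threshold fit assumes; to avoid validating the fit only
  against its own functional form, tests also generate step-function
  transitions.
* **random_walker** — idle dynamics throughout (AR(1) ω, sd 20 deg/s): an
  active but stimulus-blind swimmer, the eyeless-cavefish-style negative
  control.  Per-fish net distance has sd ≈ 0.9 rounds, so cohort means stay
  within the ±1 round zero band almost surely.
* **turner** — ω of drum-speed magnitude with sign flips at Poisson rate
  1.5 Hz, stimulus-independent: the frequent-turner phenotype that makes
  some species untestable.  It reproduces that signature qualitatively:
  near-zero net Distance with maintained angular velocity and a reaction
  delay clearly above a follower's.  Its Delay is elevated but *not* near
  the 30 s cap: at any turn rate slow enough to keep |ω| near drum speed
  after smoothing, sign-matching runs ≥ 1 s still occur within a few
  seconds of each reversal, so a near-cap mean delay is not reachable for
  this phenotype under the bout-based following definition.
* **still** — ω ≈ 0 with 2 deg/s noise; the seldom-swimming phenotype.

The radial coordinate is a reflected random walk in an annular band
(3–8 cm); per-fish heterogeneity is multiplicative log-normal (sd 0.2) on
gain and latency, drawn once per fish so the same animal is consistent
across wavelengths.  Every trajectory is deterministic in (base seed, fish
index, wavelength).

What the generator does *not* emulate: body kinematics and hydrodynamics,
luminance/contrast-dependent engagement, non-stationary motivation, tracker
noise and dropouts (tests inject those separately), and any true
behavioural noise spectrum — the AR(1) choice is a modelling decision.
Passing tests therefore demonstrate correctness of the computational
pipeline under a plausible behavioural model, not validity of the model for
any particular species.

## Problem sizes and numerics

Simulation-based checks use the study-scale design (6 fish × 5–7
wavelengths, 150 s sessions at 30 fps) with 100 replicates for recovery and
negative-control suites and 1000 replicates for null calibrations; the
acceptance script uses 40 replicates per suite and 500 calibration
replicates as its reporting scale.  Degenerate inputs are decided, not
accidental: zero-variance columns fall to the non-parametric branch; fully
tied pairs give p = 1; isolated samples between gaps get no velocity
estimate; the last sample of a session owns no time interval (half-open
throughout), which is what makes Duration = 1.0 and Distance = 20 rounds
exact for a lockstep follower.
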