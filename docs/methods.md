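# Methods

This note documents the models, conventions and design choices behind
feedkin: what each stage computes, which parameters matter, what the
synthetic-data generator does and does not emulate, and the numerical
details a maintainer would need.

## Event detection and phase segmentation

The eating cycle is defined kinematically: it begins the moment the hand
origin (midpoint between the wrist styloid processes) leaves a proximity
sphere around the mouth landmark and ends just before it next leaves it.
In the laboratory protocol this pipeline descends from, those moments were
confirmed on synchronized video; feedkin replaces video confirmation with
distance thresholds, which is the central artifact decision of the package:

| parameter | default | meaning |
|---|---|---|
| `d_mouth` | 0.10 m | hand–mouth radius; outward crossing = cycle boundary, inward = Tr/Mo boundary |
| `d_bowl` | 0.08 m | hand–bowl radius; inward crossing = Re/Ta boundary |
| `hysteresis` | 0.02 m | extra radius a bowl exit must clear (Ta/Tr boundary at `d_bowl + hysteresis`), preventing chatter at the rim |
| `min_dwell` | 0.05 s | a crossing counts only if the new state persists this long |
| `smoothing_cutoff` | 6 Hz | zero-phase 2nd-order Butterworth on positions before distances/speeds |

6 Hz is the conventional cutoff for upper-limb position data; voluntary
feeding movements live well below it while sensor noise does not. All five
values are config-exposed because they are conventions, not measurements.
Windows are half-open `[start, end)` with 0-based indices; the four phase
windows partition each cycle exactly, which the suite asserts invariantly.

Pauses during reaching (hand speed below 5% of the within-reach peak for at
least 0.3 s) are flagged but never excluded — they are part of natural
chopstick use. Failure modes that require observation (looking away,
dropping food, double scooping) cannot be detected kinematically and arrive
as annotation flags; the analysis cycle is the first successful one, and a
participant-exclusion signal is raised when every candidate cycle failed.

## Joint-angle summaries

Within each phase the per-channel summary is max, min, and range = max −
min (always ≥ 0, matching how joint-angle-change tables are conventionally
reported), plus movement time = window length / sample rate. Extrema are
taken on raw angles by default; an optional low-pass is available but off,
since smoothing systematically shrinks extrema. Three channels are negated
on import from model conventions that record the opposite direction
(palmar flexion → dorsiflexion, radial → ulnar deviation, left → right neck
rotation); the sign map is an involution and summaries are invariant under
applying it twice.

## Hand transport metrics

All speed-based quantities use the scalar tangential speed of the filtered
hand origin (central differences, one-sided at window edges). Mean velocity
is defined as path length / duration — the natural pairing with "actual
distance traveled" — rather than the time-average of speed samples; for
uniformly sampled data the two differ only by edge effects. Relative
distance (path / straight-line between window endpoints) is ≥ 1 by the
triangle inequality and is reported with an explicit degenerate-window
error when the endpoints coincide within 1 mm. Peak timing uses the first
occurrence on exact ties.

The movement-unit counter implements the amplitude-and-interval rule
(defaults 20 mm/s and 150 ms, config-exposed):

1. local extrema of the speed profile by sign change of the first
   difference, plateaus collapsing to their midpoints;
2. a maximum closer than the interval to the previously retained maximum is
   merged with it, the larger winning (the interval rule applies to maxima
   only — the source definition is ambiguous, and this reading is recorded
   as the package's choice); a gap exactly equal to the interval retains
   the peak, enforced with a 1 ns comparison guard because sample gaps are
   exact multiples of 1/120 s;
3. each retained maximum is paired with the lowest speed since the previous
   retained maximum (or window start, so the initial rise counts as the
   first unit) and counted when the excursion exceeds the amplitude limit.

The count is provably non-increasing in the amplitude limit. It is *not*
strictly monotone in the interval: merging a sub-limit peak deepens the
trough available to its neighbor, which can create one countable unit. The
guaranteed monotone quantity is the retained-peak count (the limit of a
vanishing amplitude threshold), and that is what the property tests assert
for the interval; the full count is additionally checked against a
brute-force extremum-pair oracle for exact agreement.

## Paired statistics

The Wilcoxon signed-rank z follows the convention of the mainstream
statistical packages used in this literature: zero differences dropped,
midranks on tied |d|, variance n(n+1)(2n+1)/24 − Σ(t³−t)/48, no continuity
correction, two-sided normal p. With differences d = chopsticks − spoon, z
is negative when the chopstick condition ranks lower, matching the sign
convention of published tables. The effect size is r = z/√N with N = 2 ×
n_pairs; this is the only convention consistent with published (z, n, r)
triples (e.g. 3.945/√44 = 0.595 with 22 pairs), and it is regression-tested
against a 284-row transcription of such triples at three decimals.
Categories: |r| < 0.3 below small, 0.3–0.5 small, 0.5–0.6 medium, ≥ 0.6
large. Quartiles use the HAVERAGE rule (positions (n+1)p, numpy method
`weibull`), switchable to `linear`. No multiplicity correction is applied
by default (per-test α = .05, matching the analysis this mirrors); a Holm
option exists but is off.

A caveat the tests make explicit: the uncorrected asymptotic p is a coarse
approximation at very small n — against exact 2ⁿ enumeration it can
deviate by up to ≈0.1 at n = 6 and ≈0.05 at n = 10. That error is intrinsic
to the normal approximation of a lattice distribution, not to the
implementation; W⁺ itself matches brute-force enumeration exactly. The
default floor of 5 nonzero pairs triggers a warning, not an error.

## Synthetic feeding trials

`synth_trial` builds one trial as a chain of primitives: initial mouth
dwell → [reach → table dwell → transport → mouth dwell] × 3, yielding two
complete cycles. The hand path geometry places the bowl at forward-reach
distance from a seated posture (mouth–bowl separation ≈ 0.40 m by default);
the reach is two straight minimum-jerk halves with an optional pause slot
between them, and the transport is a curved path (straight chord plus a
perpendicular sine bump) traversed under a minimum-jerk arc-length law with
superimposed speed dips.

Three constructions make the ground truth exact rather than approximate:

* **Boundary alignment.** The phase boundaries of the emitted trial are the
  same threshold crossings the segmentation stage detects. Crossing times
  of straight minimum-jerk segments are known analytically (inverting the
  quintic position law), and transport crossings are read off a dense
  arc-length grid, so commanded *phase* durations are honored by solving
  the segment durations in closed form. Truth boundary indices are then
  recorded before noise is added.
* **Detour calibration.** The bump height is solved (Brent's method) so
  that the detour ratio *measured over the threshold-to-threshold window*
  equals the commanded relative distance, making commanded and recovered
  ratios agree to ~10⁻³ on noise-free trials.
* **Countable submovements.** k commanded submovements are realized as
  k − 1 speed dips placed between the transport's crossing times, wide and
  deep enough to survive the 6 Hz measurement filter. Peaks must sit at
  least ~0.2 s apart to stay countable under the 150 ms interval rule, so
  the commanded count is clamped to the feasible maximum for the drawn
  transport duration and the effective count is recorded per cycle — with
  default (study-scale) transport durations of 0.8–1.1 s that ceiling is
  3–4 units.

Joint-angle channels are monotone cubic (PCHIP) interpolations through
phase-locked keyframes: per phase, the keyframe levels default to the
published per-sex, per-condition medians of the maximum and minimum angles,
plus a per-participant offset, per-trial jitter, and white measurement
noise. Channels are *not* kinematically consistent with the hand path (no
forward kinematics) — they share only timing. Truth extrema are evaluated
from the clean sampled series over the truth windows.

Noise and variability defaults are artifact choices (the source reports no
within-participant variances): position noise 2 mm SD, angle noise 0.5° SD,
per-trial keyframe jitter 2°, between-participant angle SD 5°, lognormal
duration dispersion σ = 0.12 with a participant-level duration factor
(σ = 0.15). Pause prevalence defaults to 84% (chopsticks) and 65% (spoon);
pause length absorbs whatever reaching-phase budget remains beyond the
ballistic motion time (≈1.2 s), which is the only way reach-phase medians
of ~5 s can coexist with a sub-second ballistic reach.

What the simulator does **not** emulate — and hence what passing tests do
not show about real data: soft-tissue and sensor-slip artifacts, utensil
tip motion, kinematic coupling between angles and hand position,
head/gaze behavior, real between-channel correlation structure, and the
absolute spatial scale of real hand transports. On that last point: real
transporting-phase hand paths are short (~0.11–0.2 m) because the wrist
moves less than the utensil tip, but proximity radii of 0.10/0.08 m require
a longer path for non-degenerate event detection, so the simulator's
distances and speeds run larger than published medians while durations,
pause rates, detour ratios and angle levels match. Cross-condition
contrasts in absolute distance are therefore not faithfully signed in the
simulator default configuration.

Reproducibility: a `SimConfig.seed` fixes every draw; identical seeds give
bit-identical recordings and files.

## Statistical validation sizes

The suite calibrates the paired test on 1000 metric-level null cohorts of
22 pairs (rejection rate must land in [0.03, 0.07] at α = .05) and checks
power on 200 replicates of a −14° condition shift (between-participant SD
5°, noise SD 2°, n = 22; ≥95% must reject). Segmentation recovery runs 200
noise-free full-motion trials (50 seeds × 2 conditions × 2 sexes) with all
boundaries required within ±2 samples in ≥95% of cases; in practice the
worst observed error is 1 sample. Metric-level (rather than full-motion)
simulation is used for the two statistical calibrations because they
exercise only the test, and the full-motion path is covered by the
segmentation and metric-recovery checks.

## Known limitations

* Proximity-threshold segmentation is a proxy for observed food contact;
  on real data the Re/Ta boundary in particular inherits the bowl-radius
  convention.
* The asymptotic p is anti-conservative at n < ~10 (see above); an exact
  test is not provided because the mirrored analysis convention is
  asymptotic.
* The movement-unit count's interval rule is order-dependent by
  definition; alternative readings of the source definition (e.g. applying
  the interval to minima as well) would change counts on pathological
  profiles.
* `EventThresholds` defaults were chosen for desk-scale synthetic geometry;
  real recordings with different landmark definitions will need them
  re-tuned through the config.
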