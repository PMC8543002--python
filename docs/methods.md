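# Methods

This note documents the models, defaults and numerical choices behind
`skifuse`, and what the synthetic-data generator does and does not emulate.

## Protocol model

A session is `laps` identical laps tiled by ordered terrain segments, each
with an incline (grade fraction), intensity-dependent belt speed (km/h) and
duration (s). Time windows are half-open `[start, end)` on a session clock
starting at 0 s, which makes 1 Hz binning and lap/segment annotation
unambiguous. The packaged default is 7 × 180 s laps with segments
60/45/45/30 s at inclines +5/+2/+12/−10 % and LI speeds 15/16/10.8/20 km/h
(HI 20/21/14.2/20 km/h). Exact per-segment durations and speeds of the
original course are published only graphically, so this fixture is an
approximate reconstruction, calibrated so that the time-weighted mean speed
— with the realistic downhill display speed (30 km/h LI, 35 km/h HI)
substituted for the treadmill's safe 20 km/h downhill — is exactly
16.7 / 21.3 km/h, giving 5.8 / 7.5 km per session. Distance is linear in
durations and the mean speed is the duration-weighted mean of segment
speeds; both are reported to one decimal.

## Synthetic sessions

The generator emulates the statistical structure the analysis assumes, not
the physics of skiing. One seeded NumPy generator drives all noise, so a
session is bit-reproducible from (protocol, intensity, profile, seed).

**Sub-technique schedule.** Terrain maps to gears (moderate uphill → G3,
flat → G4, steep uphill → G2 with a configurable leading G3 fraction at HI,
default 0.35; downhill → "other"/tuck). Nominal cycle rates are
G2 55/65, G3 50/60, G4 42/50, other 42/46 cycles/min (LI/HI). Within each
schedule window the rate is adjusted by at most ~1 % so that an integer
number of cycles tiles the window; every cycle therefore carries a single
label, transitions sit exactly at segment boundaries (optional jitter), and
the recorded truth cycle rate is the adjusted one.

**Chest sway.** The mediolateral channel is a periodic sway whose minima
("left-position") are the cycle starts. Gear signatures are harmonic
mixtures chosen to be separable and to keep exactly one local minimum per
cycle: G3 a clean fundamental (amplitude 2.8 m/s²), G2 adds a
half-frequency component (0.35 of the fundamental — every-other-cycle
asymmetry; amplitude 3.0), G4 a second harmonic (0.22, kept below the 0.25
bound above which extra minima appear; amplitude 3.2, largest
anteroposterior poling amplitude), "other" low-amplitude sway (0.75).
Per-axis Gaussian noise, default SD 0.15 m/s².

**Contact events.** Each poling cycle carries one pole push per side
(simultaneous, as in double-pole-synchronized gears) and one ski contact
per side offset by half a cycle. Contact durations are fixed fractions of
the cycle period (pole 0.28–0.40, ski 0.55–0.66; shorter at HI and always
pole < ski). The streams contain exactly the operators the detectors look
for: a 45 Hz decaying vibration burst whose first peak is the pole plant, a
sharp acceleration peak at the angular-speed minimum for pole lift-off, a
pitch-rate bump at ski plant, a quiet (< 30°/s) dwell while the ski is on
the ground, and a negative vertical-acceleration peak at ski lift-off —
making the detectors falsifiable sample-by-sample.

**Physiology.** Heart rate, oxygen uptake and muscle oxygenation follow
first-order kinetics `y(t+1) = y(t) + (target − y)(1 − e^{−1/τ})` toward
terrain-dependent setpoints (in % of individual max), clamped to [0, 100].
Default time constants: HR 25 s, V̇O₂ 30 s, TSI 10 s. At HI the HR
*setpoint* additionally ramps by the drift rate (default 0.35 %-points/min),
which produces a lap-7 minus lap-2 change of ≈ 15 × drift (the laps are
15 min apart); the ramp-lag bias `drift·τ/60` is constant and cancels in
that difference. The `first_order_response` operator also accepts a
constant-inflow `drift` term, which by itself converges to a steady offset
of `drift·τ/60` — the generator therefore applies drift to the setpoint,
not through that term. Setpoints were chosen so that session means land in
the physiological range typical of elite skiers at these intensities
(LI ≈ 74 %HRmax / 58 %V̇O₂max; HI ≈ 90 / 79), with arm oximetry below leg
oximetry and both depressed by workload.

**Kinematics, forces and power truth.** The CoM moves at the belt speed
with cycle-locked oscillations (±0.30 m/s forward, 0.25 m/s sway,
0.12 m/s vertical); body-segment markers are constant offsets from the CoM
whose mass-weighted combination cancels exactly, plus 2 mm noise. Pole
force is a `sin²` bump inside each truth poling phase, scaled per cycle so
that the cycle-average of `F·v_CoM` equals a target pole share of the work
rate (58/60/48 % of `P_cycle` for segments 1–3 at lap 1, declining 7
%-points linearly to the last lap; left/right split 48/52). The work rate
is `m g v (sin θ + μ cos θ)`, `μ = 0.016`. Downhill cycles carry no power
truth (the skier holds a rope; the partition is undefined there).

**What the generator does not emulate** — and hence what passing tests do
not show about real data: soft-tissue and sensor artefacts, within-gear
technique variability between athletes, gradual (non-stepwise) sub-technique
transitions, breath-by-breath gas-exchange noise structure, marker
occlusion, and any biomechanically realistic limb trajectories. Classifier
accuracy near 100 % on this corpus demonstrates the pipeline's correctness
on well-separated classes, not field performance on athlete recordings.

## Analysis defaults and numerical choices

* Cycle detection: Gaussian smoothing σ = 0.15 s; minima prominence
  threshold 0.3 × SD of the smoothed signal. Both configurable. Constant
  or aperiodic signal ⇒ no cycles.
* Features (12): per-axis means and variances of the three accelerometer
  channels, mediolateral amplitude, dominant-frequency power ratio,
  second-harmonic and half-frequency ratios, half-cycle RMS asymmetry,
  duration. Classifier: standardized features → RBF SVC (C = 10,
  one-vs-one); "other" is a real training class, not a rejection rule.
  A label-override table keyed by cycle start time provides the
  manual-correction hook.
* Pole contact: acceleration channels are median-centred (exact invariance
  to gravity offsets); vibration energy = 20 ms moving SD of the 20–60 Hz
  band; onset threshold = median + 4 robust SDs, with regions shorter than
  8 ms or barely above threshold discarded and each onset refined to 15 %
  of the regional envelope peak (a fixed low threshold otherwise reacts to
  filter ringing). Terminal search window ±75 ms around the first
  angular-speed minimum after the plant. Ski contact: low-rotation phase =
  |pitch| < 30°/s for ≥ 100 ms; terminal peak searched 120 ms past the
  phase. Events that cannot be completed are skipped with a warning.
* CoM velocity: 4th-order zero-phase low-pass at 10 Hz (configurable,
  `None` disables) before central differences.
* Master timeline: per-second means (2-s means for TSI, step-held 10-s
  mixing-chamber V̇O₂; a 30-s moving average is provided for plotting
  only); cycle-level values are broadcast to the seconds whose midpoint the
  cycle spans; missing data are explicit NaN so that the even laps without
  motion capture never bias power means.
* TDF/TDC operate on the 1 Hz series without extra smoothing; lap 1 is
  excluded from TDF and from the physiological TDC reference because the
  session starts from rest. "% of max level" uses HRmax / V̇O₂max where an
  individual maximum exists and the per-session maximum for TSI (no
  test-day maximum exists for oximetry; configurable).
* Aggregations drop groups observed for less than 6 s. Session deltas
  report ratio-scale variables as Δ plus an integer-rounded % of the LI
  mean, percentage-scale variables as %-point differences.
* Statistics: Shapiro–Wilk gate at α = 0.05; Wilcoxon drops zero
  differences and uses the exact null for n ≤ 25 without ties; an all-zero
  difference vector is flagged degenerate with p = 1. The repeated-measures
  ANOVA is the univariate decomposition with each within factor tested
  against its factor-by-subject interaction; no sphericity correction by
  default, Greenhouse–Geisser on request. Tukey comparisons use the
  studentized range on the effect's own error mean square, so adjusted
  p-values are never below the matching pooled-error t-test p-values.

## Known limitations

* Cycles adjacent to a sub-technique transition inherit a boundary
  localization error of up to ~50 ms from the waveform change at the join;
  this propagates into their per-cycle mean power (errors up to ~7 % there,
  ~1 % elsewhere). In practice such transition cycles belong to the
  "other" class and are excluded or manually corrected.
* The cycle work rate omits air resistance and kinetic-energy fluctuation
  terms (constant-speed indoor treadmill); `P_ski` inherits any error in
  `P_cycle` because it is defined as the residual.
* The Tukey procedure pools over the other within factor and does not model
  its correlation structure beyond the chosen error term.
* Problem sizes in the test suite are deliberately modest: most properties
  are exercised on a 3 × 60 s miniature of the protocol, with the full
  21-min session reserved for the end-to-end and precision checks, and the
  classifier corpus fixed at 20 full sessions.
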