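# skifuse

Multi-sensor analysis of roller-ski skating on varying terrain — from raw
sensor streams to cycle-level biomechanics, physiological fluctuation
statistics and low- vs high-intensity (LI/HI) session comparisons.

Cross-country ski training and racing is interval-like by nature: terrain
forces continuous shifts in work rate, sub-technique ("gear") selection and
the split of propulsion between poles (arms) and skis (legs). `skifuse`
implements the laboratory pipeline used to quantify those responses for
treadmill roller-ski sessions on a standardized varying-terrain course
(7 identical 3-min laps: moderate uphill 5%, flat 2%, steep uphill 12%,
simulated downhill), and a synthetic-data generator that produces complete
sensor recordings with ground truth so every stage is testable without
access to athlete data. It is written for sport scientists and biomechanics
researchers who work with multi-rate wearable-sensor data in Python.

## What the pipeline computes

* **Cycle detection & sub-technique classification** — movement cycles are
  segmented from the Gaussian-smoothed mediolateral chest acceleration
  (a cycle starts at the "left-position" sway minimum) and classified into
  the skating gears G2, G3, G4 or "other" (tuck, transitions, non-skiing)
  by an RBF-kernel support vector machine over a 12-dimensional per-cycle
  feature vector. Cycle rate and length follow from
  `CR = 60/duration` and `CL = v̄ · duration`, so `CL·CR/60 = v̄` exactly.
* **Contact times** — pole contact from the wrist IMU (initial contact =
  first acceleration peak at the vibration onset of the pole plant;
  terminal = largest acceleration peak near the angular-speed minimum) and
  ski contact from the ski IMU (pitch-rate peak before, and last negative
  vertical-acceleration peak after, the low-rotation ground-contact phase).
* **Power partitioning** — pole power per side as the force–velocity dot
  product `P_pole = F·v_CoM` (axial pole force resolved along the pole
  direction, CoM velocity from differentiated marker kinematics through a
  reduced body-segment table), cycle work rate
  `P_cycle = m g v (sin θ + μ cos θ)` with rolling friction `μ = 0.016`,
  and the residual `P_ski = P_cycle − P_pole`; relative shares satisfy
  `%P_pole + %P_ski = 100` exactly.
* **Master timeline & fluctuation statistics** — all variables are reduced
  to one 1 Hz table (2-s means for oximetry, step-held 10-s mixing-chamber
  oxygen uptake), then summarized by the terrain-dependent fluctuation
  `TDF = Σ_{lap 2..7} (%Peak − %Min) / 6` and the time-dependent change
  `TDC = %Mean(lap 7) − %Mean(lap ref)` (ref = 2 for physiological, 1 for
  biomechanical variables), plus grouped means, sub-technique time
  distributions and HI−LI session deltas.
* **Statistics** — Shapiro–Wilk-gated paired t / Wilcoxon signed-rank
  comparisons, two-way repeated-measures ANOVA (lap × segment, subject as
  repeated factor) and Tukey post-hoc pairwise comparisons.

## Worked example

```python
import skifuse as sf
from skifuse.synthgen import generate_session

session = generate_session(intensity="LI", seed=7)   # all 12 streams + truth
analysis = sf.analyze_session(session)               # cycles -> contacts -> power -> master
power = analysis.cycle_table.dropna(subset=["pct_p_pole"])
print(power.groupby("segment")[["p_cycle_w", "pct_p_pole"]].mean().round(1))
```

Running `examples/04_contacts_and_power.py` (which does exactly this)
prints:

```
contact times per sub-technique (side-averaged):
  G2: CT_pole   437 ms, CT_ski   724 ms, %CT_pole 39.8%
  G3: CT_pole   430 ms, CT_ski   768 ms, %CT_pole 35.8%
  G4: CT_pole   450 ms, CT_ski   874 ms, %CT_pole 32.0%

power partition over 491 cycles (odd laps, segments 1-3):
  segment 1: P_cycle   216 W, %P_pole 55.1%, %P_ski 44.9%
  segment 2: P_cycle   126 W, %P_pole 57.7%, %P_ski 42.3%
  segment 3: P_cycle   318 W, %P_pole 44.8%, %P_ski 55.2%

%P_pole by lap: {1: 55.8, 3: 53.5, 5: 51.2, 7: 48.8}
```

Poling is briefer than ski contact in every gear; the pole share of
propulsion is highest on flat terrain, lowest on the steep uphill, and
drifts toward ski power across laps. Power exists only for odd laps
(the laps the motion-capture system records) and not for the downhill,
where the skier holds a rope in a tuck. The other scripts in `examples/`
each demonstrate one capability: protocol totals, full-session generation,
classification, and fluctuation/ANOVA statistics.

The packaged default protocol reproduces the whole-session totals of
5.8 km at 16.7 km/h (LI) and 7.5 km at 21.3 km/h (HI), using a realistic
downhill display speed (30/35 km/h) in place of the treadmill's safe
20 km/h downhill when totalling distance.

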