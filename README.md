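# stepthrow

Simulation and analysis of anticipatory postural activity in visually
guided stepping.

Before a person lifts a foot to step, postural ("pre-step") activity
shifts the centre of pressure (CoP) toward the stepping foot and
accelerates the body's centre of mass (CoM) away from it and forwards, so
that at foot lift the body carries momentum matched to the intended step —
a ballistic "throw" the landing foot then "catches".  `stepthrow` is a
library for researchers in motor control and gait biomechanics who want to
quantify that coupling from dual force-plate and foot-marker recordings,
and to probe it with mid-preparation target jumps.  Because such
recordings are rarely shared, the package includes a first-class synthetic
trial generator with full ground truth, so every stage of the analysis can
be validated by parameter recovery.

## What it computes

* **CoM kinematics** — net ground-reaction force over both plates divided
  by body mass (Newton's second law), quiet-stance baselined; CoM velocity
  by trapezoidal integration anchored at pre-step initiation; CoM jerk by
  differentiation.  Zero-lag 2nd-order Butterworth filtering (30 Hz force,
  15 Hz markers).
* **Gait events** — pre-step initiation (ML CoP velocity toward the
  stepping foot > 5 cm/s sustained 50 ms after target illumination), foot
  lift (stepping-side vertical force < 1% body weight), landing (hallux
  speed < 2 cm/s on all three axes), final foot position (three-marker
  mean), plus jump-trial exclusion rules.
* **Modulation latency** — per-subject, per-time-point 95% ellipses of
  (ML, AP) CoM jerk from constant-central trials aligned at initiation; a
  jump trial's latency is the first persistent departure from that
  envelope at least 100 ms after the new target lit up.  For a trial
  tested against reference trials `x_1..x_n` with per-time mean `x̄(t)`
  and covariance `S(t)`, the trial is outside at `t` when

      (x(t) − x̄(t))ᵀ S(t)⁻¹ (x(t) − x̄(t)) > χ²₂(0.95) = 5.99.

* **Group statistics** — one-sample Hotelling's T² on within-subject 2-D
  differences (`T² = n x̄ᵀS⁻¹x̄`, `F = (n−p)/(p(n−1)) · T²` on `(p, n−p)`
  df), Hotelling group-mean confidence ellipses, Mardia's multivariate
  skewness/kurtosis normality screens, one-way repeated-measures ANOVA
  with Greenhouse–Geisser correction, Bonferroni control.
* **Synthetic cohorts** — the 10-target polar layout (20/35/50 cm at
  0°/25°/50°), 160-trial schedules with exact condition counts
  (P(jump) = 0.25, P(jump | central) = 0.33), an 80 N vertical-force
  -difference jump trigger with 16.5 ms display delay, pre-step durations
  561 (89) ms prolonged by ~69 ms in jump trials, and log-normal
  modulation reaction latencies (median 223 ms by default).

## Worked example

```sh
python examples/03_modulation_latency.py
```

```
jump trials analyzed: 60
excluded (outside ellipse at jump): 3.3%
modulation detected: 100.0%
  ... of which before foot lift: 98.3%
median latency: 238 ms (IQR 163 ms)

injected median latency: 239 ms -> recovered 238 ms
```

Three simulated subjects performed 80 trials each; of the 60 target-jump
trials, two were already outside the reference envelope when the target
jumped (excluded), and every remaining trial showed a detectable
modulation of the pre-step activity, almost always before the foot left
the ground.  The pooled median latency of 238 ms recovers the generator's
injected reaction latency (239 ms in this draw) to one millisecond —
the detector measures what was put in.  The other examples cover cohort
simulation (`01`), per-trial event detection (`02`, errors of a few
milliseconds against ground truth) and the Hotelling/ANOVA group analysis
(`04`).

There is also a thin CLI mirroring the pipeline stages:

```sh
stepthrow generate --seed 1 --out cohort/        # trial bundles + ground truth
stepthrow events --in cohort/ --out events.csv
stepthrow run-all --seed 1 --out report/         # everything, in memory
```

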