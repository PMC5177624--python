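"""Detect the gait events of a single trial and compare with ground truth.

Runs the full per-trial chain — reflection to a right-sided step, zero-lag
filtering, CoM kinematics, CoP-velocity initiation, 1% body-weight foot
lift, hallux-speed landing — and prints each detected time next to the
generator's ground truth.
"""

from stepthrow import AnalysisConfig, GeneratorParams, analyze_trial, simulate_cohort

params = GeneratorParams(n_subjects=1, trials_per_subject=16, seed=2)
trials, gt = simulate_cohort(params)
cfg = AnalysisConfig()

trial = next(t for t in trials if t.condition == "jump")
truth = gt.set_index("trial_id").loc[trial.trial_id]
res = analyze_trial(trial, cfg)
ev = res.events

print(f"trial {trial.trial_id}: {trial.side}-sided {trial.condition} step "
      f"{truth['initial_target']} -> {truth['final_target']}")
for name, det, true in [("initiation", ev.initiation, truth["initiation"]),
                        ("foot lift", ev.foot_lift, truth["foot_lift"]),
                        ("landing", ev.landing, truth["landing"])]:
    print(f"  {name:<11} detected {det:7.3f} s   truth {true:7.3f} s   "
          f"error {1e3 * (det - true):+5.1f} ms")
print(f"  pre-step duration: {1e3 * ev.prestep_duration:.0f} ms")
print(f"  CoM velocity at foot lift (ML, AP): "
      f"({res.v_lift[0]:+.3f}, {res.v_lift[1]:+.3f}) m/s "
      f"(truth {truth['v_lift_ml']:+.3f}, {truth['v_lift_ap']:+.3f})")
print(f"  landed - ideal foot position: "
      f"({1e3 * res.final_minus_ideal[0]:+.1f}, "
      f"{1e3 * res.final_minus_ideal[1]:+.1f}) mm")

# Detection errors of a few milliseconds reflect filtering and sensor
# noise; the ML velocity is negative because the body is thrown away from
# the stepping foot before the step.
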