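"""Generator contracts: schedule composition, trigger emergence, ground-truth
ordering, quiet-stance physics and reproducibility."""

import numpy as np
import pytest

from stepthrow.config import AnalysisConfig, ConfigError, GeneratorParams
from stepthrow.core import JUMP_TARGETS
from stepthrow.kinematics import com_acceleration
from stepthrow.pipeline import analyze_trial
from stepthrow.synth import make_schedule, simulate_cohort


class TestSchedule:
    def _default_schedules(self, seed=0):
        params = GeneratorParams(n_subjects=2)
        return params, make_schedule(params, np.random.default_rng(seed))

    def test_counts_realize_printed_probabilities(self):
        _, schedules = self._default_schedules()
        for plans in schedules:
            assert len(plans) == 160
            jump = [p for p in plans if p.condition == "jump"]
            const = [p for p in plans if p.condition == "constant"]
            assert len(jump) == 40   # 25% of trials jump
            central_illuminated = [p for p in plans if p.initial_target == "central"]
            # P(jump | central illuminated) = 40 / 120
            assert len(jump) / len(central_illuminated) == pytest.approx(1 / 3)
            cc = [p for p in const if p.initial_target == "central"]
            assert len(cc) == 80     # P(central | constant) = 0.67
            assert len(cc) / len(const) == pytest.approx(2 / 3, abs=0.005)
            for t in JUMP_TARGETS:
                assert sum(p.final_target == t for p in const) == 10  # p = 0.083
                assert sum(p.final_target == t for p in jump) == 10   # p = 0.25

    def test_sides_balanced_within_every_cell(self):
        _, schedules = self._default_schedules()
        for plans in schedules:
            for cond in ("constant", "jump"):
                for t in ("central",) + JUMP_TARGETS:
                    cell = [p for p in plans
                            if p.condition == cond and p.final_target == t]
                    if cell:
                        lefts = sum(p.side == "left" for p in cell)
                        assert abs(len(cell) - 2 * lefts) <= 1

    def test_same_seed_reproduces_schedule(self):
        params = GeneratorParams(n_subjects=1)
        s1 = make_schedule(params, np.random.default_rng(5))
        s2 = make_schedule(params, np.random.default_rng(5))
        assert s1 == s2

    def test_different_seeds_same_composition_different_order(self):
        params = GeneratorParams(n_subjects=1)
        s1 = make_schedule(params, np.random.default_rng(1))[0]
        s2 = make_schedule(params, np.random.default_rng(2))[0]
        assert [p.condition for p in s1] != [p.condition for p in s2]
        key = lambda s: sorted((p.condition, p.final_target, p.side) for p in s)
        assert key(s1) == key(s2)

    def test_unrealizable_total_rejected(self):
        with pytest.raises(ConfigError, match="blocks of 16|multiple of 16"):
            GeneratorParams(trials_per_subject=50).validate()


class TestTriggerRule:
    def test_force_difference_crosses_80N_exactly_at_trigger(self, small_cohort):
        _, trials, gt = small_cohort
        gtm = gt.set_index("trial_id")
        checked = 0
        for t in trials:
            if t.condition != "jump":
                continue
            diff = t.plates["stepping"].force[:, 2] - t.plates["trailing"].force[:, 2]
            fs = t.plates["stepping"].fs
            i = int(round(gtm.loc[t.trial_id, "trigger"] * fs))
            assert np.abs(diff[i]) >= 80.0
            assert np.all(np.abs(diff[:i]) < 80.0)
            checked += 1
        assert checked >= 8

    def test_mean_trigger_latency_matches_configuration(self):
        params = GeneratorParams(n_subjects=2, trials_per_subject=80, seed=9)
        _, gt = simulate_cohort(params)
        lat = (gt["trigger"] - gt["initiation"]).dropna().to_numpy()
        se = params.trigger_latency_sd / np.sqrt(len(lat))
        assert abs(lat.mean() - params.trigger_latency_target) <= 2 * se


class TestGroundTruth:
    def test_event_ordering_invariant(self, small_cohort):
        _, _, gt = small_cohort
        assert (gt["initiation"] < gt["foot_lift"]).all()
        assert (gt["foot_lift"] < gt["landing"]).all()
        jump = gt.dropna(subset=["trigger"])
        assert (jump["initiation"] < jump["trigger"]).all()
        assert (jump["trigger"] < jump["led_on"]).all()
        assert (jump["led_on"] < jump["modulation_onset"]).all()
        assert (jump["modulation_onset"] < jump["foot_lift"]).all()

    def test_quiet_stance_has_no_displacement_drift(self, small_cohort):
        # double integral of baselined net force / mass over quiet stance
        _, trials, _ = small_cohort
        for t in trials[:10]:
            plate = t.plates["stepping"]
            total = plate.force + t.plates["trailing"].force
            a = com_acceleration(total, t.subject.mass, plate.time,
                                 (plate.time[0], t.illumination_time))
            sel = plate.time <= t.illumination_time
            dt = 1.0 / plate.fs
            v = np.cumsum(a[sel, :2], axis=0) * dt
            x = np.cumsum(v, axis=0) * dt
            assert np.abs(x).max() < 1e-3  # < 1 mm

    def test_zero_throw_gain_yields_zero_lift_velocity(self, cfg):
        params = GeneratorParams(n_subjects=1, trials_per_subject=16, seed=21,
                                 throw_gain_ml=0.0, throw_gain_ap=0.0,
                                 noise_force_sd=0.0, noise_cop_sd=0.0,
                                 noise_marker_sd=0.0, motor_noise_sd=0.0)
        trials, gt = simulate_cohort(params)
        assert np.allclose(gt[["v_lift_ml", "v_lift_ap"]], 0.0)
        ta = analyze_trial(trials[0], cfg)
        assert np.abs(ta.v_lift).max() < 1e-3

    def test_zero_noise_detectors_recover_truth(self, clean_cohort, cfg):
        _, trials, gt = clean_cohort
        gtm = gt.set_index("trial_id")
        for t in trials:
            ta = analyze_trial(t, cfg, keep_jerk=False)
            row = gtm.loc[t.trial_id]
            assert abs(ta.events.initiation - row["initiation"]) <= 0.005
            assert abs(ta.events.foot_lift - row["foot_lift"]) <= 0.002
            # within one marker sample (5 ms) of the ground-truth settle
            assert abs(ta.events.landing - row["landing"]) <= 0.0055
            # landed foot position: exact target + bias (placement noise is
            # part of the landing position); tolerance covers the residual
            # sub-2 cm/s motion of the one-sample landing uncertainty
            np.testing.assert_allclose(
                ta.events.final_foot_position,
                [row["final_ml"], row["final_ap"]], atol=3e-4)

    def test_ground_truth_canonical_under_reflection(self, small_cohort):
        # left- and right-sided trials report ground truth in the same
        # right-canonical frame: ML landing positions all on the +ML side
        _, _, gt = small_cohort
        assert (gt["final_ml"] > 0).all()


class TestReproducibility:
    def test_same_seed_identical_cohort(self):
        params = GeneratorParams(n_subjects=1, trials_per_subject=16, seed=33)
        t1, g1 = simulate_cohort(params)
        t2, g2 = simulate_cohort(params)
        assert g1.equals(g2)
        np.testing.assert_array_equal(t1[0].plates["stepping"].force,
                                      t2[0].plates["stepping"].force)
        np.testing.assert_array_equal(t1[-1].markers.feet["stepping"],
                                      t2[-1].markers.feet["stepping"])

    def test_different_seed_different_data(self):
        p1 = GeneratorParams(n_subjects=1, trials_per_subject=16, seed=33)
        p2 = GeneratorParams(n_subjects=1, trials_per_subject=16, seed=34)
        _, g1 = simulate_cohort(p1)
        _, g2 = simulate_cohort(p2)
        assert not g1["initiation"].equals(g2["initiation"])
        assert sorted(g1["condition"]) == sorted(g2["condition"])
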