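"""Alignment, reference-ellipse geometry and divergence-latency detection on
constructed jerk ensembles with known properties."""

import numpy as np
import pytest
from scipy import stats

from stepthrow.config import AnalysisConfig
from stepthrow.modulation import (AlignedTrials, align_trials,
                                  cohort_modulation_summary,
                                  ellipse_boundary_radius_sq, mahalanobis_sq,
                                  modulation_latency, reference_ellipses)

FS = 1000.0
CFG = AnalysisConfig()


def _trace(rng, n_t, amp=1.0):
    """Smooth random 2-D trace: per-trial constant coefficients on slow
    sinusoids (amplitude-like between-trial variability)."""
    t = np.arange(n_t) / FS
    base = np.column_stack([np.sin(2 * np.pi * 1.5 * t),
                            np.cos(2 * np.pi * 1.1 * t)])
    coef = 1.0 + 0.1 * rng.standard_normal(2)
    wig = 0.05 * rng.standard_normal(2)
    extra = np.column_stack([np.sin(2 * np.pi * 2.3 * t + rng.uniform(0, 6)),
                             np.sin(2 * np.pi * 2.9 * t + rng.uniform(0, 6))])
    return amp * (base * coef + extra * wig)


def _ensemble(n_ref=40, n_t=1200, seed=0):
    rng = np.random.default_rng(seed)
    series = [(np.arange(n_t) / FS, _trace(rng, n_t)) for _ in range(n_ref)]
    anchors = [0.0] * n_ref
    return align_trials(series, anchors), rng


class TestAlignment:
    def test_identical_anchors_preserve_grid(self):
        aligned, _ = _ensemble(n_ref=4)
        assert aligned.rel_time[0] == pytest.approx(0.0)
        assert len(aligned.rel_time) == aligned.data.shape[1]

    def test_translation_invariance(self):
        rng = np.random.default_rng(1)
        vals = _trace(rng, 800)
        t = np.arange(800) / FS
        a1 = align_trials([(t, vals), (t, vals)], [0.2, 0.2])
        a2 = align_trials([(t, vals), (t + 0.1, vals)], [0.2, 0.3])
        np.testing.assert_allclose(a1.data, a2.data, atol=1e-12)

    def test_empty_overlap_rejected(self):
        t = np.arange(500) / FS
        v = np.zeros((500, 2))
        with pytest.raises(ValueError, match="overlap"):
            align_trials([(t, v), (t, v)], [0.0, 10.0])

    def test_short_overlap_rejected(self):
        t = np.arange(500) / FS
        v = np.zeros((500, 2))
        with pytest.raises(ValueError, match="overlap"):
            align_trials([(t, v), (t, v)], [0.0, 0.45], min_span=0.1)


class TestReferenceEllipses:
    def test_dispersion_boundary_is_chi2_quantile(self):
        # 95% membership boundary for 2-D Gaussian dispersion: chi2(2) = 5.991
        assert ellipse_boundary_radius_sq("dispersion", 0.95, 100) == \
            pytest.approx(5.9915, abs=1e-3)

    def test_prediction_boundary_inflates_small_samples(self):
        small = ellipse_boundary_radius_sq("prediction", 0.95, 10)
        large = ellipse_boundary_radius_sq("prediction", 0.95, 100000)
        assert small > large
        assert large == pytest.approx(5.9915, abs=0.01)

    def test_identical_references_regularized_and_flagged(self):
        t = np.arange(400) / FS
        data = np.tile(np.column_stack([np.sin(7 * t), np.cos(7 * t)]), (5, 1, 1))
        ell = reference_ellipses(AlignedTrials(t, data, FS))
        assert ell.regularized.all()
        d2 = mahalanobis_sq(ell, data[0])
        assert np.all(np.isfinite(d2))

    def test_gaussian_coverage_near_level(self):
        # per-time-point dispersion ellipse: independent same-law draws fall
        # inside with probability ~ the level
        rng = np.random.default_rng(2)
        n_ref, n_test, n_t = 2000, 2000, 20
        ref = rng.standard_normal((n_ref, n_t, 2))
        test = rng.standard_normal((n_test, n_t, 2))
        grid = np.arange(n_t) / FS
        ell = reference_ellipses(AlignedTrials(grid, ref, FS), level=0.95)
        inside = np.array([mahalanobis_sq(ell, tr) <= ell.radius_sq
                           for tr in test])
        assert inside.mean() == pytest.approx(0.95, abs=0.01)

    def test_too_few_references_rejected(self):
        t = np.arange(300) / FS
        with pytest.raises(ValueError, match="at least 3"):
            reference_ellipses(AlignedTrials(t, np.zeros((2, 300, 2)), FS))


def _inject(trace, rel_time, onset, amp=60.0):
    out = trace.copy()
    sel = rel_time >= onset
    ramp = np.minimum((rel_time[sel] - onset) / 0.01, 1.0)
    out[sel, 1] += amp * ramp
    return out


class TestModulationLatency:
    def _setup(self, seed=3):
        aligned, rng = _ensemble(n_ref=40, n_t=1200, seed=seed)
        ell = reference_ellipses(aligned, level=CFG.ellipse_level)
        probe = _trace(rng, 1200)
        return aligned, ell, probe

    def test_injected_divergence_recovered(self):
        _, ell, probe = self._setup()
        led = 0.1
        traj = _inject(probe, ell.rel_time, led + 0.200)
        res = modulation_latency(ell, traj, led, 1.0, CFG)
        assert res.detected and not res.excluded_outside_at_jump
        assert res.latency_ms == pytest.approx(200.0, abs=12.0)
        assert res.detected_before_foot_lift

    def test_unmodulated_trial_undetected(self):
        _, ell, probe = self._setup(seed=4)
        res = modulation_latency(ell, probe, 0.1, 1.0, CFG)
        assert not res.detected and res.latency is None

    def test_latency_floor_at_minimum_delay(self):
        # divergence injected only 30 ms after led-on: reported at 100 ms
        _, ell, probe = self._setup(seed=5)
        led = 0.1
        traj = _inject(probe, ell.rel_time, led + 0.030)
        res = modulation_latency(ell, traj, led, 1.0, CFG)
        assert res.detected
        assert res.latency_ms == pytest.approx(100.0, abs=2.0)

    def test_outside_at_jump_excluded(self):
        _, ell, probe = self._setup(seed=6)
        traj = _inject(probe, ell.rel_time, 0.05)  # diverged before led-on
        res = modulation_latency(ell, traj, 0.1, 1.0, CFG)
        assert res.excluded_outside_at_jump and not res.detected

    def test_brief_excursion_rejected_by_persistence(self):
        _, ell, probe = self._setup(seed=7)
        led = 0.1
        traj = probe.copy()
        sel = (ell.rel_time >= led + 0.2) & (ell.rel_time < led + 0.23)  # 30 ms
        traj[sel, 1] += 60.0
        res = modulation_latency(ell, traj, led, 1.0, CFG)
        assert not res.detected

    def test_scale_invariance_of_latency(self):
        _, ell, probe = self._setup(seed=8)
        led = 0.1
        aligned, rng = _ensemble(n_ref=40, n_t=1200, seed=8)
        traj = _inject(probe, ell.rel_time, led + 0.25)
        res1 = modulation_latency(ell, traj, led, 1.0, CFG)
        scaled = reference_ellipses(
            AlignedTrials(aligned.rel_time, aligned.data * 7.0, FS),
            level=CFG.ellipse_level)
        res2 = modulation_latency(scaled, traj * 7.0, led, 1.0, CFG)
        assert res1.detected and res2.detected
        assert res1.latency_ms == res2.latency_ms

    def test_detection_after_foot_lift_flagged(self):
        _, ell, probe = self._setup(seed=9)
        led = 0.1
        traj = _inject(probe, ell.rel_time, led + 0.400)
        res = modulation_latency(ell, traj, led, foot_lift_rel=0.3, cfg=CFG)
        assert res.detected and not res.detected_before_foot_lift


class TestSummary:
    def _frame(self, rows):
        import pandas as pd
        return pd.DataFrame(rows, columns=["trial_id", "subject", "direction",
                                           "excluded_outside_at_jump", "detected",
                                           "detected_before_foot_lift", "latency_ms"])

    def test_excluded_trials_never_enter_quantiles(self):
        df = self._frame([
            ("a", "S1", "medial", False, True, True, 200.0),
            ("b", "S1", "medial", False, True, True, 300.0),
            ("c", "S1", "lateral", True, False, None, None),
        ])
        s = cohort_modulation_summary(df)
        assert s["pooled"]["median_latency_ms"] == pytest.approx(250.0)
        assert s["pooled"]["pct_excluded_at_jump"] == pytest.approx(100 / 3)
        assert s["pooled"]["pct_detected"] == pytest.approx(100.0)

    def test_all_undetected_reports_absent_median(self):
        df = self._frame([("a", "S1", "medial", False, False, None, None)])
        s = cohort_modulation_summary(df)
        assert s["pooled"]["pct_detected"] == 0.0
        assert s["pooled"]["median_latency_ms"] is None
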