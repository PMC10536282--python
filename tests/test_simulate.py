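"""Simulator: template phase structure, determinism, scaling, ground truth."""

from __future__ import annotations

import numpy as np
import pytest

from gaitmark.core import ConfigurationError
from gaitmark.events import detect_threshold_events
from gaitmark.features import zero_cross_flags
from gaitmark.simulate import (
    SimConfig,
    TemplateParams,
    simulate_cohort,
    simulate_recording,
    stride_template,
)


class TestStrideTemplate:
    def test_swing_phase_has_zero_force(self):
        p = np.linspace(0.61, 0.99, 50)
        _, force = stride_template(p, TemplateParams(stance_fraction=0.6))
        assert np.all(force == 0.0)

    def test_land_gyro_crosses_zero_at_ic_phase(self):
        gyro, _ = stride_template(0.0, TemplateParams(zc_fraction=0.0))
        assert gyro == 0.0

    def test_water_lead_shifts_crossing(self):
        """With an IC lead of 5% of the stride the gyro is still negative at
        the IC phase and first crosses zero 5% of a stride later."""
        params = TemplateParams(zc_fraction=0.05)
        p = np.linspace(0.0, 0.2, 20001)
        gyro, _ = stride_template(p, params)
        assert gyro[0] < 0
        crossing = p[np.flatnonzero(np.sign(gyro[:-1]) < np.sign(gyro[1:]))[0]]
        assert crossing == pytest.approx(0.05, abs=1e-3)

    def test_two_sign_changes_per_direction(self):
        # start just inside the cycle so every crossing is interior
        p = 0.013 + np.arange(100000) / 100000.0
        gyro, _ = stride_template(p, TemplateParams())
        assert zero_cross_flags(gyro).sum() == 4

    def test_force_peak_is_unit(self):
        p = np.linspace(0.0, 0.6, 5001)
        _, force = stride_template(p, TemplateParams(stance_fraction=0.6))
        assert force.max() == pytest.approx(1.0, abs=1e-3)

    def test_bad_stance_fraction_rejected(self):
        with pytest.raises(ConfigurationError):
            TemplateParams(stance_fraction=1.2)


class TestSimulateRecording:
    def test_same_seed_is_byte_identical(self, clean_config):
        a, ev_a = simulate_recording("S01", 1.2, "none", clean_config)
        b, ev_b = simulate_recording("S01", 1.2, "none", clean_config)
        assert a == b and ev_a == ev_b

    def test_threshold_detector_recovers_truth_exactly(self, clean_recording):
        rec, truth = clean_recording
        det = detect_threshold_events(rec.vforce, fs=rec.fs)
        assert np.array_equal(det.ic, truth.ic)
        assert np.array_equal(det.fo, truth.fo)

    def test_support_halves_peak_force_exactly(self):
        cfg = SimConfig(n_subjects=1, duration=20, conditions=("none", "bws50"), seed=3)
        full, _ = simulate_recording("S01", 1.2, "none", cfg)
        half, _ = simulate_recording("S01", 1.2, "bws50", cfg)
        assert half.vforce.max() / full.vforce.max() == pytest.approx(0.5, abs=1e-9)

    def test_stride_count_matches_duration(self, clean_recording, clean_config):
        _, truth = clean_recording
        expected = clean_config.duration / clean_config.stride_time[1.2]
        assert abs(len(truth.ic) - expected) <= 1

    def test_event_counts_balanced(self, clean_recording):
        _, truth = clean_recording
        assert abs(len(truth.ic) - len(truth.fo)) <= 1

    def test_land_crossing_coincides_with_ic(self, clean_recording):
        rec, truth = clean_recording
        flags = np.flatnonzero(zero_cross_flags(rec.gyro_y))
        for ic in truth.ic:
            assert np.min(np.abs(flags - ic)) <= 1

    def test_water_ic_precedes_crossing_by_lead(self):
        cfg = SimConfig(
            n_subjects=1, duration=20, conditions=("waist",),
            noise_sd=0.0, jitter_cv=0.0, amp_jitter_cv=0.0, seed=2,
        )
        rec, truth = simulate_recording("S01", 1.2, "waist", cfg)
        lead_samples = cfg.ic_lead["water"] * cfg.fs
        g = rec.gyro_y
        ups = np.flatnonzero((g[:-1] < 0) & (g[1:] >= 0)) + 1
        for ic in truth.ic[1:-1]:
            nxt = ups[ups >= ic][0]
            assert abs((nxt - ic) - lead_samples) <= 1

    def test_duration_too_short_rejected(self):
        with pytest.raises(ConfigurationError):
            SimConfig(n_subjects=1, duration=2.0, speeds=(0.4,), seed=0)


class TestSimulateCohort:
    def test_land_grid_cardinality(self):
        cfg = SimConfig(n_subjects=12, duration=10.0, speeds=(0.8, 1.6),
                        conditions=("none", "bws30", "bws50"), seed=0)
        assert len(simulate_cohort(cfg)) == 12 * 2 * 3

    def test_water_grid_cardinality(self):
        cfg = SimConfig(n_subjects=3, duration=10.0,
                        conditions=("waist", "chest"), seed=0)
        assert len(simulate_cohort(cfg)) == 3 * 4 * 2

    def test_per_subject_sample_budget_matches_protocol_scale(self):
        """A land session (4 speeds x 3 support levels x 180 s at 100 Hz)
        yields > 200k samples per subject, the order of magnitude of a real
        single-subject session."""
        cfg = SimConfig(n_subjects=1, duration=180.0, seed=0)
        total = sum(len(rec) for rec, _ in simulate_cohort(cfg))
        assert total == 12 * 18000

    def test_empty_grid_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_cohort(SimConfig(n_subjects=0))

    def test_subject_multiplier_shared_across_conditions(self):
        cfg = SimConfig(n_subjects=2, duration=12.0, speeds=(1.2,),
                        conditions=("none", "bws30"), noise_sd=0.0,
                        jitter_cv=0.0, amp_jitter_cv=0.0, seed=4)
        recs = {r.recording_id: r for r, _ in simulate_cohort(cfg)}
        ratio_s1 = recs["S01|bws30|1.2"].gyro_y.max() / recs["S01|none|1.2"].gyro_y.max()
        ratio_s2 = recs["S02|bws30|1.2"].gyro_y.max() / recs["S02|none|1.2"].gyro_y.max()
        # the condition scaling is subject-independent
        assert ratio_s1 == pytest.approx(ratio_s2, rel=1e-9)
        assert ratio_s1 == pytest.approx(0.95, rel=1e-9)
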