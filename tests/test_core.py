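"""Domain-type invariants and recording CSV/JSON round-trips."""

from __future__ import annotations

import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gaitmark.core import (
    EvalReport,
    EventSet,
    FormatError,
    GaitRecording,
    SamplingError,
    SPEEDS,
    ValidationError,
    read_recording,
    validate_labels,
    write_recording,
)


def make_recording(n=50, fs=100.0, speed=1.2, support="none", env="land", **kw):
    defaults = dict(
        subject_id="S01",
        environment=env,
        support=support,
        speed=speed,
        fs=fs,
        time=np.arange(n) / fs,
        gyro_y=np.sin(np.arange(n) / 5.0) * 100,
        vforce=np.abs(np.cos(np.arange(n) / 7.0)) * 300,
    )
    defaults.update(kw)
    return GaitRecording(**defaults)


class TestGaitRecordingValidation:
    def test_valid_recording_passes(self):
        make_recording()

    def test_non_uniform_time_rejected(self):
        t = np.array([0.0, 0.01, 0.05])
        with pytest.raises(SamplingError):
            make_recording(n=3, time=t, gyro_y=np.zeros(3), vforce=np.zeros(3))

    def test_channel_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            make_recording(gyro_y=np.zeros(10))

    def test_negative_force_rejected(self):
        v = np.zeros(50)
        v[3] = -1.0
        with pytest.raises(ValidationError):
            make_recording(vforce=v)

    def test_empty_recording_rejected(self):
        with pytest.raises(ValidationError):
            make_recording(n=0, time=[], gyro_y=[], vforce=[])

    @pytest.mark.parametrize(
        "env,support", [("land", "waist"), ("water", "none"), ("land", "deep")]
    )
    def test_environment_support_consistency(self, env, support):
        with pytest.raises(ValidationError):
            make_recording(env=env, support=support)

    def test_off_protocol_speed_rejected(self):
        with pytest.raises(ValidationError):
            make_recording(speed=1.0)


class TestEventSet:
    def test_alternation_enforced(self):
        with pytest.raises(ValidationError):
            EventSet(ic=[10, 20], fo=[]).validate(strict_alternation=True)
        EventSet(ic=[10, 120], fo=[70]).validate(n=200)

    def test_decreasing_indices_rejected(self):
        with pytest.raises(ValidationError):
            EventSet(ic=[20, 10], fo=[]).validate()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            EventSet(ic=[10], fo=[50]).validate(n=30)


def test_validate_labels_rejects_alien_classes():
    with pytest.raises(ValidationError):
        validate_labels([0, 1, 3])
    assert validate_labels([0, 1, 2, 0]).tolist() == [0, 1, 2, 0]


def test_eval_report_consistency_checks():
    rep = EvalReport(
        confusion=np.eye(3, dtype=int) * 5,
        precision=np.ones(3),
        recall=np.ones(3),
        f1=np.ones(3),
        accuracy=1.0,
        n_samples=15,
    )
    rep.validate()
    rep.n_samples = 14
    with pytest.raises(ValidationError):
        rep.validate()


class TestRecordingIO:
    def test_three_row_round_trip(self, tmp_path):
        rec = make_recording(n=3)
        write_recording(rec, tmp_path / "r.csv", tmp_path / "r.json")
        back = read_recording(tmp_path / "r.csv", tmp_path / "r.json")
        assert back == rec
        assert back.fs == 100.0 and len(back) == 3

    def test_missing_column_is_format_error(self, tmp_path):
        (tmp_path / "r.csv").write_text("time,gyro_y\n0.0,1.0\n")
        (tmp_path / "r.json").write_text(
            json.dumps(
                {
                    "subject_id": "S01",
                    "environment": "land",
                    "support": "none",
                    "speed_mps": 1.2,
                    "fs_hz": 100,
                }
            )
        )
        with pytest.raises(FormatError):
            read_recording(tmp_path / "r.csv", tmp_path / "r.json")

    def test_metadata_missing_keys_is_format_error(self, tmp_path):
        rec = make_recording(n=3)
        write_recording(rec, tmp_path / "r.csv", tmp_path / "r.json")
        (tmp_path / "r.json").write_text('{"subject_id": "S01"}')
        with pytest.raises(FormatError):
            read_recording(tmp_path / "r.csv", tmp_path / "r.json")

    def test_yaml_metadata_accepted(self, tmp_path):
        rec = make_recording(n=4)
        write_recording(rec, tmp_path / "r.csv", tmp_path / "r.json")
        (tmp_path / "r.yaml").write_text(
            "subject_id: S01\nenvironment: land\nsupport: none\n"
            "speed_mps: 1.2\nfs_hz: 100.0\n"
        )
        back = read_recording(tmp_path / "r.csv", tmp_path / "r.yaml")
        assert back == rec

    def test_invalid_recording_refused_before_write(self, tmp_path):
        rec = make_recording()
        rec.vforce = rec.vforce.copy()
        rec.vforce[0] = -1.0  # mutate after construction
        with pytest.raises(ValidationError):
            write_recording(rec, tmp_path / "r.csv", tmp_path / "r.json")


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    n=st.integers(min_value=2, max_value=60),
    fs=st.sampled_from([100.0, 128.0, 500.0, 2000.0]),
    speed=st.sampled_from(SPEEDS),
    support=st.sampled_from(["none", "bws30", "bws50"]),
    t0=st.floats(min_value=0.0, max_value=10.0),
    seed=st.integers(min_value=0, max_value=2**31 - 1),
)
def test_round_trip_equals_identity(tmp_path_factory, n, fs, speed, support, t0, seed):
    """read(write(x)) reproduces every field bit-for-bit for random valid
    recordings."""
    rng = np.random.default_rng(seed)
    rec = GaitRecording(
        subject_id=f"S{seed % 97}",
        environment="land",
        support=support,
        speed=speed,
        fs=fs,
        time=t0 + np.arange(n) / fs,
        gyro_y=rng.normal(0, 300, n),
        vforce=np.abs(rng.normal(0, 400, n)),
    )
    tmp = tmp_path_factory.mktemp("roundtrip")
    write_recording(rec, tmp / "r.csv", tmp / "r.json")
    assert read_recording(tmp / "r.csv", tmp / "r.json") == rec
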