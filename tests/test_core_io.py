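import json

import numpy as np
import pandas as pd
import pytest

from steerlimb.core import (
    CohortSummary,
    MuscleDirectionResult,
    Trial,
    default_meta_path,
    read_results,
    read_trial,
    write_results,
    write_trial,
)
from steerlimb.errors import (
    DataError,
    DomainError,
    FormatError,
    TimingError,
    UsageError,
)


def _write_default(trial, tmp_path, mutate=None):
    path = tmp_path / f"{trial.subject_id}.csv"
    write_trial(trial, path)
    if mutate is not None:
        df = pd.read_csv(path)
        df = mutate(df)
        df.to_csv(path, index=False)
    return path


class TestTrialRoundTrip:
    def test_read_back_matches_to_1e12(self, small_cohort, tmp_path):
        trial = small_cohort[0][0]
        path = _write_default(trial, tmp_path)
        back = read_trial(path)
        assert back.subject_id == trial.subject_id
        assert back.arm_mode == trial.arm_mode
        assert back.hand_position == trial.hand_position
        assert back.task == trial.task
        assert back.channel_labels == trial.channel_labels
        assert abs(back.fs - trial.fs) < 1e-9 * trial.fs
        for name in ("time", "torque", "angle", "emg"):
            np.testing.assert_allclose(
                getattr(back, name), getattr(trial, name), rtol=0, atol=1e-12
            )

    def test_fs_and_length_inferred(self, small_cohort, tmp_path):
        trial = small_cohort[0][0]
        path = _write_default(trial, tmp_path)
        back = read_trial(path)
        assert back.n_samples == trial.n_samples
        assert back.fs == pytest.approx(1000.0, rel=1e-9)


class TestTrialValidation:
    def test_missing_column_names_it(self, small_cohort, tmp_path):
        trial = small_cohort[0][0]
        path = _write_default(trial, tmp_path, mutate=lambda df: df.drop(columns=["emg_07"]))
        with pytest.raises(FormatError, match="emg_07"):
            read_trial(path)

    def test_time_gap_raises_timing_error(self, small_cohort, tmp_path):
        trial = small_cohort[0][0]

        def gap(df):
            df.loc[500:, "time"] += 0.004  # one 0.005 s step in a 0.001 s grid
            return df

        path = _write_default(trial, tmp_path, mutate=gap)
        with pytest.raises(TimingError):
            read_trial(path)

    def test_nan_raises_data_error_with_row(self, small_cohort, tmp_path):
        trial = small_cohort[0][0]

        def poison(df):
            df.loc[17, "torque"] = np.nan
            return df

        path = _write_default(trial, tmp_path, mutate=poison)
        with pytest.raises(DataError, match="17"):
            read_trial(path)

    def test_missing_meta_key(self, small_cohort, tmp_path):
        trial = small_cohort[0][0]
        path = _write_default(trial, tmp_path)
        meta_path = default_meta_path(path)
        meta = json.loads(meta_path.read_text())
        del meta["task"]
        meta_path.write_text(json.dumps(meta))
        with pytest.raises(FormatError, match="task"):
            read_trial(path)

    @pytest.mark.parametrize(
        "arm_mode,hand_position", [("both", "0130"), ("single", "1010")]
    )
    def test_hand_position_mode_consistency(self, small_cohort, arm_mode, hand_position):
        trial = small_cohort[0][0]
        bad = Trial(
            subject_id="X",
            arm_mode=arm_mode,
            hand_position=hand_position,
            task="active",
            fs=trial.fs,
            time=trial.time,
            torque=trial.torque,
            angle=trial.angle,
            emg=trial.emg,
        )
        with pytest.raises(FormatError):
            bad.validate()

    def test_wrong_channel_count_rejected(self, small_cohort):
        trial = small_cohort[0][0]
        bad = Trial(
            subject_id="X",
            arm_mode=trial.arm_mode,
            hand_position=trial.hand_position,
            task=trial.task,
            fs=trial.fs,
            time=trial.time,
            torque=trial.torque,
            angle=trial.angle,
            emg=trial.emg[:7],
        )
        with pytest.raises(FormatError):
            bad.validate()


def _random_mdr(rng, i):
    r = float(rng.uniform(0, 1))
    return MuscleDirectionResult(
        muscle=f"MB{i % 10 + 1}",
        direction="cw" if i % 2 else "ccw",
        r=r,
        a=float(rng.uniform(0, 2)),
        c=float(rng.uniform(0, 1)),
        tau_ms=float(rng.uniform(-900, 900)),
    )


class TestResultsIO:
    def test_single_row_has_named_columns(self, tmp_path):
        rec = MuscleDirectionResult("MS1", "cw", 0.9, 0.4, 0.2, -300.0)
        path = tmp_path / "res.csv"
        write_results([rec], path)
        lines = path.read_text().splitlines()
        assert lines[0].startswith("# schema=")
        assert lines[1] == "muscle,direction,r,a,c,tau_ms"
        assert len(lines) == 3

    def test_round_trip_100_random_records(self, rng, tmp_path):
        records = [_random_mdr(rng, i) for i in range(100)]
        path = tmp_path / "res.csv"
        write_results(records, path)
        back = read_results(path)
        assert len(back) == 100
        for a, b in zip(records, back):
            assert a.muscle == b.muscle and a.direction == b.direction
            for f in ("r", "a", "c", "tau_ms"):
                assert abs(getattr(a, f) - getattr(b, f)) <= 1e-12

    def test_cohort_summary_round_trip(self, rng, tmp_path):
        recs = [
            CohortSummary(
                "both", "active", "0300", "cw", f"r_MB{i}", mean=float(rng.uniform()),
                sd=float(rng.uniform()), median=0.5, q1=0.4, q3=0.6, n_subjects=20,
            )
            for i in range(1, 11)
        ]
        path = tmp_path / "summary.csv"
        write_results(recs, path)
        back = read_results(path)
        assert all(isinstance(r, CohortSummary) for r in back)
        np.testing.assert_allclose(
            [r.mean for r in back], [r.mean for r in recs], atol=1e-12
        )

    def test_empty_list_is_usage_error(self, tmp_path):
        with pytest.raises(UsageError):
            write_results([], tmp_path / "x.csv")

    def test_mixed_kinds_is_usage_error(self, tmp_path):
        mdr = MuscleDirectionResult("MS1", "cw", 0.9, 0.4, 0.2, -300.0)
        cs = CohortSummary("both", "active", "0300", "cw", "r_MB1", 0.5, 0.1, 0.5, 0.4, 0.6, 5)
        with pytest.raises(UsageError):
            write_results([mdr, cs], tmp_path / "x.csv")


class TestResultValidation:
    @pytest.mark.parametrize("r", [-0.1, 1.1])
    def test_r_out_of_range(self, r):
        with pytest.raises(DomainError):
            MuscleDirectionResult("MS1", "cw", r, 0.1, 0.1, 0.0).validate()

    def test_quartile_ordering_enforced(self):
        with pytest.raises(DomainError):
            CohortSummary(
                "both", "active", "0300", "cw", "r", 0.5, 0.1, 0.5, 0.6, 0.4, 5
            ).validate()
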