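"""The evaluation protocol: I/O, sub-sequencing, subsets, accelerations, runs."""

import numpy as np
import pytest

from dmdmotion import (
    ConfigError,
    ErrorTable,
    ExperimentConfig,
    InvalidInputError,
    MotionSequence,
    ParseError,
    PredictionBatch,
    demo_corpus,
    dmdd_fit,
    dmdd_forecast,
    pose_mse,
    read_motion_csv,
    run_anticipation,
    run_delay_sweep,
    select_markers,
    simulate_accelerations,
    sinusoid_series,
    split_subsequences,
    synthetic_skeleton,
    write_motion_csv,
)
from dmdmotion.synthetic import SinusoidSpec

from conftest import random_linear_series


class TestMotionCSV:
    def test_round_trip_is_lossless(self, tmp_path):
        series = synthetic_skeleton(50, noise_sd=1.0, seed=3)
        path = tmp_path / "skel.csv"
        write_motion_csv(series, path)
        back = read_motion_csv(path)
        np.testing.assert_allclose(back.values, series.values, atol=1e-9)
        assert back.channel_labels == series.channel_labels
        assert back.fps == series.fps and back.units == series.units

    def test_missing_header_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("1,2,3\n4,5,6\n")
        with pytest.raises(ParseError):
            read_motion_csv(path)

    def test_shape_from_file(self, tmp_path):
        series = synthetic_skeleton(100)
        path = tmp_path / "s.csv"
        write_motion_csv(series, path)
        back = read_motion_csv(path)
        assert back.n_frames == 100 and back.n_channels == 51

    def test_non_numeric_cell_reports_line(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("# fps=50 units=mm\nframe,a\n0,1.0\n1,oops\n")
        with pytest.raises(ParseError, match=":4"):
            read_motion_csv(path)

    def test_ragged_row_rejected(self, tmp_path):
        path = tmp_path / "ragged.csv"
        path.write_text("# fps=50 units=mm\nframe,a,b\n0,1.0,2.0\n1,3.0\n")
        with pytest.raises(ParseError):
            read_motion_csv(path)


class TestSplitSubsequences:
    @pytest.mark.parametrize(
        "n, expected", [(300, 3), (250, 2), (100, 1)], ids=["exact3", "remainder", "exact1"]
    )
    def test_non_overlapping_windows(self, n, expected):
        series = MotionSequence(np.arange(n * 2.0).reshape(n, 2))
        subs = split_subsequences(series, 100)
        assert len(subs) == expected
        np.testing.assert_array_equal(subs[0].values, series.values[:100])
        if expected > 1:
            np.testing.assert_array_equal(subs[1].values, series.values[100:200])

    def test_short_series_rejected(self):
        series = MotionSequence(np.zeros((50, 1)))
        with pytest.raises(InvalidInputError, match="empty"):
            split_subsequences(series, 100)

    def test_stride_overlapping(self):
        series = MotionSequence(np.arange(200.0).reshape(200, 1))
        subs = split_subsequences(series, 100, stride=50)
        assert len(subs) == 3


class TestSelectMarkers:
    def test_full_subset_is_identity(self):
        series = synthetic_skeleton(100)
        assert select_markers(series, "M17") is series

    def test_single_marker_three_channels(self):
        sub = select_markers(synthetic_skeleton(100), "M1", target_joint="right_hand")
        assert sub.channel_labels == ["right_hand_x", "right_hand_y", "right_hand_z"]

    def test_end_effectors_and_root(self):
        sub = select_markers(synthetic_skeleton(100), "M5")
        assert sub.n_channels == 15
        assert "root_x" in sub.channel_labels

    def test_unknown_joint_rejected(self):
        with pytest.raises(InvalidInputError):
            select_markers(synthetic_skeleton(100), "M1", target_joint="tail")


class TestSimulateAccelerations:
    def test_quadratic_gives_constant_two(self):
        k = np.arange(10.0)
        series = MotionSequence((k**2).reshape(-1, 1), fps=1.0)
        acc = simulate_accelerations(series)
        assert acc.n_frames == 8
        np.testing.assert_allclose(acc.values, 2.0, atol=1e-12)
        assert acc.units == "mm/s^2"

    def test_linear_motion_has_zero_acceleration(self):
        series = MotionSequence(np.arange(20.0).reshape(-1, 1) * 3.0, fps=50.0)
        np.testing.assert_allclose(simulate_accelerations(series).values, 0.0, atol=1e-9)

    def test_sinusoid_amplitude_near_continuous_limit(self):
        A, f, fps = 10.0, 1.0, 50.0
        series = sinusoid_series(1, [[SinusoidSpec(f, A)]], fps=fps, n=200)
        acc = simulate_accelerations(series)
        measured = np.max(np.abs(acc.values))
        continuous = A * (2 * np.pi * f) ** 2
        assert abs(measured - continuous) / continuous < 0.05

    def test_too_short_rejected(self):
        with pytest.raises(InvalidInputError):
            simulate_accelerations(MotionSequence(np.zeros((2, 1)) + [[0.0], [1.0]]))


class TestExperimentConfig:
    def test_horizon_overflow_rejected(self):
        with pytest.raises(ConfigError):
            ExperimentConfig(subseq_len=100, input_len=90, horizons=[20])

    def test_inadmissible_delay_rejected(self):
        with pytest.raises(ConfigError):
            ExperimentConfig(subseq_len=150, input_len=50, delays=80)

    def test_round_trip_dict(self):
        cfg = ExperimentConfig(delays=[10, 20], metric="kl")
        clone = ExperimentConfig.from_dict(cfg.to_dict())
        assert clone.to_dict() == cfg.to_dict()

    def test_unknown_key_rejected(self):
        with pytest.raises(ConfigError):
            ExperimentConfig.from_dict({"svd_toll": 1e-9})


@pytest.fixture(scope="module")
def corpus():
    return demo_corpus(n=450, noise_sd=1.0, seed=0)


class TestRunAnticipation:
    def test_error_grows_with_horizon(self, corpus):
        cfg = ExperimentConfig(subseq_len=150, input_len=100, horizons=[5, 10, 20], delays=20)
        table = run_anticipation(corpus, cfg)
        for label in corpus:
            assert table.value(label, 20, 5) < table.value(label, 20, 20)

    def test_noise_free_linear_class_is_exact(self):
        data = {"linear": random_linear_series(m=4, n=150, seed=12)}
        cfg = ExperimentConfig(subseq_len=150, input_len=100, horizons=[5, 10, 20], delays=10)
        table = run_anticipation(data, cfg)
        for h in (5, 10, 20):
            assert table.value("linear", 10, h) < 1e-8

    def test_identical_classes_get_identical_rows(self):
        series = synthetic_skeleton(300, noise_sd=1.0, seed=4)
        cfg = ExperimentConfig(subseq_len=150, input_len=100, delays=20)
        table = run_anticipation({"a": series, "b": series}, cfg)
        a = table.frame[table.frame["class"] == "a"]["value"].to_numpy()
        b = table.frame[table.frame["class"] == "b"]["value"].to_numpy()
        np.testing.assert_array_equal(a, b)

    def test_matches_manual_batch_accounting(self, corpus):
        """Class error equals the outer mean over manually refitted sub-sequences."""
        cfg = ExperimentConfig(subseq_len=150, input_len=100, horizons=[10], delays=20)
        table = run_anticipation({"walk": corpus["walk"]}, cfg)
        subs = split_subsequences(corpus["walk"], 150)
        gts, preds = [], []
        for sub in subs:
            fit = dmdd_fit(sub.head(100), 20)
            preds.append(dmdd_forecast(fit, 10))
            gts.append(sub.values[100:110])
        manual = pose_mse(PredictionBatch(gts, preds))
        assert table.value("walk", 20, 10) == pytest.approx(manual, rel=1e-12)

    def test_kl_metric_rows(self, corpus):
        cfg = ExperimentConfig(
            subseq_len=150, input_len=100, horizons=[5], delays=20, metric="kl"
        )
        table = run_anticipation({"walk": corpus["walk"]}, cfg)
        val = table.value("walk", 20, 5)
        assert 0 <= val < 1  # accurate forecast: near-identical histograms

    def test_acceleration_pipeline_runs_through_same_machinery(self, corpus):
        cfg = ExperimentConfig(
            subseq_len=148, input_len=100, horizons=[5, 20], delays=20,
            marker_subset="M5", accel=True,
        )
        table = run_anticipation({"walk": corpus["walk"]}, cfg)
        assert (table.frame["value"] >= 0).all()
        assert table.value("walk", 20, 5) <= table.value("walk", 20, 20)


class TestRunDelaySweep:
    def test_reconstruction_sweep_shows_delay_benefit(self):
        from dmdmotion import quasi_periodic_scalar

        data = {"quasi": quasi_periodic_scalar(150, noise_sd=0.0)}
        cfg = ExperimentConfig(subseq_len=150, input_len=100, horizons=[20], delays=[0, 10, 20])
        table = run_delay_sweep(data, cfg, mode="reconstruction")
        e0 = table.value("quasi", 0, 0)
        e10 = table.value("quasi", 10, 0)
        e20 = table.value("quasi", 20, 0)
        assert e10 < 1e-6 and e20 < 1e-6
        assert e0 > 1e3 * max(e10, e20)

    def test_anticipation_sweep_has_interior_minimum(self, corpus):
        cfg = ExperimentConfig(
            subseq_len=150, input_len=100, horizons=[20],
            delays=[10, 20, 40, 50, 60, 70, 80, 90],
        )
        table = run_delay_sweep(corpus, cfg, mode="anticipation")
        interior = []
        for label in corpus:
            errs = [table.value(label, d, 20) for d in cfg.delay_list]
            best = int(np.argmin(errs))
            interior.append(0 < best < len(errs) - 1)
        assert any(interior)

    def test_single_delay_single_row_per_class(self, corpus):
        cfg = ExperimentConfig(subseq_len=150, input_len=100, horizons=[20], delays=[20])
        table = run_delay_sweep(corpus, cfg, mode="reconstruction")
        assert len(table.frame) == len(corpus)

    def test_bad_mode_rejected(self, corpus):
        cfg = ExperimentConfig(delays=[10])
        with pytest.raises(ConfigError):
            run_delay_sweep(corpus, cfg, mode="extrapolation")


class TestErrorTableOutput:
    def test_csv_is_byte_identical_across_runs(self, tmp_path):
        cfg = ExperimentConfig(subseq_len=150, input_len=100, delays=20, seed=9)
        paths = []
        for i in range(2):
            data = demo_corpus(n=300, noise_sd=1.0, seed=9)
            table = run_anticipation(data, cfg)
            p = tmp_path / f"run{i}.csv"
            table.to_csv(p)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_row_ordering_is_canonical(self, tmp_path):
        table = ErrorTable.from_records(
            [
                {"class": "b", "delay": 10, "horizon_frames": 5, "horizon_s": 0.1,
                 "metric": "mse", "value": 1.0, "K": 1},
                {"class": "a", "delay": 20, "horizon_frames": 10, "horizon_s": 0.2,
                 "metric": "mse", "value": 2.0, "K": 1},
                {"class": "a", "delay": 10, "horizon_frames": 5, "horizon_s": 0.1,
                 "metric": "mse", "value": 3.0, "K": 1},
            ]
        )
        assert list(table.frame["class"]) == ["a", "a", "b"]
        assert list(table.frame["delay"]) == [10, 20, 10]

    def test_duplicate_rows_rejected(self):
        row = {"class": "a", "delay": 10, "horizon_frames": 5, "horizon_s": 0.1,
               "metric": "mse", "value": 1.0, "K": 1}
        with pytest.raises(InvalidInputError):
            ErrorTable.from_records([row, dict(row)])
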