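"""Mitochondria classification by the diameter-vs-displacement t-test."""

import numpy as np
import pandas as pd
import pytest

from neurokin.mito import classify_mito, classify_mito_tracks, summarize_mito, track_kinematics
from neurokin.simulate import CargoSimParams, simulate_mito_tracks


def make_track(x, y, diameters=None, t=None, track_id="t1"):
    n = len(x)
    df = pd.DataFrame(
        {
            "cell_id": "c1",
            "track_id": track_id,
            "frame": np.arange(n),
            "t": np.arange(n, dtype=float) if t is None else t,
            "x": x,
            "y": y,
        }
    )
    if diameters is not None:
        df["diameter"] = diameters
    return df


class TestKinematics:
    def test_straight_run(self):
        k = track_kinematics(make_track(np.arange(11) * 0.1, np.zeros(11)))
        assert k.net_displacement == pytest.approx(1.0)
        assert k.path_length == pytest.approx(1.0)
        assert k.velocity == pytest.approx(k.speed)

    def test_out_and_back_cancels_net(self):
        x = np.concatenate([np.arange(6) * 0.2, np.arange(4, -1, -1) * 0.2])
        k = track_kinematics(make_track(x, np.zeros(11)))
        assert k.net_displacement == pytest.approx(0.0, abs=1e-12)
        assert k.path_length == pytest.approx(2.0)
        assert k.velocity == pytest.approx(0.0, abs=1e-12)

    def test_path_dominates_net_on_random_walks(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            steps = rng.normal(0, 0.1, (30, 2))
            pos = np.cumsum(steps, axis=0)
            k = track_kinematics(make_track(pos[:, 0], pos[:, 1]))
            assert k.path_length >= k.net_displacement - 1e-12
            assert k.speed >= k.velocity

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError):
            track_kinematics(make_track([0.0], [0.0]))


class TestClassifier:
    def test_large_displacement_is_mobile(self):
        rng = np.random.default_rng(1)
        n = 50
        x = np.linspace(0, 5, n)  # 5 µm run
        diam = 0.5 + 0.01 * rng.standard_normal(n)
        cls = classify_mito(make_track(x, np.zeros(n), diam))
        assert cls.label == "mobile" and cls.t_stat < 0 and cls.confidence > 0.99

    def test_small_displacement_is_stationary(self):
        rng = np.random.default_rng(2)
        n = 50
        x = np.linspace(0, 0.02, n)
        diam = 0.5 + 0.01 * rng.standard_normal(n)
        cls = classify_mito(make_track(x, np.zeros(n), diam))
        assert cls.label == "stationary" and cls.t_stat > 0

    def test_displacement_at_mean_diameter_is_undefined(self):
        rng = np.random.default_rng(3)
        n = 40
        diam = 0.5 + 0.05 * rng.standard_normal(n)
        x = np.linspace(0, diam.mean(), n)
        cls = classify_mito(make_track(x, np.zeros(n), diam))
        assert cls.label == "undefined"
        assert cls.confidence < 0.95

    def test_t_statistic_matches_manual_formula(self):
        """t = (mean diameter − displacement)/(sd/√n), two-sided confidence."""
        from scipy.stats import t as tdist

        rng = np.random.default_rng(4)
        n = 30
        diam = 0.6 + 0.08 * rng.standard_normal(n)
        x = np.linspace(0, 1.2, n)
        cls = classify_mito(make_track(x, np.zeros(n), diam))
        disp = 1.2
        t_manual = (diam.mean() - disp) / (diam.std(ddof=1) / np.sqrt(n))
        p_manual = 2 * tdist.sf(abs(t_manual), n - 1)
        assert cls.t_stat == pytest.approx(t_manual, rel=1e-12)
        assert cls.confidence == pytest.approx(1 - p_manual, rel=1e-9)

    def test_zero_variance_degenerate(self):
        cls = classify_mito(make_track(np.linspace(0, 3, 10), np.zeros(10), np.full(10, 0.5)))
        assert cls.label == "mobile" and cls.confidence == 1.0

    def test_short_track_undefined(self):
        cls = classify_mito(make_track([0, 1.0], [0, 0], [0.5, 0.5]))
        assert cls.label == "undefined"

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(5)
        n = 40
        pos = np.cumsum(rng.normal(0, 0.05, (n, 2)), axis=0)
        diam = 0.6 + 0.05 * rng.standard_normal(n)
        base = classify_mito(make_track(pos[:, 0], pos[:, 1], diam))
        th = 0.7
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        moved = pos @ rot.T + [10.0, -2.0]
        same = classify_mito(make_track(moved[:, 0], moved[:, 1], diam))
        assert same.label == base.label
        assert same.t_stat == pytest.approx(base.t_stat, rel=1e-9)

    def test_inflating_diameters_flips_mobile_to_stationary(self):
        rng = np.random.default_rng(6)
        n = 50
        x = np.linspace(0, 1.0, n)
        diam = 0.5 + 0.02 * rng.standard_normal(n)
        labels = [
            classify_mito(make_track(x, np.zeros(n), diam + shift)).label
            for shift in (0.0, 0.3, 0.8)
        ]
        assert labels[0] == "mobile" and labels[-1] == "stationary"


class TestSummary:
    def test_fractions_arithmetic(self):
        rng = np.random.default_rng(7)
        tracks = []
        for i in range(10):
            n = 30
            x = np.linspace(0, 4.0 if i < 2 else 0.01, n)
            diam = 0.5 + 0.01 * rng.standard_normal(n)
            tracks.append(make_track(x, np.zeros(n), diam, track_id=f"t{i}"))
        classified = classify_mito_tracks(pd.concat(tracks, ignore_index=True))
        summary = summarize_mito(classified)
        assert summary["mobile_fraction"].iloc[0] == pytest.approx(0.2)
        assert summary["stationary_fraction"].iloc[0] == pytest.approx(0.8)

    def test_no_mobile_tracks_reports_missing_speed(self):
        rng = np.random.default_rng(8)
        n = 30
        diam = 0.5 + 0.01 * rng.standard_normal(n)
        classified = classify_mito_tracks(make_track(np.linspace(0, 0.01, n), np.zeros(n), diam))
        summary = summarize_mito(classified)
        assert np.isnan(summary["mean_velocity_mobile"].iloc[0])

    def test_end_to_end_recovery(self):
        """Well-separated synthetic populations: every truth label recovered."""
        tracks, truth = simulate_mito_tracks(CargoSimParams.mito_defaults(n_tracks=40), seed=11)
        merged = classify_mito_tracks(tracks).merge(truth, on=["cell_id", "track_id"])
        agree = (merged["label_x"] == merged["label_y"]).mean()
        assert agree >= 0.95
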