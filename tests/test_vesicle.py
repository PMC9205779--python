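"""Vesicle pipeline: filtering, orientation, mobility gate, state segmentation."""

import numpy as np
import pandas as pd
import pytest

from neurokin.simulate import CargoSimParams, simulate_vesicle_tracks
from neurokin.vesicle import (
    VesicleTransportAnalyzer,
    classify_mobility,
    filter_tracks,
    orient_track,
    segment_states,
    summarize_vesicles,
    vesicle_metrics,
)


def make_track(s, frames=None, fps=5.0, track_id="t1", cell_id="c1"):
    s = np.asarray(s, dtype=float)
    frames = np.arange(len(s)) if frames is None else np.asarray(frames)
    return pd.DataFrame(
        {"cell_id": cell_id, "track_id": track_id, "frame": frames, "t": frames / fps, "s": s}
    )


class TestFilter:
    def test_boundary_at_min_frames(self):
        t14 = make_track(np.zeros(14), track_id="a")
        t15 = make_track(np.zeros(15), track_id="b")
        kept = filter_tracks(pd.concat([t14, t15]), min_frames=15)
        assert set(kept["track_id"]) == {"b"}

    def test_span_counts_gaps(self):
        # 10 observations spanning 15 frames: span qualifies
        frames = np.array([0, 1, 2, 4, 5, 7, 9, 11, 13, 14])
        kept = filter_tracks(make_track(np.zeros(10), frames), min_frames=15)
        assert len(kept) == 10

    def test_empty_table(self):
        empty = make_track(np.zeros(0), np.array([], int))
        assert filter_tracks(empty, 15).empty


class TestOrientation:
    def test_away_from_reference_is_positive(self):
        track = orient_track(make_track([10.0, 11.0, 12.0]), reference_s=0.0)
        assert np.all(np.diff(track["s"]) > 0)

    def test_reference_on_far_side_flips_signs(self):
        base = make_track([10.0, 11.0, 12.5])
        near = orient_track(base, reference_s=0.0)
        far = orient_track(base, reference_s=100.0)
        assert np.allclose(near["s"].diff().dropna(), -far["s"].diff().dropna())

    def test_missing_reference_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            orient_track(make_track([0.0, 1.0]), None)


class TestMobilityGate:
    @pytest.mark.parametrize(
        "net,expected",
        [(0.74, "stationary"), (0.75, "stationary"), (0.76, "mobile")],
    )
    def test_strict_threshold(self, net, expected):
        track = make_track(np.linspace(0, net, 20))
        assert classify_mobility(track, 0.75) == expected

    def test_stall_population_called_stationary(self):
        q = np.zeros((3, 3))
        q[0, 2] = q[1, 2] = 5.0  # everything falls into stall and stays
        p = CargoSimParams.vesicle_defaults(n_tracks=40, p_mobile=1.0, state_rates=q)
        tracks, _ = simulate_vesicle_tracks(p, seed=2)
        calls = [
            classify_mobility(orient_track(sub, 0.0))
            for _, sub in tracks.groupby("track_id")
        ]
        assert np.mean([c == "stationary" for c in calls]) >= 0.95


class TestSegmentation:
    def test_uniform_run_single_state(self):
        series = segment_states(make_track(np.arange(21) * 0.1))
        assert set(series.steps["state"]) == {"anterograde"}
        assert series.n_state_changes == 0
        assert len(series.runs) == 1

    def test_alternating_steps_force_changes(self):
        s = np.zeros(11)
        s[1::2] = 0.1  # +0.1 / −0.1 alternating, 10 steps
        series = segment_states(make_track(s))
        assert series.n_state_changes == 9

    def test_gap_normalization_yields_stall(self):
        """+0.03 µm across a 2-frame gap (3 frames elapsed) is 0.01 µm/frame."""
        track = make_track([0.0, 0.03], frames=[0, 3])
        series = segment_states(track)
        step = series.steps.iloc[0]
        assert step.ds_per_frame == pytest.approx(0.01)
        assert step.state == "stall"

    def test_boundary_displacement_is_stall(self):
        series = segment_states(make_track([0.0, 0.02, 0.04]), stall_threshold=0.02)
        assert set(series.steps["state"]) == {"stall"}

    def test_oversized_gap_splits_track(self):
        track = make_track([0.0, 0.1, 1.0, 1.1], frames=[0, 1, 10, 11])
        series = segment_states(track)
        assert series.steps["segment"].nunique() == 2
        assert len(series.steps) == 2  # the 9-frame jump is not a step

    def test_every_step_has_exactly_one_state(self):
        p = CargoSimParams.vesicle_defaults(n_tracks=10, p_mobile=1.0)
        tracks, _ = simulate_vesicle_tracks(p, seed=3)
        for _, sub in tracks.groupby("track_id"):
            series = segment_states(orient_track(sub, 0.0))
            frames = sub.sort_values("frame")["frame"].to_numpy()
            n_linkable = np.sum(np.diff(frames) <= 3)
            assert len(series.steps) == n_linkable
            assert series.steps["state"].isin(["anterograde", "retrograde", "stall"]).all()

    def test_raising_threshold_never_reduces_stalls(self):
        p = CargoSimParams.vesicle_defaults(n_tracks=8, p_mobile=1.0)
        tracks, _ = simulate_vesicle_tracks(p, seed=4)
        sub = orient_track(tracks[tracks.track_id == tracks.track_id.iloc[0]], 0.0)
        stalls = [
            (segment_states(sub, stall_threshold=thr).steps["state"] == "stall").sum()
            for thr in (0.005, 0.02, 0.08, 0.3)
        ]
        assert all(a <= b for a, b in zip(stalls, stalls[1:]))


class TestMetrics:
    def test_uniform_anterograde_arithmetic(self):
        track = make_track(np.arange(21) * 0.2, fps=5.0)
        series = segment_states(track)
        m = vesicle_metrics(series, track, fps=5.0)
        assert m.velocity == pytest.approx(1.0)
        assert m.speed == pytest.approx(1.0)
        assert m.max_speed == pytest.approx(1.0)
        assert m.processivity == pytest.approx(4.0)
        assert m.n_state_changes == 0

    def test_two_runs_mean_processivity(self):
        s = np.concatenate(
            [
                np.arange(0, 2.1, 0.1),  # 2 µm anterograde, 20 steps
                np.full(5, 2.0),  # stall
                2.0 - np.arange(0.1, 1.05, 0.1),  # 1 µm retrograde
            ]
        )
        track = make_track(s)
        m = vesicle_metrics(segment_states(track), track, fps=5.0)
        assert m.processivity == pytest.approx(1.5, rel=1e-6)
        assert m.n_state_changes >= 2

    def test_direction_flip_symmetry(self):
        """Flipping the reference to the far side negates velocity and swaps
        anterograde/retrograde totals; speed, processivity and state-change
        count are unchanged."""
        p = CargoSimParams.vesicle_defaults(n_tracks=12, p_mobile=1.0)
        tracks, _ = simulate_vesicle_tracks(p, seed=5)
        for _, sub in tracks.groupby("track_id"):
            near = orient_track(sub, 0.0)
            far = orient_track(sub, 500.0)
            sn, sf = segment_states(near), segment_states(far)
            mn = vesicle_metrics(sn, near, fps=5.0)
            mf = vesicle_metrics(sf, far, fps=5.0)
            assert mf.velocity == pytest.approx(-mn.velocity, abs=1e-12)
            assert mf.speed == pytest.approx(mn.speed, abs=1e-12)
            assert mf.max_speed == pytest.approx(mn.max_speed, abs=1e-12)
            assert mf.n_state_changes == mn.n_state_changes
            if np.isfinite(mn.processivity):
                assert mf.processivity == pytest.approx(mn.processivity, abs=1e-12)
            counts_n = sn.steps["state"].value_counts()
            counts_f = sf.steps["state"].value_counts()
            assert counts_n.get("anterograde", 0) == counts_f.get("retrograde", 0)
            assert counts_n.get("retrograde", 0) == counts_f.get("anterograde", 0)

    def test_per_state_speed_recovery(self):
        """Per-state mean speeds recovered within 10% when state speeds are
        well above the stall threshold."""
        p = CargoSimParams.vesicle_defaults(
            n_tracks=40, p_mobile=1.0, gap_probability=0.0, position_noise=5.0
        )
        tracks, truth = simulate_vesicle_tracks(p, seed=6)
        truth = truth.set_index("track_id")
        speeds = {"anterograde": [], "retrograde": []}
        for tid, sub in tracks.groupby("track_id"):
            series = segment_states(orient_track(sub, 0.0))
            states_truth = truth.loc[tid, "states"]
            for _, st in series.steps.iterrows():
                if st.n_frames == 1 and st.state in speeds:
                    if states_truth[int(st.frame_start)] == st.state:
                        speeds[st.state].append(abs(st.ds_per_frame) * 5.0)
        assert np.mean(speeds["anterograde"]) == pytest.approx(1.0, rel=0.10)
        assert np.mean(speeds["retrograde"]) == pytest.approx(0.9, rel=0.10)


class TestSummary:
    def test_mobile_fraction_arithmetic(self):
        rows = []
        for i in range(20):
            s0 = np.linspace(0, 2.0, 20) if i < 4 else np.zeros(20)
            rows.append(make_track(s0 + 10, track_id=f"t{i}"))
        metrics, _, summary = VesicleTransportAnalyzer().analyze(pd.concat(rows))
        assert summary["mobile_fraction"].iloc[0] == pytest.approx(0.2)

    def test_single_track_cell_mean_equals_track_value(self):
        track = make_track(np.arange(21) * 0.2 + 10)
        metrics, _, summary = VesicleTransportAnalyzer().analyze(track)
        assert summary["mean_velocity"].iloc[0] == pytest.approx(
            metrics["velocity"].iloc[0]
        )

    def test_cell_without_mobile_vesicles_has_missing_means(self):
        metrics, _, summary = VesicleTransportAnalyzer().analyze(make_track(np.zeros(20) + 5))
        assert np.isnan(summary["mean_velocity"].iloc[0])
        assert summary["mobile_fraction"].iloc[0] == 0.0

    def test_state_change_recovery(self):
        """Mean recovered state changes match the generative truth (~2 per
        track) for a fast anterograde/retrograde switching population."""
        q = np.zeros((3, 3))
        q[0, 1] = q[1, 0] = 2.0 / 60.0
        q[2, 0] = 1.0  # stall is transient and never entered
        p = CargoSimParams.vesicle_defaults(n_tracks=150, p_mobile=1.0, state_rates=q)
        tracks, truth = simulate_vesicle_tracks(p, seed=7)
        metrics, _, _ = VesicleTransportAnalyzer().analyze(tracks)
        merged = metrics[metrics.mobility == "mobile"].merge(
            truth, on=["cell_id", "track_id"]
        )
        diff = merged["n_state_changes_x"].mean() - merged["n_state_changes_y"].mean()
        sem = merged["n_state_changes_y"].std() / np.sqrt(len(merged))
        assert abs(diff) <= 3 * sem + 0.05
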