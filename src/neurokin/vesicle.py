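"""Vesicle transport: mobility gating, state segmentation and run metrics.

APP vesicles imaged at 5 frames/s along a neurite are analyzed per track:

1. tracks spanning fewer than 15 frames (3 s) are dropped;
2. arclength is signed from an axon-hillock reference, anterograde positive;
3. a track is **mobile** when its net displacement exceeds 0.75 µm over the
   observation window (strictly), otherwise stationary;
4. each pair of successive localizations of a mobile track — gaps of 1–2
   frames included, with the displacement normalized by the elapsed frames —
   is assigned a state: displacement per frame beyond ±0.02 µm/frame is
   anterograde/retrograde movement, within the threshold (inclusive) a
   stall;
5. per-track metrics: signed velocity, mean and max speed over steps,
   processivity (mean length of maximal uninterrupted moving runs), and the
   number of state changes between adjacent steps.

A gap longer than the linkable maximum splits the track into segments;
states and state changes are computed within segments only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

logger = logging.getLogger("neurokin")

__all__ = [
    "StateSeries",
    "VesicleMetrics",
    "filter_tracks",
    "orient_track",
    "classify_mobility",
    "segment_states",
    "vesicle_metrics",
    "VesicleTransportAnalyzer",
    "summarize_vesicles",
]


@dataclass
class StateSeries:
    """Per-step state assignment of one track.

    ``steps`` has one row per pair of successive observations:
    ``frame_start, frame_end, n_frames, ds_per_frame (signed µm/frame),
    state, segment``. ``runs`` groups maximal same-state step sequences with
    their length (µm) and duration (s). ``n_state_changes`` counts adjacent
    step pairs with differing states (within segments).
    """

    track_id: str
    steps: pd.DataFrame
    runs: pd.DataFrame
    n_state_changes: int


@dataclass
class VesicleMetrics:
    track_id: str
    mobility: str  # mobile | stationary
    velocity: float = np.nan  # µm/s, signed
    speed: float = np.nan  # µm/s, mean |ds/dt| over steps
    max_speed: float = np.nan  # µm/s
    processivity: float = np.nan  # µm, mean moving-run length
    n_state_changes: int = 0
    n_steps: int = 0
    extra: dict = field(default_factory=dict)


def filter_tracks(tracks: pd.DataFrame, min_frames: int = 15) -> pd.DataFrame:
    """Keep tracks whose observed frame span (last − first + 1) ≥ ``min_frames``."""
    if tracks.empty:
        return tracks
    span = tracks.groupby(["cell_id", "track_id"])["frame"].agg(lambda f: f.max() - f.min() + 1)
    keep = span[span >= min_frames].index
    out = tracks.set_index(["cell_id", "track_id"]).loc[keep].reset_index()
    logger.info(
        "duration filter: kept %d / %d tracks (≥ %d frames)", len(keep), len(span), min_frames
    )
    return out


def orient_track(track: pd.DataFrame, reference_s: float | None) -> pd.DataFrame:
    """Re-express arclength so that +s points away from the reference.

    ``reference_s`` is the axon-hillock position in the track's arclength
    coordinate; after orientation, anterograde movement (away from the cell
    body) has positive ds. The track must carry ``s``.
    """
    if reference_s is None:
        raise ValueError("an axon-hillock reference position is required (--reference)")
    if "s" not in track.columns or track["s"].isna().any():
        raise ValueError("orientation requires complete arclength column 's'")
    track = track.copy()
    direction = 1.0 if track["s"].median() >= reference_s else -1.0
    track["s"] = direction * (track["s"] - reference_s)
    return track


def classify_mobility(track: pd.DataFrame, displacement_threshold: float = 0.75) -> str:
    """Mobility gate: mobile iff |net Δs| strictly exceeds the threshold (µm)."""
    s = track.sort_values("frame")["s"].to_numpy(dtype=float)
    return "mobile" if abs(s[-1] - s[0]) > displacement_threshold else "stationary"


def segment_states(
    track: pd.DataFrame,
    stall_threshold: float = 0.02,
    max_gap: int = 2,
) -> StateSeries:
    """Assign anterograde/retrograde/stall to every inter-observation step.

    For successive observations spanning ``n ≤ max_gap + 1`` frames the
    displacement per frame is ``Δs/n`` — a 1–2 frame localization gap is
    thereby accounted for. Steps with ``|Δs/n|`` at or below
    ``stall_threshold`` (µm/frame) are stalls; larger displacements are
    anterograde (+) or retrograde (−) movement. Longer gaps split the track
    into segments (logged); runs and state changes never bridge a split.
    """
    track = track.sort_values("frame")
    frames = track["frame"].to_numpy(dtype=int)
    s = track["s"].to_numpy(dtype=float)
    tid = str(track["track_id"].iloc[0])
    dn = np.diff(frames)
    ds = np.diff(s)
    rows = []
    segment = 0
    for i, (n, d) in enumerate(zip(dn, ds)):
        if n > max_gap + 1:
            segment += 1
            logger.info("track %s: %d-frame gap at frame %d splits the track", tid, n, frames[i])
            continue
        per_frame = d / n
        if abs(per_frame) <= stall_threshold:
            state = "stall"
        elif per_frame > 0:
            state = "anterograde"
        else:
            state = "retrograde"
        rows.append(
            {
                "frame_start": frames[i],
                "frame_end": frames[i + 1],
                "n_frames": int(n),
                "ds_per_frame": per_frame,
                "state": state,
                "segment": segment,
            }
        )
    steps = pd.DataFrame(
        rows, columns=["frame_start", "frame_end", "n_frames", "ds_per_frame", "state", "segment"]
    )
    run_rows = []
    n_changes = 0
    for seg, sub in steps.groupby("segment", sort=True):
        states = sub["state"].to_numpy()
        n_changes += int(np.sum(states[1:] != states[:-1]))
        boundaries = np.flatnonzero(np.concatenate([[True], states[1:] != states[:-1]]))
        for j, start in enumerate(boundaries):
            stop = boundaries[j + 1] if j + 1 < boundaries.size else states.size
            chunk = sub.iloc[start:stop]
            run_rows.append(
                {
                    "segment": seg,
                    "state": states[start],
                    "n_steps": stop - start,
                    "length_um": float(
                        (chunk["ds_per_frame"].abs() * chunk["n_frames"]).sum()
                    ),
                    "duration_frames": int(chunk["n_frames"].sum()),
                }
            )
    runs = pd.DataFrame(
        run_rows, columns=["segment", "state", "n_steps", "length_um", "duration_frames"]
    )
    return StateSeries(track_id=tid, steps=steps, runs=runs, n_state_changes=n_changes)


def vesicle_metrics(
    series: StateSeries,
    track: pd.DataFrame,
    fps: float = 5.0,
    processivity_mode: str = "run_length",
) -> VesicleMetrics:
    """Kinematic and processivity metrics of one mobile track.

    ``processivity_mode='run_length'`` (default) is the mean length in µm of
    the maximal uninterrupted anterograde/retrograde runs;
    ``'time_fraction'`` is the fraction of observed time spent moving.
    """
    if series.steps.empty:
        raise ValueError(f"track {series.track_id}: no steps to compute metrics from")
    track = track.sort_values("frame")
    s = track["s"].to_numpy(dtype=float)
    t = track["t"].to_numpy(dtype=float)
    duration = t[-1] - t[0]
    speeds = series.steps["ds_per_frame"].abs().to_numpy() * fps
    moving = series.runs[series.runs["state"] != "stall"]
    if processivity_mode == "run_length":
        proc = float(moving["length_um"].mean()) if len(moving) else np.nan
    elif processivity_mode == "time_fraction":
        total = series.runs["duration_frames"].sum()
        proc = float(moving["duration_frames"].sum() / total) if total else np.nan
    else:
        raise ValueError("processivity_mode must be 'run_length' or 'time_fraction'")
    if not len(moving):
        logger.info("track %s: no moving runs, processivity undefined", series.track_id)
    return VesicleMetrics(
        track_id=series.track_id,
        mobility="mobile",
        velocity=float((s[-1] - s[0]) / duration),
        speed=float(speeds.mean()),
        max_speed=float(speeds.max()),
        processivity=proc,
        n_state_changes=series.n_state_changes,
        n_steps=len(series.steps),
    )


class VesicleTransportAnalyzer(BaseEstimator):
    """Full per-track vesicle pipeline: filter → orient → gate → segment → metrics.

    Parameters mirror the published constants (5 frames/s, 0.02 µm/frame
    stall threshold, 0.75 µm mobility gate, 15-frame minimum span, 2-frame
    maximum gap). ``analyze`` returns ``(metrics, steps, summary)``: one
    metrics row per track (stationary tracks carry only the mobility call),
    the per-step state table of mobile tracks, and the per-cell summary.
    """

    def __init__(
        self,
        fps: float = 5.0,
        stall_threshold: float = 0.02,
        mobility_displacement: float = 0.75,
        min_track_frames: int = 15,
        max_gap_frames: int = 2,
        reference_s: float | None = 0.0,
        processivity_mode: str = "run_length",
    ):
        self.fps = fps
        self.stall_threshold = stall_threshold
        self.mobility_displacement = mobility_displacement
        self.min_track_frames = min_track_frames
        self.max_gap_frames = max_gap_frames
        self.reference_s = reference_s
        self.processivity_mode = processivity_mode

    def analyze(self, tracks: pd.DataFrame):
        tracks = filter_tracks(tracks, self.min_track_frames)
        metric_rows, step_frames = [], []
        for (cell, tid), sub in tracks.groupby(["cell_id", "track_id"], sort=False):
            sub = orient_track(sub, self.reference_s)
            mobility = classify_mobility(sub, self.mobility_displacement)
            if mobility == "stationary":
                metric_rows.append(
                    {"cell_id": cell, "track_id": tid, "mobility": "stationary"}
                )
                continue
            series = segment_states(sub, self.stall_threshold, self.max_gap_frames)
            m = vesicle_metrics(series, sub, self.fps, self.processivity_mode)
            metric_rows.append(
                {
                    "cell_id": cell,
                    "track_id": tid,
                    "mobility": "mobile",
                    "velocity": m.velocity,
                    "speed": m.speed,
                    "max_speed": m.max_speed,
                    "processivity": m.processivity,
                    "n_state_changes": m.n_state_changes,
                    "n_steps": m.n_steps,
                }
            )
            steps = series.steps.copy()
            steps.insert(0, "track_id", tid)
            steps.insert(0, "cell_id", cell)
            step_frames.append(steps)
        metrics = pd.DataFrame(
            metric_rows,
            columns=[
                "cell_id",
                "track_id",
                "mobility",
                "velocity",
                "speed",
                "max_speed",
                "processivity",
                "n_state_changes",
                "n_steps",
            ],
        )
        steps = (
            pd.concat(step_frames, ignore_index=True) if step_frames else pd.DataFrame()
        )
        summary = summarize_vesicles(metrics) if not metrics.empty else pd.DataFrame()
        return metrics, steps, summary


def summarize_vesicles(metrics: pd.DataFrame) -> pd.DataFrame:
    """Per-cell averages over mobile tracks plus the mobile fraction.

    State changes are reported both as the per-track mean and as the per-cell
    sum (cumulative); means are missing, not zero, for cells without mobile
    tracks.
    """
    if metrics.empty:
        raise ValueError("no metrics to summarize")
    rows = []
    for cell, sub in metrics.groupby("cell_id", sort=False):
        mobile = sub[sub["mobility"] == "mobile"]
        n_mob = len(mobile)
        rows.append(
            {
                "cell_id": cell,
                "n_tracks": len(sub),
                "mobile_fraction": n_mob / len(sub),
                "mean_velocity": mobile["velocity"].mean() if n_mob else np.nan,
                "mean_speed": mobile["speed"].mean() if n_mob else np.nan,
                "mean_max_speed": mobile["max_speed"].mean() if n_mob else np.nan,
                "mean_processivity": mobile["processivity"].mean() if n_mob else np.nan,
                "mean_state_changes": mobile["n_state_changes"].mean() if n_mob else np.nan,
                "total_state_changes": int(mobile["n_state_changes"].sum()) if n_mob else 0,
            }
        )
        if not n_mob:
            logger.info("cell %s: no mobile vesicles", cell)
    return pd.DataFrame(rows)
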