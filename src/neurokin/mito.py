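"""Mobile/stationary classification of mitochondria and kinematics of the mobile pool.

A mitochondrion is called mobile when its total motion exceeds its own size.
Because the apparent diameter fluctuates from frame to frame (z-motion,
rotation, fusion/fission), the rule is statistical: the distribution of all
recorded diameters of a track is compared against the track's displacement
with a one-sample t-test. With ``t = (mean diameter − displacement) /
(sd/√n)`` and confidence ``1 − p`` (two-sided p-value):

* **mobile** — confidence > threshold and ``t < 0`` (displacement
  significantly exceeds the diameter distribution);
* **stationary** — confidence > threshold and ``t ≥ 0``;
* **undefined** — confidence ≤ threshold (excluded from further analysis).

The default confidence threshold is 0.95. Displacement is the net
start-to-end distance; the maximal excursion from the start is available as
an alternative via ``displacement="max_excursion"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

logger = logging.getLogger("neurokin")

__all__ = [
    "CargoKinematics",
    "MitoClassification",
    "track_kinematics",
    "classify_mito",
    "MitoTrackClassifier",
    "classify_mito_tracks",
    "summarize_mito",
]


@dataclass
class CargoKinematics:
    """Per-track displacement/velocity summary.

    ``velocity`` is net displacement over duration, ``speed`` is traveled
    path length over duration; ``path_length ≥ net_displacement`` always.
    """

    track_id: str
    net_displacement: float  # µm
    path_length: float  # µm
    duration: float  # s
    velocity: float  # µm/s
    speed: float  # µm/s
    max_excursion: float = np.nan  # µm, from the first position


@dataclass
class MitoClassification:
    track_id: str
    label: str  # mobile | stationary | undefined
    t_stat: float
    confidence: float
    displacement: float  # µm
    mean_diameter: float  # µm
    n_frames: int


def _positions(track: pd.DataFrame) -> np.ndarray:
    if "x" in track.columns and track["x"].notna().all() and "y" in track.columns:
        return track[["x", "y"]].to_numpy(dtype=float)
    if "s" in track.columns and track["s"].notna().all():
        return track[["s"]].to_numpy(dtype=float)
    raise ValueError("track has neither complete (x, y) nor s positions")


def track_kinematics(track: pd.DataFrame) -> CargoKinematics:
    """Net displacement, path length, duration and derived velocity/speed.

    ``track`` holds the rows of one trajectory (canonical track-table
    columns), sorted by frame. Requires ≥ 2 frames.
    """
    if len(track) < 2:
        raise ValueError("kinematics need at least 2 frames")
    track = track.sort_values("frame")
    pos = _positions(track)
    steps = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    net = float(np.linalg.norm(pos[-1] - pos[0]))
    path = float(steps.sum())
    excursion = float(np.max(np.linalg.norm(pos - pos[0], axis=1)))
    t = track["t"].to_numpy(dtype=float)
    duration = float(t[-1] - t[0])
    if duration <= 0:
        raise ValueError("track duration must be positive")
    return CargoKinematics(
        track_id=str(track["track_id"].iloc[0]),
        net_displacement=net,
        path_length=path,
        duration=duration,
        velocity=net / duration,
        speed=path / duration,
        max_excursion=excursion,
    )


def classify_mito(
    track: pd.DataFrame,
    confidence_threshold: float = 0.95,
    displacement: str = "net",
) -> MitoClassification:
    """Classify one mitochondrion track as mobile/stationary/undefined.

    One-sample t-test of the track's recorded diameters against its
    displacement (net start-to-end by default). Tracks with fewer than 3
    diameter observations are undefined (no test possible). Zero diameter
    variance is degenerate: the label follows the sign of
    ``mean diameter − displacement`` with confidence 1 (logged).
    """
    if displacement not in ("net", "max_excursion"):
        raise ValueError("displacement must be 'net' or 'max_excursion'")
    tid = str(track["track_id"].iloc[0])
    diam = track["diameter"].dropna().to_numpy(dtype=float)
    kin = track_kinematics(track)
    disp = kin.net_displacement if displacement == "net" else kin.max_excursion
    if diam.size < 3:
        return MitoClassification(
            track_id=tid,
            label="undefined",
            t_stat=np.nan,
            confidence=0.0,
            displacement=disp,
            mean_diameter=float(diam.mean()) if diam.size else np.nan,
            n_frames=len(track),
        )
    if np.ptp(diam) == 0:
        logger.info("track %s: zero diameter variance, degenerate classification", tid)
        t_stat = np.inf if diam.mean() > disp else (-np.inf if diam.mean() < disp else 0.0)
        conf = 1.0 if diam.mean() != disp else 0.0
    else:
        t_stat, p = stats.ttest_1samp(diam, popmean=disp)
        t_stat, conf = float(t_stat), 1.0 - float(p)
    if conf > confidence_threshold:
        label = "mobile" if t_stat < 0 else "stationary"
    else:
        label = "undefined"
    return MitoClassification(
        track_id=tid,
        label=label,
        t_stat=t_stat,
        confidence=conf,
        displacement=disp,
        mean_diameter=float(diam.mean()),
        n_frames=len(track),
    )


class MitoTrackClassifier(BaseEstimator):
    """Table-level wrapper applying the t-test rule to every track.

    ``classify`` returns one row per track with the label, t statistic,
    confidence, displacement, mean diameter and the mobile-pool kinematics.
    """

    def __init__(self, confidence: float = 0.95, displacement: str = "net"):
        self.confidence = confidence
        self.displacement = displacement

    def classify(self, tracks: pd.DataFrame) -> pd.DataFrame:
        rows = []
        for (cell, tid), sub in tracks.groupby(["cell_id", "track_id"], sort=False):
            cls = classify_mito(sub, self.confidence, self.displacement)
            kin = track_kinematics(sub)
            rows.append(
                {
                    "cell_id": cell,
                    "track_id": tid,
                    "label": cls.label,
                    "t_stat": cls.t_stat,
                    "confidence": cls.confidence,
                    "displacement": cls.displacement,
                    "mean_diameter": cls.mean_diameter,
                    "n_frames": cls.n_frames,
                    "net_displacement": kin.net_displacement,
                    "path_length": kin.path_length,
                    "duration": kin.duration,
                    "velocity": kin.velocity,
                    "speed": kin.speed,
                }
            )
        return pd.DataFrame(rows)


def classify_mito_tracks(
    tracks: pd.DataFrame, confidence: float = 0.95, displacement: str = "net"
) -> pd.DataFrame:
    """Classify every track of a mitochondria track table."""
    return MitoTrackClassifier(confidence, displacement).classify(tracks)


def summarize_mito(classified: pd.DataFrame) -> pd.DataFrame:
    """Per-cell fractions and mobile-pool kinematics.

    Fractions over all tracks (mobile + stationary + undefined = 1) and over
    the defined tracks only; mean velocity and speed of the mobile pool
    (missing, not zero, for cells without mobile tracks).
    """
    if classified.empty:
        raise ValueError("no classifications to summarize")
    rows = []
    for cell, sub in classified.groupby("cell_id", sort=False):
        n = len(sub)
        counts = sub["label"].value_counts()
        n_mob = int(counts.get("mobile", 0))
        n_sta = int(counts.get("stationary", 0))
        n_und = int(counts.get("undefined", 0))
        n_def = n_mob + n_sta
        mobile = sub[sub["label"] == "mobile"]
        rows.append(
            {
                "cell_id": cell,
                "n_tracks": n,
                "mobile_fraction": n_mob / n,
                "stationary_fraction": n_sta / n,
                "undefined_fraction": n_und / n,
                "mobile_fraction_defined": n_mob / n_def if n_def else np.nan,
                "mean_velocity_mobile": mobile["velocity"].mean() if n_mob else np.nan,
                "mean_speed_mobile": mobile["speed"].mean() if n_mob else np.nan,
            }
        )
        if n_def == 0:
            logger.warning("cell %s: all tracks undefined", cell)
    return pd.DataFrame(rows)
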