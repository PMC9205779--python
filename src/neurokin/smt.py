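"""Single-molecule residence-time analysis.

A tau molecule interacting with axonal microtubules by kiss-and-hop is
temporally immobile while bound: its localizations stay within a small
radius (50 nm) over consecutive frames, then jump several hundred nm to the
next binding site. Residence time is estimated by (1) counting, for each
localization series, how many consecutive frames the signal stays within the
radius of an anchor localization, (2) building the frequency histogram of
those durations, and (3) fitting a single exponential
``counts(n) = A · exp(−n·Δt/τ)``.

The criterion is anchor-based: an event extends while each following
*consecutive* frame (no gaps) lies within the radius of the event's first
localization. A gap or an excursion beyond the radius closes the event; the
closing frame may anchor the next one. Only events of ≥ 2 frames are
reported — a single frame cannot evidence dwelling. Events truncated by the
end of a series are kept (naive counting; a known censoring bias at short
track lengths).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize
from sklearn.base import BaseEstimator

from .io import LocalizationSeries

__all__ = [
    "DwellHistogram",
    "ResidenceTimeResult",
    "detect_immobile_events",
    "detect_immobile_events_all",
    "build_histogram",
    "fit_residence_time",
    "ResidenceTimeFitter",
]


@dataclass
class DwellHistogram:
    """Frequency table of immobility-event durations (frames)."""

    durations: np.ndarray  # distinct durations, frames (≥ 2)
    counts: np.ndarray
    frame_interval: float  # ms
    n_events: int


@dataclass
class ResidenceTimeResult:
    """Mono-exponential fit of the dwell histogram."""

    tau_res: float  # ms
    amplitude: float  # counts at n = 0 extrapolation
    fit_r2: float
    n_events: int
    converged: bool = True


def detect_immobile_events(
    series: LocalizationSeries, radius: float = 50.0, min_frames: int = 2
) -> list[int]:
    """Durations (frames) of immobility events in one localization series.

    ``radius`` is in nm; positions are µm. Scans frames in order: an event
    opens at an anchor localization and extends while each subsequent
    consecutive frame lies within ``radius`` of the anchor. An empty series
    yields an empty list.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    frames, x, y = series.frames, series.x, series.y
    n = frames.size
    if n == 0:
        return []
    r_um = radius * 1e-3
    durations: list[int] = []
    anchor = 0
    length = 1
    for i in range(1, n):
        consecutive = frames[i] == frames[i - 1] + 1
        within = np.hypot(x[i] - x[anchor], y[i] - y[anchor]) <= r_um
        if consecutive and within:
            length += 1
        else:
            if length >= min_frames:
                durations.append(length)
            anchor, length = i, 1
    if length >= min_frames:
        durations.append(length)
    return durations


def detect_immobile_events_all(
    series_list: Iterable[LocalizationSeries], radius: float = 50.0
) -> list[int]:
    """Pooled immobility-event durations over many molecules."""
    out: list[int] = []
    for s in series_list:
        out.extend(detect_immobile_events(s, radius=radius))
    return out


def build_histogram(durations: Sequence[int], frame_interval: float) -> DwellHistogram:
    """Integer-binned frequency table of event durations.

    ``frame_interval`` is in ms and is carried along for time conversion in
    the exponential fit.
    """
    durations = np.asarray(durations, dtype=int)
    if durations.size == 0:
        raise ValueError("no events: report zero events instead of a histogram")
    if np.any(durations < 2):
        raise ValueError("durations below 2 frames are not immobility events")
    values, counts = np.unique(durations, return_counts=True)
    return DwellHistogram(
        durations=values,
        counts=counts,
        frame_interval=float(frame_interval),
        n_events=int(durations.size),
    )


class ResidenceTimeFitter(BaseEstimator):
    """Least-squares mono-exponential fit of a dwell-duration histogram.

    Fits ``counts(n) = A · exp(−n·Δt/τ)`` on raw counts, with zero-count
    bins inside the observed duration range included as zeros. Fitted
    attributes: ``tau_ms_``, ``amplitude_``, ``r2_``, ``n_events_``,
    ``converged_``.
    """

    def __init__(self, frame_interval: float = 20.0):
        self.frame_interval = frame_interval

    def fit(self, durations: Sequence[int]):
        h = build_histogram(durations, self.frame_interval)
        res = fit_residence_time(h)
        self.tau_ms_ = res.tau_res
        self.amplitude_ = res.amplitude
        self.r2_ = res.fit_r2
        self.n_events_ = res.n_events
        self.converged_ = res.converged
        return self

    def predict(self, durations_frames):
        n = np.asarray(durations_frames, dtype=float)
        return self.amplitude_ * np.exp(-n * self.frame_interval / self.tau_ms_)


def fit_residence_time(h: DwellHistogram) -> ResidenceTimeResult:
    """Fit the dwell histogram with a single exponential; τ in ms.

    Requires ≥ 3 distinct duration bins. Initialized from a log-linear
    regression on the positive-count bins; a failed optimization returns the
    initialization flagged ``converged=False``.
    """
    if h.durations.size < 3:
        raise ValueError(
            f"only {h.durations.size} distinct duration bins; need ≥ 3 "
            "(collect more events)"
        )
    # dense bins over the observed range, zeros included
    n_bins = np.arange(h.durations.min(), h.durations.max() + 1)
    counts = np.zeros(n_bins.size)
    counts[np.searchsorted(n_bins, h.durations)] = h.counts
    t_ms = n_bins * h.frame_interval

    pos = counts > 0
    slope, intercept = np.polyfit(t_ms[pos], np.log(counts[pos]), 1)
    tau0 = -1.0 / slope if slope < 0 else t_ms.max()
    A0 = float(np.exp(intercept))

    def model(t, A, tau):
        return A * np.exp(-t / tau)

    converged = True
    try:
        popt, _ = optimize.curve_fit(
            model, t_ms, counts, p0=[A0, tau0], bounds=([0, 1e-9], [np.inf, np.inf]), maxfev=10000
        )
        A, tau = popt
    except RuntimeError:
        A, tau = A0, tau0
        converged = False
    resid = counts - model(t_ms, A, tau)
    ss_tot = float(np.sum((counts - counts.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else np.nan
    return ResidenceTimeResult(
        tau_res=float(tau),
        amplitude=float(A),
        fit_r2=r2,
        n_events=h.n_events,
        converged=converged,
    )
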