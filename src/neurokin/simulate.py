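"""Synthetic data with known ground truth for every pipeline stage.

Each generator is a pure function of ``(params, seed)`` and returns the
simulated data together with a truth record sufficient to score the
corresponding estimator:

* :func:`simulate_fdap_curve` — photoactivation decay curves from the same
  two-species reaction–diffusion forward model the fitter uses, plus
  additive measurement noise;
* :func:`simulate_smt` — kiss-and-hop single-molecule series: exponentially
  distributed bound episodes at fixed anchors, instantaneous hops of a few
  hundred nm between anchors, Gaussian localization noise;
* :func:`simulate_mito_tracks` — mitochondria with lognormal frame-to-frame
  apparent diameters and mobile/stationary subpopulations;
* :func:`simulate_vesicle_tracks` — vesicles running a 3-state
  (anterograde / retrograde / stall) continuous-time Markov chain along a
  1-D neurite, with i.i.d. tracking gaps capped at the linkable maximum.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import expm

from .fdap import ReactionDiffusionForward
from .io import FdapCurve, LocalizationSeries

__all__ = [
    "STATES",
    "FdapSimParams",
    "SmtSimParams",
    "CargoSimParams",
    "simulate_fdap_curve",
    "simulate_smt",
    "simulate_mito_tracks",
    "simulate_vesicle_tracks",
]

#: canonical state order of the 3-state transport chain
STATES = ("anterograde", "retrograde", "stall")


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# FDAP
# ---------------------------------------------------------------------------


@dataclass
class FdapSimParams:
    """Forward-model parameters of a simulated FDAP acquisition.

    Defaults mirror the published acquisition: a 6 µm activated window
    imaged at 1 frame/s for 112 frames. The default rates put ~70% of the
    labeled species in the bound state (the regime reported for tubulin)
    with a 2 s dissociation time constant, slow enough for the individual
    rates to be resolvable at a 1 s frame interval — at much faster exchange
    only their ratio (through D_eff) is identifiable.
    """

    d_free: float = 10.0  # µm²/s
    k_on_star: float = 7.0 / 6.0  # 1/s
    k_off: float = 0.5  # 1/s
    window_length: float = 6.0  # µm
    frame_interval: float = 1.0  # s
    n_frames: int = 112
    noise_sigma: float = 0.02  # additive, on normalized fluorescence
    pure_diffusion: bool = False

    def __post_init__(self):
        if min(self.k_on_star, self.k_off, self.noise_sigma) < 0:
            raise ValueError("rates and noise_sigma must be ≥ 0")
        if self.d_free < 0:
            raise ValueError("d_free must be ≥ 0")


def simulate_fdap_curve(p: FdapSimParams, seed=None, cell_id: str = "sim") -> tuple[FdapCurve, dict]:
    """Simulate one FDAP curve; returns ``(curve, truth)``.

    The activated top-hat is partitioned at the binding equilibrium, the
    window-averaged total is evaluated by the spectral reaction–diffusion
    solver, Gaussian noise is added, and the curve is renormalized at its
    first (t = 0) sample — exactly the normalization applied to measured
    curves. With ``pure_diffusion`` (or both rates 0) the bound state is
    absent and ``d_free`` acts as the effective diffusion constant.
    """
    rng = _rng(seed)
    t = np.arange(p.n_frames, dtype=float) * p.frame_interval
    k_on, k_off = (0.0, 0.0) if p.pure_diffusion else (p.k_on_star, p.k_off)
    if p.d_free == 0:
        clean = np.ones_like(t)  # nothing leaves the window
    else:
        forward = ReactionDiffusionForward(t, window_length=p.window_length, d_free=p.d_free)
        clean = forward(k_on, k_off)
    noisy = clean + p.noise_sigma * rng.standard_normal(t.size)
    if noisy[0] <= 0:
        raise RuntimeError("noise drove the first sample non-positive; lower noise_sigma")
    values = noisy / noisy[0]
    curve = FdapCurve(
        cell_id=cell_id,
        times=t,
        values=values,
        window_length=p.window_length,
        frame_interval=p.frame_interval,
        n_frames=p.n_frames,
    )
    truth = dataclasses.asdict(p)
    truth["k_on_star"], truth["k_off"] = k_on, k_off
    truth["bound_fraction"] = k_on / (k_on + k_off) if (k_on + k_off) > 0 else 0.0
    return curve, truth


# ---------------------------------------------------------------------------
# single-molecule kiss-and-hop
# ---------------------------------------------------------------------------


@dataclass
class SmtSimParams:
    """Kiss-and-hop simulation parameters (times in ms, lengths in nm).

    ``frame_interval`` has no canonical value and must be supplied; the
    camera interval is an acquisition setting, not a constant of the method.
    """

    frame_interval: float  # ms
    mean_dwell: float = 60.0  # ms, exponential mean of bound episodes
    hop_distance_scale: float = 300.0  # nm between successive binding sites
    n_molecules: int = 200
    track_length_frames: int = 100
    localization_sigma: float = 16.7  # nm, per axis

    def __post_init__(self):
        if self.mean_dwell <= 0:
            raise ValueError("mean_dwell must be > 0")
        if self.localization_sigma < 0 or self.hop_distance_scale < 0:
            raise ValueError("length scales must be ≥ 0")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if self.frame_interval >= 50 * self.mean_dwell:
            warnings.warn(
                "frame_interval ≥ 50 × mean_dwell: dwell episodes are unresolvable "
                "at this sampling rate",
                stacklevel=2,
            )


def simulate_smt(p: SmtSimParams, seed=None) -> tuple[list[LocalizationSeries], pd.DataFrame]:
    """Simulate kiss-and-hop localization series; returns ``(series, truth)``.

    A molecule alternates bound episodes (exponential duration, position
    fixed at the episode anchor) with instantaneous hops of length
    ``hop_distance_scale`` in a uniformly random planar direction. The camera
    samples every ``frame_interval`` with a random phase relative to the
    episode boundaries; each localization gets isotropic Gaussian noise.
    ``truth`` lists every episode's duration in frames (sampled frame count,
    0 for episodes falling between frames).
    """
    rng = _rng(seed)
    dt = p.frame_interval
    total = p.track_length_frames * dt
    series: list[LocalizationSeries] = []
    rows = []
    for m in range(p.n_molecules):
        # episode boundaries with random phase; over-draw then trim
        n_guess = int(total / p.mean_dwell * 3) + 10
        durations = rng.exponential(p.mean_dwell, size=n_guess)
        while durations.sum() < total + dt:
            durations = np.concatenate([durations, rng.exponential(p.mean_dwell, size=n_guess)])
        edges = np.concatenate([[0.0], np.cumsum(durations)]) - rng.uniform(0, durations[0])
        frame_times = np.arange(p.track_length_frames) * dt
        episode = np.searchsorted(edges, frame_times, side="right") - 1
        n_episodes = episode.max() + 1
        # anchor positions: cumulative fixed-length hops, random directions (µm)
        theta = rng.uniform(0, 2 * np.pi, size=n_episodes)
        hops = (p.hop_distance_scale * 1e-3) * np.column_stack([np.cos(theta), np.sin(theta)])
        anchors = np.cumsum(hops, axis=0) - hops[0]
        noise = (p.localization_sigma * 1e-3) * rng.standard_normal((p.track_length_frames, 2))
        pos = anchors[episode] + noise
        mol = f"mol{m:04d}"
        series.append(
            LocalizationSeries(
                molecule_id=mol,
                frames=np.arange(p.track_length_frames),
                x=pos[:, 0],
                y=pos[:, 1],
                frame_interval=dt * 1e-3,
                localization_sigma=p.localization_sigma,
            )
        )
        counts = np.bincount(episode, minlength=n_episodes)
        for ep in range(n_episodes):
            rows.append({"molecule_id": mol, "episode": ep, "n_frames": int(counts[ep])})
    return series, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# organelle transport
# ---------------------------------------------------------------------------


@dataclass
class CargoSimParams:
    """Parameters of the organelle-track generators.

    ``state_rates`` is the 3×3 generator matrix of the
    anterograde/retrograde/stall chain (off-diagonal entries are transition
    rates in 1/s, row order :data:`STATES`); per-frame transition
    probabilities are its matrix exponential at the frame interval.
    Use :meth:`mito_defaults` / :meth:`vesicle_defaults` for populations
    matching the respective acquisitions (2 s/frame mitochondria over 8 min;
    5 frames/s vesicles over 60 s).
    """

    n_tracks: int = 100
    p_mobile: float = 0.2
    speeds: dict = field(default_factory=lambda: {"anterograde": 1.0, "retrograde": 0.9})
    state_rates: np.ndarray | None = None
    duration: float = 60.0  # s
    fps: float = 5.0
    gap_probability: float = 0.05
    max_gap_frames: int = 2
    diameter_mean: float | None = None  # µm, mitochondria only
    diameter_cv: float | None = None
    position_noise: float = 10.0  # nm, per localization
    n_cells: int = 5
    #: µm from the axon-hillock reference; far enough that no track can
    #: reach or cross the reference within the observation window
    start_position_range: tuple[float, float] = (60.0, 120.0)

    def __post_init__(self):
        if not 0 <= self.p_mobile <= 1 or not 0 <= self.gap_probability <= 1:
            raise ValueError("probabilities must lie in [0, 1]")
        if any(v < 0 for v in self.speeds.values()):
            raise ValueError("speeds must be ≥ 0")
        if self.state_rates is None:
            self.state_rates = self.default_state_rates()
        self.state_rates = np.asarray(self.state_rates, dtype=float)
        if self.state_rates.shape != (3, 3):
            raise ValueError("state_rates must be 3×3 (anterograde, retrograde, stall)")
        off = self.state_rates[~np.eye(3, dtype=bool)]
        if np.any(off < 0):
            raise ValueError("transition rates must be ≥ 0")
        q = self.state_rates.copy()
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        self.state_rates = q

    @staticmethod
    def default_state_rates() -> np.ndarray:
        # moderate processivity: runs of tens of seconds, occasional reversals
        a2r, a2s = 0.005, 0.03
        r2a, r2s = 0.010, 0.03
        s2a, s2r = 0.150, 0.05
        return np.array(
            [[0.0, a2r, a2s], [r2a, 0.0, r2s], [s2a, s2r, 0.0]]
        )

    @classmethod
    def vesicle_defaults(cls, **overrides) -> "CargoSimParams":
        return cls(**overrides)

    @classmethod
    def mito_defaults(cls, **overrides) -> "CargoSimParams":
        base = dict(
            n_tracks=60,
            p_mobile=0.2,
            speeds={"anterograde": 0.5, "retrograde": 0.4},
            state_rates=np.array(
                [[0.0, 0.002, 0.01], [0.004, 0.0, 0.01], [0.02, 0.01, 0.0]]
            ),
            duration=480.0,
            fps=0.5,
            gap_probability=0.0,
            diameter_mean=0.6,
            diameter_cv=0.15,
            position_noise=30.0,
            n_cells=5,
        )
        base.update(overrides)
        return cls(**base)


def _stationary_distribution(q: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eig(q.T)
    i = np.argmin(np.abs(vals))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def _markov_states(q: np.ndarray, n_frames: int, fps: float, rng: np.random.Generator) -> np.ndarray:
    """Per-frame state indices of the 3-state chain, initialized at stationarity."""
    P = expm(q / fps)
    P = np.clip(P, 0.0, 1.0)
    P /= P.sum(axis=1, keepdims=True)
    cum = np.cumsum(P, axis=1)
    states = np.empty(n_frames, dtype=int)
    states[0] = rng.choice(3, p=_stationary_distribution(q))
    u = rng.random(n_frames - 1)
    for i in range(1, n_frames):
        states[i] = np.searchsorted(cum[states[i - 1]], u[i - 1])
    return states


def _inject_gaps(frames: np.ndarray, gap_probability: float, max_gap: int, rng) -> np.ndarray:
    """Boolean keep-mask: i.i.d. frame drops, never more than ``max_gap`` in a
    row and never the first or last frame, so tracks remain linkable."""
    keep = rng.random(frames.size) >= gap_probability
    keep[0] = keep[-1] = True
    run = 0
    for i in range(frames.size):
        if not keep[i]:
            run += 1
            if run > max_gap:
                keep[i] = True
                run = 0
        else:
            run = 0
    return keep


def _spread_cells(n_tracks: int, n_cells: int) -> list[str]:
    return [f"cell{(i % n_cells):02d}" for i in range(n_tracks)]


def simulate_vesicle_tracks(p: CargoSimParams, seed=None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate vesicle tracks along a 1-D neurite; returns ``(tracks, truth)``.

    Mobile tracks (probability ``p_mobile``) run the 3-state chain; per frame
    the arclength s advances by ±speed/fps (0 in stall) plus localization
    noise. Stationary tracks idle in the stall state. Anterograde is the
    +s direction (away from the axon hillock at s = 0). ``truth`` has one row
    per track (label, generative state-change count, per-step states as an
    array) — everything needed to score mobility calls, segmentation and
    state-change recovery.
    """
    rng = _rng(seed)
    n_frames = int(round(p.duration * p.fps)) + 1
    cells = _spread_cells(p.n_tracks, p.n_cells)
    sigma = p.position_noise * 1e-3
    speed = np.array([p.speeds["anterograde"] / p.fps, -p.speeds["retrograde"] / p.fps, 0.0])
    rows, truth_rows = [], []
    for i in range(p.n_tracks):
        tid = f"track{i:04d}"
        mobile = rng.random() < p.p_mobile
        if mobile:
            states = _markov_states(p.state_rates, n_frames, p.fps, rng)
        else:
            states = np.full(n_frames, 2)  # stall
        ds = speed[states[:-1]]
        s = rng.uniform(*p.start_position_range) + np.concatenate([[0.0], np.cumsum(ds)])
        s_obs = s + sigma * rng.standard_normal(n_frames)
        frames = np.arange(n_frames)
        keep = (
            _inject_gaps(frames, p.gap_probability, p.max_gap_frames, rng)
            if p.gap_probability > 0
            else np.ones(n_frames, dtype=bool)
        )
        for fr, sv in zip(frames[keep], s_obs[keep]):
            rows.append(
                {"cell_id": cells[i], "track_id": tid, "frame": int(fr), "t": fr / p.fps, "s": sv}
            )
        step_states = np.array([STATES[j] for j in states[:-1]], dtype=object)
        truth_rows.append(
            {
                "cell_id": cells[i],
                "track_id": tid,
                "label": "mobile" if mobile else "stationary",
                "n_state_changes": int(np.sum(states[:-1][1:] != states[:-1][:-1])),
                "states": step_states,
            }
        )
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


def simulate_mito_tracks(p: CargoSimParams, seed=None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate mitochondria tracks in the plane; returns ``(tracks, truth)``.

    The neurite runs along x. Stationary mitochondria jitter around a fixed
    point with ``position_noise``; mobile ones follow the 3-state chain along
    x. Every frame records an apparent diameter drawn lognormal with mean
    ``diameter_mean`` and coefficient of variation ``diameter_cv``, emulating
    the frame-to-frame diameter fluctuation from z-motion and rotation that
    motivates the t-test classification rule.
    """
    if p.diameter_mean is None or p.diameter_cv is None:
        raise ValueError("diameter_mean and diameter_cv must be set for mitochondria")
    rng = _rng(seed)
    n_frames = int(round(p.duration * p.fps)) + 1
    cells = _spread_cells(p.n_tracks, p.n_cells)
    sigma = p.position_noise * 1e-3
    sig_log = np.sqrt(np.log1p(p.diameter_cv**2))
    mu_log = np.log(p.diameter_mean) - 0.5 * sig_log**2
    speed = np.array([p.speeds["anterograde"] / p.fps, -p.speeds["retrograde"] / p.fps, 0.0])
    rows, truth_rows = [], []
    for i in range(p.n_tracks):
        tid = f"track{i:04d}"
        mobile = rng.random() < p.p_mobile
        if mobile:
            states = _markov_states(p.state_rates, n_frames, p.fps, rng)
            x = np.concatenate([[0.0], np.cumsum(speed[states[:-1]])])
        else:
            x = np.zeros(n_frames)
        x = x + rng.uniform(*p.start_position_range) + sigma * rng.standard_normal(n_frames)
        y = sigma * rng.standard_normal(n_frames)
        diam = rng.lognormal(mu_log, sig_log, size=n_frames)
        frames = np.arange(n_frames)
        keep = (
            _inject_gaps(frames, p.gap_probability, p.max_gap_frames, rng)
            if p.gap_probability > 0
            else np.ones(n_frames, dtype=bool)
        )
        for fr in frames[keep]:
            rows.append(
                {
                    "cell_id": cells[i],
                    "track_id": tid,
                    "frame": int(fr),
                    "t": fr / p.fps,
                    "x": x[fr],
                    "y": y[fr],
                    "diameter": diam[fr],
                }
            )
        truth_rows.append(
            {"cell_id": cells[i], "track_id": tid, "label": "mobile" if mobile else "stationary"}
        )
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)
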