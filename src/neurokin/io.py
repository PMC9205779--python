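"""Data model, tabular I/O and configuration for the transport/kinetics pipeline.

The pipeline works on three tabular inputs, all plain long-format CSV:

* **track tables** — organelle trajectories, one localization per row
  (``cell_id, track_id, frame, t, s | x,y [, diameter]``), the flat spot
  tables exported by TrackMate or Imaris;
* **FDAP curves** — per-cell normalized fluorescence decay after
  photoactivation (``cell_id, t, F``);
* **localization series** — single-molecule positions per frame
  (``molecule_id, frame, x, y``).

Units are micrometres and seconds throughout (localization precision is
carried in nanometres, as it is quoted in the field). Frames are 0-based and
``t = frame * frame_interval``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("neurokin")

__all__ = [
    "TRACK_COLUMNS",
    "COLUMN_ALIASES",
    "FdapCurve",
    "LocalizationSeries",
    "AnalysisConfig",
    "SchemaError",
    "ValidationError",
    "read_tracks",
    "write_tracks",
    "validate_tracks",
    "read_fdap",
    "write_fdap",
    "read_localizations",
    "write_localizations",
    "validate_config",
    "write_run_metadata",
]


class SchemaError(ValueError):
    """A mandatory column is missing or unmappable."""


class ValidationError(ValueError):
    """Rows parsed but violate a table invariant (named in the message)."""


#: Canonical track-table columns. ``s`` is signed arclength along the neurite
#: (anterograde positive, increasing away from the axon hillock); ``x, y`` are
#: planar coordinates; at least one of the two must be present. ``diameter``
#: is the per-frame apparent organelle diameter (mitochondria only).
TRACK_COLUMNS = ("cell_id", "track_id", "frame", "t", "s", "x", "y", "diameter")

#: Header aliases for common tracker exports, applied case-insensitively.
#: Extend or override with a YAML mapping file passed to :func:`read_tracks`.
COLUMN_ALIASES: dict[str, str] = {
    # TrackMate spot table
    "track_id": "track_id",
    "trackid": "track_id",
    "frame": "frame",
    "position_x": "x",
    "position_y": "y",
    "position_t": "t",
    "radius": "diameter",  # TrackMate exports a radius; callers may rescale
    # Imaris spreadsheet export
    "time": "frame",
    "position x": "x",
    "position y": "y",
    "diameter x": "diameter",
    # common manual names
    "cell": "cell_id",
    "cell_id": "cell_id",
    "track": "track_id",
    "t": "t",
    "s": "s",
    "x": "x",
    "y": "y",
    "diameter": "diameter",
}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class FdapCurve:
    """One photoactivated cell's normalized fluorescence decay.

    ``times`` start at 0 (first post-activation frame) and ``values`` are
    normalized so ``values[0] == 1``. ``window_length`` is the length of the
    photoactivated neurite segment in µm.
    """

    cell_id: str
    times: np.ndarray
    values: np.ndarray
    window_length: float = 6.0
    frame_interval: float = 1.0
    n_frames: int = 112

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValidationError(f"curve {self.cell_id}: times/values must be equal-length 1-D")
        if self.times.size and self.times[0] < 0:
            raise ValidationError(f"curve {self.cell_id}: negative times")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValidationError(f"curve {self.cell_id}: times not strictly increasing")
        if self.window_length <= 0:
            raise ValidationError(f"curve {self.cell_id}: window_length must be > 0")
        if self.values.size and not np.isclose(self.values[0], 1.0, atol=1e-9):
            raise ValidationError(
                f"curve {self.cell_id}: values[0] = {self.values[0]!r}, expected 1 "
                "(normalize at the first post-activation frame, e.g. via read_fdap)"
            )


@dataclass
class LocalizationSeries:
    """Per-frame sub-pixel positions of one labeled molecule (µm).

    Frame gaps are allowed; frames must strictly increase. The theoretical
    localization precision is carried as metadata in nm.
    """

    molecule_id: str
    frames: np.ndarray
    x: np.ndarray
    y: np.ndarray
    frame_interval: float = 0.02
    localization_sigma: float = 16.7

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.frames.shape == self.x.shape == self.y.shape):
            raise ValidationError(f"series {self.molecule_id}: frames/x/y length mismatch")
        if self.frames.size > 1 and not np.all(np.diff(self.frames) > 0):
            raise ValidationError(f"series {self.molecule_id}: frames not strictly increasing")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValidationError(f"series {self.molecule_id}: non-finite positions")


@dataclass
class AnalysisConfig:
    """Printed analysis constants of the transport/kinetics pipeline.

    Defaults encode the published acquisition and gating constants:
    5 frames/s vesicle imaging, a 0.02 µm/frame stall threshold (0.1 µm/s),
    a 0.75 µm mobility gate over a 60 s observation, 15-frame (3 s) minimum
    tracks, a 2-frame (400 ms) maximum linking gap, a 50 nm single-molecule
    immobility radius, and a 0.95 confidence level for the mitochondria
    t-test rule. ``d_free`` (µm²/s, free-protein diffusion constant used by
    the reaction–diffusion fit) has no universal value and must be set per
    protein.
    """

    fps_vesicle: float = 5.0
    stall_threshold: float = 0.02  # µm/frame
    mobility_displacement: float = 0.75  # µm
    observation_time: float = 60.0  # s
    min_track_frames: int = 15
    max_gap_frames: int = 2
    immobility_radius: float = 50.0  # nm
    mito_confidence: float = 0.95
    d_free: float | None = None  # µm²/s, required for reaction-diffusion fits
    rng_seed: int | None = None
    #: derived audit fields, populated by validate_config
    audit: dict = field(default_factory=dict, compare=False)

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)} - {"audit"}
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        return validate_config(cls(**raw))


def validate_config(cfg: AnalysisConfig) -> AnalysisConfig:
    """Validate invariants and populate derived audit fields.

    The audit fields re-express the frame-based constants in physical units
    (stall threshold in µm/s, maximum gap in ms, minimum track duration in s)
    so a run's configuration can be checked against the published values at a
    glance. Idempotent: the audit is a pure function of the config.
    """
    positive = {
        "fps_vesicle": cfg.fps_vesicle,
        "stall_threshold": cfg.stall_threshold,
        "mobility_displacement": cfg.mobility_displacement,
        "observation_time": cfg.observation_time,
        "immobility_radius": cfg.immobility_radius,
    }
    for name, value in positive.items():
        if not value > 0:
            raise ValidationError(f"config.{name} must be strictly positive, got {value}")
    if cfg.min_track_frames < 2:
        raise ValidationError(f"config.min_track_frames must be ≥ 2, got {cfg.min_track_frames}")
    if cfg.max_gap_frames < 0:
        raise ValidationError(f"config.max_gap_frames must be ≥ 0, got {cfg.max_gap_frames}")
    if not 0 < cfg.mito_confidence < 1:
        raise ValidationError(f"config.mito_confidence must lie in (0, 1), got {cfg.mito_confidence}")
    if cfg.d_free is not None and cfg.d_free <= 0:
        raise ValidationError(f"config.d_free must be positive when set, got {cfg.d_free}")
    cfg.audit = {
        "stall_speed_um_per_s": cfg.stall_threshold * cfg.fps_vesicle,
        "max_gap_ms": cfg.max_gap_frames * 1000.0 / cfg.fps_vesicle,
        "min_track_duration_s": cfg.min_track_frames / cfg.fps_vesicle,
    }
    return cfg


# ---------------------------------------------------------------------------
# track tables
# ---------------------------------------------------------------------------


def _map_columns(columns: Iterable[str], aliases: Mapping[str, str]) -> dict[str, str]:
    mapping = {}
    for col in columns:
        key = col.strip().lower()
        if key in aliases:
            mapping[col] = aliases[key]
    return mapping


def validate_tracks(
    df: pd.DataFrame,
    schema: str = "vesicle",
    frame_interval: float | None = None,
) -> pd.DataFrame:
    """Validate and canonicalize a track table.

    Checks mandatory columns, strictly increasing frames within each
    (cell_id, track_id), presence of either ``s`` or ``(x, y)`` per row, and
    (when ``frame_interval`` is declared) consistency of ``t`` with
    ``frame * frame_interval`` to 1e-6 s. Returns the table sorted by
    (cell_id, track_id, frame) with canonical dtypes.
    """
    if schema not in ("mito", "vesicle"):
        raise SchemaError(f"unknown track schema {schema!r}")
    df = df.copy()
    if "cell_id" not in df.columns:
        df["cell_id"] = "cell0"
    for col in ("track_id", "frame"):
        if col not in df.columns:
            raise SchemaError(f"missing mandatory column '{col}'")
    has_s = "s" in df.columns
    has_xy = "x" in df.columns and "y" in df.columns
    if not has_s and not has_xy:
        raise SchemaError("need position columns: either 's' or both 'x' and 'y'")
    if schema == "mito" and "diameter" not in df.columns:
        raise SchemaError("missing mandatory column 'diameter' (mito schema)")

    df["cell_id"] = df["cell_id"].astype(str)
    df["track_id"] = df["track_id"].astype(str)
    frames = pd.to_numeric(df["frame"], errors="coerce")
    bad = df.index[frames.isna() | (frames < 0) | (frames % 1 != 0)]
    if len(bad):
        raise ValidationError(f"unparseable/negative frame values at rows {list(bad[:10])}")
    df["frame"] = frames.astype(int)
    if "t" not in df.columns:
        if frame_interval is None:
            raise SchemaError("no 't' column and no frame_interval to derive it from")
        df["t"] = df["frame"] * frame_interval
    df["t"] = pd.to_numeric(df["t"])
    for col in ("s", "x", "y", "diameter"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col])

    df = df.sort_values(["cell_id", "track_id", "frame"], kind="stable").reset_index(drop=True)

    pos_ok = pd.Series(False, index=df.index)
    if has_s:
        pos_ok |= df["s"].notna()
    if has_xy:
        pos_ok |= df["x"].notna() & df["y"].notna()
    if not pos_ok.all():
        raise ValidationError(
            f"rows without any position (neither s nor x/y): {list(df.index[~pos_ok][:10])}"
        )

    for (cell, track), sub in df.groupby(["cell_id", "track_id"], sort=False):
        dframes = np.diff(sub["frame"].to_numpy())
        if np.any(dframes <= 0):
            raise ValidationError(
                f"track {track!r} in cell {cell!r}: frames not strictly increasing "
                "(duplicate or out-of-order frame)"
            )
    if frame_interval is not None:
        err = (df["t"] - df["frame"] * frame_interval).abs().max()
        if err > 1e-6:
            raise ValidationError(
                f"t inconsistent with frame * frame_interval (max deviation {err:.3g} s)"
            )
    return df


def read_tracks(
    path: str | Path,
    schema: str = "vesicle",
    aliases: Mapping[str, str] | None = None,
    alias_file: str | Path | None = None,
    frame_interval: float | None = None,
) -> pd.DataFrame:
    """Read a tracker CSV export into a validated canonical track table.

    ``aliases`` / ``alias_file`` (YAML mapping of header name to canonical
    column) extend the built-in TrackMate/Imaris aliases.
    """
    path = Path(path)
    table = pd.read_csv(path, comment="#")
    alias_map = dict(COLUMN_ALIASES)
    if alias_file is not None:
        with open(alias_file) as fh:
            extra = yaml.safe_load(fh) or {}
        alias_map.update({str(k).strip().lower(): v for k, v in extra.items()})
    if aliases:
        alias_map.update({str(k).strip().lower(): v for k, v in aliases.items()})
    table = table.rename(columns=_map_columns(table.columns, alias_map))
    table = table[[c for c in table.columns if c in TRACK_COLUMNS]]
    try:
        out = validate_tracks(table, schema=schema, frame_interval=frame_interval)
    except (SchemaError, ValidationError) as exc:
        raise type(exc)(f"{path.name}: {exc}") from None
    logger.info("read %d rows / %d tracks from %s", len(out), out["track_id"].nunique(), path)
    return out


def write_tracks(df: pd.DataFrame, path: str | Path) -> None:
    """Write a canonical track table as CSV (full float precision)."""
    cols = [c for c in TRACK_COLUMNS if c in df.columns]
    df[cols].to_csv(path, index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# FDAP curves
# ---------------------------------------------------------------------------


def read_fdap(
    path: str | Path,
    window_length: float = 6.0,
    frame_interval: float = 1.0,
) -> list[FdapCurve]:
    """Read FDAP curves (columns ``cell_id, t, F``), one curve per cell.

    Each curve is renormalized so its first sample equals 1; the applied
    factor is logged. A non-positive first fluorescence value cannot be
    normalized and raises :class:`ValidationError`.
    """
    df = pd.read_csv(path, comment="#")
    for col in ("cell_id", "t", "F"):
        if col not in df.columns:
            raise SchemaError(f"{Path(path).name}: missing mandatory column '{col}'")
    curves = []
    for cell, sub in df.groupby("cell_id", sort=False):
        sub = sub.sort_values("t")
        t = sub["t"].to_numpy(dtype=float)
        f = sub["F"].to_numpy(dtype=float)
        if f[0] <= 0:
            raise ValidationError(f"cell {cell!r}: first fluorescence value {f[0]} ≤ 0, cannot normalize")
        if not np.isclose(f[0], 1.0):
            logger.info("cell %s: renormalizing by F(0) = %g", cell, f[0])
        curves.append(
            FdapCurve(
                cell_id=str(cell),
                times=t - t[0],
                values=f / f[0],
                window_length=window_length,
                frame_interval=frame_interval,
                n_frames=len(f),
            )
        )
    return curves


def write_fdap(curves: Sequence[FdapCurve], path: str | Path) -> None:
    frames = [
        pd.DataFrame({"cell_id": c.cell_id, "t": c.times, "F": c.values}) for c in curves
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# localization series
# ---------------------------------------------------------------------------


def read_localizations(
    path: str | Path,
    frame_interval: float = 0.02,
    localization_sigma: float = 16.7,
) -> list[LocalizationSeries]:
    """Read single-molecule localizations (``molecule_id, frame, x, y`` in µm)."""
    df = pd.read_csv(path, comment="#")
    for col in ("molecule_id", "frame", "x", "y"):
        if col not in df.columns:
            raise SchemaError(f"{Path(path).name}: missing mandatory column '{col}'")
    out = []
    for mol, sub in df.groupby("molecule_id", sort=False):
        sub = sub.sort_values("frame")
        out.append(
            LocalizationSeries(
                molecule_id=str(mol),
                frames=sub["frame"].to_numpy(dtype=int),
                x=sub["x"].to_numpy(dtype=float),
                y=sub["y"].to_numpy(dtype=float),
                frame_interval=frame_interval,
                localization_sigma=localization_sigma,
            )
        )
    return out


def write_localizations(series: Sequence[LocalizationSeries], path: str | Path) -> None:
    frames = [
        pd.DataFrame({"molecule_id": s.molecule_id, "frame": s.frames, "x": s.x, "y": s.y})
        for s in series
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# run metadata
# ---------------------------------------------------------------------------


def write_run_metadata(path: str | Path, config: AnalysisConfig | dict | None, seed: int | None, **extra) -> None:
    """Write the JSON sidecar recording config echo, seed and versions."""
    import numpy
    import pandas
    import scipy

    from . import __version__

    if dataclasses.is_dataclass(config):
        config = dataclasses.asdict(config)
    meta = {
        "neurokin": __version__,
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
        "seed": seed,
        "config": config,
        **extra,
    }
    with open(path, "w") as fh:
        json.dump(meta, fh, indent=2, default=str)
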