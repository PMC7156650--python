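"""Reading and writing of movies, label images, seed tables, and config.

Movies are stored as multi-page TIFF with axis order ``(t, c, z, y, x)``
declared in the (tifffile "shaped") metadata together with the physical
calibration, so files round-trip bit-for-bit through this module. Seed
calls and track/trace tables are plain CSV with a header row; ground truth
and run manifests are JSON; configuration is a flat YAML key-value file.

Coordinate convention, used everywhere in the package: x indexes columns,
y indexes rows, z and t are 0-based plane / frame indices.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .exceptions import (CalibrationError, ConfigError, FormatError,
                         InputValidationError, SchemaError)
from .params import (CHANNEL_ROLES, AnalysisConfig, DetectionParams,
                     MarkerParams, TraceParams)

logger = logging.getLogger("endoescape")

MOVIE_AXES = "TCZYX"


@dataclass
class Movie:
    """A 5D intensity movie with physical calibration.

    ``data`` has axis order (t, c, z, y, x); intensities must be finite and
    non-negative, and every dimension must be at least 1.
    """

    data: np.ndarray
    frame_interval_s: float
    pixel_size_um: float = 0.1
    z_step_um: float = 0.3
    channel_names: tuple = ()

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 5:
            raise InputValidationError(
                f"movie data must be 5D (t, c, z, y, x), got {self.data.ndim}D")
        if any(s < 1 for s in self.data.shape):
            raise InputValidationError(
                f"every movie dimension must be >= 1, got shape {self.data.shape}")
        if self.frame_interval_s <= 0:
            raise InputValidationError("frame_interval_s must be positive")
        if not np.isfinite(self.data).all() or (self.data < 0).any():
            raise InputValidationError("movie intensities must be finite and >= 0")
        if not self.channel_names:
            self.channel_names = tuple(f"ch{i}" for i in range(self.data.shape[1]))
        self.channel_names = tuple(self.channel_names)
        if len(self.channel_names) != self.data.shape[1]:
            raise InputValidationError("channel_names length must match channel axis")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_z(self) -> int:
        return self.data.shape[2]

    @property
    def shape(self):
        return self.data.shape


@dataclass
class SeedCall:
    """Approximate (x, y, t) of a candidate de novo galectin focus."""

    x_px: int
    y_px: int
    t_frame: int
    cell_label: int | None = None


def write_movie(movie: Movie, path) -> None:
    """Write ``movie`` as a multi-page TIFF whose metadata declares the axis
    order and calibration. Dtype is preserved (16-bit stays 16-bit)."""
    path = Path(path)
    meta = {
        "axes": MOVIE_AXES,
        "frame_interval_s": float(movie.frame_interval_s),
        "pixel_size_um": float(movie.pixel_size_um),
        "z_step_um": float(movie.z_step_um),
        "channel_names": list(movie.channel_names),
    }
    try:
        tifffile.imwrite(path, movie.data, metadata=meta,
                         photometric="minisblack")
    except OSError as exc:
        raise OSError(f"cannot write movie to {path}: {exc}") from exc


def read_movie(path, calibration: dict | None = None) -> Movie:
    """Read a movie written by :func:`write_movie`.

    ``calibration`` may override/supply ``frame_interval_s``,
    ``pixel_size_um``, ``z_step_um`` and ``channel_names``; a movie without
    stored calibration and without an override raises
    :class:`CalibrationError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"movie file not found: {path}")
    try:
        with tifffile.TiffFile(path) as tif:
            shapes = {page.shape for page in tif.pages}
            if len(shapes) > 1:
                raise FormatError(
                    f"{path}: inconsistent page shapes {sorted(shapes)}")
            data = tif.asarray()
            meta = {}
            if tif.shaped_metadata:
                meta = dict(tif.shaped_metadata[0])
    except tifffile.TiffFileError as exc:
        raise FormatError(f"{path}: not a readable TIFF ({exc})") from exc
    if data.ndim == 4:          # single-channel movie collapsed on write
        data = data[:, None]
    if data.ndim != 5:
        raise FormatError(f"{path}: expected 5D (t,c,z,y,x) data, got {data.ndim}D")
    calibration = dict(calibration or {})
    merged = {**meta, **calibration}
    if "frame_interval_s" not in merged:
        raise CalibrationError(
            f"{path}: no frame_interval_s in metadata and no calibration override")
    return Movie(
        data=data,
        frame_interval_s=float(merged["frame_interval_s"]),
        pixel_size_um=float(merged.get("pixel_size_um", 0.1)),
        z_step_um=float(merged.get("z_step_um", 0.3)),
        channel_names=tuple(merged.get("channel_names", ())),
    )


SEED_COLUMNS = ("x", "y", "t")


def read_seed_calls(path, movie_shape=None) -> list[SeedCall]:
    """Read seed calls from CSV (columns x, y, t[, cell]) or a JSON list.

    Coordinates are 0-based. When ``movie_shape`` (t, c, z, y, x) is given,
    out-of-bounds seeds raise :class:`InputValidationError` naming the row.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"seed-call file not found: {path}")
    if path.suffix.lower() == ".json":
        records = json.loads(path.read_text())
        df = pd.DataFrame.from_records(records)
        if df.empty:
            df = pd.DataFrame(columns=SEED_COLUMNS)
    else:
        df = pd.read_csv(path)
    missing = [c for c in SEED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    seeds = []
    for i, row in df.iterrows():
        seed = SeedCall(x_px=int(row["x"]), y_px=int(row["y"]),
                        t_frame=int(row["t"]),
                        cell_label=int(row["cell"]) if "cell" in df.columns
                        and pd.notna(row.get("cell")) else None)
        if movie_shape is not None:
            nt, _, _, ny, nx = movie_shape
            if not (0 <= seed.x_px < nx and 0 <= seed.y_px < ny
                    and 0 <= seed.t_frame < nt):
                raise InputValidationError(
                    f"{path}: seed in row {i} out of movie bounds: {seed}")
        seeds.append(seed)
    return seeds


def write_seed_calls(seeds, path) -> None:
    rows = [{"x": s.x_px, "y": s.y_px, "t": s.t_frame,
             **({"cell": s.cell_label} if s.cell_label is not None else {})}
            for s in seeds]
    pd.DataFrame(rows, columns=["x", "y", "t", "cell"][: 4 if any(
        s.cell_label is not None for s in seeds) else 3]).to_csv(path, index=False)


def read_labels(path) -> np.ndarray:
    """Read a single-plane integer label image (0 = background)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"label image not found: {path}")
    arr = tifffile.imread(path)
    if not np.issubdtype(arr.dtype, np.integer):
        raise FormatError(
            f"{path}: label image must have integer pixel values, got {arr.dtype}")
    if arr.ndim != 2:
        raise FormatError(f"{path}: label image must be single-plane 2D")
    return arr


def write_labels(labels: np.ndarray, path) -> None:
    labels = np.asarray(labels)
    if not np.issubdtype(labels.dtype, np.integer):
        raise FormatError("label image must have integer dtype")
    tifffile.imwrite(path, labels.astype(np.uint16))


# ---------------------------------------------------------------------------
# track / trace tables

def write_tracks(tracks, movie: Movie, path, sidecar_path=None) -> None:
    """Export tracks as long CSV (one row per frame) plus a JSON sidecar
    holding per-event onset frame, threshold, and flags."""
    rows = []
    sidecar = []
    for event_id, tr in enumerate(tracks):
        for static, frames, pos, inten, bg in (
                (1, tr.static_frames, None, tr.static_intensities, tr.static_local_bg),
                (0, tr.frames, tr.positions, tr.intensities, tr.local_bg)):
            for i, f in enumerate(frames):
                z, y, x = (tr.t0_position if static else tuple(pos[i]))
                row = {"event_id": event_id, "frame": int(f), "static": static,
                       "z": int(z), "y": int(y), "x": int(x)}
                for c, name in enumerate(movie.channel_names):
                    row[f"intensity_{name}"] = float(inten[i, c])
                    row[f"local_bg_{name}"] = float(bg[i, c])
                rows.append(row)
        sidecar.append({"event_id": event_id, "t0_frame": int(tr.t0_frame),
                        "threshold_used": float(tr.threshold_used),
                        "t0_position": [int(v) for v in tr.t0_position],
                        "flags": sorted(tr.flags)})
    pd.DataFrame(rows).to_csv(path, index=False)
    if sidecar_path is not None:
        Path(sidecar_path).write_text(json.dumps(sidecar, indent=1))


def read_tracks(path, sidecar_path) -> list:
    """Re-assemble :class:`~endoescape.events.VesicleTrack` objects written
    by :func:`write_tracks`."""
    from .events import VesicleTrack  # local import to avoid a cycle

    df = pd.read_csv(path)
    sidecar = json.loads(Path(sidecar_path).read_text())
    chan_cols = [c for c in df.columns if c.startswith("intensity_")]
    bg_cols = [c.replace("intensity_", "local_bg_") for c in chan_cols]
    tracks = []
    for entry in sidecar:
        sub = df[df["event_id"] == entry["event_id"]]
        stat = sub[sub["static"] == 1].sort_values("frame")
        trk = sub[sub["static"] == 0].sort_values("frame")
        tracks.append(VesicleTrack(
            t0_frame=int(entry["t0_frame"]),
            t0_position=tuple(entry["t0_position"]),
            frames=trk["frame"].to_numpy(),
            positions=trk[["z", "y", "x"]].to_numpy(),
            intensities=trk[chan_cols].to_numpy(float),
            local_bg=trk[bg_cols].to_numpy(float),
            static_frames=stat["frame"].to_numpy(),
            static_intensities=stat[chan_cols].to_numpy(float),
            static_local_bg=stat[bg_cols].to_numpy(float),
            threshold_used=float(entry["threshold_used"]),
            flags=set(entry["flags"]),
        ))
    return tracks


# ---------------------------------------------------------------------------
# configuration

def _flat_config(config: AnalysisConfig) -> dict:
    flat = {}
    for section in (config.detection, config.traces, config.markers):
        for f in dataclasses.fields(section):
            v = getattr(section, f.name)
            flat[f.name] = list(v) if isinstance(v, tuple) else v
    for role, idx in config.channels.items():
        flat[f"channel_{role}"] = idx
    flat["rng_seed"] = config.rng_seed
    return flat


def save_config(config: AnalysisConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(_flat_config(config), sort_keys=True))


def load_config(path=None, overrides: dict | None = None) -> AnalysisConfig:
    """Load a flat YAML config; unknown keys are rejected.

    Defaults (no file) equal the assay's published parameter values.
    """
    flat = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"{path}: config must be a flat key-value mapping")
        flat.update(loaded)
    flat.update(overrides or {})

    sections = {cls: {f.name: f for f in dataclasses.fields(cls)}
                for cls in (DetectionParams, TraceParams, MarkerParams)}
    kwargs = {cls: {} for cls in sections}
    channels = {}
    rng_seed = 0
    for key, value in flat.items():
        if key.startswith("channel_"):
            role = key[len("channel_"):]
            if role not in CHANNEL_ROLES:
                raise ConfigError(f"unknown channel role in config key: {key!r}")
            channels[role] = int(value)
            continue
        if key == "rng_seed":
            rng_seed = int(value)
            continue
        owner = next((cls for cls, fl in sections.items() if key in fl), None)
        if owner is None:
            raise ConfigError(f"unknown config key: {key!r}")
        if isinstance(value, list):
            value = tuple(value)
        kwargs[owner][key] = value
    if not channels:
        channels = {"galectin": 0, "cargo": 1}
    return AnalysisConfig(
        detection=DetectionParams(**kwargs[DetectionParams]),
        traces=TraceParams(**kwargs[TraceParams]),
        markers=MarkerParams(**kwargs[MarkerParams]),
        channels=channels,
        rng_seed=rng_seed,
    )
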