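"""Onset-aligned traces and event-level release statistics.

A trace is one channel of one tracked vesicle: per frame, the raw mask
mean minus a centered 11-frame rolling average of the local background,
aligned so the onset frame maps to relative time 0. Cargo traces are
normalized to their pre-onset window mean (~3-60 s before onset), galectin
traces to their maximum. The release fraction of a single vesicle is
1 - post/pre from single-frame measurements ~15 s before and ~45 s after
onset; fold recruitment is the focus mean ~90-105 s after onset over the
cell background mean ~10-25 s before.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .exceptions import CoverageError, InputValidationError, NormalizationError
from .events import VesicleTrack
from .io import Movie
from .params import TraceParams

__all__ = ["TraceParams", "Trace", "ReleaseMetrics", "build_trace",
           "normalize_cargo", "normalize_galectin", "release_fraction",
           "cargo_present", "fold_recruitment", "event_rate", "mean_ci",
           "rolling_background", "traces_to_frame"]


@dataclass
class Trace:
    """A t0-aligned, background-subtracted intensity time series."""

    rel_time_s: np.ndarray
    values: np.ndarray
    channel: int
    normalization: str = "none"      # none | cargo_pre_mean | max

    def __post_init__(self) -> None:
        self.rel_time_s = np.asarray(self.rel_time_s, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.rel_time_s.shape != self.values.shape:
            raise InputValidationError("rel_time_s and values must align")
        if len(self.rel_time_s) and (np.diff(self.rel_time_s) <= 0).any():
            raise InputValidationError("rel_time_s must be strictly increasing")

    def value_at(self, rel_time_s: float) -> float:
        """Single-frame value at the frame nearest the requested time."""
        idx = int(np.argmin(np.abs(self.rel_time_s - rel_time_s)))
        return float(self.values[idx])


@dataclass
class ReleaseMetrics:
    """Single-vesicle release read-out."""

    pre_intensity: float
    post_intensity: float
    released_fraction: float
    cargo_present: bool = True


def rolling_background(bg: np.ndarray, window: int) -> np.ndarray:
    """Centered rolling mean with shrinking windows at the edges."""
    return (pd.Series(np.asarray(bg, dtype=float))
            .rolling(window, center=True, min_periods=1).mean().to_numpy())


def seconds_to_frames(seconds: float, frame_interval_s: float) -> int:
    """Convert a time offset to whole frames (nearest, minimum 1)."""
    return max(1, int(round(seconds / frame_interval_s)))


def build_trace(track: VesicleTrack, channel: int, movie: Movie,
                params: TraceParams) -> Trace:
    """Background-subtracted, onset-aligned trace for one channel.

    The local background at the fitted (or frozen pre-onset) position is
    smoothed with a centered rolling average over ``bg_rolling_window``
    frames (shrinking at the series edges) and subtracted frame by frame.
    """
    frames, raw, bg = track.channel_series(channel)
    if len(frames) < 1:
        raise InputValidationError("track has no measured frames")
    smooth_bg = rolling_background(bg, params.bg_rolling_window)
    rel = (frames - track.t0_frame) * movie.frame_interval_s
    return Trace(rel_time_s=rel, values=raw - smooth_bg, channel=channel)


def normalize_cargo(trace: Trace, params: TraceParams,
                    frame_interval_s: float) -> Trace:
    """Divide by the mean over the pre-onset window (~3-60 s before t0)."""
    lo, hi = params.cargo_pre_window_s
    sel = (trace.rel_time_s >= -hi) & (trace.rel_time_s <= -lo)
    if not sel.any():
        raise CoverageError(
            f"cargo pre-window [-{hi}, -{lo}] s contains no trace frames")
    ref = float(trace.values[sel].mean())
    if ref <= 0:
        raise NormalizationError(
            f"cargo pre-window mean must be positive, got {ref:g}")
    return replace(trace, values=trace.values / ref,
                   normalization="cargo_pre_mean")


def normalize_galectin(trace: Trace) -> Trace:
    """Divide by the trace maximum (peak maps to 1)."""
    peak = float(trace.values.max())
    if peak <= 0:
        raise NormalizationError(f"trace maximum must be positive, got {peak:g}")
    return replace(trace, values=trace.values / peak, normalization="max")


def release_fraction(trace: Trace, params: TraceParams,
                     frame_interval_s: float) -> ReleaseMetrics:
    """1 - post/pre from single frames nearest -pre_offset and +post_offset."""
    pre_t, post_t = -params.release_pre_offset_s, params.release_post_offset_s
    margin = frame_interval_s / 2.0
    if trace.rel_time_s[0] > pre_t + margin or trace.rel_time_s[-1] < post_t - margin:
        raise CoverageError(
            f"trace [{trace.rel_time_s[0]:g}, {trace.rel_time_s[-1]:g}] s does "
            f"not cover the release offsets ({pre_t:g}, {post_t:g}) s")
    pre = trace.value_at(pre_t)
    post = trace.value_at(post_t)
    if pre <= 0:
        raise NormalizationError(f"pre-release intensity must be positive, got {pre:g}")
    # a noisy post measurement can dip below zero; a vesicle cannot release
    # more than its content
    released = min(1.0, 1.0 - post / pre)
    return ReleaseMetrics(pre_intensity=pre, post_intensity=post,
                          released_fraction=released)


def cargo_present(track: VesicleTrack, channel: int,
                  params: TraceParams, frame_interval_s: float = 3.0) -> bool:
    """Did the vesicle contain cargo immediately before the damage event?

    True iff the mean background-subtracted cargo intensity over the frames
    within ``release_pre_offset_s`` before onset strictly exceeds
    ``cargo_presence_k`` times the s.d. of the local background over the
    same frames. The numeric rule is a configurable stand-in for the
    assay's visual call.
    """
    n_pre = seconds_to_frames(params.release_pre_offset_s, frame_interval_s)
    sel = (track.static_frames >= track.t0_frame - n_pre)
    if not sel.any():
        raise CoverageError("no pre-onset frames available for the presence call")
    raw = track.static_intensities[sel, channel]
    bg = track.static_local_bg[sel, channel]
    return bool((raw - bg).mean() > params.cargo_presence_k * bg.std())


def fold_recruitment(track: VesicleTrack, cell_background_track: np.ndarray,
                     params: TraceParams, frame_interval_s: float,
                     channel: int | None = None,
                     image_background: float = 0.0) -> float:
    """Galectin fold recruitment of one event.

    Mean focus intensity over the post window (~90-105 s after onset)
    divided by the mean cell-background measurement over the pre window
    (~10-25 s before onset), both after subtracting the image background.
    ``cell_background_track`` is indexed by movie frame.
    """
    if channel is None:
        channel = track.fit_channel
    cell_bg = np.asarray(cell_background_track, dtype=float)
    frames, raw, _ = track.channel_series(channel)
    rel = (frames - track.t0_frame) * frame_interval_s
    lo, hi = params.fold_post_window_s
    post_sel = (rel >= lo) & (rel <= hi)
    if not post_sel.any():
        raise CoverageError(f"track does not cover the focus window [{lo}, {hi}] s")
    plo, phi = params.fold_pre_window_s
    bg_frames = np.arange(len(cell_bg))
    bg_rel = (bg_frames - track.t0_frame) * frame_interval_s
    pre_sel = (bg_rel >= -phi) & (bg_rel <= -plo)
    if not pre_sel.any():
        raise CoverageError(
            f"cell background does not cover the pre window [-{phi}, -{plo}] s")
    denom = float(cell_bg[pre_sel].mean() - image_background)
    if denom <= 0:
        raise NormalizationError(
            f"pre-window cell background (image-background subtracted) must be "
            f"positive, got {denom:g}")
    return float((raw[post_sel].mean() - image_background) / denom)


def event_rate(n_new_foci: int, n_cells: int, observation_min: float) -> float:
    """De novo galectin foci per cell per hour."""
    if n_cells <= 0 or observation_min <= 0:
        raise InputValidationError("n_cells and observation_min must be positive")
    return n_new_foci / n_cells / (observation_min / 60.0)


def mean_ci(values) -> tuple[float, float]:
    """Mean and 95% CI half-width, computed as 1.96 x s.e.m.

    The s.e.m. uses the population s.d. (ddof=0), i.e. the half-width is
    1.96 * s.d. / sqrt(n).
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise InputValidationError("mean_ci needs at least two values")
    return float(values.mean()), float(1.96 * values.std() / np.sqrt(values.size))


def traces_to_frame(traces: dict, channel_names=None) -> pd.DataFrame:
    """Long-format table of traces: event_id, channel, rel_time_s, value,
    normalization. ``traces`` maps event id -> list of :class:`Trace`."""
    rows = []
    for event_id, trs in traces.items():
        for tr in trs:
            name = (channel_names[tr.channel] if channel_names is not None
                    else tr.channel)
            for t, v in zip(tr.rel_time_s, tr.values):
                rows.append({"event_id": event_id, "channel": name,
                             "rel_time_s": float(t), "value": float(v),
                             "normalization": tr.normalization})
    return pd.DataFrame(rows)
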