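"""Seeded onset detection and 4D tracking of damaged vesicles.

From an approximate seed coordinate, :func:`detect_t0` scans the galectin
channel for the first frame at which a focus measurement exceeds an
adaptive threshold (mean + k s.d. of all prior scan measurements), confirms
the candidate by forward tracking, and returns a :class:`VesicleTrack`.
:func:`track_event` then extends the track by fitting the measurement mask
to the maximum mask-mean position inside a confined x/y/z tracking volume,
frame by frame, measuring every channel in the fitted single z-plane.

All object measurements use a circular mask of pixel centers within
``mask_diameter_px / 2`` of an integer-valued center; the local background
is the median over a one-pixel-wide ring placed ``bg_ring_offset_px``
outside the mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import NamedTuple

import numpy as np
from scipy import ndimage

from .exceptions import InputValidationError
from .io import Movie, SeedCall
from .params import DetectionParams

__all__ = ["DetectionParams", "VesicleTrack", "MaskMean", "measure_mask",
           "local_background", "detect_t0", "track_event", "track_from_seed",
           "disk_offsets", "ring_offsets"]


@lru_cache(maxsize=32)
def disk_offsets(diameter: int) -> tuple:
    """(dy, dx) integer offsets whose centers lie within radius diameter/2."""
    r = diameter / 2.0
    n = int(np.ceil(r))
    offs = [(dy, dx) for dy in range(-n, n + 1) for dx in range(-n, n + 1)
            if dy * dy + dx * dx <= r * r]
    return tuple(offs)


@lru_cache(maxsize=32)
def ring_offsets(diameter: int, ring_offset: int, halfwidth: int) -> tuple:
    """Offsets of the background ring at distance mask-radius + ring_offset,
    with radial half thickness ``halfwidth``."""
    r0 = diameter / 2.0 + ring_offset
    lo, hi = r0 - halfwidth, r0 + halfwidth
    n = int(np.ceil(hi))
    offs = [(dy, dx) for dy in range(-n, n + 1) for dx in range(-n, n + 1)
            if lo <= np.hypot(dy, dx) <= hi]
    return tuple(offs)


class MaskMean(NamedTuple):
    mean: float
    n_pixels: int
    clipped: bool


def measure_mask(plane: np.ndarray, x: int, y: int, diameter: int) -> MaskMean:
    """Mean intensity of the circular mask centered on pixel (x, y).

    A mask that extends past the plane border is clipped to the in-bounds
    pixels and flagged (``clipped=True``); it is never silently wrong.
    """
    plane = np.asarray(plane)
    ny, nx = plane.shape
    offs = disk_offsets(diameter)
    ys = np.fromiter((y + dy for dy, _ in offs), dtype=int)
    xs = np.fromiter((x + dx for _, dx in offs), dtype=int)
    inside = (ys >= 0) & (ys < ny) & (xs >= 0) & (xs < nx)
    if not inside.any():
        raise InputValidationError(
            f"measurement mask at (x={x}, y={y}) lies fully outside the plane")
    vals = plane[ys[inside], xs[inside]]
    return MaskMean(float(vals.mean()), int(inside.sum()), bool(~inside.all()))


def local_background(plane: np.ndarray, x: int, y: int,
                     params: DetectionParams) -> MaskMean:
    """Median intensity over the background ring around (x, y).

    Returns the median, the number of ring pixels used, and a flag set when
    part of the ring fell outside the plane. A fully clipped ring raises.
    """
    plane = np.asarray(plane)
    ny, nx = plane.shape
    offs = ring_offsets(params.mask_diameter_px, params.bg_ring_offset_px,
                        params.bg_ring_halfwidth_px)
    ys = np.fromiter((y + dy for dy, _ in offs), dtype=int)
    xs = np.fromiter((x + dx for _, dx in offs), dtype=int)
    inside = (ys >= 0) & (ys < ny) & (xs >= 0) & (xs < nx)
    if not inside.any():
        raise InputValidationError(
            f"background ring at (x={x}, y={y}) lies fully outside the plane")
    vals = plane[ys[inside], xs[inside]]
    return MaskMean(float(np.median(vals)), int(inside.sum()), bool(~inside.all()))


@dataclass
class VesicleTrack:
    """A confirmed damage event: onset frame, fitted path, and measurements.

    ``intensities`` / ``local_bg`` have shape (n_frames, n_channels) and are
    single-plane mask means / ring medians at the fitted positions;
    ``static_*`` hold the pre-onset measurements taken at the frozen onset
    coordinates.
    """

    t0_frame: int
    t0_position: tuple              # (z, y, x)
    frames: np.ndarray              # tracked frame indices, starting at t0
    positions: np.ndarray           # (n, 3) fitted (z, y, x)
    intensities: np.ndarray         # (n, n_channels)
    local_bg: np.ndarray            # (n, n_channels)
    static_frames: np.ndarray
    static_intensities: np.ndarray
    static_local_bg: np.ndarray
    threshold_used: float
    fit_channel: int = 0
    flags: set = field(default_factory=set)

    @property
    def last_frame(self) -> int:
        return int(self.frames[-1])

    def all_frames(self) -> np.ndarray:
        return np.concatenate([self.static_frames, self.frames])

    def channel_series(self, channel: int):
        """(frames, raw intensity, local background) over static + tracked."""
        frames = self.all_frames()
        raw = np.concatenate([self.static_intensities[:, channel],
                              self.intensities[:, channel]])
        bg = np.concatenate([self.static_local_bg[:, channel],
                             self.local_bg[:, channel]])
        return frames, raw, bg


@lru_cache(maxsize=32)
def _disk_kernel(diameter: int) -> np.ndarray:
    r = int(np.ceil(diameter / 2.0))
    kern = np.zeros((2 * r + 1, 2 * r + 1))
    for dy, dx in disk_offsets(diameter):
        kern[dy + r, dx + r] = 1.0
    return kern


_COUNTS_CACHE: dict = {}


def _mask_mean_plane(plane: np.ndarray, diameter: int) -> np.ndarray:
    """Clipped mask-mean at every center of ``plane`` via correlation.

    Equals :func:`measure_mask` at every pixel (border masks are clipped to
    in-bounds pixels, exactly as the enumeration does).
    """
    kern = _disk_kernel(diameter)
    key = (plane.shape, diameter)
    counts = _COUNTS_CACHE.get(key)
    if counts is None:
        counts = ndimage.correlate(np.ones(plane.shape), kern, mode="constant")
        counts = np.rint(counts)
        _COUNTS_CACHE[key] = counts
    sums = ndimage.correlate(np.asarray(plane, dtype=float), kern, mode="constant")
    return sums / counts


def _fit_window(volume: np.ndarray, z_lo: int, z_hi: int, y_lo: int, y_hi: int,
                x_lo: int, x_hi: int, diameter: int, ref_pos: tuple):
    """Best mask-mean position in an inclusive (z, y, x) window.

    Ties are broken by smallest Euclidean displacement from ``ref_pos``,
    then lowest (z, y, x). Returns ((z, y, x), mean).
    """
    nz, ny, nx = volume.shape
    z_lo, z_hi = max(0, z_lo), min(nz - 1, z_hi)
    y_lo, y_hi = max(0, y_lo), min(ny - 1, y_hi)
    x_lo, x_hi = max(0, x_lo), min(nx - 1, x_hi)
    best = None
    rz, ry, rx = ref_pos
    for z in range(z_lo, z_hi + 1):
        means = _mask_mean_plane(volume[z], diameter)[y_lo:y_hi + 1, x_lo:x_hi + 1]
        m = means.max()
        ties = np.argwhere(means == m)
        ys = ties[:, 0] + y_lo
        xs = ties[:, 1] + x_lo
        d2 = (z - rz) ** 2 + (ys - ry) ** 2 + (xs - rx) ** 2
        order = np.lexsort((xs, ys, np.full_like(xs, z), d2))
        cand = (float(m), int(d2[order[0]]), (z, int(ys[order[0]]), int(xs[order[0]])))
        if best is None or cand[0] > best[0] or (
                cand[0] == best[0] and (cand[1], cand[2]) < (best[1], best[2])):
            best = cand
    return best[2], best[0]


def _measure_all_channels(movie: Movie, frame: int, pos: tuple,
                          params: DetectionParams):
    z, y, x = pos
    nc = movie.n_channels
    inten = np.empty(nc)
    bg = np.empty(nc)
    clipped = False
    for c in range(nc):
        plane = movie.data[frame, c, z]
        mm = measure_mask(plane, x, y, params.mask_diameter_px)
        lb = local_background(plane, x, y, params)
        inten[c] = mm.mean
        bg[c] = lb.mean
        clipped = clipped or mm.clipped or lb.clipped
    return inten, bg, clipped


def _scan_measurement(movie: Movie, frame: int, seed: SeedCall,
                      params: DetectionParams, channel: int):
    """Best mask-mean over the full z volume within the seed's x/y window."""
    volume = movie.data[frame, channel]
    o = params.xy_seed_offset_px
    return _fit_window(volume, 0, movie.n_z - 1,
                       seed.y_px - o, seed.y_px + o,
                       seed.x_px - o, seed.x_px + o,
                       params.mask_diameter_px,
                       ref_pos=(movie.n_z // 2, seed.y_px, seed.x_px))


def _track_step(movie: Movie, frame: int, prev_pos: tuple,
                params: DetectionParams, channel: int):
    z, y, x = prev_pos
    nz, ny, nx = movie.data.shape[2:]
    oz, oxy = params.track_z_offset_planes, params.track_xy_offset_px
    clipped = (z - oz < 0 or z + oz > nz - 1 or y - oxy < 0 or y + oxy > ny - 1
               or x - oxy < 0 or x + oxy > nx - 1)
    pos, mean = _fit_window(movie.data[frame, channel],
                            z - oz, z + oz, y - oxy, y + oxy, x - oxy, x + oxy,
                            params.mask_diameter_px, ref_pos=prev_pos)
    return pos, mean, clipped


def _confirm(movie: Movie, t0: int, pos: tuple, theta: float,
             params: DetectionParams, channel: int) -> bool:
    """Forward-track for confirm_frames frames; every measurement must
    strictly exceed the threshold frozen at candidate time."""
    prev = pos
    for j in range(1, params.confirm_frames + 1):
        frame = t0 + j
        if frame >= movie.n_frames:
            return False
        prev, mean, _ = _track_step(movie, frame, prev, params, channel)
        if not mean > theta:
            return False
    return True


def _build_track(movie: Movie, t0: int, pos: tuple, theta: float,
                 params: DetectionParams, channel: int,
                 flags: set) -> VesicleTrack:
    inten, bg, clip = _measure_all_channels(movie, t0, pos, params)
    static_start = t0 - params.static_pre_frames
    if static_start < 0:
        flags.add("static_window_truncated")
        static_start = 0
    static_frames = np.arange(static_start, t0)
    static_int = np.empty((len(static_frames), movie.n_channels))
    static_bg = np.empty_like(static_int)
    for i, f in enumerate(static_frames):
        static_int[i], static_bg[i], c = _measure_all_channels(movie, f, pos, params)
        clip = clip or c
    if clip:
        flags.add("mask_clipped")
    return VesicleTrack(
        t0_frame=t0, t0_position=pos, frames=np.array([t0]),
        positions=np.array([pos]), intensities=inten[None],
        local_bg=bg[None], static_frames=static_frames,
        static_intensities=static_int, static_local_bg=static_bg,
        threshold_used=theta, fit_channel=channel, flags=flags)


def detect_t0(movie: Movie, seed: SeedCall, params: DetectionParams,
              channel: int = 0) -> VesicleTrack | None:
    """Find the onset frame of galectin recruitment from a seed call.

    Scanning starts ``initial_lookback_frames`` before the seed frame (or at
    frame 0, flagged). Each scanned frame contributes the best mask-mean in
    the seed window over the complete z volume; once at least
    ``min_pre_measurements`` scan values exist, a measurement strictly above
    mean + threshold_k * s.d. of all prior scan values marks a candidate
    onset, which must then stay above the frozen threshold for
    ``confirm_frames`` consecutive tracked frames. The scan history is kept
    across rejected candidates. Returns ``None`` when the movie ends without
    a confirmed event.
    """
    nt, _, nz, ny, nx = movie.shape
    if not (0 <= seed.x_px < nx and 0 <= seed.y_px < ny and 0 <= seed.t_frame < nt):
        raise InputValidationError(f"seed out of movie bounds: {seed}")
    flags: set = set()
    start = seed.t_frame - params.initial_lookback_frames
    if start < 0:
        start = 0
        flags.add("lookback_truncated")
    history: list[float] = []
    for frame in range(start, nt):
        pos, mean = _scan_measurement(movie, frame, seed, params, channel)
        if len(history) >= params.min_pre_measurements:
            h = np.asarray(history)
            theta = float(h.mean() + params.threshold_k * h.std())
            if mean > theta and _confirm(movie, frame, pos, theta, params, channel):
                track = _build_track(movie, frame, pos, theta, params,
                                     channel, flags)
                return track_event(movie, track, params,
                                   until_frame=frame + params.confirm_frames)
        history.append(mean)
    return None


def track_event(movie: Movie, track: VesicleTrack, params: DetectionParams,
                until_frame: int) -> VesicleTrack:
    """Extend a confirmed track frame by frame up to ``until_frame``.

    For each new frame the mask is fitted to the maximum mask-mean position
    within +/- ``track_xy_offset_px`` (x, y) and +/- ``track_z_offset_planes``
    (z) of the previous position; all channels are measured in the fitted
    single z-plane. Frames whose tracking volume was clipped at the movie
    border are flagged.
    """
    until_frame = min(until_frame, movie.n_frames - 1)
    new_frames, new_pos, new_int, new_bg = [], [], [], []
    prev = tuple(track.positions[-1])
    for frame in range(track.last_frame + 1, until_frame + 1):
        pos, _, clipped = _track_step(movie, frame, prev, params,
                                      track.fit_channel)
        if clipped:
            track.flags.add(f"track_volume_clipped@{frame}")
        inten, bg, mclip = _measure_all_channels(movie, frame, pos, params)
        if mclip:
            track.flags.add("mask_clipped")
        new_frames.append(frame)
        new_pos.append(pos)
        new_int.append(inten)
        new_bg.append(bg)
        prev = pos
    if new_frames:
        track.frames = np.concatenate([track.frames, np.array(new_frames)])
        track.positions = np.concatenate([track.positions, np.array(new_pos)])
        track.intensities = np.concatenate([track.intensities, np.array(new_int)])
        track.local_bg = np.concatenate([track.local_bg, np.array(new_bg)])
    return track


def track_from_seed(movie: Movie, t0: int, position: tuple,
                    params: DetectionParams, until_frame: int,
                    channel: int = 0) -> VesicleTrack:
    """Build a track from a known onset frame and (z, y, x) position.

    Bypasses detection (threshold set to NaN); used to measure along a
    known event, e.g. a planted ground-truth event or a manual call.
    """
    track = _build_track(movie, t0, tuple(int(v) for v in position),
                         float("nan"), params, channel, set())
    return track_event(movie, track, params, until_frame)
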