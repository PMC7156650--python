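"""Tunable parameter sets for detection, trace statistics, and marker calls.

Defaults reproduce the analysis settings of the widefield galectin-9 assay:
a +/-6 px seed search window, a 25-frame lookback, an onset threshold of
mean + 5 s.d. of the prior measurements, 5-frame confirmation, a 12 px / 5
z-plane tracking volume, a 6 px diameter measurement mask, an 11-frame
rolling local background, release read-outs ~15 s before / ~45 s after
onset, and marker assessment over five measurements ~3-16 s after onset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

from .exceptions import ParameterError


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ParameterError(msg)


@dataclass(frozen=True)
class DetectionParams:
    """Settings for seeded onset detection and 4D single-vesicle tracking.

    All distances are in pixels / z-planes on the image grid, all counts in
    frames.
    """

    #: half-width of the square x/y search window around the seed
    xy_seed_offset_px: int = 6
    #: the scan starts this many frames before the seed frame
    initial_lookback_frames: int = 25
    #: onset threshold is mean + threshold_k * s.d. of prior scan measurements
    threshold_k: float = 5.0
    #: consecutive supra-threshold frames required to confirm a candidate
    confirm_frames: int = 5
    #: half-width of the square x/y tracking window around the last position
    track_xy_offset_px: int = 12
    #: half-depth of the z tracking window around the last position
    track_z_offset_planes: int = 5
    #: diameter of the circular measurement mask
    mask_diameter_px: int = 6
    #: number of frames measured statically at the frozen onset coordinates
    static_pre_frames: int = 20
    #: minimum scan measurements before a threshold may be formed
    min_pre_measurements: int = 5
    #: half thickness of the local-background ring (ring radius is
    #: mask radius + bg_ring_offset_px, +/- bg_ring_halfwidth_px)
    bg_ring_offset_px: int = 8
    bg_ring_halfwidth_px: int = 1

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            _require(v > 0, f"DetectionParams.{f.name} must be positive, got {v!r}")
        _require(int(self.mask_diameter_px) == self.mask_diameter_px,
                 "mask_diameter_px must be an integer")


@dataclass(frozen=True)
class TraceParams:
    """Settings for trace normalization and event-level release statistics."""

    #: centered rolling-average window (frames) for the local background
    bg_rolling_window: int = 11
    #: cargo normalization window, seconds before onset (start, end)
    cargo_pre_window_s: tuple[float, float] = (3.0, 60.0)
    #: single-frame release read-out, seconds before onset
    release_pre_offset_s: float = 15.0
    #: single-frame release read-out, seconds after onset
    release_post_offset_s: float = 45.0
    #: focus window for fold recruitment, seconds after onset (start, end)
    fold_post_window_s: tuple[float, float] = (90.0, 105.0)
    #: cell-background window for fold recruitment, seconds before onset
    fold_pre_window_s: tuple[float, float] = (10.0, 25.0)
    #: s.d. multiplier for the cargo-presence call
    cargo_presence_k: float = 3.0

    def __post_init__(self) -> None:
        _require(self.bg_rolling_window >= 1, "bg_rolling_window must be >= 1")
        for name in ("cargo_pre_window_s", "fold_post_window_s", "fold_pre_window_s"):
            lo, hi = getattr(self, name)
            _require(0 < lo < hi, f"TraceParams.{name} must satisfy 0 < start < end")
        _require(self.release_pre_offset_s > 0, "release_pre_offset_s must be positive")
        _require(self.release_post_offset_s > 0, "release_post_offset_s must be positive")
        _require(self.cargo_presence_k > 0, "cargo_presence_k must be positive")


@dataclass(frozen=True)
class MarkerParams:
    """Settings for compartment-marker normalization and classification."""

    #: s.d. multiplier on log10 cell intensities for marker-object segmentation
    object_log_k: float = 1.0
    #: cells with marker-object SNR < snr_min are excluded (strict inequality)
    snr_min: float = 50.0
    #: assessment window, seconds after onset
    assess_start_s: float = 3.0
    assess_end_s: float = 16.0
    #: number of assessment measurements kept regardless of frame interval
    assess_n_measurements: int = 5
    #: normalized window mean must strictly exceed this to call positive
    positive_threshold: float = 0.5
    #: positives with trace s.d./mean above this are reclassified negative
    unreliable_cv: float = 1.0
    #: evaluation horizon of the retained trace, seconds after onset
    eval_horizon_s: float = 64.0

    def __post_init__(self) -> None:
        for name in ("object_log_k", "snr_min", "assess_start_s", "assess_end_s",
                     "positive_threshold", "unreliable_cv", "eval_horizon_s"):
            _require(getattr(self, name) > 0, f"MarkerParams.{name} must be positive")
        _require(self.assess_n_measurements >= 1, "assess_n_measurements must be >= 1")
        _require(self.assess_start_s < self.assess_end_s <= self.eval_horizon_s,
                 "assessment window must lie inside the evaluation horizon")


# roles the configuration may map onto channel indices
CHANNEL_ROLES = ("galectin", "cargo", "marker")


@dataclass
class AnalysisConfig:
    """Flat bundle of every tunable plus the channel-role mapping."""

    detection: DetectionParams = field(default_factory=DetectionParams)
    traces: TraceParams = field(default_factory=TraceParams)
    markers: MarkerParams = field(default_factory=MarkerParams)
    #: maps channel role ("galectin", "cargo", "marker") -> channel index
    channels: dict = field(default_factory=lambda: {"galectin": 0, "cargo": 1})
    rng_seed: int = 0
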