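"""Shared fixtures: parameter presets and synthetic movie helpers."""

from __future__ import annotations

import numpy as np
import pytest

from endoescape import io as eio
from endoescape import simgen
from endoescape.params import DetectionParams, MarkerParams, TraceParams


@pytest.fixture
def det_params():
    return DetectionParams()

@pytest.fixture
def trace_params():
    return TraceParams()

@pytest.fixture
def marker_params():
    return MarkerParams()


def small_sim(seed=0, noise=True, **overrides):
    """Compact two-channel movie parameters used throughout the tests.

    The geometry (48 px field, 6 z-planes, 55 frames at 3 s) is a
    scaled-down acquisition that still covers the full analysis windows
    (-60 s cargo pre-window to +45 s release read-out around any onset).
    """
    kwargs = dict(
        n_frames=55, n_z=6, image_size_px=(48, 48),
        channels=("galectin", "cargo"), n_events=1, n_decoy_markers=0,
        event_amplitude=10000.0, cargo_level=10000.0,
        motion_sigma_px=0.5, t0_min_frame=21, t0_margin_end=16,
        rng_seed=seed)
    if not noise:
        kwargs.update(noise_poisson=False, noise_gaussian_sd=0.0)
    kwargs.update(overrides)
    return simgen.SimParams(**kwargs)


def amplitude_for_snr(params, snr):
    """Source amplitude whose expected mask-mean increase is ``snr`` times
    the per-pixel noise s.d."""
    return snr * simgen.pixel_noise_sd(params) / simgen.mask_gain_factor(params)


def seed_for_event(event, n_frames, jitter=(2, 1, -2)):
    """An approximate seed call near a planted event (as a user would click
    on the appearing focus a frame or two after onset)."""
    dx, dy, dt = jitter
    z, y, x = event.path[event.true_t0_frame]
    return eio.SeedCall(x_px=int(x) + dx, y_px=int(y) + dy,
                        t_frame=min(n_frames - 1, event.true_t0_frame + 2 + dt))


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
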