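"""Trace building, normalization, and event-level release statistics."""

import numpy as np
import pytest

from endoescape import events, simgen, traces
from endoescape.events import VesicleTrack
from endoescape.exceptions import (CoverageError, InputValidationError,
                                   NormalizationError)
from endoescape.io import Movie
from endoescape.params import TraceParams

from _oracles import oracle_rolling_mean
from conftest import small_sim


def make_track(raw, bg, t0=20, n_static=10, cargo=None, cargo_bg=None):
    """Assemble a two-channel VesicleTrack from explicit measurement series.

    ``raw``/``bg`` fill channel 0 over static + tracked frames; channel 1
    may be given separately (defaults to channel 0).
    """
    raw = np.asarray(raw, dtype=float)
    bg = np.asarray(bg, dtype=float)
    cargo = raw if cargo is None else np.asarray(cargo, dtype=float)
    cargo_bg = bg if cargo_bg is None else np.asarray(cargo_bg, dtype=float)
    n = len(raw)
    frames = np.arange(t0 - n_static, t0 - n_static + n)
    static = frames < t0
    inten = np.column_stack([raw, cargo])
    lbg = np.column_stack([bg, cargo_bg])
    pos = np.tile([2, 16, 16], (int((~static).sum()), 1))
    return VesicleTrack(
        t0_frame=t0, t0_position=(2, 16, 16), frames=frames[~static],
        positions=pos, intensities=inten[~static], local_bg=lbg[~static],
        static_frames=frames[static], static_intensities=inten[static],
        static_local_bg=lbg[static], threshold_used=0.0)


def dummy_movie(n_frames=60, interval=3.0):
    return Movie(np.zeros((n_frames, 2, 1, 4, 4)), frame_interval_s=interval)


class TestBuildTrace:
    def test_constant_background_subtracted(self, trace_params):
        track = make_track(raw=np.full(30, 110.0), bg=np.full(30, 10.0))
        tr = traces.build_trace(track, 0, dummy_movie(), trace_params)
        np.testing.assert_allclose(tr.values, 100.0)

    def test_alignment_maps_t0_to_zero(self, trace_params):
        track = make_track(raw=np.arange(30.0), bg=np.zeros(30), t0=20)
        tr = traces.build_trace(track, 0, dummy_movie(), trace_params)
        assert 0.0 in tr.rel_time_s
        i0 = np.flatnonzero(tr.rel_time_s == 0.0)[0]
        assert tr.values[i0] == 10.0  # the measurement taken at frame 20

    def test_linear_drift_removed_exactly_in_interior(self, trace_params):
        """A centered window averages a linear background drift exactly, so
        a flat signal on a drifting background comes out flat."""
        t = np.arange(40.0)
        track = make_track(raw=5.0 + t, bg=t)
        tr = traces.build_trace(track, 0, dummy_movie(), trace_params)
        inner = slice(trace_params.bg_rolling_window // 2,
                      -(trace_params.bg_rolling_window // 2))
        np.testing.assert_allclose(tr.values[inner], 5.0, atol=1e-9)

    def test_matches_windowed_mean_oracle(self, trace_params, rng):
        bg = rng.normal(50, 5, size=35)
        raw = rng.normal(200, 5, size=35)
        track = make_track(raw=raw, bg=bg)
        tr = traces.build_trace(track, 0, dummy_movie(), trace_params)
        expect = raw - oracle_rolling_mean(bg, trace_params.bg_rolling_window)
        np.testing.assert_allclose(tr.values, expect, atol=1e-12)


class TestNormalization:
    def _trace(self, values, interval=3.0, t0_index=20):
        n = len(values)
        rel = (np.arange(n) - t0_index) * interval
        return traces.Trace(rel_time_s=rel, values=np.asarray(values, float),
                            channel=1)

    def test_cargo_pre_window_mean_becomes_one(self, trace_params):
        vals = np.full(40, 100.0)
        vals[25:] = 50.0
        tr = traces.normalize_cargo(self._trace(vals), trace_params, 3.0)
        pre = (tr.rel_time_s >= -60) & (tr.rel_time_s <= -3)
        assert tr.values[pre].mean() == pytest.approx(1.0, abs=1e-9)
        assert tr.values[30] == 0.5
        assert tr.normalization == "cargo_pre_mean"

    def test_unit_pre_mean_is_identity(self, trace_params):
        vals = np.ones(40)
        tr = traces.normalize_cargo(self._trace(vals), trace_params, 3.0)
        np.testing.assert_array_equal(tr.values, vals)

    def test_zero_pre_mean_rejected(self, trace_params):
        with pytest.raises(NormalizationError):
            traces.normalize_cargo(self._trace(np.zeros(40)), trace_params, 3.0)

    def test_galectin_peak_maps_to_one(self):
        tr = traces.normalize_galectin(self._trace([0.0, 50.0, 250.0, 100.0],
                                                   t0_index=0))
        assert tr.values.max() == 1.0
        np.testing.assert_allclose(tr.values, [0.0, 0.2, 1.0, 0.4])

    def test_normalized_galectin_unchanged(self):
        tr = self._trace([0.0, 0.2, 1.0, 0.4], t0_index=0)
        np.testing.assert_array_equal(traces.normalize_galectin(tr).values,
                                      tr.values)

    def test_all_zero_galectin_rejected(self):
        with pytest.raises(NormalizationError):
            traces.normalize_galectin(self._trace(np.zeros(5), t0_index=0))


class TestReleaseFraction:
    def _trace(self, pre, post, interval=3.0):
        rel = np.arange(-30, 31) * interval
        vals = np.where(rel < 0, pre, post).astype(float)
        return traces.Trace(rel_time_s=rel, values=vals, channel=1)

    @pytest.mark.parametrize("pre,post,expect", [
        (1.0, 0.25, 0.75), (0.8, 0.8, 0.0), (1.0, 0.0, 1.0)])
    def test_single_frame_arithmetic(self, trace_params, pre, post, expect):
        m = traces.release_fraction(self._trace(pre, post), trace_params, 3.0)
        assert m.released_fraction == pytest.approx(expect, abs=1e-12)
        assert m.pre_intensity == pre and m.post_intensity == post

    def test_uncovered_offsets_rejected(self, trace_params):
        rel = np.arange(0, 10) * 3.0
        tr = traces.Trace(rel_time_s=rel, values=np.ones(10), channel=1)
        with pytest.raises(CoverageError):
            traces.release_fraction(tr, trace_params, 3.0)

    def test_scale_invariance_under_cargo_normalization(self, trace_params):
        """Normalizing the cargo trace must not change the release fraction."""
        rng = np.random.default_rng(5)
        rel = np.arange(-25, 25) * 3.0
        vals = np.where(rel < 0, 100.0, 30.0) + rng.normal(0, 2, size=rel.size)
        tr = traces.Trace(rel_time_s=rel, values=vals, channel=1)
        m_raw = traces.release_fraction(tr, trace_params, 3.0)
        m_norm = traces.release_fraction(
            traces.normalize_cargo(tr, trace_params, 3.0), trace_params, 3.0)
        assert m_norm.released_fraction == pytest.approx(
            m_raw.released_fraction, abs=1e-12)

    def test_planted_fraction_recovered_noise_free(self, det_params,
                                                   trace_params):
        """End to end: detect, track, trace, and recover a planted release
        fraction exactly in a noise-free movie."""
        p = small_sim(seed=17, noise=False, motion_sigma_px=0.0,
                      release_fraction_true=0.9)
        movie, truth = simgen.simulate_movie(p)
        ev = truth.events[0]
        track = events.track_from_seed(movie, ev.true_t0_frame,
                                       ev.path[ev.true_t0_frame], det_params,
                                       until_frame=p.n_frames - 1)
        tr = traces.normalize_cargo(
            traces.build_trace(track, 1, movie, trace_params),
            trace_params, movie.frame_interval_s)
        m = traces.release_fraction(tr, trace_params, movie.frame_interval_s)
        assert m.released_fraction == pytest.approx(0.9, abs=1e-9)


class TestCargoPresence:
    def test_zero_channel_is_absent(self, trace_params):
        track = make_track(raw=np.full(30, 80.0), bg=np.full(30, 80.0),
                           cargo=np.zeros(30), cargo_bg=np.zeros(30))
        assert traces.cargo_present(track, 1, trace_params, 3.0) is False

    def test_strong_cargo_is_present(self, trace_params):
        rng = np.random.default_rng(0)
        bg = rng.normal(10, 1, size=30)
        track = make_track(raw=np.zeros(30), bg=np.zeros(30),
                           cargo=bg + 100.0, cargo_bg=bg)
        assert traces.cargo_present(track, 1, trace_params, 3.0) is True

    def test_no_pre_frames_rejected(self, trace_params):
        track = make_track(raw=np.ones(10), bg=np.zeros(10), n_static=0)
        with pytest.raises(CoverageError):
            traces.cargo_present(track, 1, trace_params, 3.0)


class TestFoldRecruitment:
    def test_hand_arithmetic(self, trace_params):
        raw = np.zeros(80)
        t0, n_static = 20, 10
        raw[:] = 140.0
        track = make_track(raw=raw, bg=np.zeros(80), t0=t0, n_static=n_static)
        cell_bg = np.full(100, 10.0)
        fold = traces.fold_recruitment(track, cell_bg, trace_params, 3.0,
                                       channel=0)
        assert fold == pytest.approx(14.0)

    def test_flat_trace_equals_cell_background(self, trace_params):
        track = make_track(raw=np.full(80, 10.0), bg=np.zeros(80))
        fold = traces.fold_recruitment(track, np.full(100, 10.0), trace_params,
                                       3.0, channel=0)
        assert fold == pytest.approx(1.0)

    def test_planted_amplitude_gives_closed_form_fold(self, det_params,
                                                      trace_params):
        """fold = (a + b) / b for a planted mask-mean gain a over a uniform
        cytosolic level b, noise-free."""
        p = small_sim(seed=23, noise=False, motion_sigma_px=0.0,
                      n_frames=70, t0_min_frame=22, t0_margin_end=40,
                      cell_galectin_level=40.0)
        movie, truth = simgen.simulate_movie(p)
        ev = truth.events[0]
        track = events.track_from_seed(movie, ev.true_t0_frame,
                                       ev.path[ev.true_t0_frame], det_params,
                                       until_frame=p.n_frames - 1)
        cell = simgen.cell_region_mask(p)
        cell_bg = movie.data[:, 0, p.n_z // 2][:, cell].mean(axis=1)
        fold = traces.fold_recruitment(track, cell_bg, trace_params,
                                       movie.frame_interval_s, channel=0,
                                       image_background=p.background_level)
        a = ev.amplitude * simgen.mask_gain_factor(p)
        b = p.cell_galectin_level
        assert fold == pytest.approx((a + b) / b, rel=0.02)


class TestEventRateAndCI:
    def test_event_rate_arithmetic(self):
        assert traces.event_rate(30, 10, 30.0) == pytest.approx(6.0)
        assert traces.event_rate(0, 10, 30.0) == 0.0
        with pytest.raises(InputValidationError):
            traces.event_rate(5, 0, 30.0)

    def test_poisson_rate_recovered_within_sampling_error(self):
        """Counting planted events over many simulated acquisitions recovers
        the planted mean rate within 3 s.e."""
        rng = np.random.default_rng(42)
        lam, n_cells, minutes, n_acq = 2.0, 10, 30.0, 20
        rates = []
        for _ in range(n_acq):
            n = rng.poisson(lam * n_cells * minutes / 60.0)
            rates.append(traces.event_rate(n, n_cells, minutes))
        est = np.mean(rates)
        se = np.sqrt(lam / (n_cells * minutes / 60.0) / n_acq)
        assert abs(est - lam) <= 3 * se

    def test_mean_ci_examples(self):
        mean, hw = traces.mean_ci([0.0, 2.0])
        assert mean == 1.0
        assert hw == pytest.approx(1.96 / np.sqrt(2), abs=1e-12)
        assert traces.mean_ci([5.0, 5.0, 5.0])[1] == 0.0
        # sample with s.e.m. exactly 1
        assert traces.mean_ci([0.0, 0.0, 4.0, 4.0])[1] == pytest.approx(1.96)
        with pytest.raises(InputValidationError):
            traces.mean_ci([1.0])
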