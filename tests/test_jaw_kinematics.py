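"""Clip conventions, cycle detection, and the drinking/eating metric set."""

import warnings

import numpy as np
import pytest

from oracles import oracle_drinking, oracle_eating
from swallowkit import (
    CycleEvents,
    MotionTrace,
    SwallowAnnotation,
    aggregate_mouse,
    compute_drinking_metrics,
    compute_eating_metrics,
    detect_jaw_cycles,
    splice_clip,
)
from swallowkit.jaw import DrinkingMetrics, EatingMetrics
from swallowkit.synthetic import JawTraceSpec, gen_jaw_trace


class TestSpliceClip:
    def test_window_arithmetic_at_30fps(self):
        trace = MotionTrace(np.zeros(300), fps=30.0)
        clip, (w0, w1) = splice_clip(trace, swallow_frame=100, clip_seconds=2.0)
        # five context frames each side of the 60-frame window:
        # clip covers original frames 95..164, analysis window 100..159
        assert len(clip) == 70
        assert (w0, w1) == (5, 65)

    def test_left_context_clamped(self):
        trace = MotionTrace(np.zeros(300), fps=30.0)
        clip, (w0, w1) = splice_clip(trace, swallow_frame=2)
        assert w0 == 2  # only two context frames available
        assert w1 - w0 == 60

    def test_eating_window_length(self):
        trace = MotionTrace(np.zeros(700), fps=30.0)
        clip, (w0, w1) = splice_clip(trace, swallow_frame=30, clip_seconds=20.0)
        assert w1 - w0 == 600

    def test_out_of_range_swallow_rejected(self):
        trace = MotionTrace(np.zeros(100), fps=30.0)
        with pytest.raises(ValueError):
            splice_clip(trace, swallow_frame=100)


class TestDetectJawCycles:
    def test_clean_raised_cosine_counts(self, clean_jaw_8hz):
        trace, truth = clean_jaw_8hz
        ev = detect_jaw_cycles(trace)
        assert len(ev.open_times) == 16
        assert len(ev.close_times) == 16
        assert ev.alternates()

    def test_matches_truth_within_one_frame_under_noise(self):
        amp = 0.79
        for seed in range(10):
            spec = JawTraceSpec(
                lick_rate_hz=8.71, amplitude_mm=amp, noise_sd_mm=0.05 * amp, seed=seed
            )
            trace, truth = gen_jaw_trace(spec)
            ev = detect_jaw_cycles(trace)
            t_open = truth.event_times["jaw_open"]
            assert len(ev.open_times) == len(t_open)
            assert np.abs(ev.open_times - t_open).max() <= 1.0 / trace.fps + 1e-9

    def test_constant_trace_yields_no_events(self):
        ev = detect_jaw_cycles(MotionTrace(np.full(60, 3.0), fps=30.0))
        assert len(ev.open_times) == 0 and len(ev.close_times) == 0

    def test_manual_edit_hooks(self):
        ev = CycleEvents(open_times=[0.5], close_times=[0.25, 0.75])
        ev2 = ev.add_open(1.0).remove_close(0.25)
        assert 1.0 in ev2.open_times
        assert 0.25 not in ev2.close_times
        with pytest.raises(ValueError):
            ev.remove_open(9.9)


def _uniform_fixture():
    """8 Hz train with swallows every 500 ms; everything analytically forced."""
    fps = 30.0
    spec = JawTraceSpec(
        lick_rate_hz=8.0, amplitude_mm=0.79, duration_s=2.0, fps=fps,
        noise_sd_mm=0.0, swallow_every_n_licks=4, ptt_frames=3,
    )
    trace, truth = gen_jaw_trace(spec)
    events = CycleEvents(
        open_times=truth.event_times["jaw_open"],
        close_times=truth.event_times["jaw_close"],
    )
    swallows = [SwallowAnnotation(**a) for a in truth.annotations]
    return trace, events, swallows


class TestDrinkingMetrics:
    def test_uniform_train_all_metrics_forced(self):
        trace, events, swallows = _uniform_fixture()
        m = compute_drinking_metrics(events, swallows, trace, (0, 60))
        assert m.lick_rate == pytest.approx(8.0)
        assert m.inter_lick_interval == pytest.approx(125.0)
        assert m.swallow_rate == pytest.approx(2.0)
        assert m.inter_swallow_interval == pytest.approx(500.0)
        assert m.lick_swallow_ratio == pytest.approx(4.0)
        assert m.pharyngeal_transit_time == pytest.approx(100.0)

    def test_triangle_wave_opening_velocity(self):
        # one cycle: opens 5 mm in 62.5 ms -> 80 mm/s
        fps = 16.0  # frame period 62.5 ms
        vals = np.array([0.0, 5.0, 0.0, 5.0, 0.0])
        trace = MotionTrace(vals, fps=fps)
        events = CycleEvents(
            open_times=np.array([1, 3]) / fps, close_times=np.array([0, 2, 4]) / fps
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = compute_drinking_metrics(events, [], trace, (0, 5))
        assert m.jaw_opening_velocity == pytest.approx(80.0)
        assert m.jaw_closing_velocity == pytest.approx(80.0)

    def test_no_swallows_missing_not_zero(self):
        trace, events, _ = _uniform_fixture()
        with pytest.warns(UserWarning):
            m = compute_drinking_metrics(events, [], trace, (0, 60))
        assert np.isnan(m.inter_swallow_interval)
        assert np.isnan(m.lick_swallow_ratio)
        assert np.isnan(m.pharyngeal_transit_time)
        assert m.lick_rate == pytest.approx(8.0)

    def test_context_frames_do_not_change_metrics(self):
        # shifting the same events/annotations into a padded clip is a no-op
        fps = 30.0
        spec = JawTraceSpec(lick_rate_hz=8.0, duration_s=3.0, fps=fps, noise_sd_mm=0.0)
        trace, truth = gen_jaw_trace(spec)
        events = detect_jaw_cycles(trace)
        swallows = [SwallowAnnotation(rest_frame=30, esophagus_entry_frame=33)]
        clip, window = splice_clip(trace, swallow_frame=30, clip_seconds=2.0)
        shift = 30 - window[0]
        clip_events = CycleEvents(
            open_times=[t - shift / fps for t in events.open_times if 0 <= t - shift / fps < clip.duration_s],
            close_times=[t - shift / fps for t in events.close_times if 0 <= t - shift / fps < clip.duration_s],
        )
        clip_swallows = [
            SwallowAnnotation(rest_frame=30 - shift, esophagus_entry_frame=33 - shift)
        ]
        m_clip = compute_drinking_metrics(clip_events, clip_swallows, clip, window)
        m_full = compute_drinking_metrics(
            events,
            [SwallowAnnotation(rest_frame=30, esophagus_entry_frame=33)],
            trace,
            (30, 90),
        )
        assert m_clip.lick_rate == pytest.approx(m_full.lick_rate)
        assert m_clip.inter_lick_interval == pytest.approx(m_full.inter_lick_interval)

    def test_rate_times_ili_consistency(self):
        # uniform trains satisfy lick_rate * ILI = 1000 up to frame effects
        for rate in (6.0, 8.0, 10.0):
            spec = JawTraceSpec(lick_rate_hz=rate, duration_s=2.0, noise_sd_mm=0.0)
            trace, truth = gen_jaw_trace(spec)
            ev = detect_jaw_cycles(trace)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m = compute_drinking_metrics(ev, [], trace, (0, 60))
            assert m.lick_rate * m.inter_lick_interval == pytest.approx(
                1000.0, rel=1.0 / 30
            )

    def test_ptt_quantized_to_frames(self):
        trace, events, swallows = _uniform_fixture()
        m = compute_drinking_metrics(events, swallows, trace, (0, 60))
        frame_ms = 1000.0 / 30.0
        n_frames = round(m.pharyngeal_transit_time / frame_ms)
        assert m.pharyngeal_transit_time == pytest.approx(n_frames * frame_ms, abs=1e-9)


class TestEatingMetrics:
    def test_counted_intervals_averaged(self):
        fps = 30.0
        closes = np.concatenate(
            [
                np.linspace(1.0, 1.9667, 8),  # 8 cycles in [30, 60)
                np.linspace(5.0, 5.9667, 8),
                np.linspace(10.0, 10.9667, 9),
            ]
        )
        events = CycleEvents(open_times=closes + 0.01, close_times=closes)
        trace = MotionTrace(np.zeros(600), fps=fps)
        swallows = [
            SwallowAnnotation(rest_frame=f, esophagus_entry_frame=f + 3)
            for f in (0, 150, 300, 450)
        ]
        m = compute_eating_metrics(
            events, swallows, [(30, 60), (150, 180), (300, 330)], trace, (0, 600)
        )
        assert m.mastication_rate == pytest.approx(25.0 / 3.0)
        assert m.swallow_rate == pytest.approx(4.0 / 20.0)
        assert m.inter_swallow_interval == pytest.approx(5.0)

    def test_interval_outside_window_rejected(self):
        trace = MotionTrace(np.zeros(600), fps=30.0)
        events = CycleEvents(open_times=[], close_times=[])
        with pytest.raises(ValueError):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                compute_eating_metrics(events, [], [(590, 620)], trace, (0, 600))

    def test_fewer_than_three_intervals_warns(self):
        trace = MotionTrace(np.zeros(600), fps=30.0)
        events = CycleEvents(open_times=[], close_times=[])
        with pytest.warns(UserWarning):
            compute_eating_metrics(events, [], [(0, 30)], trace, (0, 600))


class TestAggregateMouse:
    def _metrics(self, lick_rate, isi=500.0):
        return DrinkingMetrics(
            lick_rate=lick_rate,
            inter_lick_interval=120.0,
            swallow_rate=2.0,
            inter_swallow_interval=isi,
            lick_swallow_ratio=4.0,
            pharyngeal_transit_time=100.0,
            jaw_opening_velocity=13.0,
            jaw_closing_velocity=14.0,
        )

    def test_identical_clips_identity(self):
        clips = [self._metrics(8.0)] * 5
        rec = aggregate_mouse(clips)
        assert rec.drinking.lick_rate == pytest.approx(8.0)

    def test_mean_across_clips(self):
        clips = [self._metrics(v) for v in (8, 8, 8, 9, 9)]
        assert aggregate_mouse(clips).drinking.lick_rate == pytest.approx(8.4)

    def test_missing_value_excluded_from_mean(self):
        clips = [self._metrics(8.0, isi=float("nan"))] + [
            self._metrics(8.0, isi=500.0)
        ] * 4
        rec = aggregate_mouse(clips)
        assert rec.drinking.inter_swallow_interval == pytest.approx(500.0)

    def test_zero_clips_rejected(self):
        with pytest.raises(ValueError):
            aggregate_mouse([])

    def test_series_uses_reported_column_names(self):
        rec = aggregate_mouse([self._metrics(8.0)], EatingMetrics(8.3, 0.3, 4.0))
        s = rec.to_series("m1")
        assert s["Lick rate (#/s)"] == pytest.approx(8.0)
        assert s["Mastication rate (#/s)"] == pytest.approx(8.3)


class TestOracleEquivalence:
    def test_drinking_matches_bruteforce_on_random_configs(self, rng):
        """Vectorized metrics equal a from-scratch loop implementation."""
        fps = 30.0
        for _ in range(200):
            n_cycles = rng.integers(4, 20)
            closes = np.sort(rng.uniform(0, 2, size=n_cycles))
            keep = np.concatenate(([True], np.diff(closes) > 0.03))
            closes = closes[keep]
            opens = closes[:-1] + rng.uniform(0.25, 0.75, size=len(closes) - 1) * np.diff(closes)
            vals = rng.uniform(0, 5, size=61)
            trace = MotionTrace(vals, fps=fps)
            n_sw = rng.integers(0, 5)
            swallows = []
            for _ in range(n_sw):
                r = int(rng.integers(0, 50))
                swallows.append(SwallowAnnotation(r, r + int(rng.integers(1, 6))))
            events = CycleEvents(open_times=opens, close_times=closes)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m = compute_drinking_metrics(events, swallows, trace, (0, 60))
            expected = oracle_drinking(
                list(closes),
                list(opens),
                lambda t: vals[min(max(int(round(t * fps)), 0), 60)],
                fps,
                [(s.rest_frame, s.esophagus_entry_frame, s.swallow_frame) for s in swallows],
                0.0,
                2.0,
            )
            for name, want in expected.items():
                got = getattr(m, name)
                if np.isnan(want):
                    assert np.isnan(got), name
                else:
                    assert got == pytest.approx(want, abs=1e-10), name

    def test_eating_matches_bruteforce(self, rng):
        fps = 30.0
        trace = MotionTrace(np.zeros(601), fps=fps)
        for _ in range(100):
            closes = np.sort(rng.uniform(0, 20, size=rng.integers(20, 120)))
            events = CycleEvents(open_times=[], close_times=closes)
            swallows = [
                SwallowAnnotation(int(f), int(f) + 3)
                for f in np.sort(rng.choice(np.arange(0, 570, 7), size=4, replace=False))
            ]
            intervals = [(0, 30), (210, 240), (480, 510)]
            m = compute_eating_metrics(events, swallows, intervals, trace, (0, 600))
            expected = oracle_eating(
                list(closes),
                [(s.rest_frame, s.esophagus_entry_frame, s.swallow_frame) for s in swallows],
                intervals,
                fps,
                0.0,
                20.0,
            )
            assert m.mastication_rate == pytest.approx(expected["mastication_rate"], abs=1e-10)
            assert m.swallow_rate == pytest.approx(expected["swallow_rate"], abs=1e-10)
            if np.isnan(expected["inter_swallow_interval"]):
                assert np.isnan(m.inter_swallow_interval)
            else:
                assert m.inter_swallow_interval == pytest.approx(
                    expected["inter_swallow_interval"], abs=1e-10
                )
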