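"""Respiratory cycle segmentation and the laryngeal motion metric set."""

import numpy as np
import pytest

from oracles import oracle_laryngeal
from swallowkit import (
    LARResponse,
    MarkerTrack,
    MotionTrace,
    compute_laryngeal_metrics,
    detect_respiratory_cycles,
    glottal_lateral_traces,
    lar_duration,
)
from swallowkit.larynx import RespiratoryCycles, WidthCycle
from swallowkit.synthetic import (
    GlottalTraceSpec,
    gen_glottal_traces,
    glottal_marker_positions,
)


def _width(left, right):
    return MotionTrace(right.values - left.values, fps=right.fps, units="px")


class TestDetectRespiratoryCycles:
    def test_clean_150_per_min_counts(self, clean_glottal_150):
        left, right, truth = clean_glottal_150
        cyc = detect_respiratory_cycles(left, right, _width(left, right))
        assert len(cyc.width_cycles) == 25
        assert len(cyc.left) == 25
        assert len(cyc.right) == 25

    def test_peak_times_match_truth_within_one_frame(self, clean_glottal_150):
        left, right, truth = clean_glottal_150
        cyc = detect_respiratory_cycles(left, right, _width(left, right))
        peaks = np.array([w.peak_time for w in cyc.width_cycles])
        assert np.abs(peaks - truth.event_times["abduction_peak"]).max() <= 1 / 30 + 1e-9

    def test_static_larynx_zero_cycles(self):
        flat = MotionTrace(np.full(300, 5.0), fps=30.0, units="px")
        neg = MotionTrace(-flat.values, fps=30.0, units="px")
        cyc = detect_respiratory_cycles(neg, flat, _width(neg, flat))
        assert len(cyc.width_cycles) == 0
        assert len(cyc.left) == 0 and len(cyc.right) == 0


class TestLaryngealMetrics:
    def test_symmetric_antiphase_semantics(self, clean_glottal_150):
        left, right, _ = clean_glottal_150
        cyc = detect_respiratory_cycles(left, right, _width(left, right))
        m = compute_laryngeal_metrics(cyc, left, right)
        assert m.mmrr == pytest.approx(1.0, abs=1e-9)
        assert m.occr == pytest.approx(1.0, abs=1e-9)
        assert m.mcorr == pytest.approx(-1.0, abs=1e-9)
        assert m.respiratory_rate == pytest.approx(150.0)

    def test_paradoxical_motion_positive_correlation(self):
        left, right, _ = gen_glottal_traces(GlottalTraceSpec(paradoxical=True))
        cyc = RespiratoryCycles(left=[], right=[], width_cycles=[])
        m = compute_laryngeal_metrics(cyc, left, right)
        assert m.mcorr == pytest.approx(1.0, abs=1e-9)

    def test_half_amplitude_gives_mmrr_half(self):
        left, right, _ = gen_glottal_traces(
            GlottalTraceSpec(left_amplitude_px=10.0, right_amplitude_px=5.0)
        )
        cyc = detect_respiratory_cycles(left, right, _width(left, right))
        m = compute_laryngeal_metrics(cyc, left, right)
        assert m.mmrr == pytest.approx(0.5, abs=0.02)

    def test_vf_angle_from_sixty_degree_geometry(self):
        # both edges 30 deg off the midline axis at peak abduction
        n = 61
        fps = 30.0
        t = np.arange(n) / fps
        d = 0.5 * (1 - np.cos(2 * np.pi * 1.0 * t))  # 1 Hz, amplitude 1
        axial = 40.0
        half_span = axial * np.tan(np.radians(30.0))
        lx = -half_span * d
        rx = half_span * d
        lpos = np.column_stack([50.0 + lx, np.full(n, 20.0 + axial)])
        rpos = np.column_stack([50.0 + rx, np.full(n, 20.0 + axial)])
        cpos = np.tile([50.0, 20.0], (n, 1))
        tracks = (
            MarkerTrack("left", lpos, np.ones(n)),
            MarkerTrack("right", rpos, np.ones(n)),
            MarkerTrack("comm", cpos, np.ones(n)),
        )
        lat_l, lat_r, width = glottal_lateral_traces(*tracks, fps=fps)
        cyc = detect_respiratory_cycles(lat_l, lat_r, width)
        m = compute_laryngeal_metrics(cyc, lat_l, lat_r, tracks=tracks)
        assert m.vf_angle_max == pytest.approx(60.0, abs=1.0)
        assert m.vf_angle_min == pytest.approx(0.0, abs=1.0)

    def test_rigid_transform_invariance(self):
        left, right, _ = gen_glottal_traces(
            GlottalTraceSpec(left_amplitude_px=10.0, right_amplitude_px=7.0)
        )
        pos = glottal_marker_positions(left, right)
        n = len(left)

        def metrics_from(transform):
            tracks = tuple(
                MarkerTrack(k, transform(pos[k]), np.ones(n))
                for k in ("left_glottal", "right_glottal", "dorsal_commissure")
            )
            lat_l, lat_r, width = glottal_lateral_traces(*tracks, fps=30.0)
            cyc = detect_respiratory_cycles(lat_l, lat_r, width)
            return compute_laryngeal_metrics(cyc, lat_l, lat_r, tracks=tracks)

        base = metrics_from(lambda p: p)
        theta = 0.5
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        moved = metrics_from(lambda p: p @ rot.T + np.array([7.0, -12.0]))
        for field in ("mmrr", "occr", "mcorr", "vf_angle_max", "respiratory_rate"):
            assert getattr(moved, field) == pytest.approx(getattr(base, field), abs=1e-6)

    def test_oracle_equivalence_on_random_cycles(self, rng):
        for _ in range(300):
            n_cyc = int(rng.integers(1, 12))
            amps = rng.uniform(0.5, 10.0, size=(n_cyc, 2))
            cycles = RespiratoryCycles(
                left=[None] * int(rng.integers(1, 30)),
                right=[None] * int(rng.integers(0, 30)),
                width_cycles=[
                    WidthCycle(0.0, 0.0, 0.0, a, b) for a, b in amps
                ],
            )
            lv = rng.normal(size=60)
            rv = rng.normal(size=60)
            left = MotionTrace(lv, fps=30.0, units="px")
            right = MotionTrace(rv, fps=30.0, units="px")
            m = compute_laryngeal_metrics(
                cycles, left, right, clip_seconds=10.0, smooth_window=1
            )
            expected = oracle_laryngeal(
                [tuple(p) for p in amps],
                len(cycles.left),
                len(cycles.right),
                list(lv),
                list(rv),
                10.0,
            )
            assert m.mmrr == pytest.approx(expected["mmrr"], abs=1e-10)
            assert m.occr == pytest.approx(expected["occr"], abs=1e-10)
            assert m.mcorr == pytest.approx(expected["mcorr"], abs=1e-10)
            assert m.respiratory_rate == pytest.approx(expected["respiratory_rate"], abs=1e-10)


class TestMcorrNoiseRobustness:
    @pytest.mark.parametrize("paradoxical,target", [(False, -1.0), (True, 1.0)])
    def test_within_five_percent_noise(self, paradoxical, target):
        devs = []
        for seed in range(5):
            left, right, _ = gen_glottal_traces(
                GlottalTraceSpec(
                    paradoxical=paradoxical, noise_sd_px=0.5, seed=seed  # 5% of amplitude
                )
            )
            cyc = RespiratoryCycles(left=[], right=[], width_cycles=[])
            m = compute_laryngeal_metrics(cyc, left, right)
            devs.append(abs(m.mcorr - target))
        assert max(devs) <= 0.05


class TestLARDuration:
    def test_example_500ms(self):
        assert lar_duration(LARResponse(True, 100, 115), fps=30.0) == pytest.approx(500.0)

    def test_degenerate_zero(self):
        assert lar_duration(LARResponse(True, 40, 40), fps=30.0) == 0.0

    def test_quantized_to_frame_period(self):
        d = lar_duration(LARResponse(True, 12, 29), fps=30.0)
        assert d == pytest.approx(round(d / (1000.0 / 30.0)) * 1000.0 / 30.0)

    def test_absent_response_missing(self):
        assert np.isnan(lar_duration(LARResponse(False), fps=30.0))

    def test_reversed_frames_rejected(self):
        with pytest.raises(ValueError):
            lar_duration(LARResponse(True, 20, 10), fps=30.0)
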