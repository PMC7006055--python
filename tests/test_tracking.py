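"""Calibration, template tracking, and glottal geometry."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from swallowkit import (
    CalibrationScale,
    MarkerTrack,
    TrackingLostError,
    adjust_glottal_points,
    calibrate_scale,
    glottal_lateral_traces,
    jaw_gape_trace,
    track_markers,
)
from swallowkit.synthetic import (
    JawTraceSpec,
    SyntheticTruth,
    VideoGeometry,
    gen_jaw_trace,
    jaw_marker_truth,
    render_marker_video,
)


class TestCalibration:
    @pytest.mark.parametrize("px,mm,expected", [(100.0, 10.0, 0.1), (200.0, 10.0, 0.05)])
    def test_scale(self, px, mm, expected):
        assert calibrate_scale(px, mm).mm_per_pixel == pytest.approx(expected)

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            calibrate_scale(0.0)


def _static_truth(n_frames=10, positions=((50.0, 50.0), (50.0, 100.0))):
    markers = {
        f"m{i}": np.tile(np.asarray(p), (n_frames, 1)) for i, p in enumerate(positions)
    }
    return SyntheticTruth(marker_positions=markers)


class TestTrackMarkers:
    def test_static_marker_constant_position(self):
        truth = _static_truth()
        frames = render_marker_video(truth)
        tracks = track_markers(frames, [(50.0, 50.0), (50.0, 100.0)])
        for t, key in zip(tracks, ("m0", "m1")):
            np.testing.assert_allclose(t.positions, truth.marker_positions[key], atol=0.01)
            assert np.all(t.confidence >= 0.9)

    def test_static_markers_are_brightest_blobs(self):
        truth = _static_truth()
        frames = render_marker_video(truth)
        ys, xs = np.where(frames[3] == frames[3].max())
        found = set(zip(xs.tolist(), ys.tolist()))
        assert (50, 50) in found and (50, 100) in found

    def test_moving_marker_recovered_within_one_pixel(self, clean_jaw_8hz):
        trace, truth = clean_jaw_8hz
        truth = jaw_marker_truth(trace, truth, mm_per_pixel=0.1)
        frames = render_marker_video(truth)
        init = [truth.marker_positions[k][0] for k in ("upper_jaw", "lower_jaw")]
        tracks = track_markers(frames, init, labels=["upper_jaw", "lower_jaw"])
        for t in tracks:
            err = np.abs(t.positions - truth.marker_positions[t.label]).max()
            assert err <= 1.0

    def test_marker_exit_raises_tracking_lost(self):
        n = 20
        x = np.linspace(30.0, 200.0, n)  # walks out of a 160-px-wide frame
        pos = np.column_stack([x, np.full(n, 60.0)])
        ok = pos[:, 0] <= 160 - 1 - 4
        pos[~ok] = pos[ok][-1]  # keep render in-bounds; truth for render only
        truth = SyntheticTruth(marker_positions={"m": pos})
        frames = list(render_marker_video(truth))
        # after the marker freezes, blank it out entirely to emulate exit
        first_gone = int(np.argmax(~ok))
        for f in range(first_gone, n):
            frames[f] = np.full_like(frames[f], 20)
        with pytest.raises(TrackingLostError) as err:
            track_markers(frames, [(30.0, 60.0)], search_radius_px=10)
        assert err.value.frame_index == first_gone

    def test_initial_position_must_fit_template(self):
        frames = render_marker_video(_static_truth())
        with pytest.raises(ValueError):
            track_markers(frames, [(1.0, 1.0)])


class TestJawGapeTrace:
    def test_constant_separation(self):
        up = MarkerTrack("u", np.tile([10.0, 10.0], (5, 1)), np.ones(5))
        lo = MarkerTrack("l", np.tile([10.0, 60.0], (5, 1)), np.ones(5))
        g = jaw_gape_trace(up, lo, CalibrationScale(0.1, 100.0), 30.0)
        np.testing.assert_allclose(g.values, 5.0)

    def test_coincident_markers_zero(self):
        up = MarkerTrack("u", np.tile([10.0, 10.0], (5, 1)), np.ones(5))
        g = jaw_gape_trace(up, up, CalibrationScale(0.1, 100.0), 30.0)
        np.testing.assert_allclose(g.values, 0.0)

    def test_matches_per_frame_hypot(self, rng):
        a = rng.uniform(0, 100, size=(40, 2))
        b = rng.uniform(0, 100, size=(40, 2))
        up = MarkerTrack("u", a, np.ones(40))
        lo = MarkerTrack("l", b, np.ones(40))
        scale = 0.07
        g = jaw_gape_trace(up, lo, CalibrationScale(scale, 10 / scale), 30.0)
        expected = [
            np.sqrt((a[i, 0] - b[i, 0]) ** 2 + (a[i, 1] - b[i, 1]) ** 2) * scale
            for i in range(40)
        ]
        np.testing.assert_allclose(g.values, expected)

    def test_length_mismatch_rejected(self):
        up = MarkerTrack("u", np.zeros((5, 2)) + 10, np.ones(5))
        lo = MarkerTrack("l", np.zeros((4, 2)) + 10, np.ones(4))
        with pytest.raises(ValueError):
            jaw_gape_trace(up, lo, CalibrationScale(0.1, 100.0), 30.0)


class TestAdjustGlottalPoints:
    def test_nearer_point_moved_to_farther_distance(self):
        c = np.array([0.0, 0.0])
        left = np.array([-12.0, 0.0])  # |L-C| = 12
        right = np.array([0.0, 10.0])  # |R-C| = 10, nearer
        l2, r2 = adjust_glottal_points(left, right, c)
        np.testing.assert_allclose(l2, left)
        np.testing.assert_allclose(r2, [0.0, 12.0])
        assert np.hypot(*l2) == pytest.approx(np.hypot(*r2))

    def test_symmetric_input_unchanged(self):
        c = np.array([5.0, 5.0])
        l2, r2 = adjust_glottal_points([0.0, 5.0], [10.0, 5.0], c)
        np.testing.assert_allclose(l2, [0.0, 5.0])
        np.testing.assert_allclose(r2, [10.0, 5.0])

    def test_coincident_point_rejected(self):
        with pytest.raises(ValueError):
            adjust_glottal_points([1.0, 1.0], [5.0, 5.0], [5.0, 5.0])

    @settings(derandomize=True, max_examples=50)
    @given(
        lx=st.floats(-50, 50),
        ly=st.floats(1, 50),
        rx=st.floats(-50, 50),
        ry=st.floats(1, 50),
    )
    def test_idempotent_and_equidistant(self, lx, ly, rx, ry):
        c = np.array([0.0, -1.0])
        l1, r1 = adjust_glottal_points([lx, ly], [rx, ry], c)
        assert np.hypot(*(l1 - c)) == pytest.approx(np.hypot(*(r1 - c)), rel=1e-9)
        l2, r2 = adjust_glottal_points(l1, r1, c)
        np.testing.assert_allclose(l1, l2, atol=1e-9)
        np.testing.assert_allclose(r1, r2, atol=1e-9)


def _tracks_from_positions(pos_l, pos_r, pos_c):
    n = len(pos_l)
    return (
        MarkerTrack("left", pos_l, np.ones(n)),
        MarkerTrack("right", pos_r, np.ones(n)),
        MarkerTrack("comm", pos_c, np.ones(n)),
    )


class TestGlottalLateralTraces:
    def test_symmetric_antiphase_signs(self):
        n = 30
        t = np.arange(n)
        dx = 5.0 + 2.0 * np.sin(2 * np.pi * t / 10)
        c = np.tile([50.0, 20.0], (n, 1))
        lpos = np.column_stack([50.0 - dx, np.full(n, 60.0)])
        rpos = np.column_stack([50.0 + dx, np.full(n, 60.0)])
        lat_l, lat_r, width = glottal_lateral_traces(
            *_tracks_from_positions(lpos, rpos, c), fps=30.0
        )
        np.testing.assert_allclose(lat_l.values, -lat_r.values, atol=1e-9)
        assert np.all(lat_r.values > 0)
        np.testing.assert_allclose(width.values, 2 * dx, atol=1e-9)

    def test_static_points_constant(self):
        n = 10
        c = np.tile([50.0, 20.0], (n, 1))
        lpos = np.tile([40.0, 60.0], (n, 1))
        rpos = np.tile([62.0, 60.0], (n, 1))
        lat_l, lat_r, width = glottal_lateral_traces(
            *_tracks_from_positions(lpos, rpos, c), fps=30.0
        )
        assert np.ptp(lat_l.values) == 0
        assert np.ptp(lat_r.values) == 0
        assert np.ptp(width.values) == 0

    def test_rigid_transform_invariance(self, rng):
        n = 40
        t = np.arange(n)
        dx = 5.0 + 2.0 * np.sin(2 * np.pi * t / 9)
        c = np.tile([50.0, 20.0], (n, 1))
        lpos = np.column_stack([50.0 - dx, np.full(n, 60.0)])
        rpos = np.column_stack([50.0 + dx * 0.7, np.full(n, 60.0)])
        base = glottal_lateral_traces(*_tracks_from_positions(lpos, rpos, c), fps=30.0)

        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        shift = np.array([13.0, -4.0])
        moved = glottal_lateral_traces(
            *_tracks_from_positions(
                lpos @ rot.T + shift, rpos @ rot.T + shift, c @ rot.T + shift
            ),
            fps=30.0,
        )
        for a, b in zip(base, moved):
            np.testing.assert_allclose(a.values, b.values, atol=1e-8)
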