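"""NCC landmark tracking and fascicle geometry from tracked lines."""

import math

import numpy as np
import pytest

from tahill.errors import (DegenerateTemplateError, GeometryError,
                           TrackLostError)
from tahill.synthetic_data import synth_us_sequence
from tahill.ultrasound_tracking import (FrameSequence, LandmarkTrack,
                                        _ncc_scores, fascicle_geometry,
                                        tendon_length_from_landmarks,
                                        track_template_ncc)


def _speckle(shape, seed):
    rng = np.random.default_rng(seed)
    return rng.random(shape)


class TestTrackTemplateNcc:
    def test_integer_shift_sequence_recovered_exactly(self):
        base = _speckle((80, 80), 0)
        frames = [np.roll(base, (2 * k, 3 * k), axis=(0, 1)) for k in range(6)]
        seq = FrameSequence(frames=frames)
        track = track_template_ncc(seq, (30, 30), template_half_size=5,
                                   search_half_size=6)
        expected = np.array([(30 + 2 * k, 30 + 3 * k) for k in range(6)])
        np.testing.assert_array_equal(track.positions, expected)
        assert np.all(track.confidence > 0.999)

    def test_static_sequence_stays_put_with_unit_confidence(self):
        base = _speckle((50, 50), 1)
        seq = FrameSequence(frames=[base] * 5)
        track = track_template_ncc(seq, (25, 25))
        assert np.all(track.positions == (25, 25))
        np.testing.assert_allclose(track.confidence, 1.0, atol=1e-9)

    def test_small_template_on_shift_sequence(self):
        # exactness holds down to 3x3 templates with nonzero variance
        base = _speckle((60, 60), 2)
        frames = [np.roll(base, (k, -k), axis=(0, 1)) for k in range(5)]
        track = track_template_ncc(FrameSequence(frames=frames), (30, 30),
                                   template_half_size=1, search_half_size=4)
        expected = np.array([(30 + k, 30 - k) for k in range(5)])
        np.testing.assert_array_equal(track.positions, expected)

    def test_zero_variance_template_rejected(self):
        frames = [np.zeros((40, 40)), np.zeros((40, 40))]
        with pytest.raises(DegenerateTemplateError):
            track_template_ncc(FrameSequence(frames=frames), (20, 20))

    def test_track_lost_reports_last_valid_frame(self):
        base = _speckle((40, 40), 3)
        frames = [np.roll(base, (6 * k, 0), axis=(0, 1)) for k in range(6)]
        with pytest.raises(TrackLostError) as exc:
            track_template_ncc(FrameSequence(frames=frames), (30, 20),
                               template_half_size=3, search_half_size=7)
        assert exc.value.last_valid_frame >= 0

    def test_scores_match_reference_matcher(self):
        # independent oracle: scikit-image's normalized cross-correlation
        skimage_feature = pytest.importorskip("skimage.feature")
        region = _speckle((31, 31), 4)
        template = region[10:21, 10:21].copy()
        ours = _ncc_scores(template, region)
        theirs = skimage_feature.match_template(region, template)
        np.testing.assert_allclose(ours, theirs, atol=1e-8)

    def test_chosen_displacement_has_maximal_score(self):
        base = _speckle((60, 60), 5)
        frames = [base, np.roll(base, (1, 2), axis=(0, 1))]
        seq = FrameSequence(frames=frames)
        track = track_template_ncc(seq, (30, 30), template_half_size=4,
                                   search_half_size=5)
        h, s = 4, 5
        r, c = 30, 30
        template = base[r - h:r + h + 1, c - h:c + h + 1]
        region = frames[1][r - h - s:r + h + s + 1, c - h - s:c + h + s + 1]
        scores = _ncc_scores(template, region)
        dr, dc = track.positions[1] - (r, c)
        assert scores[dr + s, dc + s] >= scores.max() - 1e-12

    def test_synthetic_sequence_oracle(self):
        rng = np.random.default_rng(6)
        path = rng.integers(-2, 3, size=(10, 2))
        seq, truth = synth_us_sequence(path, size=(64, 64), seed=6)
        track = track_template_ncc(seq, tuple(truth[0]), template_half_size=5,
                                   search_half_size=4)
        assert np.abs(track.positions - truth).max() <= 1


def _line_track(points):
    pts = np.asarray(points, dtype=float)
    return LandmarkTrack(name="x", positions=pts,
                         confidence=np.ones(len(pts)))


def _apo_fascicle_tracks(n=3, angle_deg=30.0, sep=30.0):
    """Horizontal parallel aponeuroses `sep` px apart, fascicle at the given
    angle spanning between them."""
    a = math.radians(angle_deg)
    run = sep / math.tan(a)
    tracks = {
        "sup_apo_prox": [(0.0, 0.0)] * n,
        "sup_apo_dist": [(0.0, 100.0)] * n,
        "deep_apo_prox": [(sep, 0.0)] * n,
        "deep_apo_dist": [(sep, 100.0)] * n,
        "fasc_prox": [(0.0, 50.0)] * n,
        "fasc_dist": [(sep, 50.0 + run)] * n,
    }
    return {k: _line_track(v) for k, v in tracks.items()}


class TestFascicleGeometry:
    def test_closed_form_pennation_and_length(self):
        tracks = _apo_fascicle_tracks(angle_deg=30.0, sep=30.0)
        geo = fascicle_geometry(tracks, mm_per_pixel=0.1)
        np.testing.assert_allclose(geo.pennation, math.radians(30.0),
                                   atol=1e-12)
        np.testing.assert_allclose(geo.fascicle_length,
                                   0.1 * 30.0 / math.sin(math.radians(30.0)),
                                   atol=1e-9)

    def test_endpoints_on_aponeuroses_unchanged_by_extension(self):
        tracks = _apo_fascicle_tracks()
        geo_full = fascicle_geometry(tracks, mm_per_pixel=1.0)
        # shrink the tracked fascicle segment toward its middle: the line is
        # the same, so the extended intersections must not move
        fp = np.asarray(tracks["fasc_prox"].positions)
        fd = np.asarray(tracks["fasc_dist"].positions)
        tracks["fasc_prox"] = _line_track(fp + 0.25 * (fd - fp))
        tracks["fasc_dist"] = _line_track(fd - 0.25 * (fd - fp))
        geo_part = fascicle_geometry(tracks, mm_per_pixel=1.0)
        np.testing.assert_allclose(geo_part.fascicle_length,
                                   geo_full.fascicle_length, atol=1e-9)

    def test_two_fascicles_are_averaged(self):
        tracks = _apo_fascicle_tracks()
        t45 = _apo_fascicle_tracks(angle_deg=45.0)
        tracks["fasc2_prox"] = t45["fasc_prox"]
        tracks["fasc2_dist"] = t45["fasc_dist"]
        geo = fascicle_geometry(tracks, mm_per_pixel=1.0)
        expected = 0.5 * (math.radians(30) + math.radians(45))
        np.testing.assert_allclose(geo.pennation, expected, atol=1e-12)

    def test_intersections_match_linear_solver(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            pts = rng.uniform(0, 100, size=(6, 2))
            # guard against near-parallel draws
            tracks = {
                "sup_apo_prox": [pts[0]], "sup_apo_dist": [pts[1]],
                "deep_apo_prox": [pts[2]], "deep_apo_dist": [pts[3]],
                "fasc_prox": [pts[4]], "fasc_dist": [pts[5]],
            }
            d_sup = pts[1] - pts[0]
            d_deep = pts[3] - pts[2]
            d_fas = pts[5] - pts[4]
            def det(u, v):
                return u[0] * v[1] - u[1] * v[0]
            if abs(det(d_fas, d_sup)) < 1.0 or abs(det(d_fas, d_deep)) < 1.0:
                continue
            tracks = {k: _line_track(v) for k, v in tracks.items()}
            geo = fascicle_geometry(tracks, mm_per_pixel=1.0)
            # independent 2x2 solve for both intersections
            inters = []
            for p0, d0 in ((pts[0], d_sup), (pts[2], d_deep)):
                A = np.column_stack([d_fas, -d0])
                t_u = np.linalg.solve(A, p0 - pts[4])
                inters.append(pts[4] + t_u[0] * d_fas)
            expected = np.linalg.norm(inters[0] - inters[1])
            np.testing.assert_allclose(geo.fascicle_length[0], expected,
                                       atol=1e-9)

    def test_rotation_invariance(self):
        tracks = _apo_fascicle_tracks()
        geo0 = fascicle_geometry(tracks, mm_per_pixel=1.0)
        rng = np.random.default_rng(8)
        for theta in rng.uniform(0, 2 * np.pi, 5):
            rot = np.array([[math.cos(theta), -math.sin(theta)],
                            [math.sin(theta), math.cos(theta)]])
            rotated = {k: _line_track(np.asarray(v.positions) @ rot.T)
                       for k, v in tracks.items()}
            geo = fascicle_geometry(rotated, mm_per_pixel=1.0)
            np.testing.assert_allclose(geo.fascicle_length,
                                       geo0.fascicle_length, atol=1e-9)
            np.testing.assert_allclose(geo.pennation, geo0.pennation,
                                       atol=1e-9)

    def test_parallel_fascicle_raises(self):
        tracks = _apo_fascicle_tracks()
        tracks["fasc_prox"] = _line_track([(10.0, 0.0)] * 3)
        tracks["fasc_dist"] = _line_track([(10.0, 100.0)] * 3)
        with pytest.raises(GeometryError):
            fascicle_geometry(tracks, mm_per_pixel=1.0)


class TestTendonLengthFromLandmarks:
    def test_three_four_five(self):
        out = tendon_length_from_landmarks([[0.0, 0.0, 0.0]],
                                           [[0.0, 30.0, 40.0]])
        np.testing.assert_allclose(out, [50.0])

    def test_coincident_points_rejected(self):
        with pytest.raises(GeometryError):
            tendon_length_from_landmarks([[1.0, 2.0, 3.0]], [[1.0, 2.0, 3.0]])

    def test_matches_norm_oracle(self):
        rng = np.random.default_rng(9)
        a = rng.uniform(-50, 50, (40, 3))
        b = a + rng.uniform(1.0, 60.0, (40, 3))
        out = tendon_length_from_landmarks(a, b)
        oracle = np.sqrt(((a - b) ** 2).sum(axis=1))
        np.testing.assert_allclose(out, oracle, atol=1e-12)
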