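"""Drift correction, temporal projection, and focus tracking."""

import math

import numpy as np
import pytest
from scipy import ndimage as ndi

from focikit.dynamics import (
    FocusTrack,
    RenderWindow,
    RigidTransform,
    annotate_track_sites,
    clamp_render,
    default_lut,
    dynamics_summary,
    register_rigid,
    temporal_projection,
    track_foci,
)
from focikit.segmentation import FocusObject


def detection(y, x, fid=0):
    return FocusObject(
        id=fid, roi_label="r", pixel_set=np.array([[int(y), int(x)]]),
        area_px=1, centroid=(float(y), float(x)),
    )


def spotty_image(seed=0, shape=(96, 96), n=14):
    rng = np.random.default_rng(seed)
    img = np.full(shape, 50.0)
    for y, x in rng.integers(15, shape[0] - 15, (n, 2)):
        img[y - 4 : y + 5, x - 4 : x + 5] += 60.0  # blocky "cells"
        img[y, x] += 500.0
    return ndi.gaussian_filter(img, 1.0)


class TestRigidTransform:
    def test_compose_with_inverse_is_identity(self):
        t = RigidTransform(dy=2.3, dx=-1.1, theta=4.0)
        r = t.compose(t.inverse())
        dt, dr = r.magnitude()
        assert dt < 1e-12 and dr < 1e-12

    def test_point_mapping_matches_image_warp(self):
        img = np.zeros((41, 41))
        img[20, 12] = 100.0
        t = RigidTransform(dy=3.0, dx=2.0, theta=30.0)
        warped = t.apply_to_image(img, fill=0.0)
        py, px = t.apply_to_points(np.array([[20.0, 12.0]]), img.shape)[0]
        yy, xx = np.unravel_index(np.argmax(warped), warped.shape)
        assert math.hypot(yy - py, xx - px) < 1.0

    def test_theta_bound(self):
        with pytest.raises(ValueError):
            RigidTransform(theta=95.0)


class TestClampRender:
    @pytest.mark.parametrize(
        "value,expected", [(400.0, 0.0), (5500.0, 1.0), (2950.0, 0.5), (0.0, 0.0), (9000.0, 1.0)]
    )
    def test_window_mapping(self, value, expected):
        out = clamp_render(np.array([[value]]), RenderWindow(400, 5500))
        assert out[0, 0] == pytest.approx(expected)

    def test_invalid_window(self):
        with pytest.raises(ValueError):
            RenderWindow(100, 100)


class TestRegistration:
    def test_identical_frames_near_identity(self):
        img = spotty_image(1)
        transforms, aligned = register_rigid([img, img.copy(), img.copy()])
        for t in transforms:
            assert abs(t.dy) < 0.05 and abs(t.dx) < 0.05 and abs(t.theta) < 0.05
        np.testing.assert_allclose(aligned[1], img, atol=0.01)

    def test_integer_shift_recovered(self):
        img = spotty_image(2)
        shifted = ndi.shift(img, (3.0, -2.0), order=1, cval=float(np.median(img)))
        transforms, _ = register_rigid([img, shifted])
        assert transforms[1].dy == pytest.approx(-3.0, abs=0.25)
        assert transforms[1].dx == pytest.approx(2.0, abs=0.25)

    def test_planted_rigid_motion_recovered(self):
        img = spotty_image(3, shape=(128, 128))
        planted = RigidTransform(dy=-2.0, dx=1.5, theta=1.2)
        moved = planted.apply_to_image(img)
        transforms, _ = register_rigid([img, moved])
        residual = transforms[1].compose(planted)
        dt, dr = residual.magnitude()
        assert dt < 0.5 and dr < 0.5

    def test_single_frame_identity(self):
        transforms, aligned = register_rigid([spotty_image(4)])
        assert transforms[0].magnitude() == (0.0, 0.0)
        assert aligned.shape[0] == 1

    def test_featureless_frames_identity_not_error(self):
        flat = np.full((32, 32), 9.0)
        transforms, _ = register_rigid([flat, flat.copy()])
        assert transforms[1].magnitude() == (0.0, 0.0)

    def test_mismatched_shapes_rejected(self):
        with pytest.raises(ValueError):
            register_rigid([np.zeros((8, 8)), np.zeros((9, 9))])


class TestTemporalProjection:
    def test_single_frame_is_pure_red(self):
        frame = np.full((4, 4), 5500.0)
        proj = temporal_projection(frame[None], RenderWindow(400, 5500))
        np.testing.assert_allclose(proj.rgb[0, 0], [1.0, 0.0, 0.0], atol=1e-12)

    def test_rgb_lut_full_stack_blends_white(self):
        frames = np.full((3, 4, 4), 5500.0)
        lut = np.array([[1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
        proj = temporal_projection(frames, RenderWindow(400, 5500), lut=lut)
        np.testing.assert_allclose(proj.rgb, 1.0)

    def test_pixel_bright_in_one_frame_keeps_frame_colour(self):
        frames = np.full((3, 4, 4), 400.0)
        frames[0, 1, 1] = 5500.0
        lut = np.array([[1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
        proj = temporal_projection(frames, RenderWindow(400, 5500), lut=lut)
        np.testing.assert_allclose(proj.rgb[1, 1], [1.0, 0.0, 0.0])

    def test_default_lut_endpoints(self):
        lut = default_lut(21)
        np.testing.assert_allclose(lut[0], [1.0, 0.0, 0.0], atol=1e-12)
        np.testing.assert_allclose(lut[-1], [0.0, 0.0, 1.0], atol=1e-12)

    def test_whiteness_property(self):
        """A pixel rendered >= 0.8 in >= 80% of frames blends to min RGB >= 0.8."""
        n = 21
        window = RenderWindow(0, 1000)
        rng = np.random.default_rng(0)
        frames = np.zeros((n, 3, 3))
        # pixel (1,1): bright (0.9) in a random 17 of 21 frames (>= 80%)
        bright = rng.choice(n, size=17, replace=False)
        frames[bright, 1, 1] = 900.0
        proj = temporal_projection(frames, window)
        assert proj.rgb[1, 1].min() >= 0.8

    def test_lut_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            temporal_projection(np.zeros((3, 2, 2)), lut=np.zeros((2, 3)))


class TestTracking:
    def test_fixed_focus_single_track(self):
        per_frame = [[detection(10, 10)] for _ in range(8)]
        tracks = track_foci(per_frame, link_radius_px=3.0)
        assert len(tracks) == 1
        summary = dynamics_summary(tracks)
        assert tracks[0].site_persistence == 1.0
        assert tracks[0].n_relocations == 0
        assert summary["static_fraction"] == 1.0

    def test_distant_foci_stay_separate(self):
        per_frame = [[detection(5, 5, 0), detection(40, 40, 1)] for _ in range(5)]
        tracks = track_foci(per_frame, link_radius_px=4.0)
        assert len(tracks) == 2

    def test_gap_bridging(self):
        """A focus absent for one frame and displaced by ~0.45 px reconnects
        into a single track with one recorded gap."""
        per_frame = []
        for f in range(10):
            if f <= 4:
                per_frame.append([detection(10, 10)])
            elif f == 5:
                per_frame.append([])
            else:
                per_frame.append([detection(10.4, 10.2)])
        tracks = track_foci(per_frame, link_radius_px=2.0, max_gap=1)
        assert len(tracks) == 1
        assert tracks[0].gap_frames == [5]
        assert tracks[0].lifetime == 9

    def test_gap_over_limit_splits_track(self):
        per_frame = [[detection(10, 10)]] * 3 + [[], []] + [[detection(10, 10)]] * 3
        tracks = track_foci(per_frame, link_radius_px=2.0, max_gap=1)
        assert len(tracks) == 2

    def test_detection_conservation(self):
        rng = np.random.default_rng(12)
        per_frame = []
        for _ in range(12):
            per_frame.append(
                [detection(*rng.uniform(0, 50, 2), fid=i) for i in range(rng.integers(0, 5))]
            )
        tracks = track_foci(per_frame, link_radius_px=6.0)
        n_entries = sum(tr.lifetime for tr in tracks)
        n_detections = sum(len(d) for d in per_frame)
        assert n_entries == n_detections
        for tr in tracks:
            assert len(set(tr.frames)) == len(tr.frames)  # one entry per frame

    def test_relocation_counted(self):
        per_frame = [[detection(10, 10)]] * 5 + [[detection(10, 25)]] * 5
        tracks = track_foci(per_frame, link_radius_px=20.0)
        assert len(tracks) == 1
        annotate_track_sites(tracks[0], site_radius_px=3.0)
        assert tracks[0].n_relocations == 1
        assert tracks[0].site_persistence == 0.5

    def test_single_entry_track_convention(self):
        tracks = track_foci([[detection(3, 3)]], link_radius_px=2.0)
        summary = dynamics_summary(tracks)
        assert tracks[0].site_persistence == 1.0
        assert summary["n_short_tracks"] == 1
        assert math.isnan(summary["static_fraction"])
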