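"""Synthetic microcolony generator: determinism, photometry, ground truth."""

import dataclasses as dc
import math

import numpy as np
import pytest

from focikit import SceneSpec, generate_microcolony, generate_timelapse
from focikit.dynamics import RigidTransform
from focikit.synthetic import (
    PlacementError,
    export_ground_truth,
    load_ground_truth,
    spot_contrast_image,
)


class TestDeterminism:
    def test_same_seed_bit_identical(self, tiny_scene_spec):
        s1, t1 = generate_microcolony(tiny_scene_spec)
        s2, t2 = generate_microcolony(tiny_scene_spec)
        np.testing.assert_array_equal(s1.pixels, s2.pixels)
        assert len(t1.foci) == len(t2.foci)
        for a, b in zip(t1.foci, t2.foci):
            assert a.amplitude == b.amplitude
            assert a.states[0].y == b.states[0].y

    def test_distinct_seeds_differ(self, tiny_scene_spec):
        s1, _ = generate_microcolony(tiny_scene_spec)
        s2, _ = generate_microcolony(dc.replace(tiny_scene_spec, seed=99))
        assert not np.array_equal(s1.pixels, s2.pixels)


class TestPhotometry:
    def test_empty_scene_matches_background_statistics(self):
        spec = SceneSpec(image_shape=(128, 128), n_cells=0, n_z=1, seed=2)
        stack, truth = generate_microcolony(spec)
        mean = float(stack.pixels[0, 0, 0].mean())
        # Poisson keeps the mean; read noise is zero-mean
        assert mean == pytest.approx(spec.background_level, rel=0.01)
        assert truth.n_cells == 0 and truth.foci == []

    def test_doubling_amplitude_doubles_spot_contribution(self):
        base = SceneSpec(
            image_shape=(128, 128), n_cells=5, n_z=1, layout="uniform",
            enable_noise=False, seed=7,
        )
        img0 = generate_microcolony(dc.replace(base, focus_amplitude_median=0.0))[0]
        img1 = generate_microcolony(base)[0]
        img2 = generate_microcolony(dc.replace(base, focus_amplitude_median=5000.0))[0]
        a = img1.pixels.astype(float) - img0.pixels.astype(float)
        b = img2.pixels.astype(float) - img1.pixels.astype(float)
        # spots(2A) - spots(A) == spots(A); quantisation allows +-1 count each
        np.testing.assert_allclose(b, a, atol=2.0)

    def test_spot_contrast_image_peaks_at_amplitude(self):
        spec = SceneSpec(image_shape=(96, 96), n_cells=1, n_z=1, layout="uniform",
                         focus_prob_per_cell=1.0, focus_amplitude_sigma=0.0, seed=3)
        _, truth = generate_microcolony(spec)
        img = spot_contrast_image(spec, truth)
        # integrated flux of a Gaussian spot: amplitude * 2*pi*sigma^2
        expected = spec.focus_amplitude_median * 2 * np.pi * spec.psf_sigma_px**2
        assert img.sum() == pytest.approx(expected, rel=0.01)


class TestGroundTruth:
    def test_focus_count_binomial(self):
        spec = SceneSpec(image_shape=(512, 512), n_cells=200, n_z=1,
                         focus_prob_per_cell=0.76, seed=5)
        _, truth = generate_microcolony(spec)
        n, p = 200, 0.76
        bound = 3 * math.sqrt(n * p * (1 - p))
        assert abs(len(truth.foci) - n * p) <= bound

    def test_foci_inside_their_cells(self, tiny_scene_spec):
        _, truth = generate_microcolony(tiny_scene_spec)
        cells = {c.cell_id: c for c in truth.cells}
        for f in truth.foci:
            cell = cells[f.cell_id]
            a, b = cell.endpoints
            s = f.states[0]
            d = np.array(b) - np.array(a)
            t = np.dot((s.y - a[0], s.x - a[1]), d) / (d @ d)
            t = min(max(t, 0.0), 1.0)
            closest = np.array(a) + t * d
            assert math.hypot(s.y - closest[0], s.x - closest[1]) <= cell.width_px / 2

    def test_infeasible_packing_raises(self):
        spec = SceneSpec(image_shape=(64, 64), n_cells=500, n_z=1, seed=0)
        with pytest.raises(PlacementError):
            generate_microcolony(spec)


class TestTimelapse:
    def _spec(self, **kw):
        defaults = dict(
            image_shape=(160, 160), n_cells=6, n_z=1, layout="uniform",
            n_frames=12, dropout_prob=0.0, seed=21,
        )
        defaults.update(kw)
        return SceneSpec(**defaults)

    def test_no_relocation_means_single_site(self):
        _, truth = generate_timelapse(self._spec(relocation_prob=0.0))
        for f in truth.foci:
            assert len(f.sites) == 1 and f.relocation_frames == []

    def test_always_relocate_changes_site_each_reassembly(self):
        _, truth = generate_timelapse(self._spec(relocation_prob=1.0, seed=22))
        n_reassemblies = 0
        for f in truth.foci:
            assert len(f.sites) == len(f.relocation_frames) + 1
            n_reassemblies += len(f.relocation_frames)
            for (y0, x0), (y1, x1) in zip(f.sites, f.sites[1:]):
                assert math.hypot(y1 - y0, x1 - x0) >= truth.spec.min_relocation_px * 0.99
        assert n_reassemblies > 0  # regime actually exercised

    def test_drift_trajectory_is_composed_steps(self):
        step = RigidTransform(dy=0.3, dx=-0.2, theta=0.1)
        _, truth = generate_timelapse(self._spec(drift_per_frame=(0.3, -0.2, 0.1)))
        composed = RigidTransform()
        pts = np.array([[40.0, 40.0], [100.0, 80.0]])
        for t, planted in enumerate(truth.drift):
            np.testing.assert_allclose(
                planted.apply_to_points(pts, truth.spec.image_shape),
                composed.apply_to_points(pts, truth.spec.image_shape),
                atol=1e-9,
            )
            composed = step.compose(composed)

    def test_rendered_positions_follow_drift(self):
        _, truth = generate_timelapse(self._spec(drift_per_frame=(0.5, 0.0, 0.0)))
        for f in truth.foci:
            for s in f.states:
                expected = truth.drift[s.frame].apply_to_points(
                    np.array([[s.y, s.x]]), truth.spec.image_shape
                )[0]
                assert s.rendered_y == pytest.approx(expected[0], abs=1e-9)
                assert s.rendered_x == pytest.approx(expected[1], abs=1e-9)

    def test_needs_two_frames(self):
        with pytest.raises(ValueError):
            generate_timelapse(self._spec(n_frames=1))


class TestExport:
    def test_roundtrip(self, tmp_path, tiny_scene_spec):
        _, truth = generate_timelapse(
            dc.replace(tiny_scene_spec, n_frames=5, image_shape=(160, 160))
        )
        export_ground_truth(truth, tmp_path)
        back = load_ground_truth(tmp_path)
        assert back.n_cells == truth.n_cells
        assert back.spec == truth.spec
        assert len(back.foci) == len(truth.foci)
        for a, b in zip(truth.foci, back.foci):
            assert a.relocation_frames == b.relocation_frames
            assert [s.frame for s in a.states] == [s.frame for s in b.states]
            assert a.states[0].y == pytest.approx(b.states[0].y)
        for da, db in zip(truth.drift, back.drift):
            assert (da.dy, da.dx, da.theta) == (db.dy, db.dx, db.theta)

    def test_empty_scene_writes_headers(self, tmp_path):
        spec = SceneSpec(image_shape=(64, 64), n_cells=0, n_z=1, seed=1)
        _, truth = generate_microcolony(spec)
        export_ground_truth(truth, tmp_path)
        header = (tmp_path / "foci.csv").read_text().splitlines()[0]
        assert header.startswith("focus_id,cell_id,frame")
        assert len((tmp_path / "cells.csv").read_text().splitlines()) == 1
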