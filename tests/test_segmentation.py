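"""SD-threshold segmentation against exhaustive oracles."""

import numpy as np
import pytest

from focikit import ImageStack, ROI, ROISet, SegmentationParams, segment_foci
from focikit.segmentation import DegenerateROIError, extract_foci, threshold_roi


def brute_force_foci(plane, y0, y1, x0, x1, k_sd=2.2, min_size=6, connectivity=8):
    """Independent oracle: direct mean/SD summation + recursive flood fill.

    Returns the set of focus pixel sets (as frozensets of (y, x)) for a
    rectangular ROI with inclusive bounds.
    """
    vals = []
    for y in range(y0, y1 + 1):
        for x in range(x0, x1 + 1):
            vals.append(float(plane[y, x]))
    mean = sum(vals) / len(vals)
    var = sum((v - mean) ** 2 for v in vals) / len(vals)
    thr = mean + k_sd * var**0.5
    above = {
        (y, x)
        for y in range(y0, y1 + 1)
        for x in range(x0, x1 + 1)
        if float(plane[y, x]) > thr
    }
    if connectivity == 8:
        neigh = [(dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1) if (dy, dx) != (0, 0)]
    else:
        neigh = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    seen = set()
    comps = []
    for start in sorted(above):
        if start in seen:
            continue
        stack, comp = [start], set()
        while stack:
            p = stack.pop()
            if p in seen or p not in above:
                continue
            seen.add(p)
            comp.add(p)
            for dy, dx in neigh:
                stack.append((p[0] + dy, p[1] + dx))
        comps.append(frozenset(comp))
    return {c for c in comps if len(c) > min_size}


def as_pixel_sets(foci):
    return {frozenset(map(tuple, f.pixel_set)) for f in foci}


class TestThresholdROI:
    def test_uniform_roi_yields_empty_mask(self):
        plane = np.full((10, 10), 42.0)
        roi = ROI.from_rect("u", (0, 0), (9, 9))
        assert threshold_roi(plane, roi).mask.sum() == 0

    def test_planted_block_thresholds_exactly(self, planted_block_plane):
        roi = ROI.from_rect("b", (0, 0), (15, 15))
        mask = threshold_roi(planted_block_plane, roi).mask
        expected = np.zeros((16, 16), dtype=bool)
        expected[6:9, 6:9] = True
        np.testing.assert_array_equal(mask, expected)

    def test_k_zero_reduces_to_above_mean(self):
        rng = np.random.default_rng(0)
        plane = rng.integers(0, 100, (12, 12)).astype(float)
        roi = ROI.from_rect("m", (0, 0), (11, 11))
        mask = threshold_roi(plane, roi, SegmentationParams(k_sd=0.0)).mask
        np.testing.assert_array_equal(mask, plane > plane.mean())

    def test_mask_confined_to_roi(self):
        plane = np.zeros((12, 12))
        plane[0, 0] = 1000.0  # bright pixel outside the ROI
        plane[6, 6] = 1000.0
        roi = ROI.from_rect("part", (4, 4), (9, 9))
        mask = threshold_roi(plane, roi).mask
        assert mask[6, 6] and not mask[0, 0]

    def test_degenerate_roi_raises(self):
        plane = np.zeros((5, 5))
        roi = ROI("pt", [(1.0, 0.6), (1.0, 1.4), (1.4, 1.0)])  # one pixel centre
        with pytest.raises(DegenerateROIError):
            threshold_roi(plane, roi)


class TestExtractFoci:
    def _mask(self, arr):
        from focikit.segmentation import BinaryMask

        arr = np.asarray(arr, dtype=bool)
        return BinaryMask(mask=arr, roi_label="m", footprint=np.ones_like(arr))

    def test_empty_mask(self):
        assert extract_foci(self._mask(np.zeros((5, 5)))) == []

    def test_strict_size_filter(self):
        arr = np.zeros((12, 12), dtype=bool)
        arr[1:3, 1:4] = True  # area 6: filtered at min_size 6 (strict >)
        arr[6:9, 6:9] = True  # area 9: kept
        foci = extract_foci(self._mask(arr))
        assert len(foci) == 1
        assert foci[0].area_px == 9
        assert foci[0].centroid == (7.0, 7.0)

    def test_diagonal_connectivity(self):
        arr = np.zeros((6, 6), dtype=bool)
        arr[2, 2] = arr[3, 3] = True
        p8 = SegmentationParams(connectivity=8, min_size_px=0)
        p4 = SegmentationParams(connectivity=4, min_size_px=0)
        assert len(extract_foci(self._mask(arr), p8)) == 1
        assert len(extract_foci(self._mask(arr), p4)) == 2

    def test_ids_assigned_in_raster_order(self):
        arr = np.zeros((20, 20), dtype=bool)
        arr[10:14, 1:4] = True
        arr[1:5, 10:13] = True
        foci = extract_foci(self._mask(arr), SegmentationParams(min_size_px=0))
        assert [f.id for f in foci] == [0, 1]
        assert foci[0].centroid[0] < foci[1].centroid[0] or foci[0].pixel_set[0][0] < foci[1].pixel_set[0][0]


class TestSegmentFoci:
    def test_uniform_stack_no_foci(self):
        stack = ImageStack(pixels=np.full((1, 2, 1, 16, 16), 300, dtype=np.uint16))
        rois = ROISet([ROI.from_rect("r", (0, 0), (15, 15))])
        assert segment_foci(stack, rois) == []

    def test_planted_block_in_stack(self, planted_block_stack):
        rois = ROISet([ROI.from_rect("r", (0, 0), (15, 15))])
        foci = segment_foci(planted_block_stack, rois)
        assert len(foci) == 1
        assert foci[0].area_px == 9
        assert foci[0].centroid == (7.0, 7.0)

    def test_default_params_applied(self, planted_block_stack):
        """Omitted params fall back to k_sd=2.2, min_size_px=6."""
        rois = ROISet([ROI.from_rect("r", (0, 0), (15, 15))])
        explicit = segment_foci(
            planted_block_stack, rois, params=SegmentationParams(k_sd=2.2, min_size_px=6)
        )
        assert as_pixel_sets(segment_foci(planted_block_stack, rois)) == as_pixel_sets(explicit)

    def test_agrees_with_bruteforce_on_random_images(self):
        rng = np.random.default_rng(123)
        for _ in range(30):
            plane = rng.integers(0, 4000, (32, 32)).astype(np.uint16)
            # plant occasional bright blocks so non-trivial foci exist
            if rng.random() < 0.7:
                y, x = rng.integers(2, 26, 2)
                plane[y : y + 3, x : x + 3] = 60000
            y0, x0 = rng.integers(0, 12, 2)
            y1 = int(rng.integers(y0 + 4, 32))
            x1 = int(rng.integers(x0 + 4, 32))
            stack = ImageStack(pixels=plane[None, None, None])
            rois = ROISet([ROI.from_rect("r", (y0, x0), (y1, x1))])
            got = as_pixel_sets(segment_foci(stack, rois))
            want = brute_force_foci(plane, y0, y1, x0, x1)
            assert got == want

    def test_monotone_in_k_and_size(self):
        rng = np.random.default_rng(7)
        plane = rng.integers(0, 2000, (24, 24)).astype(float)
        plane[5:9, 5:9] = 30000
        roi = ROISet([ROI.from_rect("r", (0, 0), (23, 23))])
        stack = ImageStack(pixels=plane[None, None, None])
        masks = [
            threshold_roi(plane, roi["r"], SegmentationParams(k_sd=k)).mask.sum()
            for k in (0.5, 1.0, 2.2, 4.0)
        ]
        assert sorted(masks, reverse=True) == masks
        counts = [
            len(segment_foci(stack, roi, params=SegmentationParams(min_size_px=m)))
            for m in (0, 4, 9, 20)
        ]
        assert sorted(counts, reverse=True) == counts

    def test_deterministic_repeat(self, tiny_scene_spec):
        from focikit import generate_microcolony
        from focikit.validate import scene_roi

        stack, truth = generate_microcolony(tiny_scene_spec)
        rois = ROISet([scene_roi(truth)])
        a = segment_foci(stack, rois)
        b = segment_foci(stack, rois)
        assert [(f.id, f.area_px, tuple(map(tuple, f.pixel_set))) for f in a] == [
            (f.id, f.area_px, tuple(map(tuple, f.pixel_set))) for f in b
        ]

    def test_3d_mode_volume(self):
        pixels = np.full((1, 3, 1, 16, 16), 100, dtype=np.uint16)
        pixels[0, 1, 0, 6:9, 6:9] = 5000
        stack = ImageStack(pixels=pixels)
        roi = ROI.from_rect("v", (0, 0), (15, 15), z_range=(0, 2))
        foci = segment_foci(stack, ROISet([roi]), mode="3d")
        assert len(foci) == 1
        assert foci[0].area_px == 9
        assert foci[0].centroid[0] == 1.0  # z centroid in stack coordinates
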