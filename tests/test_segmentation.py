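import numpy as np
import pytest

import thermoroi as tr
from thermoroi.errors import DegenerateFrameError, EmptyRoIWarning, ParameterError, ValidationError
from thermoroi.segmentation import BinaryMask, NormalizedFrame, ThresholdedFrame


def flood_fill_regions(mask):
    """Brute-force 4-connected labeling oracle: BFS flood fill in raster order."""
    mask = np.asarray(mask, dtype=bool)
    labels = np.zeros(mask.shape, dtype=int)
    nxt = 0
    for r0 in range(mask.shape[0]):
        for c0 in range(mask.shape[1]):
            if mask[r0, c0] and labels[r0, c0] == 0:
                nxt += 1
                queue = [(r0, c0)]
                labels[r0, c0] = nxt
                while queue:
                    r, c = queue.pop()
                    for rr, cc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
                        if (
                            0 <= rr < mask.shape[0]
                            and 0 <= cc < mask.shape[1]
                            and mask[rr, cc]
                            and labels[rr, cc] == 0
                        ):
                            labels[rr, cc] = nxt
                            queue.append((rr, cc))
    return labels


class TestNormalize:
    def test_affine_map_forced_by_endpoints(self):
        frame = tr.TemperatureFrame(values=[[20.0, 26.0], [32.0, 32.0]])
        norm = tr.normalize(frame)
        assert np.allclose(norm.values, [[0.0, 0.5], [1.0, 1.0]])
        assert (norm.src_min_c, norm.src_max_c) == (20.0, 32.0)

    def test_range_contract_and_denormalization(self, small_frame):
        norm = tr.normalize(small_frame)
        assert norm.values.min() == 0.0 and norm.values.max() == 1.0
        assert np.allclose(norm.denormalize(), small_frame.values)

    def test_constant_frame_is_degenerate(self):
        with pytest.raises(DegenerateFrameError):
            tr.normalize(tr.TemperatureFrame(values=np.full((2, 2), 25.0)))


class TestThreshold:
    def test_boundary_value_is_kept(self):
        norm = NormalizedFrame(np.array([[0.79, 0.80], [1.0, 0.0]]), 20.0, 30.0)
        thr = tr.threshold(norm, 0.8)
        assert np.array_equal(thr.values, [[0.0, 0.80], [1.0, 0.0]])

    def test_max_pixel_always_survives(self, small_frame):
        thr = tr.threshold(tr.normalize(small_frame), 0.8)
        assert (thr.values > 0).any()

    def test_idempotent(self, small_frame):
        thr = tr.threshold(tr.normalize(small_frame), 0.8)
        again = tr.threshold(NormalizedFrame(thr.values, 20.0, 34.0), 0.8)
        assert np.array_equal(again.values, thr.values)

    @pytest.mark.parametrize("tau", [0.0, 1.0, -0.1, 1.5])
    def test_tau_out_of_range(self, small_frame, tau):
        with pytest.raises(ParameterError):
            tr.threshold(tr.normalize(small_frame), tau)


def test_binarize_is_indicator():
    thr = ThresholdedFrame(np.array([[0.0, 0.85], [0.9, 0.0]]), 0.8)
    mask = tr.binarize(thr)
    assert np.array_equal(mask.values, [[0, 1], [1, 0]])
    # re-binarizing a mask interpreted as values is a fixed point
    assert np.array_equal(tr.binarize(ThresholdedFrame(mask.values, 0.8)).values, mask.values)


class TestLabelComponents:
    def test_diagonal_pixels_are_separate(self):
        mask = np.zeros((6, 6), dtype=np.uint8)
        mask[2, 2] = mask[3, 3] = 1
        assert len(tr.label_components(BinaryMask(mask))) == 2

    def test_areas_match_flood_fill_oracle(self):
        mask = np.zeros((6, 6), dtype=np.uint8)
        mask[1:4, 1:4] = 1
        mask[5, 3:5] = 1
        regions = tr.label_components(BinaryMask(mask))
        oracle = flood_fill_regions(mask)
        assert sorted(r.area_px for r in regions) == sorted(
            np.bincount(oracle.ravel())[1:].tolist()
        ) == [2, 9]

    def test_labels_partition_matches_oracle(self, study_sweep):
        _, captures, _ = study_sweep
        seg = tr.segment(captures.frames[0])
        oracle = flood_fill_regions(seg.mask.values)
        assert len(tr.label_components(seg.mask)) == oracle.max()

    def test_full_frame_single_region(self):
        regions = tr.label_components(BinaryMask(np.ones((4, 5), dtype=np.uint8)))
        assert len(regions) == 1
        assert regions[0].area_px == 20
        assert regions[0].touches_border

    def test_empty_mask(self):
        assert tr.label_components(BinaryMask(np.zeros((4, 4), dtype=np.uint8))) == ()


class TestSelectRoi:
    def test_largest_area_wins(self):
        mask = np.zeros((6, 6), dtype=np.uint8)
        mask[1:4, 1:4] = 1
        mask[5, 3:5] = 1
        regions = tr.label_components(BinaryMask(mask))
        label = tr.select_roi(regions, (6, 6))
        assert next(r for r in regions if r.label == label).area_px == 9

    def test_centrality_breaks_area_ties(self):
        mask = np.zeros((9, 9), dtype=np.uint8)
        mask[0:2, 0:2] = 1  # corner
        mask[4:6, 4:6] = 1  # centered
        regions = tr.label_components(BinaryMask(mask))
        label = tr.select_roi(regions, (9, 9))
        assert next(r for r in regions if r.label == label).bbox == (4, 4, 2, 2)

    def test_empty_list(self):
        assert tr.select_roi([], (6, 6)) is None


class TestSegment:
    def test_border_blob_removed(self):
        """Warm ellipse kept, smaller warm border blob removed."""
        values = np.full((60, 80), 22.0)
        rows, cols = np.mgrid[0:60, 0:80]
        ellipse = ((rows - 30) / 18.0) ** 2 + ((cols - 40) / 22.0) ** 2 <= 1
        values[ellipse] = 34.0
        blob = (rows - 2) ** 2 + (cols - 4) ** 2 <= 9  # ~30 px at the border
        values[blob] = 33.5
        seg = tr.segment(tr.TemperatureFrame(values=values))
        assert np.array_equal(seg.roi_mask, ellipse)
        assert not (seg.cleaned.values[blob & ~ellipse] > 0).any()

    def test_single_region_support_equals_threshold_mask(self, small_frame):
        seg = tr.segment(small_frame)
        assert np.array_equal(seg.cleaned.values > 0, seg.mask.values.astype(bool))

    def test_temperature_fidelity(self, study_sweep):
        """Segmentation never alters temperatures: RoI values equal the input."""
        _, captures, _ = study_sweep
        frame = captures.frames[3]
        seg = tr.segment(frame)
        assert np.array_equal(seg.roi_temps_c, frame.values[seg.roi_mask])

    def test_raising_tau_shrinks_mask(self, study_sweep):
        _, captures, _ = study_sweep
        frame = captures.frames[0]
        masks = [tr.segment(frame, tau).mask.values for tau in (0.5, 0.7, 0.8, 0.9)]
        for lo, hi in zip(masks, masks[1:]):
            assert not (hi & ~lo).any()  # mask(tau2) subset of mask(tau1)


class TestRoiPercentage:
    def test_study_grid_values(self):
        assert tr.roi_percentage(14361, (240, 320)) == 18.70
        assert tr.roi_percentage(10298, (240, 320)) == 13.41

    def test_endpoints(self):
        assert tr.roi_percentage(0, (240, 320)) == 0.0
        assert tr.roi_percentage(76800, (240, 320)) == 100.0

    def test_area_exceeding_frame(self):
        with pytest.raises(ValidationError):
            tr.roi_percentage(76801, (240, 320))


class TestRenderFalseColor:
    def test_background_reserved_and_endpoint_mapping(self, small_frame):
        seg = tr.segment(small_frame)
        img = tr.render_false_color(seg)
        assert np.all(img.pixels[~seg.roi_mask] == np.array(img.background_color))
        # pixel holding the frame maximum gets the colormap's highest color
        top = np.unravel_index(np.argmax(np.asarray(small_frame.values)), small_frame.shape)
        assert np.array_equal(img.pixels[top], img.lut[255])
        # no RoI pixel uses the reserved background color
        assert not np.all(
            img.pixels[seg.roi_mask] == np.array(img.background_color), axis=-1
        ).any()

    def test_mapping_inversion_within_quantization_step(self, study_sweep):
        _, captures, _ = study_sweep
        seg = tr.segment(captures.frames[0])
        img = tr.render_false_color(seg)
        vals = seg.cleaned.values[seg.roi_mask]
        recovered = img.value_for_index(img.index_for_value(vals))
        step = (img.norm_range[1] - img.norm_range[0]) / 254.0
        assert np.abs(recovered - vals).max() <= step

    def test_empty_roi_renders_uniform_background(self):
        seg = tr.segment(tr.TemperatureFrame(values=[[20.0, 21.0], [22.0, 34.0]]))
        import dataclasses

        seg_empty = dataclasses.replace(
            seg, roi_mask=np.zeros((2, 2), dtype=bool), roi_temps_c=np.array([])
        )
        with pytest.warns(EmptyRoIWarning):
            img = tr.render_false_color(seg_empty)
        assert np.all(img.pixels == np.array(img.background_color))
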