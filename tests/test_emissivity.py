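import numpy as np
import pytest

import thermoroi as tr
from thermoroi.errors import ConfigurationError, ValidationError

# Published per-angle reference-zone averages for two volunteers' sweeps
# (normal-view reference at 0 degrees, room temperature 20 C).
ANGLES = (0, 12, 24, 36, 48, 60, 72, 84)
S1_AVG = (32.44, 32.84, 32.88, 33.16, 33.24, 33.31, 33.24, 33.64)
S1_PCT = (0.00, 3.22, 3.54, 5.79, 6.43, 6.99, 6.43, 9.65)
S2_AVG = (31.01, 31.19, 31.28, 31.63, 31.83, 31.89, 32.02, 32.24)
S2_PCT = (0.00, 1.63, 2.45, 5.63, 7.45, 7.99, 9.17, 11.17)


class TestAngularError:
    def test_published_magnitudes(self):
        assert round(abs(tr.angular_error(32.44, 33.64, 20.0)) * 100, 2) == 9.65
        assert round(abs(tr.angular_error(31.01, 31.19, 20.0)) * 100, 2) == 1.63

    def test_zero_when_angles_agree(self):
        assert tr.angular_error(32.44, 32.44, 20.0) == 0.0

    def test_sign_is_negative_when_oblique_reads_warmer(self):
        assert tr.angular_error(32.44, 33.64, 20.0) < 0

    def test_reference_equal_to_ambient_rejected(self):
        with pytest.raises(ValidationError):
            tr.angular_error(20.0, 25.0, 20.0)


class TestRegionAverage:
    def test_uniform_region(self):
        frame = tr.TemperatureFrame(values=np.full((6, 6), 33.0))
        assert tr.region_average(frame, tr.ReferenceBox((1, 1, 3, 3))) == 33.0

    def test_two_point_masked_mean(self):
        values = np.full((4, 4), 20.0)
        values[1, 1], values[1, 2] = 32.0, 34.0
        mask = np.zeros((4, 4), dtype=np.uint8)
        mask[1, 1] = mask[1, 2] = 1
        frame = tr.TemperatureFrame(values=values)
        assert tr.region_average(frame, tr.ReferenceBox((0, 0, 4, 4)), mask) == 33.0

    def test_box_outside_mask(self):
        frame = tr.TemperatureFrame(values=np.full((4, 4), 30.0))
        mask = np.zeros((4, 4), dtype=np.uint8)
        mask[0, 0] = 1
        with pytest.raises(ValidationError):
            tr.region_average(frame, tr.ReferenceBox((2, 2, 2, 2)), mask)


class TestProfileFromAverages:
    @pytest.mark.parametrize(
        "avgs,pcts", [(S1_AVG, S1_PCT), (S2_AVG, S2_PCT)], ids=["sweep-1", "sweep-2"]
    )
    def test_published_profiles(self, avgs, pcts):
        profile = tr.profile_from_averages(ANGLES, avgs, ta_c=20.0)
        assert [r.delta_t_percent for r in profile] == list(pcts)

    def test_reference_record_is_exactly_zero(self):
        profile = tr.profile_from_averages((0,), (32.44,), ta_c=20.0)
        assert len(profile) == 1 and profile[0].delta_t == 0.0

    def test_missing_reference_angle(self):
        with pytest.raises(ConfigurationError):
            tr.profile_from_averages((12, 24), (32.0, 33.0), ta_c=20.0)


class TestCompensate:
    @pytest.fixture()
    def drifted(self):
        drift = {a: 0.1 * i for i, a in enumerate((0, 12, 24, 36))}
        spec = tr.PhantomSpec(
            seed=5, noise_sd_c=0.0, render_visible=False,
            angles_deg=(0, 12, 24, 36), drift_profile=drift,
        )
        captures, truth = tr.generate_sweep(spec)
        segs = [tr.segment(f) for f in captures.frames]
        roi = next(r for r in segs[0].regions if r.label == segs[0].roi_label)
        box = tr.default_reference_box(roi.bbox)
        profile = tr.build_error_profile(
            captures.frames, box, [s.roi_mask for s in segs], ta_c=20.0
        )
        return captures, truth, segs, box, profile

    def test_reference_average_restored_exactly(self, drifted):
        captures, _, segs, box, profile = drifted
        tn = profile[0].tn_c
        for frame, rec, seg in zip(captures.frames, profile, segs):
            comp = tr.compensate(frame, rec, seg.roi_mask)
            assert tr.region_average(comp, box, seg.roi_mask) == pytest.approx(tn, abs=1e-9)

    def test_reference_frame_unchanged(self, drifted):
        captures, _, segs, _, profile = drifted
        comp = tr.compensate(captures.frames[0], profile[0], segs[0].roi_mask)
        assert np.array_equal(comp.values, captures.frames[0].values)

    def test_background_untouched_and_differences_invariant(self, drifted):
        captures, _, segs, _, profile = drifted
        frame, rec, seg = captures.frames[2], profile[2], segs[2]
        comp = tr.compensate(frame, rec, seg.roi_mask)
        assert np.array_equal(comp.values[~seg.roi_mask], frame.values[~seg.roi_mask])
        assert np.allclose(
            np.subtract.outer(comp.values[seg.roi_mask][:50], comp.values[seg.roi_mask][:50]),
            np.subtract.outer(frame.values[seg.roi_mask][:50], frame.values[seg.roi_mask][:50]),
        )

    def test_idempotence_after_remeasurement(self, drifted):
        captures, _, segs, box, profile = drifted
        frame, rec, seg = captures.frames[3], profile[3], segs[3]
        comp = tr.compensate(frame, rec, seg.roi_mask)
        re_avg = tr.region_average(comp, box, seg.roi_mask)
        rec2 = tr.EmissivityRecord(
            angle_deg=frame.angle_deg, tn_c=rec.tn_c, ttheta_c=re_avg, ta_c=20.0,
            delta_t=tr.angular_error(rec.tn_c, re_avg, 20.0),
        )
        assert abs(rec2.delta_t) < 1e-12
        comp2 = tr.compensate(comp, rec2, seg.roi_mask)
        assert np.allclose(comp2.values, comp.values, atol=1e-9)

    def test_empty_mask_rejected(self, drifted):
        captures, _, _, _, profile = drifted
        with pytest.raises(ValidationError):
            tr.compensate(captures.frames[0], profile[0], np.zeros((240, 320), dtype=bool))


def test_interpolate_delta_folds_and_clamps():
    profile = tr.profile_from_averages(ANGLES, S1_AVG, ta_c=20.0)
    assert tr.interpolate_delta(profile, 0.0) == 0.0
    # midway between measured samples
    mid = tr.interpolate_delta(profile, 18.0)
    assert min(profile[1].delta_t, profile[2].delta_t) <= mid <= max(
        profile[1].delta_t, profile[2].delta_t
    )
    # angles beyond the last sample reuse it; angles past 180 fold back
    assert tr.interpolate_delta(profile, 120.0) == profile[-1].delta_t
    assert tr.interpolate_delta(profile, 348.0) == tr.interpolate_delta(profile, 12.0)
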