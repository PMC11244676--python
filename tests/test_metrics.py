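"""The three artifact metrics against analytic and hand-computed oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from metartiq import (
    CTVolume,
    ROISpec,
    compute_amplitude_low_freq,
    compute_bloom_vol,
    compute_roi_metrics,
    compute_spectrum,
    extract_metal_contour,
)
from metartiq.metrics import CONTOUR_SAMPLES
from metartiq.phantom import PhantomSpec, StreakSpec, generate_phantom
from metartiq.volume import ContourTrace


class TestRoiMetrics:
    def test_identical_rois_give_zero_diff(self, rng):
        vol = CTVolume(rng.normal(0, 100, (3, 32, 32)), spacing=(1, 1, 1))
        roi = ROISpec(slice_index=1, shape="circle", center=(16, 16), size=5)
        m = compute_roi_metrics(vol, roi, roi)
        assert m.diff_hu == 0.0

    def test_sign_convention_artifact_minus_reference(self):
        # lung-type values: artifact mean -813, reference -600 -> diff -213
        data = np.zeros((1, 10, 20))
        data[0, :, :10] = -813.0
        data[0, :, 10:] = -600.0
        vol = CTVolume(data, spacing=(1, 1, 1))
        art = ROISpec(0, "rectangle", center=(4.5, 4.5), size=(3, 3))
        ref = ROISpec(0, "rectangle", center=(4.5, 14.5), size=(3, 3))
        m = compute_roi_metrics(vol, art, ref)
        assert m.diff_hu == pytest.approx(-213.0)

    def test_sample_sd_hand_oracle(self):
        # 3x3 ROI holding {0x3, 100x3, 200x3}: mean 100,
        # sample SD = sqrt(sum (x-100)^2 / 8) = sqrt(60000/8)
        data = np.zeros((1, 5, 5))
        data[0, 1:4, 1:4] = np.array([[0, 0, 0], [100, 100, 100], [200, 200, 200]])
        vol = CTVolume(data, spacing=(1, 1, 1))
        art = ROISpec(0, "rectangle", center=(2, 2), size=(1, 1))
        ref = ROISpec(0, "rectangle", center=(2, 2), size=(1, 1))
        m = compute_roi_metrics(vol, art, ref)
        assert m.sd_artifact == pytest.approx(np.sqrt(60000.0 / 8.0))


class TestContourExtraction:
    def test_disk_contour_radius_oracle(self, disk_volume):
        trace = extract_metal_contour(disk_volume, 1, metal_threshold=800, offset_voxels=3)
        assert len(trace) == CONTOUR_SAMPLES
        radii = np.hypot(trace.points[:, 0] - 64, trace.points[:, 1] - 64)
        assert np.all(np.abs(radii - 23.0) <= 0.75)

    def test_start_point_and_orientation_deterministic(self, disk_volume):
        t1 = extract_metal_contour(disk_volume, 1, 800, 3)
        t2 = extract_metal_contour(disk_volume, 1, 800, 3)
        np.testing.assert_array_equal(t1.points, t2.points)
        # starts at minimal row, then minimal column
        assert t1.points[0, 0] == pytest.approx(t1.points[:, 0].min())
        # counter-clockwise: positive shoelace area with x = col, y = row
        x, y = t1.points[:, 1], t1.points[:, 0]
        area = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
        assert area > 0

    def test_square_block_perimeter_oracle(self):
        sl = np.zeros((64, 64))
        sl[20:30, 20:30] = 3000.0
        vol = CTVolume(np.stack([sl] * 3), spacing=(1, 1, 1))
        trace = extract_metal_contour(vol, 1, 800, 3)
        closed = np.vstack([trace.points, trace.points[:1]])
        perimeter = np.sum(np.linalg.norm(np.diff(closed, axis=0), axis=1))
        # Euclidean dilation of a 10x10 block by a radius-3 disk, iso-0.5
        # boundary: rounded square with straight sides 9 and corner radius 3.5
        expected = 4 * 9.0 + 2 * np.pi * 3.5
        assert perimeter == pytest.approx(expected, rel=0.05)

    def test_two_islands_keeps_larger(self):
        sl = np.zeros((64, 64))
        sl[10:30, 10:30] = 3000.0
        sl[45:50, 45:50] = 3000.0
        vol = CTVolume(np.stack([sl] * 3), spacing=(1, 1, 1))
        trace = extract_metal_contour(vol, 1, 800, 1)
        assert trace.points[:, 0].max() < 40  # never near the small island

    def test_no_metal_raises(self):
        vol = CTVolume(np.zeros((3, 32, 32)), spacing=(1, 1, 1))
        with pytest.raises(ValueError, match="no metal"):
            extract_metal_contour(vol, 1, 800, 3)

    def test_border_touching_metal_raises(self):
        sl = np.zeros((32, 32))
        sl[0:20, 0:20] = 3000.0
        vol = CTVolume(np.stack([sl] * 3), spacing=(1, 1, 1))
        with pytest.raises(ValueError, match="border"):
            extract_metal_contour(vol, 1, 800, 3)


def _circle_trace(hu, radius=10.0):
    n = len(hu)
    t = np.arange(n)
    pts = np.column_stack([20 + radius * np.sin(2 * np.pi * t / n),
                           20 + radius * np.cos(2 * np.pi * t / n)])
    return ContourTrace(points=pts, hu_samples=np.asarray(hu, float), slice_index=0)


class TestSpectrum:
    def test_constant_signal_is_dc_only(self):
        spec = compute_spectrum(_circle_trace(np.full(16, 123.0)))
        assert spec.amplitudes[0] == pytest.approx(16 * 123.0)
        np.testing.assert_allclose(spec.amplitudes[1:], 0.0, atol=1e-9)

    def test_cosine_closed_form(self):
        t = np.arange(8)
        spec = compute_spectrum(_circle_trace(np.cos(2 * np.pi * t / 8)))
        assert spec.amplitudes[1] == pytest.approx(4.0)
        assert spec.amplitudes[2] == pytest.approx(0.0, abs=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.lists(st.floats(-2000, 4000), min_size=8, max_size=64))
    def test_parseval_and_conjugate_symmetry(self, values):
        h = np.asarray(values)
        spec = compute_spectrum(_circle_trace(h))
        assert np.sum(spec.amplitudes**2) / len(h) == pytest.approx(
            np.sum(h**2), rel=1e-6, abs=1e-6
        )
        np.testing.assert_allclose(spec.amplitudes[1:], spec.amplitudes[1:][::-1], rtol=1e-9, atol=1e-7)

    def test_nonfinite_sample_rejected(self):
        h = np.full(16, 10.0)
        h[3] = np.inf
        with pytest.raises(ValueError, match="non-finite"):
            compute_spectrum(_circle_trace(h))


def _quiet_spec(**over):
    base = dict(noise_sd=0.0, streak=StreakSpec(amplitude_hu=0.0), bloom_sigma_mm=0.0, seed=0)
    base.update(over)
    return PhantomSpec(**base)


class TestAmplitudeLowFreq:
    def test_zero_streak_near_zero(self):
        vol, _ = generate_phantom(_quiet_spec())
        res = compute_amplitude_low_freq(vol, vol.shape[0] // 2)
        assert res.amplitude_low_freq < 0.01 * 8000.0 * CONTOUR_SAMPLES

    def test_cosine_streak_closed_form(self):
        # A = 50 HU first-order modulation -> per-slice |X_1|+|X_2| = A*N/2
        vol, _ = generate_phantom(
            _quiet_spec(streak=StreakSpec(amplitude_hu=50.0, angular_order=1, radial_decay_mm=1e6))
        )
        res = compute_amplitude_low_freq(vol, vol.shape[0] // 2)
        assert res.amplitude_low_freq == pytest.approx(50.0 * CONTOUR_SAMPLES / 2, rel=0.05)

    def test_identical_slices_zero_cv(self, disk_volume):
        res = compute_amplitude_low_freq(disk_volume, 1, metal_threshold=800)
        assert res.cv == pytest.approx(0.0, abs=1e-9)
        assert len(res.per_slice) == 3

    def test_dc_shift_and_start_point_invariance(self):
        t = np.arange(CONTOUR_SAMPLES)
        h = 30 * np.cos(2 * np.pi * t / CONTOUR_SAMPLES + 0.4)
        a0 = compute_spectrum(_circle_trace(h))
        a_shift = compute_spectrum(_circle_trace(h + 500.0))
        a_roll = compute_spectrum(_circle_trace(np.roll(h, 17)))
        low = lambda s: s.amplitudes[1] + s.amplitudes[2]
        assert low(a_shift) == pytest.approx(low(a0), rel=1e-9)
        assert low(a_roll) == pytest.approx(low(a0), rel=1e-9)


class TestBloomVol:
    def test_block_counting_oracle(self):
        data = np.zeros((20, 20, 20))
        data[5:15, 5:15, 5:15] = 3000.0
        vol = CTVolume(data, spacing=(1, 1, 1))
        res = compute_bloom_vol(vol, lower=800, upper=32762)
        assert res.volume_cm3 == pytest.approx(1.000)
        assert res.voxel_count == 1000

    def test_largest_component_rule(self):
        data = np.zeros((20, 20, 20))
        data[5:15, 5:15, 5:15] = 3000.0
        data[1, 1, 1:3] = 3000.0  # separate 2-voxel island
        vol = CTVolume(data, spacing=(1, 1, 1))
        assert compute_bloom_vol(vol, 800, 32762).voxel_count == 1000

    def test_cylinder_analytic_oracle(self):
        # r = 10 mm, h = 30 mm: pi * 1 * 3 cm^3 within 3%
        spec = _quiet_spec(grid_shape=(40, 128, 128), implant_height_mm=30.0)
        vol, truth = generate_phantom(spec)
        res = compute_bloom_vol(vol, lower=(8000 + 40) / 2, upper=32762)
        assert truth.true_volume_cm3 == pytest.approx(np.pi * 3.0, rel=1e-9)
        assert res.volume_cm3 == pytest.approx(np.pi * 3.0, rel=0.03)

    def test_monotone_in_lower_threshold(self):
        vol, _ = generate_phantom(PhantomSpec(seed=5))
        vols = [compute_bloom_vol(vol, lower=lo).volume_cm3 for lo in (3000, 2000, 800, 500)]
        assert all(b >= a for a, b in zip(vols, vols[1:]))

    def test_empty_band_raises(self):
        vol = CTVolume(np.zeros((4, 4, 4)), spacing=(1, 1, 1))
        with pytest.raises(ValueError, match="threshold band"):
            compute_bloom_vol(vol, 800, 32762)
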