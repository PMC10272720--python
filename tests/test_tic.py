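"""TICs, peak detection, peak matching, and peak-shift velocimetry."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ticvelo.geometry import extract_centerline, extract_vessel_mask
from ticvelo.image_io import AngioSequence
from ticvelo.phantom import PhantomConfig, generate_phantom
from ticvelo.tic import (
    ROI,
    PeakSet,
    TimeIntensityCurve,
    compute_tic,
    detect_peaks,
    estimate_velocity,
    place_rois,
    retention_ratio,
    roi_separation_mm,
)


def tic_from(values, fps=30.0):
    return TimeIntensityCurve(values=np.asarray(values, dtype=float), fps=fps)


def dip_curve(n, dips, depth=100.0, base=1000.0, width=3):
    """Baseline with triangular dips centered at the given frames."""
    y = np.full(n, base)
    for center in dips:
        for k in range(-width, width + 1):
            if 0 <= center + k < n:
                y[center + k] -= depth * (1 - abs(k) / (width + 1))
    return y


class TestComputeTic:
    def test_constant_sequence(self):
        seq = AngioSequence(np.full((4, 40, 40), 100, dtype=np.uint16), fps=30, resolution=0.2)
        roi = ROI(center_index=0, bounds=(10, 30, 10, 30))
        tic = compute_tic(seq, roi)
        np.testing.assert_allclose(tic.values, 100.0)
        assert len(tic) == 4 and tic.fps == 30

    def test_checkerboard_mean(self):
        frame = np.indices((40, 40)).sum(axis=0) % 2 * np.uint16(255)
        seq = AngioSequence(np.stack([frame, frame]), fps=30, resolution=0.2)
        tic = compute_tic(seq, ROI(center_index=0, bounds=(0, 20, 0, 20)))
        np.testing.assert_allclose(tic.values, 127.5)

    def test_out_of_bounds_roi(self):
        seq = AngioSequence(np.zeros((2, 40, 40), dtype=np.uint16), fps=30, resolution=0.2)
        with pytest.raises(ValueError, match="outside frame"):
            compute_tic(seq, ROI(center_index=0, bounds=(30, 50, 0, 20)))

    def test_single_pulse_single_minimum(self, straight_phantom):
        """A noiseless pulse passing the ROI gives a TIC whose global
        minimum is at the pulse-transit frame of the ROI center."""
        config, _, _ = straight_phantom
        single = PhantomConfig(n_pulses=1)
        seq, truth = generate_phantom(single)
        cl = extract_centerline(extract_vessel_mask(seq))
        roi, _ = place_rois(cl, seq, strategy="manual_indices", indices=(200, 400))
        tic = compute_tic(seq, roi)
        peaks = detect_peaks(tic)
        assert len(peaks) == 1
        r, c = cl.points[200]
        i_truth = int(np.argmin(np.linalg.norm(
            truth.centerline_points - np.array([r, c]), axis=1)))
        assert peaks.peak_frames[0] == truth.peak_pass_times[0, i_truth]


class TestDetectPeaks:
    def test_single_triangular_dip(self):
        tic = tic_from(dip_curve(60, [17]))
        peaks = detect_peaks(tic)
        assert list(peaks.peak_frames) == [17]

    def test_phantom_peak_count_and_times(self):
        """Four noiseless pulses give four detected peaks at the truth
        pass times of the ROI's arc position."""
        config = PhantomConfig(n_pulses=4)
        seq, truth = generate_phantom(config)
        cl = extract_centerline(extract_vessel_mask(seq))
        roi, _ = place_rois(cl, seq, strategy="manual_indices", indices=(150, 400))
        peaks = detect_peaks(compute_tic(seq, roi))
        assert len(peaks) == 4
        r, c = cl.points[150]
        i_truth = int(np.argmin(np.linalg.norm(
            truth.centerline_points - np.array([r, c]), axis=1)))
        np.testing.assert_array_equal(peaks.peak_frames, truth.peak_pass_times[:, i_truth])

    def test_exclude_first_drops_first_peak(self):
        tic = tic_from(dip_curve(120, [20, 50, 80]))
        all_peaks = detect_peaks(tic)
        rest = detect_peaks(tic, exclude_first=True)
        assert list(rest.peak_frames) == list(all_peaks.peak_frames)[1:]
        assert rest.excluded_first

    def test_prominence_filters_shallow_dip(self):
        y = dip_curve(90, [30])
        y[60] -= 2.0  # tiny dip, below 5% of dynamic range
        peaks = detect_peaks(tic_from(y))
        assert list(peaks.peak_frames) == [30]

    def test_no_peak_is_an_error(self):
        with pytest.raises(ValueError, match="TIC too short|no contrast peak"):
            detect_peaks(tic_from(np.linspace(0, 100, 50)))

    @settings(derandomize=True, max_examples=25)
    @given(scale=st.floats(0.05, 20.0), offset=st.floats(-500.0, 500.0))
    def test_affine_intensity_invariance(self, scale, offset):
        """Peak frames are invariant under monotone affine intensity maps."""
        base = dip_curve(120, [20, 55, 90])
        reference = detect_peaks(tic_from(base)).peak_frames
        mapped = detect_peaks(tic_from(scale * base + offset)).peak_frames
        np.testing.assert_array_equal(mapped, reference)

    def test_peakset_requires_increasing_frames(self):
        with pytest.raises(ValueError, match="increasing"):
            PeakSet(peak_frames=np.array([5, 5, 9]))


class TestPlaceRois:
    def test_manual_placement(self, straight_phantom):
        _, seq, _ = straight_phantom
        cl = extract_centerline(extract_vessel_mask(seq))
        prox, dist = place_rois(cl, seq, strategy="manual_indices", indices=(50, 250))
        assert prox.edge_px == dist.edge_px == 20
        for roi, idx in ((prox, 50), (dist, 250)):
            r, c = cl.points[idx]
            r0, r1, c0, c1 = roi.bounds
            assert abs((r0 + r1) / 2 - r) <= 1.0 and abs((c0 + c1) / 2 - c) <= 1.0

    def test_auto_ordering(self, straight_phantom):
        _, seq, _ = straight_phantom
        cl = extract_centerline(extract_vessel_mask(seq))
        prox, dist = place_rois(cl, seq, strategy="auto")
        assert prox.center_index < dist.center_index
        assert roi_separation_mm(cl, prox, dist, seq.resolution) > 0

    def test_auto_distal_before_fadeout(self):
        """With strong dispersion, the auto distal ROI sits where a TIC
        peak is still detectable (brute-force prominence above threshold)."""
        config = PhantomConfig(dispersion_px_per_frame=12.0, pulse_sigma_s=0.05)
        seq, _ = generate_phantom(config)
        cl = extract_centerline(extract_vessel_mask(seq))
        prox, dist = place_rois(cl, seq, strategy="auto", fade_fraction=0.1)
        dist_tic = compute_tic(seq, dist)
        peaks = detect_peaks(dist_tic, min_prominence=0.0)
        assert len(peaks) >= 1

    def test_overlapping_rois_rejected(self, straight_phantom):
        _, seq, _ = straight_phantom
        cl = extract_centerline(extract_vessel_mask(seq))
        with pytest.raises(ValueError, match="overlap"):
            place_rois(cl, seq, strategy="manual_indices", indices=(100, 110))

    def test_reversed_indices_rejected(self, straight_phantom):
        _, seq, _ = straight_phantom
        cl = extract_centerline(extract_vessel_mask(seq))
        with pytest.raises(ValueError, match="precede"):
            place_rois(cl, seq, strategy="manual_indices", indices=(250, 50))


class TestEstimateVelocity:
    def test_single_pair_arithmetic(self):
        """dx=20 mm, one peak pair 2 frames apart at 30 fps -> 300 mm/s, SD 0."""
        prox = tic_from(dip_curve(40, [10]))
        dist = tic_from(dip_curve(40, [12]))
        est = estimate_velocity(prox, dist, dx_mm=20.0)
        assert est.per_peak_velocities.tolist() == [300.0]
        assert est.mean_velocity == 300.0
        assert est.sd_velocity == 0.0
        assert est.per_peak_dt_frames.tolist() == [2]

    def test_three_pair_mean(self):
        """dt = {2, 2, 3} at dx = 20 mm, 30 fps -> {300, 300, 200}, mean 266.7."""
        prox = tic_from(dip_curve(120, [20, 50, 80]))
        dist = tic_from(dip_curve(120, [22, 52, 83]))
        est = estimate_velocity(prox, dist, dx_mm=20.0)
        np.testing.assert_allclose(est.per_peak_velocities, [300.0, 300.0, 200.0])
        assert est.mean_velocity == pytest.approx(266.7, abs=0.05)

    def test_nonpositive_delay_is_an_error(self):
        prox = tic_from(dip_curve(60, [20]))
        dist = tic_from(dip_curve(60, [20]))
        with pytest.raises(ValueError, match="non-positive peak delay"):
            estimate_velocity(prox, dist, dx_mm=20.0)

    def test_truncates_to_shorter_peak_list(self):
        prox = tic_from(dip_curve(120, [20, 50, 80]))
        dist = tic_from(dip_curve(120, [23, 53]))
        est = estimate_velocity(prox, dist, dx_mm=20.0)
        assert len(est.per_peak_velocities) == 2

    def test_subframe_refinement_close_to_integer_estimate(self):
        prox = tic_from(dip_curve(60, [15]))
        dist = tic_from(dip_curve(60, [19]))
        est_int = estimate_velocity(prox, dist, dx_mm=20.0)
        est_sub = estimate_velocity(prox, dist, dx_mm=20.0, subframe=True)
        assert est_sub.mean_velocity == pytest.approx(est_int.mean_velocity, rel=0.2)

    def test_quantization_band_on_phantom(self, straight_phantom):
        """Noiseless phantom: the estimate stays within the half-frame
        quantization band around the true transit time."""
        config, seq, truth = straight_phantom
        cl = extract_centerline(extract_vessel_mask(seq))
        prox, dist = place_rois(cl, seq, strategy="manual_indices", indices=(30, 430))
        dx = roi_separation_mm(cl, prox, dist, seq.resolution)
        est = estimate_velocity(compute_tic(seq, prox), compute_tic(seq, dist), dx)
        dt_true = dx * config.fps / truth.bolus_velocity
        low = dx * config.fps / (dt_true + 0.5)
        high = dx * config.fps / (dt_true - 0.5)
        assert low <= est.mean_velocity <= high

    def test_cross_correlation_oracle(self):
        """On noiseless single-pulse phantoms the detected peak shift equals
        the brute-force cross-correlation lag between inverted TICs."""
        # ROI separations are whole multiples of the per-frame bolus
        # advance, so the transit time is an integer number of frames and
        # both methods measure the same well-defined lag
        cases = [
            (PhantomConfig(n_pulses=1), 8),
            (PhantomConfig(n_pulses=1, fps=15.0, bolus_velocity=200.0), 6),
            (PhantomConfig(n_pulses=1, path_kind="sinusoid", shape=(128, 512),
                           bolus_velocity=250.0), 9),
        ]
        for config, dt_frames in cases:
            seq, _ = generate_phantom(config)
            cl = extract_centerline(extract_vessel_mask(seq))
            target_arc = cl.cumulative_arc_px[30] + dt_frames * config.px_per_frame
            i_dist = int(np.argmin(np.abs(cl.cumulative_arc_px - target_arc)))
            prox, dist = place_rois(cl, seq, strategy="manual_indices",
                                    indices=(30, i_dist))
            tic_p, tic_d = compute_tic(seq, prox), compute_tic(seq, dist)
            dx = roi_separation_mm(cl, prox, dist, seq.resolution)
            est = estimate_velocity(tic_p, tic_d, dx)

            a = -(tic_p.values - tic_p.values.mean())
            b = -(tic_d.values - tic_d.values.mean())
            n = len(a)
            lags = range(-n + 1, n)
            scores = []
            for lag in lags:
                s = sum(a[i] * b[i + lag] for i in range(n) if 0 <= i + lag < n)
                scores.append(s)
            best_lag = list(lags)[int(np.argmax(scores))]
            assert est.per_peak_dt_frames[0] == best_lag


class TestRetentionRatio:
    REFERENCE = [
        (441.4, 252.4, 57.2),
        (309.4, 200.2, 64.7),
        (285.3, 122.7, 43.0),
        (452.9, 249.1, 55.0),
        (255.6, 173.7, 68.0),
        (269.9, 192.5, 71.3),
    ]

    @pytest.mark.parametrize("before,after,expected", REFERENCE)
    def test_reference_values(self, before, after, expected):
        assert retention_ratio(before, after) == pytest.approx(expected, abs=0.05)

    def test_identity(self):
        assert retention_ratio(333.3, 333.3) == 100.0

    def test_nonpositive_before_rejected(self):
        with pytest.raises(ValueError):
            retention_ratio(0.0, 100.0)
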