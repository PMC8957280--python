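import itertools

import numpy as np
import pytest

from pulseline.detection import (
    DegenerateWindowError,
    DetectionSettings,
    PeakSet,
    classify_ecg_peaks,
    detect_peaks,
    make_window,
    reimpute_edge_amplitudes,
    scale_window,
)


class TestScaleWindow:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            ([0, 5, 10], [0, 50, 100]),
            ([2, 4, 3, 8], [0, 100 / 3, 100 / 6, 100]),
        ],
    )
    def test_affine_examples(self, raw, expected):
        np.testing.assert_allclose(scale_window(np.array(raw, float)), expected)

    def test_constant_window_degenerate(self):
        with pytest.raises(DegenerateWindowError):
            scale_window(np.array([-3.0, -3.0, -3.0]))

    def test_idempotent(self, rng):
        x = rng.normal(size=100)
        once = scale_window(x)
        np.testing.assert_allclose(scale_window(once), once, atol=1e-12)

    def test_invariant_to_positive_affine(self, rng):
        x = rng.normal(size=100)
        np.testing.assert_allclose(scale_window(3.7 * x - 11.0), scale_window(x), atol=1e-9)


def _raised_sine_window(freq=1.0, fs=1000.0, width=10.0):
    t = np.arange(int(width * fs) + 1) / fs
    return make_window(50 + 50 * np.sin(2 * np.pi * freq * (t - 0.25)), fs, 0.0, width)


class TestDetectPeaks:
    def test_one_peak_per_cycle(self):
        window = _raised_sine_window()
        peaks = detect_peaks(window, DetectionSettings())
        assert len(peaks) == 10
        np.testing.assert_allclose(np.diff(peaks.times), 1.0, atol=0.01)

    def test_min_distance_suppresses_close_crest(self):
        fs = 1000.0
        t = np.arange(int(10 * fs)) / fs
        y = np.zeros_like(t)
        # two crests 100 ms apart, second slightly taller, then regular ones
        for c, a in [(1.0, 0.9), (1.1, 1.0), (3.0, 1.0), (5.0, 1.0), (7.0, 1.0)]:
            y += a * np.exp(-0.5 * ((t - c) / 0.03) ** 2)
        window = make_window(y, fs, 0.0, 10.0)
        peaks = detect_peaks(window, DetectionSettings(min_amplitude=30))
        crest_times = peaks.times[(peaks.times > 0.8) & (peaks.times < 1.3)]
        assert len(crest_times) == 1
        assert crest_times[0] == pytest.approx(1.1, abs=0.01)

    def test_amplitude_threshold(self):
        fs = 1000.0
        t = np.arange(int(10 * fs)) / fs
        y = np.exp(-0.5 * ((t - 2.0) / 0.05) ** 2)  # height 100 after scaling
        y += 0.4 * np.exp(-0.5 * ((t - 5.0) / 0.05) ** 2)  # height ~40
        window = make_window(y, fs, 0.0, 10.0)
        at_50 = detect_peaks(window, DetectionSettings(min_amplitude=50))
        at_30 = detect_peaks(window, DetectionSettings(min_amplitude=30))
        assert len(at_50) == 1
        assert len(at_30) == 2

    def test_empty_peakset_allowed(self):
        fs = 1000.0
        window = make_window(np.linspace(0, 1, int(10 * fs)), fs, 0.0, 10.0)
        peaks = detect_peaks(window, DetectionSettings())
        assert len(peaks) == 0

    def test_properties_bounded(self):
        window = _raised_sine_window()
        peaks = detect_peaks(window, DetectionSettings())
        assert np.all(peaks.prominences <= peaks.heights + 1e-9)
        assert np.all(peaks.heights <= 100 + 1e-9)
        assert np.all(np.diff(peaks.times) > 0)


def _brute_force_kmeans(points, k=3):
    """Exhaustive minimum within-cluster sum of squares over all partitions."""
    n = len(points)
    best, best_labels = np.inf, None
    for labels in itertools.product(range(k), repeat=n):
        labels = np.array(labels)
        if len(set(labels.tolist())) != k:
            continue
        ss = 0.0
        for c in range(k):
            cluster = points[labels == c]
            ss += ((cluster - cluster.mean(axis=0)) ** 2).sum()
        if ss < best - 1e-12:
            best, best_labels = ss, labels
    return best_labels


class TestClassifyEcgPeaks:
    def test_three_separated_groups_r_cluster_chosen(self):
        # (width s, height, prominence): narrow/high R, wide/low P and T
        groups = {
            "r": (0.03, 95.0, 90.0),
            "t": (0.12, 25.0, 20.0),
            "p": (0.10, 18.0, 15.0),
        }
        times, widths, heights, proms, labels = [], [], [], [], []
        rng = np.random.default_rng(5)
        t = 0.2
        for beat in range(4):
            for name in ("p", "r", "t"):
                w, h, pr = groups[name]
                times.append(t)
                widths.append(w + rng.normal(0, 0.002))
                heights.append(h + rng.normal(0, 1.0))
                proms.append(pr + rng.normal(0, 1.0))
                labels.append(name)
                t += 0.3
        peaks = PeakSet(np.array(times), np.array(heights), np.array(proms), np.array(widths))
        kept = classify_ecg_peaks(peaks)
        expected_times = np.array(times)[np.array(labels) == "r"]
        np.testing.assert_allclose(kept.times, expected_times)
        # cross-check the partition against exhaustive minimisation
        feats = np.column_stack([widths, heights, proms])
        z = (feats - feats.mean(0)) / feats.std(0)
        brute = _brute_force_kmeans(z)
        r_label = brute[np.array(labels) == "r"][0]
        assert set(np.flatnonzero(brute == r_label)) == set(
            np.flatnonzero(np.array(labels) == "r")
        )

    def test_identical_features_fall_back(self):
        n = 8
        peaks = PeakSet(
            np.arange(n, dtype=float),
            np.full(n, 80.0),
            np.full(n, 75.0),
            np.full(n, 0.05),
        )
        kept = classify_ecg_peaks(peaks)
        assert kept.clustering_fallback
        assert len(kept) == n  # all above the default threshold

    def test_too_few_peaks_fall_back_with_threshold(self):
        peaks = PeakSet(
            np.array([0.0, 1.0, 2.0]),
            np.array([80.0, 40.0, 90.0]),
            np.array([75.0, 35.0, 85.0]),
            np.array([0.05, 0.1, 0.04]),
        )
        kept = classify_ecg_peaks(peaks)
        assert kept.clustering_fallback
        np.testing.assert_allclose(kept.heights, [80.0, 90.0])

    def test_recovers_generator_r_waves(self, ecg_recording):
        from pulseline.preprocess import preprocess

        prepared = preprocess(ecg_recording.signal)
        fs = prepared.sampling_rate
        window = make_window(prepared.samples[: int(20 * fs) + 1], fs, 0.0, 20.0)
        kept = detect_peaks(window, DetectionSettings(ecg_prt_clustering=True))
        truth = ecg_recording.beat_times[ecg_recording.beat_times <= 20.0]
        assert len(kept) == len(truth)
        errs = np.abs(kept.times - truth)
        assert np.max(errs) < 0.01


class TestReimputeEdges:
    def _window_and_peaks(self):
        fs = 1000.0
        t = np.arange(int(10 * fs)) / fs
        y = np.zeros_like(t)
        for c in np.arange(0.5, 10.0, 1.0):
            y += np.exp(-0.5 * ((t - c) / 0.05) ** 2)
        window = make_window(y, fs, 0.0, 10.0)
        peaks = detect_peaks(window, DetectionSettings())
        return window, peaks

    def test_interior_untouched_and_idempotent_on_clean(self):
        window, peaks = self._window_and_peaks()
        out = reimpute_edge_amplitudes(peaks, window)
        np.testing.assert_array_equal(out.prominences[1:-1], peaks.prominences[1:-1])
        np.testing.assert_allclose(out.prominences[0], peaks.prominences[0], atol=1e-6)

    def test_truncated_first_base_repaired(self):
        # First peak rides a raised baseline segment, so its raw prominence
        # is underestimated relative to the neighbour's baseline.
        fs = 1000.0
        t = np.arange(int(10 * fs)) / fs
        y = np.zeros_like(t)
        for c in np.arange(0.5, 10.0, 1.0):
            y += np.exp(-0.5 * ((t - c) / 0.05) ** 2)
        y[:300] += np.linspace(0.5, 0.0, 300)  # partial wave before first peak
        window = make_window(y, fs, 0.0, 10.0)
        peaks = detect_peaks(window, DetectionSettings(min_amplitude=40))
        out = reimpute_edge_amplitudes(peaks, window)
        neighbour_baseline = peaks.heights[1] - peaks.prominences[1]
        assert out.prominences[0] == pytest.approx(
            peaks.heights[0] - neighbour_baseline, abs=1e-9
        )
        assert out.prominences[0] >= peaks.prominences[0]

    def test_fewer_than_two_peaks_unchanged(self):
        single = PeakSet(np.array([1.0]), np.array([90.0]), np.array([80.0]), np.array([0.05]))
        assert reimpute_edge_amplitudes(single) is single
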