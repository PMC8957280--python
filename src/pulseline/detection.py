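"""Per-window peak detection.

Each analysis window is scaled to the 0-100 range before detection, so the
amplitude threshold is a percentage of the within-window dynamic range and
the detector is invariant to gain and offset of the recording.

For ECG, amplitude-only detection can latch onto prominent P or T waves.
The optional clustering mode drops the amplitude threshold to a near-zero
floor, detects every candidate deflection, and sorts candidates into three
clusters (k-means on peak width, height and prominence). R waves are the
cluster with the highest prominence and the lowest width; only those are
kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import find_peaks, peak_widths
from sklearn.cluster import KMeans

__all__ = [
    "DegenerateWindowError",
    "AnalysisWindow",
    "PeakSet",
    "DetectionSettings",
    "scale_window",
    "make_window",
    "detect_peaks",
    "classify_ecg_peaks",
    "reimpute_edge_amplitudes",
]

# Fixed k-means seed: reruns of the pipeline must be bit-identical.
_KMEANS_SEED = 171


class DegenerateWindowError(ValueError):
    """Raised when a window is constant and cannot be scaled to 0-100."""


@dataclass(frozen=True)
class AnalysisWindow:
    """One sliding-window excerpt, scaled to [0, 100]."""

    onset: float  # seconds from recording start
    width: float  # seconds
    samples: np.ndarray  # scaled amplitudes
    sampling_rate: float


@dataclass(frozen=True)
class PeakSet:
    """Detected peaks of one window, ordered by time.

    times
        Absolute peak times in seconds (recording clock), strictly increasing.
    heights
        Scaled amplitude at the peak, measured from the window minimum (0).
    prominences
        Scaled prominence of each peak.
    widths
        Peak width in seconds at half prominence.
    clustering_fallback
        True when ECG clustering was requested but not applicable, and plain
        thresholded detection was used instead.
    """

    times: np.ndarray
    heights: np.ndarray
    prominences: np.ndarray
    widths: np.ndarray
    clustering_fallback: bool = False

    def __len__(self) -> int:
        return len(self.times)

    def take(self, idx: np.ndarray) -> "PeakSet":
        order = np.sort(np.asarray(idx, dtype=int))
        return PeakSet(
            self.times[order],
            self.heights[order],
            self.prominences[order],
            self.widths[order],
            self.clustering_fallback,
        )


@dataclass(frozen=True)
class DetectionSettings:
    """Peak-detection thresholds, in scaled (0-100) units."""

    min_amplitude: float = 50.0
    min_distance_ms: float = 250.0
    ecg_prt_clustering: bool = False
    clustering_floor: float = 5.0

    def __post_init__(self) -> None:
        if not 0 <= self.min_amplitude <= 100:
            raise ValueError("min_amplitude must lie in [0, 100]")
        if self.min_distance_ms <= 0:
            raise ValueError("min_distance_ms must be > 0")


def scale_window(samples: np.ndarray) -> np.ndarray:
    """Affine map of one window onto [0, 100] (min -> 0, max -> 100)."""
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ValueError("window is empty")
    lo, hi = samples.min(), samples.max()
    if hi == lo:
        raise DegenerateWindowError("degenerate window: constant signal")
    return 100.0 * (samples - lo) / (hi - lo)


def make_window(
    samples: np.ndarray, sampling_rate: float, onset: float, width: float
) -> AnalysisWindow:
    """Scale a raw excerpt and wrap it as an AnalysisWindow."""
    return AnalysisWindow(onset, width, scale_window(samples), sampling_rate)


def detect_peaks(window: AnalysisWindow, settings: DetectionSettings) -> PeakSet:
    """Find local maxima above the amplitude threshold, at least
    ``min_distance_ms`` apart, with heights, prominences and widths.

    With ECG clustering on, detection runs at the near-zero clustering floor
    and `classify_ecg_peaks` is applied afterwards.
    """
    threshold = (
        settings.clustering_floor if settings.ecg_prt_clustering else settings.min_amplitude
    )
    distance = max(1, int(round(settings.min_distance_ms * window.sampling_rate / 1000.0)))
    idx, props = find_peaks(window.samples, height=threshold, distance=distance, prominence=0)
    if len(idx) == 0:
        empty = np.empty(0)
        return PeakSet(empty, empty.copy(), empty.copy(), empty.copy())
    width_samples = peak_widths(
        window.samples, idx, rel_height=0.5, prominence_data=(
            props["prominences"], props["left_bases"], props["right_bases"]
        ),
    )[0]
    peaks = PeakSet(
        times=window.onset + idx / window.sampling_rate,
        heights=props["peak_heights"],
        prominences=props["prominences"],
        widths=width_samples / window.sampling_rate,
    )
    if settings.ecg_prt_clustering:
        peaks = classify_ecg_peaks(peaks, default_threshold=settings.min_amplitude)
    return peaks


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def classify_ecg_peaks(peaks: PeakSet, default_threshold: float = 50.0) -> PeakSet:
    """Partition ECG candidate peaks into three clusters and keep R waves.

    Features are per-window z-scored (width, height, prominence); k-means
    with k = 3 and 10 restarts under a fixed seed. The retained cluster
    maximises (prominence z-centroid - width z-centroid); ties go to the
    narrower cluster. With fewer than 6 candidates, or fewer than 3 distinct
    feature vectors, clustering is not meaningful and detection falls back to
    plain amplitude thresholding at ``default_threshold``, flagged on the
    result.
    """
    features = np.column_stack([peaks.widths, peaks.heights, peaks.prominences])
    n_distinct = len(np.unique(features, axis=0))
    if len(peaks) < 6 or n_distinct < 3:
        keep = np.flatnonzero(peaks.heights >= default_threshold)
        return replace(peaks.take(keep), clustering_fallback=True)
    z = np.column_stack([_zscore(col) for col in features.T])
    km = KMeans(n_clusters=3, n_init=10, random_state=_KMEANS_SEED)
    labels = km.fit_predict(z)
    centroids = km.cluster_centers_  # columns: width, height, prominence (z)
    score = centroids[:, 2] - centroids[:, 0]
    best = np.flatnonzero(score == score.max())
    r_cluster = best[np.argmin(centroids[best, 0])]  # tie: narrower width
    return peaks.take(np.flatnonzero(labels == r_cluster))


def reimpute_edge_amplitudes(peaks: PeakSet, window: AnalysisWindow | None = None) -> PeakSet:
    """Recompute the prominences of the first and last peaks against the
    baseline of their nearest interior neighbour.

    A window can begin or end mid-beat, so the detected base of an edge peak
    may sit on e.g. a P wave, underestimating its prominence. The neighbour's
    baseline (height minus prominence) is a better estimate of the local
    baseline. Interior peaks are untouched; with fewer than 2 peaks the input
    is returned unchanged.
    """
    if len(peaks) < 2:
        return peaks
    prominences = peaks.prominences.copy()
    for edge, neighbour in ((0, 1), (-1, -2)):
        baseline = peaks.heights[neighbour] - peaks.prominences[neighbour]
        prominences[edge] = np.clip(peaks.heights[edge] - baseline, 0.0, peaks.heights[edge])
    return PeakSet(peaks.times, peaks.heights, prominences, peaks.widths,
                   peaks.clustering_fallback)
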