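"""Per-window heart rate and time-domain heart rate variability.

All interbeat intervals (IBIs) are carried in milliseconds. RMSSD divides
the sum of squared successive differences by the number of differences
(interval count minus one), the standard convention; SDNN and SDSD use the
sample (n-1) denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import welch

__all__ = [
    "IbiSeries",
    "WindowMetrics",
    "ibi_series",
    "compute_bpm",
    "compute_time_domain",
    "compute_hf_power",
]

HF_BAND = (0.15, 0.4)  # Hz
HF_RESAMPLE_HZ = 4.0
HF_MIN_INTERVALS = 4
HF_MIN_SPAN_S = 1.0 / HF_BAND[0] / 1.5  # one period of 0.15 Hz, 6.7 s


@dataclass(frozen=True)
class IbiSeries:
    """Interbeat intervals between neighbouring peaks, in milliseconds."""

    intervals: np.ndarray

    def __post_init__(self) -> None:
        intervals = np.asarray(self.intervals, dtype=float)
        object.__setattr__(self, "intervals", intervals)
        if np.any(intervals <= 0):
            raise ValueError("all interbeat intervals must be > 0")

    def __len__(self) -> int:
        return len(self.intervals)


@dataclass(frozen=True)
class WindowMetrics:
    bpm: float
    rmssd_ms: float
    sdnn_ms: float
    sdsd_ms: float
    pnn20: float
    pnn50: float
    hf_power: float  # ms^2, NaN when the window holds too little data


def ibi_series(peak_times: np.ndarray) -> IbiSeries:
    """Intervals (ms) between successive peak times (s)."""
    return IbiSeries(np.diff(np.asarray(peak_times, dtype=float)) * 1000.0)


def compute_bpm(peak_times: np.ndarray) -> float:
    """Beats per minute: (k - 1) * 60 / (t_last - t_first), k = peak count."""
    t = np.asarray(peak_times, dtype=float)
    if len(t) < 2:
        raise ValueError("BPM needs at least 2 peaks")
    return (len(t) - 1) * 60.0 / (t[-1] - t[0])


def compute_time_domain(ibis: IbiSeries) -> dict[str, float]:
    """RMSSD, SDNN, SDSD, PNN20 and PNN50 from one window's intervals.

    Returns NaN for measures whose minimum data requirement (2 intervals)
    is not met.
    """
    iv = ibis.intervals
    out = dict.fromkeys(("rmssd_ms", "sdnn_ms", "sdsd_ms", "pnn20", "pnn50"), float("nan"))
    if len(iv) >= 2:
        diffs = np.diff(iv)
        out["rmssd_ms"] = float(np.sqrt(np.mean(diffs**2)))
        out["sdnn_ms"] = float(np.std(iv, ddof=1))
        out["sdsd_ms"] = float(np.std(diffs, ddof=1)) if len(diffs) >= 2 else float("nan")
        out["pnn20"] = float(np.mean(np.abs(diffs) > 20.0))
        out["pnn50"] = float(np.mean(np.abs(diffs) > 50.0))
    return out


def compute_hf_power(peak_times: np.ndarray) -> float:
    """High-frequency power (0.15-0.4 Hz) of the IBI tachogram, in ms^2.

    The tachogram (IBI against beat time) is cubic-interpolated onto a
    uniform 4 Hz grid and integrated over the HF band of a Welch
    periodogram. Spectral estimation needs more data than the time-domain
    measures: with fewer than 4 intervals, or a beat span shorter than one
    period of the lower band edge, NaN is returned.
    """
    t = np.asarray(peak_times, dtype=float)
    if len(t) < HF_MIN_INTERVALS + 1:
        return float("nan")
    span = t[-1] - t[0]
    if span < HF_MIN_SPAN_S:
        return float("nan")
    ibis = np.diff(t) * 1000.0
    beat_t = t[1:]
    grid = np.arange(beat_t[0], beat_t[-1], 1.0 / HF_RESAMPLE_HZ)
    if len(grid) < 8:
        return float("nan")
    tachogram = CubicSpline(beat_t, ibis)(grid)
    tachogram = tachogram - tachogram.mean()
    nperseg = min(len(grid), 256)
    freqs, psd = welch(tachogram, fs=HF_RESAMPLE_HZ, nperseg=nperseg)
    band = (freqs >= HF_BAND[0]) & (freqs <= HF_BAND[1])
    return float(np.trapezoid(psd[band], freqs[band]))


def window_metrics(peak_times: np.ndarray) -> WindowMetrics:
    """All per-window measures from the detected peak times of one window."""
    td = compute_time_domain(ibi_series(peak_times))
    return WindowMetrics(
        bpm=compute_bpm(peak_times),
        hf_power=compute_hf_power(peak_times),
        **{k: td[k] for k in ("rmssd_ms", "sdnn_ms", "sdsd_ms", "pnn20", "pnn50")},
    )
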