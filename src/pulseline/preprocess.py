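"""Preprocessing of raw cardiac waveforms.

A raw single-channel recording (ECG or PPG) is turned into the series on
which sliding-window analysis runs by three stages, in order:

1. cubic-spline upsampling to a high uniform rate (default 1 kHz), which
   sharpens the temporal localisation of peaks detected later;
2. a zero-phase high-pass Butterworth filter (default 0.5 Hz) that removes
   baseline wander and the DC offset;
3. Savitzky-Golay smoothing (default 100 ms window, 3rd-order polynomial)
   that suppresses sharp spiking while preserving peak timing.

The Butterworth stage uses a 2nd-order design applied forward and backward
(``sosfiltfilt``), so peak times are not shifted and the effective magnitude
response is the square of the single-pass response.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import butter, savgol_filter, sosfiltfilt

__all__ = [
    "RawSignal",
    "PreparedSignal",
    "upsample",
    "highpass",
    "smooth",
    "preprocess",
]

DEFAULT_RESAMPLE_RATE = 1000.0
DEFAULT_HIGHPASS_HZ = 0.5
DEFAULT_SMOOTH_MS = 100.0
DEFAULT_SMOOTH_ORDER = 3


@dataclass(frozen=True)
class RawSignal:
    """A uniformly sampled single-channel waveform.

    Parameters
    ----------
    samples
        Amplitudes in arbitrary units. Must be non-empty and finite.
    sampling_rate
        Sampling rate in Hz, strictly positive.
    start_time
        Time of the first sample in seconds (default 0).
    """

    samples: np.ndarray
    sampling_rate: float
    start_time: float = 0.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if samples.ndim != 1 or samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(samples)):
            raise ValueError(
                "samples contain non-finite values; artifact handling is the "
                "cleaning stage's job, not the filters'"
            )

    @property
    def duration(self) -> float:
        """Time span from first to last sample, in seconds."""
        return (len(self.samples) - 1) / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        """Sample instants in seconds."""
        return self.start_time + np.arange(len(self.samples)) / self.sampling_rate


@dataclass(frozen=True)
class PreparedSignal(RawSignal):
    """A preprocessed waveform, ready for windowed analysis.

    ``provenance`` records the preprocessing configuration used to obtain it.
    """

    provenance: dict = field(default_factory=dict)


def upsample(signal: RawSignal, target_rate: float) -> RawSignal:
    """Resample to a higher rate with an interpolating cubic spline.

    The interpolant passes exactly through every original sample, so the
    waveform is unchanged at the original instants; the recording span is
    preserved to within one output sample.
    """
    if len(signal.samples) < 4:
        raise ValueError("signal too short: cubic spline interpolation needs >= 4 samples")
    if target_rate < signal.sampling_rate:
        raise ValueError("downsampling not supported here; use synth.downsample")
    if target_rate == signal.sampling_rate:
        return signal
    t_old = signal.times
    span = signal.duration
    n_out = int(round(span * target_rate)) + 1
    t_new = signal.start_time + np.arange(n_out) / target_rate
    # Guard against the last point drifting past the data by rounding error.
    t_new = np.minimum(t_new, t_old[-1])
    spline = CubicSpline(t_old, signal.samples)
    return RawSignal(spline(t_new), target_rate, signal.start_time)


def highpass(signal: RawSignal, cutoff_hz: float = DEFAULT_HIGHPASS_HZ) -> RawSignal:
    """Remove drift below ``cutoff_hz`` with a zero-phase Butterworth filter.

    Order-2 design applied forward and backward: no phase distortion, squared
    magnitude response.
    """
    nyquist = signal.sampling_rate / 2.0
    if not 0 < cutoff_hz < nyquist:
        raise ValueError(f"invalid cutoff: need 0 < cutoff < Nyquist ({nyquist} Hz)")
    sos = butter(2, cutoff_hz, btype="highpass", fs=signal.sampling_rate, output="sos")
    filtered = sosfiltfilt(sos, signal.samples)
    return RawSignal(filtered, signal.sampling_rate, signal.start_time)


def _window_samples(window_ms: float, sampling_rate: float, polyorder: int) -> int:
    """Savitzky-Golay window length in samples: nearest odd, >= polyorder + 2."""
    n = int(round(window_ms * sampling_rate / 1000.0))
    if n % 2 == 0:
        n += 1
    if n < polyorder + 2:
        raise ValueError(
            f"smoothing window too short: {window_ms} ms is {n} samples at "
            f"{sampling_rate} Hz, need at least {polyorder + 2}"
        )
    return n


def smooth(
    signal: RawSignal,
    window_ms: float = DEFAULT_SMOOTH_MS,
    polyorder: int = DEFAULT_SMOOTH_ORDER,
) -> RawSignal:
    """Savitzky-Golay smoothing; polynomials up to ``polyorder`` pass through
    unchanged away from the edges. Edges are mirror-padded."""
    n = _window_samples(window_ms, signal.sampling_rate, polyorder)
    if n % 2 == 0 or n < polyorder + 2:
        raise ValueError("smoothing window too short")
    if n >= len(signal.samples):
        raise ValueError("smoothing window too short relative to signal length")
    smoothed = savgol_filter(signal.samples, n, polyorder, mode="mirror")
    return RawSignal(smoothed, signal.sampling_rate, signal.start_time)


def preprocess(
    signal: RawSignal,
    resample_rate: float = DEFAULT_RESAMPLE_RATE,
    highpass_cutoff: float = DEFAULT_HIGHPASS_HZ,
    smoothing_window_ms: float = DEFAULT_SMOOTH_MS,
    smoothing_order: int = DEFAULT_SMOOTH_ORDER,
) -> PreparedSignal:
    """Full preprocessing chain: upsample, then high-pass, then smooth."""
    stage = upsample(signal, resample_rate)
    stage = highpass(stage, highpass_cutoff)
    stage = smooth(stage, smoothing_window_ms, smoothing_order)
    return PreparedSignal(
        samples=stage.samples,
        sampling_rate=resample_rate,
        start_time=signal.start_time,
        provenance={
            "resample_rate": resample_rate,
            "highpass_cutoff_hz": highpass_cutoff,
            "smoothing_window_ms": smoothing_window_ms,
            "smoothing_order": smoothing_order,
        },
    )
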