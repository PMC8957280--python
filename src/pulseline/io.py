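"""Reading and writing the plain-text formats the tool exchanges.

Two input dialects are supported for cardiac waveforms:

* single column — one amplitude per line, optional header; the sampling
  rate must be supplied by the caller;
* two columns (time, amplitude) — the time column must be uniformly
  spaced to within 1 ppm, and the sampling rate is inferred from it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .preprocess import RawSignal

__all__ = ["read_signal", "write_signal", "write_results", "read_results"]

_UNIFORMITY_PPM = 1e-6


def read_signal(path, sampling_rate: float | None = None) -> RawSignal:
    """Read a waveform CSV (one or two columns) into a RawSignal."""
    df = pd.read_csv(path, header=None, comment="#")
    # Tolerate a header row of non-numeric labels.
    try:
        df = df.astype(float)
    except (ValueError, TypeError):
        df = df.iloc[1:].astype(float)
    if df.shape[1] == 1:
        if sampling_rate is None:
            raise ValueError("single-column input requires an explicit sampling rate")
        return RawSignal(df.iloc[:, 0].to_numpy(), sampling_rate)
    if df.shape[1] == 2:
        t = df.iloc[:, 0].to_numpy()
        dt = np.diff(t)
        if len(dt) == 0:
            raise ValueError("two-column input needs at least 2 samples")
        mean_dt = dt.mean()
        if mean_dt <= 0 or np.any(np.abs(dt - mean_dt) > _UNIFORMITY_PPM * mean_dt):
            raise ValueError("time column must be uniformly spaced to within 1 ppm")
        inferred = 1.0 / mean_dt
        if sampling_rate is not None and not np.isclose(sampling_rate, inferred, rtol=1e-3):
            raise ValueError(
                f"supplied sampling rate {sampling_rate} Hz disagrees with the "
                f"time column ({inferred:.6g} Hz)"
            )
        return RawSignal(df.iloc[:, 1].to_numpy(), inferred, start_time=float(t[0]))
    raise ValueError("expected a one-column (amplitude) or two-column (time, amplitude) CSV")


def write_signal(signal: RawSignal, path, two_column: bool = False) -> None:
    """Write a waveform as CSV (amplitude only, or time + amplitude)."""
    if two_column:
        pd.DataFrame({"t": signal.times, "amplitude": signal.samples}).to_csv(path, index=False)
    else:
        pd.Series(signal.samples).to_csv(path, index=False, header=False)


def write_results(results: pd.DataFrame, path) -> None:
    """Write an analysis result table as CSV with a header row."""
    results.to_csv(path, index=False)


def read_results(path) -> pd.DataFrame:
    """Read an analysis result table back from CSV."""
    df = pd.read_csv(path)
    df["reasons"] = df["reasons"].fillna("")
    return df
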