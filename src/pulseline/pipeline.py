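"""Sliding-window orchestration: preprocess -> analyze -> visualize.

`analyze` slides a fixed-width window across a prepared signal (onsets 0,
m, 2m, ... while onset + width fits inside the recording; the trailing
partial window is dropped), runs scaling, peak detection, optional ECG
clustering, edge-amplitude re-imputation, metric computation and outlier
screening in each window, and returns one pandas DataFrame row per window.

Rows with ``accepted == True`` form the cleaned series; rows that merely
have enough peaks (no ``too_few_peaks`` / ``degenerate_window`` reason)
form the uncleaned series.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cleaning, detection, metrics as metrics_mod
from .cleaning import OutlierSettings, resolve_preset, screen_window
from .detection import DegenerateWindowError, DetectionSettings, make_window
from .preprocess import PreparedSignal, RawSignal

__all__ = [
    "AnalysisSettings",
    "analyze",
    "cleaned_series",
    "uncleaned_series",
    "visualize",
    "RESULT_COLUMNS",
]

logger = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "onset_s", "bpm", "rmssd", "sdnn", "sdsd", "pnn20", "pnn50", "hf",
    "n_peaks", "accepted", "reasons",
]

_SCREEN_ONLY_REASONS = {"too_few_peaks", "degenerate_window"}


@dataclass(frozen=True)
class AnalysisSettings:
    """Sliding-window, detection and rejection configuration.

    ``window_movement_s`` and ``window_overlap_s`` are two views of the same
    parameter (overlap = width - movement); give at most one.
    """

    window_width_s: float = 10.0
    window_movement_s: float | None = None
    window_overlap_s: float | None = None
    detection: DetectionSettings = field(default_factory=DetectionSettings)
    outliers: OutlierSettings | str = "moderate"

    def __post_init__(self) -> None:
        if self.window_movement_s is not None and self.window_overlap_s is not None:
            raise ValueError("give window_movement_s or window_overlap_s, not both")
        if isinstance(self.outliers, str):
            object.__setattr__(self, "outliers", resolve_preset(self.outliers))
        movement = self.movement
        if not 0 < movement <= self.window_width_s:
            raise ValueError("window movement must satisfy 0 < movement <= width")

    @property
    def movement(self) -> float:
        if self.window_overlap_s is not None:
            return self.window_width_s - self.window_overlap_s
        return self.window_movement_s if self.window_movement_s is not None else self.window_width_s


def _analyze_one_window(
    signal: PreparedSignal, onset: float, settings: AnalysisSettings
) -> dict:
    width = settings.window_width_s
    fs = signal.sampling_rate
    i0 = int(round((onset - signal.start_time) * fs))
    i1 = int(round((onset - signal.start_time + width) * fs)) + 1
    row = dict.fromkeys(RESULT_COLUMNS, float("nan"))
    row["onset_s"] = onset
    try:
        window = make_window(signal.samples[i0:i1], fs, onset, width)
    except DegenerateWindowError:
        row.update(n_peaks=0, accepted=False, reasons="degenerate_window")
        return row
    peaks = detection.detect_peaks(window, settings.detection)
    peaks = detection.reimpute_edge_amplitudes(peaks, window)
    row["n_peaks"] = len(peaks)
    if len(peaks) >= 2:
        ibis = metrics_mod.ibi_series(peaks.times)
        wm = metrics_mod.window_metrics(peaks.times)
        row.update(
            bpm=wm.bpm, rmssd=wm.rmssd_ms, sdnn=wm.sdnn_ms, sdsd=wm.sdsd_ms,
            pnn20=wm.pnn20, pnn50=wm.pnn50, hf=wm.hf_power,
        )
    else:
        ibis, wm = None, None
    verdict = screen_window(peaks, ibis, wm, width, settings.outliers)
    row["accepted"] = verdict.accepted
    row["reasons"] = ";".join(verdict.reasons + verdict.flags)
    return row


def analyze(signal: PreparedSignal | RawSignal, settings: AnalysisSettings | None = None) -> pd.DataFrame:
    """Run windowed HR/HRV extraction over a prepared signal.

    Returns one row per window position with onset, BPM, the time-domain
    HRV measures, HF power, peak count, the accepted flag and the
    semicolon-joined rejection reasons.
    """
    settings = settings or AnalysisSettings()
    duration = signal.duration
    width, movement = settings.window_width_s, settings.movement
    if duration < width:
        raise ValueError(
            f"signal ({duration:.3f} s) is shorter than one window ({width} s)"
        )
    n_windows = int(np.floor((duration - width) / movement + 1e-9)) + 1
    onsets = signal.start_time + movement * np.arange(n_windows)
    rows = [_analyze_one_window(signal, onset, settings) for onset in onsets]
    table = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    retained = table["accepted"].mean() if len(table) else float("nan")
    logger.info("analyzed %d windows, cleaned retention %.1f%%", len(table), 100 * retained)
    return table


def _screen_pass(reasons: pd.Series) -> pd.Series:
    """True where no minimum-peaks / degenerate reason is present."""
    return reasons.fillna("").map(
        lambda r: not (_SCREEN_ONLY_REASONS & set(r.split(";")))
    )


def uncleaned_series(results: pd.DataFrame) -> pd.DataFrame:
    """Windows passing only the sufficient-peaks screen."""
    return results[_screen_pass(results["reasons"])]


def cleaned_series(results: pd.DataFrame) -> pd.DataFrame:
    """Windows passing the full constraint battery."""
    return results[results["accepted"].astype(bool)]


def visualize(results: pd.DataFrame, metric: str = "bpm", path: str = "pulseline.png",
              cleaned_only: bool = False):
    """Static time-course plot of one metric; rejected windows marked.

    Returns the path written.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if metric not in results.columns or metric in ("reasons", "accepted", "onset_s"):
        raise ValueError(f"unknown metric {metric!r}")
    if results.empty:
        raise ValueError("no results to plot")
    fig, ax = plt.subplots(figsize=(10, 4))
    clean = cleaned_series(results)
    if cleaned_only and not clean.empty:
        ax.plot(clean["onset_s"], clean[metric], "-o", ms=3, label=f"{metric} (cleaned)")
    else:
        view = uncleaned_series(results)
        ax.plot(view["onset_s"], view[metric], "-o", ms=3, label=metric)
        rejected = view[~view["accepted"].astype(bool)]
        if not rejected.empty:
            ax.plot(rejected["onset_s"], rejected[metric], "x", color="crimson",
                    ms=7, label="rejected")
        if clean.empty:
            ax.annotate("no windows survived cleaning", xy=(0.5, 0.9),
                        xycoords="axes fraction", ha="center", color="crimson")
    ax.set_xlabel("window onset (s)")
    ax.set_ylabel(metric)
    ax.legend(loc="best")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
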