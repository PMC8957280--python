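"""Window-level artifact rejection.

Every analysis window passes through a battery of constraints:

* biological — the measures must be plausible for human physiology:
  a minimum number of peaks, BPM inside a preset range, RMSSD inside a
  preset range;
* statistical — the beats within the window must be mutually consistent:
  no peak height, prominence or interbeat interval may deviate from the
  window median by more than a preset number of MAD (median absolute
  deviation) units, and the detected beats must span at least half the
  window width.

Three named presets trade sensitivity against retention. The uncleaned
series applies only the minimum-peaks screen; the cleaned series applies
everything.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .detection import PeakSet
from .metrics import IbiSeries, WindowMetrics

__all__ = [
    "OutlierSettings",
    "WindowVerdict",
    "PRESETS",
    "resolve_preset",
    "mad_units",
    "biological_screen",
    "statistical_screen",
    "screen_window",
]

# Reasons that reject a window; informational flags do not.
_REJECTION_REASONS = frozenset(
    {
        "too_few_peaks",
        "bpm_range",
        "rmssd_range",
        "mad_height",
        "mad_prominence",
        "mad_ibi",
        "span_too_short",
        "degenerate_window",
    }
)
INFORMATIONAL_FLAGS = frozenset({"clustering_fallback"})

# Tolerance for the degenerate-MAD rule (MAD == 0): values within this
# absolute epsilon of the median pass, anything further is flagged.
_DEGENERATE_EPS_FACTOR = 1e-9

# Normal-consistency constant for the MAD: for Gaussian data
# 1.4826 * MAD estimates the standard deviation, so a threshold of
# "5 MAD units" is a robust z-score of 5 rather than 5 raw MAD multiples
# (~3.4 sigma, which ordinary beat-to-beat variability trips regularly).
MAD_NORMAL_CONSISTENCY = 1.4826


@dataclass(frozen=True)
class OutlierSettings:
    """Numeric thresholds of one rejection preset.

    BPM and RMSSD outside [min, max] are rejected; MAD thresholds are in
    MAD units.
    ``min_span_fraction`` is the minimum first-to-last-peak span as a
    fraction of the window width; ``min_peaks`` is the minimum peak count
    for any metric to be computed at all.
    """

    preset_name: str
    bpm_min: float
    bpm_max: float
    rmssd_min: float
    rmssd_max: float
    mad_threshold_peaks: float
    mad_threshold_ibi: float
    min_span_fraction: float = 0.5
    min_peaks: int = 3
    # Resolution floors for the MAD denominators (not strictness knobs):
    # on a near-perfect signal the raw MAD shrinks to numerical ripple and
    # any measurement-resolution jitter would explode into spurious "MAD
    # units". Deviations are therefore expressed against max(MAD, floor),
    # with floors at the scale of the measurement resolution: 0.5 scaled
    # units for heights/prominences (0-100 range), 2 ms for intervals
    # (peak-time quantisation at the 1 kHz analysis rate).
    mad_floor_peaks: float = 0.5
    mad_floor_ibi_ms: float = 2.0

    def __post_init__(self) -> None:
        if not (self.bpm_min < self.bpm_max and self.rmssd_min < self.rmssd_max):
            raise ValueError("interval bounds must satisfy min < max")
        if self.mad_threshold_peaks <= 0 or self.mad_threshold_ibi <= 0:
            raise ValueError("MAD thresholds must be > 0")


PRESETS: dict[str, OutlierSettings] = {
    "liberal": OutlierSettings("liberal", 20, 200, 0, 300, 7, 7),
    "moderate": OutlierSettings("moderate", 30, 190, 5, 262, 5, 5),
    "conservative": OutlierSettings("conservative", 40, 180, 10, 200, 4, 4),
}


@dataclass(frozen=True)
class WindowVerdict:
    """Outcome of screening one window."""

    accepted: bool
    reasons: tuple[str, ...] = ()
    flags: tuple[str, ...] = ()

    @staticmethod
    def from_reasons(reasons: list[str], flags: list[str] = ()) -> "WindowVerdict":
        reasons = tuple(dict.fromkeys(reasons))
        return WindowVerdict(accepted=not reasons, reasons=reasons, flags=tuple(flags))


def resolve_preset(name: str) -> OutlierSettings:
    """Look up a named preset (liberal / moderate / conservative)."""
    try:
        return PRESETS[name]
    except KeyError:
        valid = ", ".join(sorted(PRESETS))
        raise ValueError(f"unknown outlier preset {name!r}; valid presets: {valid}") from None


def mad_units(values: np.ndarray, floor: float = 0.0) -> np.ndarray:
    """Deviation of each value from the median, in MAD units (unscaled).

    ``floor`` puts a lower bound on the MAD denominator, expressing the
    measurement resolution below which spread is not meaningful. With a
    fully degenerate denominator (MAD zero and no floor) — all values at
    the median — any value farther than an absolute epsilon from the median
    is assigned an infinite deviation: a lone spike among identical values
    is exactly the artifact this rule targets.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 3:
        raise ValueError("MAD screening needs at least 3 values")
    med = np.median(values)
    abs_dev = np.abs(values - med)
    mad = max(np.median(abs_dev), floor)
    if mad == 0:
        eps = _DEGENERATE_EPS_FACTOR * max(abs(med), 1.0)
        return np.where(abs_dev > eps, np.inf, 0.0)
    return abs_dev / mad


def biological_screen(
    metrics: WindowMetrics | None,
    n_peaks: int,
    settings: OutlierSettings,
) -> list[str]:
    """Physiological-plausibility rules: peak count, BPM range, RMSSD range."""
    reasons: list[str] = []
    if n_peaks < settings.min_peaks:
        return ["too_few_peaks"]
    if metrics is None:
        return ["too_few_peaks"]
    # Values strictly outside the bounds are rejected; a value exactly at a
    # bound passes, so the liberal lower RMSSD bound of 0 imposes no
    # constraint.
    if metrics.bpm < settings.bpm_min or metrics.bpm > settings.bpm_max:
        reasons.append("bpm_range")
    if not np.isnan(metrics.rmssd_ms) and (
        metrics.rmssd_ms < settings.rmssd_min or metrics.rmssd_ms > settings.rmssd_max
    ):
        reasons.append("rmssd_range")
    return reasons


def statistical_screen(
    peaks: PeakSet,
    ibis: IbiSeries,
    window_width: float,
    settings: OutlierSettings,
) -> list[str]:
    """Within-window consistency rules: MAD of heights, prominences and
    intervals, plus minimum first-to-last-peak span.

    Thresholds are robust z-scores: deviations in raw MAD units are
    divided by the normal-consistency constant before comparison. MAD
    rules are skipped (cannot be assessed) with fewer than 3 values.
    """
    reasons: list[str] = []
    c = MAD_NORMAL_CONSISTENCY
    if len(peaks) >= 3:
        if np.any(mad_units(peaks.heights, settings.mad_floor_peaks)
                  > settings.mad_threshold_peaks * c):
            reasons.append("mad_height")
        if np.any(mad_units(peaks.prominences, settings.mad_floor_peaks)
                  > settings.mad_threshold_peaks * c):
            reasons.append("mad_prominence")
    if len(ibis) >= 3:
        if np.any(mad_units(ibis.intervals, settings.mad_floor_ibi_ms)
                  > settings.mad_threshold_ibi * c):
            reasons.append("mad_ibi")
    if len(peaks) >= 2:
        span = peaks.times[-1] - peaks.times[0]
        if span < settings.min_span_fraction * window_width:
            reasons.append("span_too_short")
    return reasons


def screen_window(
    peaks: PeakSet,
    ibis: IbiSeries | None,
    metrics: WindowMetrics | None,
    window_width: float,
    settings: OutlierSettings,
) -> WindowVerdict:
    """Combine the biological and statistical screens into one verdict.

    The verdict's ``accepted`` flag defines membership in the cleaned
    series; membership in the uncleaned series requires only that
    ``too_few_peaks`` (and ``degenerate_window``) are absent.
    """
    flags = ["clustering_fallback"] if peaks.clustering_fallback else []
    reasons = biological_screen(metrics, len(peaks), settings)
    if "too_few_peaks" not in reasons and ibis is not None:
        reasons += statistical_screen(peaks, ibis, window_width, settings)
    return WindowVerdict.from_reasons(reasons, flags)
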