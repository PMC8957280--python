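"""Validation statistics: ICC, RMSE, Cohen's d, paired-t power, jerk.

`icc_a1` is the two-way mixed-effects, absolute-agreement, single-measure
intraclass correlation (McGraw & Wong's ICC(A,1)), computed from the
two-way ANOVA mean squares of the subjects x raters table. It is the
agreement statistic used throughout the recovery studies, where the two
"raters" are ground truth and pipeline estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AccelSeries",
    "PowerSpec",
    "icc_a1",
    "icc_label",
    "rmse",
    "cohens_d_paired",
    "d_from_t",
    "paired_t_power",
    "paired_t_sample_size",
    "jerk_magnitude",
    "read_accel_csv",
]


@dataclass(frozen=True)
class AccelSeries:
    """Uniformly sampled triaxial accelerometer series (m/s^2)."""

    timestamps: np.ndarray  # seconds
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray

    def __post_init__(self) -> None:
        for name in ("timestamps", "ax", "ay", "az"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.timestamps)
        if any(len(getattr(self, a)) != n for a in ("ax", "ay", "az")):
            raise ValueError("axis series must have equal lengths")
        if n >= 2:
            dt = np.diff(self.timestamps)
            if np.any(np.abs(dt - dt.mean()) > 1e-6 * dt.mean()):
                raise ValueError("timestamps must be uniform to within 1 ppm")

    @property
    def dt(self) -> float:
        return float(np.mean(np.diff(self.timestamps)))


@dataclass(frozen=True)
class PowerSpec:
    """Design parameters of a paired t-test power calculation."""

    d: float
    alpha: float
    power: float
    sides: int = 2

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 < self.power < 1:
            raise ValueError("power must lie in (0, 1)")
        if self.d <= 0:
            raise ValueError("effect size d must be > 0")
        if self.sides not in (1, 2):
            raise ValueError("sides must be 1 or 2")


def icc_a1(x: np.ndarray, y: np.ndarray) -> float:
    """ICC(A,1): two-way, absolute agreement, single measure, two raters.

    From the two-way ANOVA decomposition of the n x 2 table with subjects
    as rows and raters as columns:

        ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    with MSR the rows (subjects) mean square, MSC the columns (raters)
    mean square and MSE the interaction/error mean square; k = 2 raters.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("icc_a1 expects two equal-length 1-D vectors")
    if len(x) < 3:
        raise ValueError("ICC needs at least 3 paired observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("icc_a1 expects finite values")
    table = np.column_stack([x, y])
    n, k = table.shape
    grand = table.mean()
    row_means = table.mean(axis=1)
    col_means = table.mean(axis=0)
    if np.allclose(table, grand):
        raise ValueError("ICC undefined: zero total variance")
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((table - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return float((msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n))


def icc_label(icc: float) -> str:
    """Conventional semantic label for an ICC value."""
    if icc < 0.5:
        return "poor"
    if icc < 0.75:
        return "moderate"
    if icc < 0.90:
        return "good"
    return "excellent"


def rmse(truth: np.ndarray, estimate: np.ndarray) -> float:
    """Root-mean-square error over pairs with a finite estimate."""
    truth = np.asarray(truth, dtype=float)
    estimate = np.asarray(estimate, dtype=float)
    if truth.shape != estimate.shape:
        raise ValueError("rmse expects equal-length vectors")
    ok = np.isfinite(truth) & np.isfinite(estimate)
    if not ok.any():
        raise ValueError("rmse: no valid pairs")
    return float(np.sqrt(np.mean((truth[ok] - estimate[ok]) ** 2)))


def cohens_d_paired(a: np.ndarray, b: np.ndarray) -> float:
    """Paired Cohen's d: mean(a - b) / sample SD of (a - b)."""
    diff = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    sd = np.std(diff, ddof=1)
    if sd == 0:
        raise ValueError("Cohen's d undefined: zero variance of differences")
    return float(np.mean(diff) / sd)


def d_from_t(t: float, n: int) -> float:
    """Cohen's d recovered from a paired t statistic with n pairs: t / sqrt(n)."""
    if n < 2:
        raise ValueError("need at least 2 pairs")
    return float(t / np.sqrt(n))


def paired_t_power(n: int, spec: PowerSpec) -> float:
    """Power of a paired t-test with n pairs, from the noncentral t."""
    if n < 2:
        return 0.0
    df = n - 1
    nc = spec.d * np.sqrt(n)
    if spec.sides == 2:
        tcrit = stats.t.ppf(1 - spec.alpha / 2, df)
        upper = stats.nct.sf(tcrit, df, nc)
        # Rejection in the wrong-signed tail; vanishingly small for d > 0 and
        # NaN-prone deep in the tail of scipy's nct, hence the guard.
        lower = stats.nct.cdf(-tcrit, df, nc)
        if not np.isfinite(lower):
            lower = 0.0
        return float(upper + lower)
    tcrit = stats.t.ppf(1 - spec.alpha, df)
    return float(stats.nct.sf(tcrit, df, nc))


def paired_t_sample_size(spec: PowerSpec, n_max: int = 10_000_000) -> int:
    """Smallest n pairs whose paired-t power reaches the target.

    Doubling bracket followed by binary search on the monotone power
    function.
    """
    lo, hi = 2, 4
    while paired_t_power(hi, spec) < spec.power:
        lo, hi = hi, hi * 2
        if hi > n_max:
            raise ValueError("target power unreachable within n_max pairs")
    while lo < hi:
        mid = (lo + hi) // 2
        if paired_t_power(mid, spec) >= spec.power:
            hi = mid
        else:
            lo = mid + 1
    return lo


def jerk_magnitude(accel: AccelSeries) -> tuple[np.ndarray, float]:
    """Per-sample triaxial jerk magnitudes (m/s^3) and their mean.

    Per-axis jerk is the first difference of acceleration divided by the
    sampling interval; the magnitude is the Euclidean norm across axes.
    """
    if len(accel.timestamps) < 2:
        raise ValueError("jerk needs at least 2 samples")
    dt = accel.dt
    jx = np.diff(accel.ax) / dt
    jy = np.diff(accel.ay) / dt
    jz = np.diff(accel.az) / dt
    mag = np.sqrt(jx**2 + jy**2 + jz**2)
    return mag, float(mag.mean())


def read_accel_csv(path) -> AccelSeries:
    """Read a t, ax, ay, az CSV into an AccelSeries."""
    df = pd.read_csv(path)
    cols = {c.lower().strip(): c for c in df.columns}
    try:
        return AccelSeries(
            df[cols["t"]].to_numpy(), df[cols["ax"]].to_numpy(),
            df[cols["ay"]].to_numpy(), df[cols["az"]].to_numpy(),
        )
    except KeyError as exc:
        raise ValueError("accelerometer CSV needs columns t, ax, ay, az") from exc
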