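"""Non-parametric rest-activity rhythm indicators: IS, IV, L5, M10, RA.

These five statistics characterize a rest-activity rhythm without assuming
any functional shape:

* **IS** (inter-daily stability) — variance of the mean 24 h profile over
  total variance, scaled so that a perfectly repeated day scores 1 and
  white noise scores ~1/d for d days.
* **IV** (intra-daily variability) — normalized mean squared successive
  difference; near 0 for a smooth 24 h sine, about 2 for white noise,
  larger for heavily fragmented rhythms.
* **L5 / M10** — mean activity in the least active 5 and most active 10
  consecutive hours of the average day (windows may wrap past midnight).
* **RA** (relative amplitude) — (M10 − L5)/(M10 + L5), the day-night
  contrast on a 0-1 scale.

IS and IV are computed on hourly means by convention; L5/M10 search the
averaged daily profile at its native resolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .actigraphy_io import (
    DEFAULT_COMPLETENESS_THRESHOLD,
    DEFAULT_MIN_DAYS,
    DailyProfile,
    EpochSeries,
    bin_series,
    daily_profile,
    trim_to_whole_days,
)
from .errors import DegenerateInputError, InsufficientDataError, ParameterError


@dataclass(frozen=True)
class NonparamResult:
    """The five indicators plus the clock onsets of the L5/M10 windows."""

    IS: float
    IV: float
    L5: float
    M10: float
    RA: float
    L5_onset: float
    M10_onset: float
    n_days: int
    resolution_IS_IV: int
    resolution_L5_M10: int


def interdaily_stability(binned: np.ndarray, p: int) -> float:
    """Inter-daily stability of an hourly-binned series.

    ``IS = n * sum_h (mean_h - mean)^2 / (p * sum_i (x_i - mean)^2)`` with
    n the number of data points, p the bins per day, ``mean_h`` the
    across-days mean at clock bin h. Invalid bins (NaN) are excluded from
    every sum. Ranges from ~0 (noise) to 1 (identical days).
    """
    x = np.asarray(binned, dtype=float)
    if len(x) < 2 * p:
        raise InsufficientDataError("IS needs at least 2 whole days")
    if len(x) % p != 0:
        raise ParameterError("binned length must be a multiple of p")
    grid = x.reshape(-1, p)
    valid = ~np.isnan(x)
    n = int(valid.sum())
    if n == 0 or np.nanstd(x) == 0:
        raise DegenerateInputError("IS undefined for constant input")
    mean = np.nanmean(x)
    hourly = np.nanmean(grid, axis=0)  # clock-time means over days
    num = n * np.nansum((hourly - mean) ** 2)
    den = p * np.nansum((x - mean) ** 2)
    return float(num / den)


def intradaily_variability(binned: np.ndarray) -> float:
    """Intra-daily variability: normalized mean squared successive difference.

    ``IV = n * sum_{i>=2} (x_i - x_{i-1})^2 / ((n-1) * sum_i (x_i - mean)^2)``.
    Differences are only taken between adjacent valid bins (pairwise
    deletion around gaps).
    """
    x = np.asarray(binned, dtype=float)
    valid = ~np.isnan(x)
    n = int(valid.sum())
    if n < 2:
        raise InsufficientDataError("IV needs at least 2 valid bins")
    if np.nanstd(x) == 0:
        raise DegenerateInputError("IV undefined for constant input")
    mean = np.nanmean(x)
    diffs = np.diff(x)
    adjacent = valid[1:] & valid[:-1]
    num = n * np.sum(diffs[adjacent] ** 2)
    den = (n - 1) * np.nansum((x - mean) ** 2)
    return float(num / den)


def _circular_window_means(values: np.ndarray, w: int) -> np.ndarray:
    """Mean of every length-w circular window, indexed by start bin."""
    ext = np.concatenate([values, values[: w - 1]])
    c = np.concatenate([[0.0], np.cumsum(ext)])
    return (c[w:] - c[:-w]) / w


def l5_m10(profile: DailyProfile) -> tuple[float, float, float, float]:
    """Least-active-5 h and most-active-10 h windows of the average day.

    Windows are circular (they may span midnight) and stepped at the
    profile resolution; ties break to the earliest start. Returns
    ``(L5, M10, L5_onset, M10_onset)`` with onsets in decimal clock hours.
    """
    hours_per_bin = profile.resolution / 3600
    w5 = round(5 / hours_per_bin)
    w10 = round(10 / hours_per_bin)
    if w5 < 1 or w10 > len(profile):
        raise ParameterError(
            "profile resolution too coarse for the 5 h / 10 h windows"
        )
    m5 = _circular_window_means(profile.values, w5)
    m10 = _circular_window_means(profile.values, w10)
    i5 = int(np.argmin(m5))  # argmin/argmax return the first optimum
    i10 = int(np.argmax(m10))
    return (
        float(m5[i5]),
        float(m10[i10]),
        i5 * hours_per_bin,
        i10 * hours_per_bin,
    )


def relative_amplitude(L5: float, M10: float) -> float:
    """Day-night contrast (M10 - L5)/(M10 + L5), in [0, 1] when M10 >= L5."""
    if M10 + L5 <= 0:
        raise DegenerateInputError("RA undefined when M10 + L5 = 0")
    return (M10 - L5) / (M10 + L5)


def nonparam_summary(
    series: EpochSeries,
    resolution_is_iv: int = 3600,
    resolution_l5_m10: int | None = None,
    completeness_threshold: float = DEFAULT_COMPLETENESS_THRESHOLD,
    min_days: int = DEFAULT_MIN_DAYS,
    trim: bool = True,
) -> NonparamResult:
    """Compute all five indicators for one subject-wave recording.

    The series is day-trimmed, binned hourly for IS/IV, and averaged into
    a daily profile at ``resolution_l5_m10`` (default: the native epoch
    length) for the window statistics.
    """
    try:
        trimmed = trim_to_whole_days(series) if trim else series
        if trimmed.n_whole_days < min_days:
            raise InsufficientDataError(
                f"{trimmed.n_whole_days} whole day(s) < required {min_days}"
            )
        if resolution_l5_m10 is None:
            resolution_l5_m10 = trimmed.epoch_length
        means, valid, _ = bin_series(
            trimmed, resolution_is_iv, completeness_threshold
        )
        hourly = np.where(valid, means, np.nan)
        p = 86400 // resolution_is_iv
        is_ = interdaily_stability(hourly, p)
        iv = intradaily_variability(hourly)
        prof = daily_profile(
            trimmed, resolution_l5_m10, completeness_threshold
        )
        l5, m10, l5_on, m10_on = l5_m10(prof)
        ra = relative_amplitude(l5, m10)
    except Exception as exc:
        exc.args = (
            f"subject {series.subject_id} wave {series.wave}: {exc}",
        )
        raise
    return NonparamResult(
        IS=is_,
        IV=iv,
        L5=l5,
        M10=m10,
        RA=ra,
        L5_onset=l5_on,
        M10_onset=m10_on,
        n_days=trimmed.n_whole_days,
        resolution_IS_IV=resolution_is_iv,
        resolution_L5_M10=resolution_l5_m10,
    )
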