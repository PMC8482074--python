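"""Reading, validation and temporal regularization of epoch-level actigraphy.

Wrist actigraphs record movement as non-negative activity counts per fixed
epoch (one minute in the supported protocol). This module parses the
delimited exports, masks off-wrist periods, aligns recordings to calendar
midnights, and aggregates epochs into clock-time bins — the substrate on
which the circadian indicators operate.

The plain text format is one header row ``subject_id,timestamp,activity,
off_wrist`` followed by one row per epoch. Device exports prepend an
arbitrary metadata preamble terminated by the same header line.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import (
    InsufficientDataError,
    ParameterError,
    StructuralError,
    ValidationError,
)

logger = logging.getLogger(__name__)

SECONDS_PER_DAY = 86400

PLAIN_HEADER = ("subject_id", "timestamp", "activity", "off_wrist")

#: A bin is usable when at least this fraction of its epochs are valid.
DEFAULT_COMPLETENESS_THRESHOLD = 0.5

#: A subject-wave enters rhythm analysis only with at least this many whole days.
DEFAULT_MIN_DAYS = 3


@dataclass(frozen=True)
class EpochSeries:
    """One subject-wave actigraphy recording on a regular epoch grid.

    Attributes
    ----------
    subject_id : str
        Opaque participant identifier.
    wave : int
        Weeks since baseline (0, 8, 16 or 24 in the supported design).
    start_time : pd.Timestamp
        Wall-clock time of the first epoch.
    epoch_length : int
        Seconds per epoch; must divide 3600 so epochs nest in clock hours.
    counts : np.ndarray
        Non-negative activity counts, one per epoch.
    valid_mask : np.ndarray
        Boolean, parallel to ``counts``; False marks off-wrist/missing epochs.
    """

    subject_id: str
    wave: int
    start_time: pd.Timestamp
    epoch_length: int
    counts: np.ndarray
    valid_mask: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        mask = np.asarray(self.valid_mask, dtype=bool)
        if counts.shape != mask.shape or counts.ndim != 1:
            raise ValidationError(
                "counts and valid_mask must be parallel 1-D sequences"
            )
        if self.epoch_length <= 0 or 3600 % self.epoch_length != 0:
            raise ValidationError(
                f"epoch_length {self.epoch_length} s must divide 3600"
            )
        if np.any(counts[mask] < 0):
            raise ValidationError("negative activity counts in valid epochs")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "valid_mask", mask)

    def __len__(self) -> int:
        return len(self.counts)

    @property
    def duration_seconds(self) -> int:
        return len(self) * self.epoch_length

    @property
    def epochs_per_day(self) -> int:
        return SECONDS_PER_DAY // self.epoch_length

    @property
    def n_whole_days(self) -> int:
        return len(self) // self.epochs_per_day

    @property
    def fraction_valid(self) -> float:
        return float(self.valid_mask.mean()) if len(self) else 0.0

    def epoch_times(self) -> pd.DatetimeIndex:
        return pd.date_range(
            self.start_time, periods=len(self), freq=f"{self.epoch_length}s"
        )


@dataclass(frozen=True)
class DailyProfile:
    """Across-days mean activity at each clock time of an average day."""

    resolution: int
    values: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if len(values) * self.resolution != SECONDS_PER_DAY:
            raise ValidationError(
                "profile length x resolution must equal 86400 s"
            )
        if np.any(values < 0):
            raise ValidationError("profile values must be non-negative")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return len(self.values)


def _parse_body(
    text_lines: list[str],
    first_data_lineno: int,
    subject_id: str | None,
    wave: int,
) -> EpochSeries:
    body = io.StringIO("\n".join(text_lines))
    df = pd.read_csv(body, dtype={"subject_id": str})
    missing = set(PLAIN_HEADER) - set(df.columns)
    if missing:
        raise StructuralError(f"missing columns: {sorted(missing)}")
    if df.empty:
        raise StructuralError("file contains no epoch rows")

    times = pd.to_datetime(df["timestamp"], format="%Y-%m-%dT%H:%M:%S")
    deltas = times.diff().dropna().dt.total_seconds().to_numpy()
    if len(deltas) == 0:
        epoch_length = 60
    else:
        epoch_length = deltas[0]
        bad = np.nonzero(deltas != epoch_length)[0]
        if len(bad):
            row = first_data_lineno + int(bad[0]) + 1
            raise StructuralError(
                f"non-constant epoch spacing at data row {row}: expected "
                f"{epoch_length:g} s, got {deltas[bad[0]]:g} s"
            )
        if epoch_length <= 0:
            raise StructuralError("timestamps are not strictly increasing")

    counts = pd.to_numeric(df["activity"], errors="coerce").to_numpy(float)
    if np.any(np.isnan(counts)):
        row = first_data_lineno + int(np.nonzero(np.isnan(counts))[0][0])
        raise StructuralError(f"non-numeric activity at data row {row}")
    off = df["off_wrist"].astype(int).to_numpy()
    if not np.isin(off, (0, 1)).all():
        raise ValidationError("off_wrist must be 0 or 1")
    valid = off == 0
    if np.any(counts[valid] < 0):
        row = first_data_lineno + int(np.nonzero(valid & (counts < 0))[0][0])
        raise ValidationError(f"negative activity count at data row {row}")
    # off-wrist counts are meaningless; zero them so invalid data can never leak
    counts = np.where(valid, counts, 0.0)

    sid = subject_id if subject_id is not None else str(df["subject_id"].iloc[0])
    return EpochSeries(
        subject_id=sid,
        wave=wave,
        start_time=times.iloc[0],
        epoch_length=int(epoch_length),
        counts=counts,
        valid_mask=valid,
    )


def read_epoch_file(
    path,
    dialect: str = "plain",
    subject_id: str | None = None,
    wave: int = 0,
) -> EpochSeries:
    """Parse an epoch-level actigraphy file into an :class:`EpochSeries`.

    Parameters
    ----------
    path : path-like
        Delimited text file.
    dialect : {"plain", "device_export"}
        ``plain`` expects the header as the first line; ``device_export``
        skips arbitrary preamble lines until the header line is found.
    subject_id, wave
        Override/annotate the series identity (wave defaults to 0).
    """
    if dialect not in ("plain", "device_export"):
        raise ParameterError(f"unknown dialect {dialect!r}")
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()

    header_line = ",".join(PLAIN_HEADER)
    if dialect == "plain":
        if not lines or lines[0].strip() != header_line:
            raise StructuralError(
                f"expected header {header_line!r} on line 1 of {path}"
            )
        start = 0
    else:
        try:
            start = next(
                i for i, ln in enumerate(lines) if ln.strip() == header_line
            )
        except StopIteration:
            raise StructuralError(
                f"no header line {header_line!r} found in device export {path}"
            ) from None
    return _parse_body(lines[start:], start + 2, subject_id, wave)


def write_epoch_file(series: EpochSeries, path) -> None:
    """Write a series in the plain dialect (inverse of :func:`read_epoch_file`)."""
    times = series.epoch_times().strftime("%Y-%m-%dT%H:%M:%S")
    df = pd.DataFrame(
        {
            "subject_id": series.subject_id,
            "timestamp": times,
            "activity": series.counts,
            "off_wrist": (~series.valid_mask).astype(int),
        }
    )
    df.to_csv(path, index=False)


def trim_to_whole_days(series: EpochSeries) -> EpochSeries:
    """Clip a recording to consecutive whole calendar days.

    The returned series starts at the first clock midnight at or after the
    recording start and keeps the maximal whole number of 24 h days. Day
    statistics (IS, IV, daily profiles) require clock-aligned days.
    """
    if series.duration_seconds < SECONDS_PER_DAY:
        raise InsufficientDataError(
            f"{series.subject_id}: recording spans "
            f"{series.duration_seconds / 3600:.1f} h, need >= 24 h"
        )
    start = series.start_time
    midnight = start.normalize()
    if midnight < start:
        midnight += pd.Timedelta(days=1)
    offset_epochs = int(
        (midnight - start).total_seconds() // series.epoch_length
    )
    remaining = len(series) - offset_epochs
    n_days = remaining // series.epochs_per_day
    if n_days < 1:
        raise InsufficientDataError(
            f"{series.subject_id}: fewer than one whole day after midnight "
            "alignment"
        )
    stop = offset_epochs + n_days * series.epochs_per_day
    logger.info(
        "%s wave %d: retained %d whole day(s) from %s",
        series.subject_id,
        series.wave,
        n_days,
        midnight,
    )
    return replace(
        series,
        start_time=midnight,
        counts=series.counts[offset_epochs:stop],
        valid_mask=series.valid_mask[offset_epochs:stop],
    )


def bin_series(
    series: EpochSeries,
    resolution: int,
    completeness_threshold: float = DEFAULT_COMPLETENESS_THRESHOLD,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Aggregate epochs into fixed-width bins of ``resolution`` seconds.

    Returns ``(bin_means, bin_valid, valid_fraction)`` where ``bin_means[k]``
    is the mean of the valid epochs in bin k (NaN when none), ``bin_valid``
    flags bins whose valid fraction reaches the completeness threshold, and
    ``valid_fraction`` gives that fraction per bin. A trailing partial bin
    is dropped.
    """
    if resolution % series.epoch_length != 0:
        raise ParameterError(
            f"resolution {resolution} s is not a multiple of the "
            f"{series.epoch_length} s epoch length"
        )
    if SECONDS_PER_DAY % resolution != 0:
        raise ParameterError(f"resolution {resolution} s must divide 86400")
    k = resolution // series.epoch_length
    n_bins = len(series) // k
    counts = series.counts[: n_bins * k].reshape(n_bins, k)
    mask = series.valid_mask[: n_bins * k].reshape(n_bins, k)
    n_valid = mask.sum(axis=1)
    with np.errstate(invalid="ignore"):
        means = np.where(
            n_valid > 0, (counts * mask).sum(axis=1) / np.maximum(n_valid, 1),
            np.nan,
        )
    frac = n_valid / k
    return means, frac >= completeness_threshold, frac


def daily_profile(
    series: EpochSeries,
    resolution: int,
    completeness_threshold: float = DEFAULT_COMPLETENESS_THRESHOLD,
) -> DailyProfile:
    """Average a day-trimmed series over days at each clock offset.

    ``values[k]`` is the mean over days of the (valid) bin at clock offset
    ``k * resolution`` seconds past midnight.
    """
    if series.n_whole_days < 1 or len(series) % series.epochs_per_day != 0:
        raise InsufficientDataError(
            "series must be day-trimmed before profiling"
        )
    means, valid, _ = bin_series(series, resolution, completeness_threshold)
    bins_per_day = SECONDS_PER_DAY // resolution
    days = len(means) // bins_per_day
    grid = np.where(valid, means, np.nan).reshape(days, bins_per_day)
    n_ok = np.sum(~np.isnan(grid), axis=0)
    if np.any(n_ok == 0):
        k = int(np.nonzero(n_ok == 0)[0][0])
        raise InsufficientDataError(
            f"no valid data at clock offset {k * resolution / 3600:.2f} h "
            "on any day"
        )
    profile = np.nanmean(grid, axis=0)
    return DailyProfile(resolution=resolution, values=profile)
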