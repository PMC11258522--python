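"""Nonparametric rest-activity rhythm (RAR) metrics.

Given a >=7-day minute-epoch acti-count series the module computes the
five standard nonparametric circadian indicators:

IS (interdaily stability)
    With ``X_i`` (i = 1..N) the hourly-averaged acti-counts, ``Xbar_h``
    (h = 1..p, p = 24) the mean over days at each clock hour, and ``Xbar``
    the grand mean::

        IS = (N * sum_h (Xbar_h - Xbar)^2) / (p * sum_i (X_i - Xbar)^2)

    the fraction of total hourly variance explained by the average 24-h
    template; in [0, 1], higher = more day-to-day regularity.

IV (intradaily variability)
    ::

        IV = (N * sum_{i=2..N} (X_i - X_{i-1})^2)
             / ((N - 1) * sum_i (X_i - Xbar)^2)

    the normalised mean-squared first difference of the hourly series;
    roughly in [0, 2] for rhythmic data (2 for white noise, up to 4 for a
    strictly alternating series), higher = more rest/activity
    fragmentation.

M10 / L5 / RA
    Within each calendar day, M10 is the largest mean over 10 consecutive
    hours (600-minute moving window) and L5 the smallest mean over 5
    consecutive hours (300-minute window); the composite M10/L5 average
    the daily values, and the relative amplitude is
    ``RA = (M10 - L5) / (M10 + L5)``.

Windows are searched at 1-minute resolution and constrained within the
calendar day by default; a midnight-wrapping (circular) search and an
hourly-resolution search are available as options.  An hour is valid when
at least 45 of its 60 minutes are present; a day containing any invalid
hour is excluded from every metric, and exclusions are reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConstantSeriesError, InsufficientDaysError, ValidationError
from .series import MINUTES_PER_DAY, EpochSeries

logger = logging.getLogger(__name__)

M10_MINUTES = 600
L5_MINUTES = 300
HOURS_PER_DAY = 24

__all__ = [
    "HourlySeries",
    "DayWindows",
    "RARMetrics",
    "hourly_average",
    "interdaily_stability",
    "intradaily_variability",
    "m10_l5_per_day",
    "composite_rar",
    "relative_amplitude",
]


@dataclass
class HourlySeries:
    """Hourly-averaged acti-counts, one row per day, 24 columns.

    ``values[d, h]`` is the mean acti-count over the valid minutes of
    clock-hour ``h`` of (retained) day ``d``; NaN marks an invalid hour.
    ``day_numbers`` keeps the original day index of each retained row so
    first differences across an excluded day can be recognised.
    """

    start_time: pd.Timestamp
    values: np.ndarray
    day_numbers: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != HOURS_PER_DAY:
            raise ValidationError("hourly values must have shape (days, 24)")
        if self.day_numbers is None:
            self.day_numbers = np.arange(self.values.shape[0])
        else:
            self.day_numbers = np.asarray(self.day_numbers, dtype=int)
        if self.day_numbers.shape != (self.values.shape[0],):
            raise ValidationError("day_numbers must match the number of day rows")

    @property
    def day_count(self) -> int:
        return self.values.shape[0]

    @property
    def n_hours(self) -> int:
        return self.values.size

    def flat(self) -> np.ndarray:
        """Chronological 1-D hourly series X_i."""
        return self.values.ravel()

    def template(self) -> np.ndarray:
        """24-point daily template Xbar_h (mean over days per clock hour)."""
        return self.values.mean(axis=0)

    def drop_invalid_days(self) -> tuple["HourlySeries", list[int]]:
        """Remove days containing any invalid (NaN) hour.

        Returns the reduced series and the original indices of the
        excluded days.
        """
        bad = np.isnan(self.values).any(axis=1)
        excluded = [int(d) for d in self.day_numbers[bad]]
        return (
            HourlySeries(self.start_time, self.values[~bad], self.day_numbers[~bad]),
            excluded,
        )


@dataclass
class DayWindows:
    """Per-day M10/L5 window statistics.

    Onsets are minutes after local midnight of the window start; the
    ``*_onset_clock`` properties render them as HH:MM clock time.
    """

    day: int
    date: pd.Timestamp
    m10: float
    l5: float
    m10_onset_min: int
    l5_onset_min: int

    @staticmethod
    def _clock(minutes: int) -> str:
        return f"{(minutes // 60) % 24:02d}:{minutes % 60:02d}"

    @property
    def m10_onset_clock(self) -> str:
        return self._clock(self.m10_onset_min)

    @property
    def l5_onset_clock(self) -> str:
        return self._clock(self.l5_onset_min)


@dataclass
class RARMetrics:
    """The five composite rest-activity rhythm indicators plus per-day detail."""

    IS: float
    IV: float
    M10: float
    L5: float
    RA: float
    per_day: list[DayWindows]
    n_days_used: int
    excluded_days: list[int]

    def as_dict(self) -> dict[str, float]:
        return {
            "IS": self.IS,
            "IV": self.IV,
            "M10": self.M10,
            "L5": self.L5,
            "RA": self.RA,
            "n_days_used": self.n_days_used,
        }


def _whole_day_matrix(epochs: EpochSeries) -> np.ndarray:
    """Reshape a midnight-aligned, whole-day epoch series to (days, 1440)."""
    if epochs.start_time != epochs.start_time.normalize():
        raise ValidationError(
            f"epoch series must start at local midnight (got {epochs.start_time})"
        )
    if epochs.n_minutes % MINUTES_PER_DAY != 0:
        raise ValidationError(
            f"epoch series must span whole days ({epochs.n_minutes} minutes given)"
        )
    return epochs.counts.reshape(-1, MINUTES_PER_DAY)


def hourly_average(epochs: EpochSeries, min_valid_minutes: int = 45) -> HourlySeries:
    """Average minute acti-counts into the hourly series X_i.

    Each X_i is the mean over the valid (non-missing) minutes of one clock
    hour; an hour with fewer than ``min_valid_minutes`` valid minutes is
    NaN (invalid).
    """
    days = _whole_day_matrix(epochs)
    cube = days.reshape(days.shape[0], HOURS_PER_DAY, 60)
    valid = ~np.isnan(cube)
    n_valid = valid.sum(axis=2)
    sums = np.where(valid, cube, 0.0).sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        hourly = np.where(n_valid >= min_valid_minutes, sums / np.maximum(n_valid, 1), np.nan)
    return HourlySeries(start_time=epochs.start_time, values=hourly)


def _check_series(h: HourlySeries, min_days: int) -> tuple[np.ndarray, float]:
    x = h.flat()
    if np.isnan(x).any():
        raise ValidationError(
            "hourly series contains invalid hours; drop invalid days first"
        )
    if h.day_count < min_days:
        raise InsufficientDaysError(
            f"insufficient days: {h.day_count} < {min_days} required"
        )
    ss_total = float(((x - x.mean()) ** 2).sum())
    if ss_total == 0.0:
        raise ConstantSeriesError("undefined: constant series")
    return x, ss_total


def interdaily_stability(h: HourlySeries) -> float:
    """Interdaily stability IS in [0, 1]; requires >= 2 days, nonconstant X."""
    x, ss_total = _check_series(h, min_days=2)
    template = h.template()
    ss_template = float(((template - x.mean()) ** 2).sum())
    return (h.n_hours * ss_template) / (HOURS_PER_DAY * ss_total)


def intradaily_variability(h: HourlySeries) -> float:
    """Intradaily variability IV >= 0; requires >= 3 hourly points, nonconstant X.

    First differences are only taken between hours adjacent in real time;
    pairs spanning an excluded day are skipped (with complete data this is
    the plain ``i = 2..N`` sum).
    """
    x, ss_total = _check_series(h, min_days=1)
    n = x.size
    if n < 3:
        raise ValidationError("need at least 3 hourly points for IV")
    diffs = np.diff(x)
    # hour i belongs to day day_numbers[i // 24]; a diff is contiguous when
    # the two hours sit in the same or consecutive original days
    day_of = np.repeat(h.day_numbers, HOURS_PER_DAY)
    contiguous = (day_of[1:] - day_of[:-1]) <= 1
    m = int(contiguous.sum())
    if m == 0:
        raise ValidationError("no contiguous hour pairs for IV")
    ss_diff = float((diffs[contiguous] ** 2).sum())
    return (n * ss_diff) / (m * ss_total)


def _window_means(day: np.ndarray, width: int, wrap: bool) -> np.ndarray:
    """Mean of every ``width``-minute window of one day, NaN-aware.

    Returns one mean per admissible start minute (1440 starts when
    wrapping, 1440 - width + 1 otherwise).
    """
    if wrap:
        day = np.concatenate([day, day[: width - 1]])
    valid = ~np.isnan(day)
    csum = np.concatenate([[0.0], np.where(valid, day, 0.0).cumsum()])
    cnum = np.concatenate([[0], valid.cumsum()])
    n_start = day.size - width + 1
    idx = np.arange(n_start)
    num = csum[idx + width] - csum[idx]
    den = cnum[idx + width] - cnum[idx]
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / np.maximum(den, 1), np.nan)


def _first_extremum(means: np.ndarray, mode: str) -> int:
    """Earliest window start attaining the max/min, tolerant of the
    ~1e-13 cumsum jitter that would otherwise break exact ties."""
    opt = np.nanmax(means) if mode == "max" else np.nanmin(means)
    tol = 1e-9 * max(1.0, abs(float(opt)))
    hits = np.flatnonzero(np.abs(means - opt) <= tol)
    return int(hits[0])


def m10_l5_per_day(
    epochs: EpochSeries,
    resolution: str = "minute",
    wrap: bool = False,
    min_valid_minutes: int = 45,
) -> tuple[list[DayWindows], list[int]]:
    """Most-active-10-h and least-active-5-h window per calendar day.

    M10_d maximises (and L5_d minimises) the mean acti-count over a
    600-minute (resp. 300-minute) moving window; by default the window is
    searched at 1-minute resolution and must lie fully inside the day
    (``wrap=True`` allows it to cross midnight circularly within the day's
    own profile).  Ties break toward the earliest onset.  Days with any
    invalid hour are excluded and returned separately.
    """
    if resolution not in ("minute", "hour"):
        raise ValidationError("resolution must be 'minute' or 'hour'")
    days = _whole_day_matrix(epochs)
    hourly = hourly_average(epochs, min_valid_minutes=min_valid_minutes)
    bad_days = np.isnan(hourly.values).any(axis=1)

    out: list[DayWindows] = []
    excluded: list[int] = []
    for d in range(days.shape[0]):
        if bad_days[d]:
            excluded.append(d)
            continue
        if resolution == "minute":
            profile = days[d]
            m_means = _window_means(profile, M10_MINUTES, wrap)
            l_means = _window_means(profile, L5_MINUTES, wrap)
            m_idx = _first_extremum(m_means, "max")
            l_idx = _first_extremum(l_means, "min")
            m10, l5 = float(m_means[m_idx]), float(l_means[l_idx])
            m_onset, l_onset = m_idx, l_idx
        else:
            profile = hourly.values[d]
            m_means = _window_means(profile, 10, wrap)
            l_means = _window_means(profile, 5, wrap)
            m_idx = _first_extremum(m_means, "max")
            l_idx = _first_extremum(l_means, "min")
            m10, l5 = float(m_means[m_idx]), float(l_means[l_idx])
            m_onset, l_onset = m_idx * 60, l_idx * 60
        out.append(
            DayWindows(
                day=d,
                date=epochs.start_time + pd.Timedelta(days=d),
                m10=m10,
                l5=l5,
                m10_onset_min=m_onset,
                l5_onset_min=l_onset,
            )
        )
    return out, excluded


def relative_amplitude(m10: float, l5: float) -> float:
    """RA = (M10 - L5) / (M10 + L5); NaN when both windows are zero."""
    if m10 < 0 or l5 < 0:
        raise ValidationError("M10 and L5 must be nonnegative")
    total = m10 + l5
    if total == 0:
        logger.warning("RA undefined: M10 + L5 == 0; returning NaN")
        return float("nan")
    return (m10 - l5) / total


def composite_rar(
    epochs: EpochSeries,
    min_days: int = 7,
    force: bool = False,
    resolution: str = "minute",
    wrap: bool = False,
    min_valid_minutes: int = 45,
) -> RARMetrics:
    """All five RAR indicators from a whole-day epoch series.

    Composite M10/L5 average the per-day window means over the retained
    days; RA is computed from the composites (not as a mean of daily RAs);
    IS/IV come from the retained hourly series.  Fewer than ``min_days``
    retained days raises unless ``force=True`` (logged).
    """
    hourly = hourly_average(epochs, min_valid_minutes=min_valid_minutes)
    valid_hourly, excluded = hourly.drop_invalid_days()
    if excluded:
        logger.warning("excluding days with invalid hours: %s", excluded)
    if valid_hourly.day_count < min_days:
        msg = f"insufficient days: {valid_hourly.day_count} valid < {min_days} required"
        if not force:
            raise InsufficientDaysError(msg)
        logger.warning("%s -- proceeding (force=True)", msg)
    per_day, excluded_w = m10_l5_per_day(
        epochs, resolution=resolution, wrap=wrap, min_valid_minutes=min_valid_minutes
    )
    assert excluded_w == excluded
    m10 = float(np.mean([d.m10 for d in per_day]))
    l5 = float(np.mean([d.l5 for d in per_day]))
    return RARMetrics(
        IS=interdaily_stability(valid_hourly),
        IV=intradaily_variability(valid_hourly),
        M10=m10,
        L5=l5,
        RA=relative_amplitude(m10, l5),
        per_day=per_day,
        n_days_used=valid_hourly.day_count,
        excluded_days=excluded,
    )
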