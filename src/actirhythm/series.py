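"""Core time-series containers and their plain-text (CSV) representations.

Three containers follow the signal through the pipeline:

``AccelRecording``
    Raw tri-axial wrist acceleration in g-units at a fixed sample rate.
``SampleSeries``
    A scalar sample-rate signal derived from the recording (gravity-removed
    magnitude, or the band-passed version of it).
``EpochSeries``
    Minute-epoch acti-counts: one nonnegative activity value per minute,
    NaN marking an explicitly missing minute.  This is the substrate of all
    rest-activity rhythm metrics.

Timestamps are naive local clock time; the day boundary is local midnight,
because M10/L5 are clock-time quantities.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import CsvFormatError, ValidationError

MINUTES_PER_DAY = 1440
#: Default start used by the simulator (an arbitrary local midnight Monday).
DEFAULT_START = pd.Timestamp("2024-01-01 00:00")

_TS_FMT = "%Y-%m-%dT%H:%M"


def _as_minute_timestamp(ts) -> pd.Timestamp:
    ts = pd.Timestamp(ts)
    if ts.second or ts.microsecond or ts.nanosecond:
        raise ValidationError(f"timestamp {ts} is not minute-aligned")
    return ts


@dataclass
class AccelRecording:
    """Raw tri-axial acceleration samples at a fixed rate.

    Parameters
    ----------
    start_time : timestamp
        Minute-aligned local start time of the recording.
    sample_rate : float
        Samples per second; must exceed 6 Hz so the 0.5-3 Hz movement band
        is representable.
    samples : ndarray, shape (n, 3)
        Per-sample (ax, ay, az) in g-units.
    """

    start_time: pd.Timestamp
    sample_rate: float
    samples: np.ndarray

    def __post_init__(self):
        self.start_time = _as_minute_timestamp(self.start_time)
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValidationError("samples must have shape (n, 3)")
        if self.samples.shape[0] == 0:
            raise ValidationError("empty recording")
        if not self.sample_rate > 6.0:
            raise ValidationError(
                f"sample_rate {self.sample_rate} Hz too low; need > 6 Hz "
                "for the 0.5-3 Hz movement band"
            )

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate


@dataclass
class SampleSeries:
    """Scalar signal at the recording's sample rate (pre-epoch stage)."""

    start_time: pd.Timestamp
    sample_rate: float
    values: np.ndarray

    def __post_init__(self):
        self.start_time = pd.Timestamp(self.start_time)
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size == 0:
            raise ValidationError("empty sample series")


@dataclass
class EpochSeries:
    """1-minute acti-count series.

    ``counts`` is a 1-D float array, one entry per minute starting at
    ``start_time``; entries are nonnegative, with NaN marking an explicitly
    missing minute (gaps are never implicit).
    """

    start_time: pd.Timestamp
    counts: np.ndarray

    def __post_init__(self):
        self.start_time = _as_minute_timestamp(self.start_time)
        self.counts = np.asarray(self.counts, dtype=float).ravel()
        if self.counts.size == 0:
            raise ValidationError("empty epoch series")
        finite = self.counts[~np.isnan(self.counts)]
        if finite.size and finite.min() < 0:
            raise ValidationError("acti-counts must be nonnegative")

    @property
    def n_minutes(self) -> int:
        return self.counts.size

    @property
    def n_days(self) -> int:
        """Number of whole 1440-minute days covered."""
        return self.counts.size // MINUTES_PER_DAY

    def timestamps(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start_time, periods=self.n_minutes, freq="min")


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def write_epoch_csv(series: EpochSeries, path) -> None:
    """Write an :class:`EpochSeries` as ``timestamp,counts`` CSV.

    Missing minutes are written as rows with an empty ``counts`` field, so
    gaps stay explicit and the round-trip is lossless.
    """
    ts = series.timestamps()
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["timestamp", "counts"])
        for t, c in zip(ts, series.counts):
            w.writerow([t.strftime(_TS_FMT), "" if np.isnan(c) else repr(float(c))])


def read_epoch_csv(path) -> EpochSeries:
    """Read a ``timestamp,counts`` CSV written by :func:`write_epoch_csv`.

    Rejects non-monotone or duplicated timestamps and malformed rows,
    naming the offending line number.
    """
    times: list[pd.Timestamp] = []
    counts: list[float] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header[:2]] != ["timestamp", "counts"]:
            raise CsvFormatError(f"{path}: line 1: expected header 'timestamp,counts'")
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 2:
                raise CsvFormatError(f"{path}: line {lineno}: expected 2 fields, got {len(row)}")
            try:
                ts = _as_minute_timestamp(pd.Timestamp(row[0]))
            except (ValueError, ValidationError) as exc:
                raise CsvFormatError(f"{path}: line {lineno}: bad timestamp {row[0]!r}: {exc}") from exc
            if row[1].strip() == "":
                val = np.nan
            else:
                try:
                    val = float(row[1])
                except ValueError as exc:
                    raise CsvFormatError(f"{path}: line {lineno}: bad count {row[1]!r}") from exc
                if val < 0:
                    raise CsvFormatError(f"{path}: line {lineno}: negative count {val}")
            times.append(ts)
            counts.append(val)
    if not times:
        raise CsvFormatError(f"{path}: no data rows")
    for i in range(1, len(times)):
        delta = (times[i] - times[i - 1]).total_seconds()
        if delta == 0:
            raise CsvFormatError(f"{path}: line {i + 2}: duplicated minute {times[i]}")
        if delta != 60:
            raise CsvFormatError(
                f"{path}: line {i + 2}: non-contiguous timestamp {times[i]} "
                "(gaps must be explicit empty-count rows)"
            )
    return EpochSeries(start_time=times[0], counts=np.array(counts))


def write_accel_csv(rec: AccelRecording, path) -> None:
    """Write raw acceleration as ``timestamp,ax,ay,az`` CSV (g-units)."""
    step = 1.0 / rec.sample_rate
    t0 = rec.start_time
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["timestamp", "ax", "ay", "az"])
        for i, (ax, ay, az) in enumerate(rec.samples):
            t = t0 + pd.Timedelta(seconds=i * step)
            w.writerow([t.isoformat(), repr(float(ax)), repr(float(ay)), repr(float(az))])


def read_accel_csv(path, sample_rate: float | None = None) -> AccelRecording:
    """Read a ``timestamp,ax,ay,az`` CSV.

    The sample rate is inferred from the first two timestamps unless given
    explicitly.
    """
    rows: list[tuple[float, float, float]] = []
    times: list[pd.Timestamp] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header[:4]] != ["timestamp", "ax", "ay", "az"]:
            raise CsvFormatError(f"{path}: line 1: expected header 'timestamp,ax,ay,az'")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 4:
                raise CsvFormatError(f"{path}: line {lineno}: expected 4 fields")
            try:
                times.append(pd.Timestamp(row[0]))
                rows.append((float(row[1]), float(row[2]), float(row[3])))
            except ValueError as exc:
                raise CsvFormatError(f"{path}: line {lineno}: {exc}") from exc
    if len(rows) < 2 and sample_rate is None:
        raise CsvFormatError(f"{path}: need >= 2 rows to infer sample rate")
    if sample_rate is None:
        dt = (times[1] - times[0]).total_seconds()
        if dt <= 0:
            raise CsvFormatError(f"{path}: non-increasing timestamps")
        sample_rate = 1.0 / dt
    return AccelRecording(start_time=times[0], sample_rate=sample_rate, samples=np.array(rows))
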