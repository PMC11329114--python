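"""Reading, writing and windowing of DAM-style activity monitor files.

Trikinetics-style monitors report one row per minute.  Two dialects are
supported through the same reader:

* a *per-beam* dialect in which each row carries one integer count per
  infrared beam (multi-beam monitors place several beams along each fly
  tube), and
* a *per-tube* dialect in which counts have already been summed over the
  beams of each tube (the output of :func:`sum_beams` /
  :func:`write_summed_file`, and the natural form of single-beam
  monitors).

The default row structure is tab-separated::

    index  date  time  status  m1 m2 m3 m4 m5 m6  light  c1 c2 ... cN

with ``date`` as ``DD Mon YY``, ``time`` as ``HH:MM:SS``, six integer
metadata columns, a binary light-sensor column, and ``N`` count columns
whose geometry is described by a :class:`BeamLayout`.  The geometry is
fully configurable so that other monitor firmware dialects can be read
without code changes.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from damsleep.errors import (
    AlignmentError,
    DataError,
    MonitorParseError,
    ParameterError,
    WindowError,
)

#: Number of leading non-count columns in the default dialect:
#: index, date, time, status, six metadata columns, light flag.
DEFAULT_COUNT_COLUMNS_START = 11

_DATE_FORMAT = "%d %b %y"
_TIME_FORMAT = "%H:%M:%S"


@dataclass(frozen=True)
class BeamLayout:
    """Geometry of the count columns of a monitor file.

    Parameters
    ----------
    tubes_per_monitor
        Number of fly tubes the monitor holds.
    beams_per_tube
        Number of infrared beams crossing each tube.  Multi-beam
        monitors use 15; classic single-beam monitors use 1 (which also
        describes the per-tube summed dialect).
    count_columns_start
        Zero-based column index at which count columns begin.
    beam_order
        Optional mapping from count-column offset to ``(tube, beam)``
        pairs (both zero-based).  Defaults to tube-major order: the
        first ``beams_per_tube`` columns belong to tube 0, and so on.
    """

    tubes_per_monitor: int
    beams_per_tube: int = 15
    count_columns_start: int = DEFAULT_COUNT_COLUMNS_START
    beam_order: Mapping[int, tuple[int, int]] | None = field(default=None)

    def __post_init__(self) -> None:
        if self.tubes_per_monitor < 1 or self.beams_per_tube < 1:
            raise ParameterError("tubes_per_monitor and beams_per_tube must be >= 1")
        n = self.n_count_columns
        if self.beam_order is not None:
            pairs = set(self.beam_order.values())
            expected = {
                (t, b)
                for t in range(self.tubes_per_monitor)
                for b in range(self.beams_per_tube)
            }
            if set(self.beam_order.keys()) != set(range(n)) or pairs != expected:
                raise ParameterError(
                    "beam_order must be a bijection from column offsets "
                    f"0..{n - 1} onto all (tube, beam) pairs"
                )

    @property
    def n_count_columns(self) -> int:
        return self.tubes_per_monitor * self.beams_per_tube

    def tube_of_column(self) -> np.ndarray:
        """Tube index (zero-based) of each count column, in column order."""
        if self.beam_order is None:
            return np.repeat(
                np.arange(self.tubes_per_monitor), self.beams_per_tube
            )
        out = np.empty(self.n_count_columns, dtype=int)
        for offset, (tube, _beam) in self.beam_order.items():
            out[offset] = tube
        return out


@dataclass(frozen=True)
class LightSchedule:
    """A rectangular light:dark schedule.

    ``lights_on_clock_time`` is the wall-clock time of lights-on;
    the photoperiod lasts ``photoperiod_hours`` of every
    ``cycle_hours``-hour cycle.  Phase intervals are half-open:
    the lights-on minute belongs to day, the lights-off minute to night.
    """

    lights_on_clock_time: _dt.time = _dt.time(8, 0)
    photoperiod_hours: float = 12.0
    cycle_hours: float = 24.0

    def __post_init__(self) -> None:
        if not 0 < self.photoperiod_hours < self.cycle_hours:
            raise ParameterError("need 0 < photoperiod_hours < cycle_hours")

    def zt_hours(self, timestamps: pd.DatetimeIndex) -> np.ndarray:
        """Zeitgeber time in hours (ZT0 = lights-on) for each timestamp."""
        on = self.lights_on_clock_time
        minutes = (
            timestamps.hour * 60 + timestamps.minute - (on.hour * 60 + on.minute)
        )
        cycle_min = self.cycle_hours * 60
        return np.asarray(minutes % cycle_min, dtype=float) / 60.0

    def is_day(self, timestamps: pd.DatetimeIndex) -> np.ndarray:
        """True where the timestamp falls in [lights-on, lights-off)."""
        return self.zt_hours(timestamps) < self.photoperiod_hours

    def is_lights_on_minute(self, timestamps: pd.DatetimeIndex) -> np.ndarray:
        return self.zt_hours(timestamps) == 0.0


@dataclass
class MonitorRecording:
    """One parsed monitor file: timestamps, status codes and count matrix."""

    monitor_id: str
    timestamps: pd.DatetimeIndex
    status: np.ndarray
    counts: np.ndarray
    layout: BeamLayout
    light_flag: np.ndarray | None = None
    inserted: np.ndarray | None = None  # True for gap-repair rows
    valid_status: frozenset[int] = frozenset({1})

    def __post_init__(self) -> None:
        if len(self.timestamps) != self.counts.shape[0]:
            raise DataError("row count does not match timestamp count")
        if self.counts.shape[1] != self.layout.n_count_columns:
            raise DataError(
                f"count matrix has {self.counts.shape[1]} columns; layout "
                f"declares {self.layout.n_count_columns}"
            )
        if np.any(self.counts < 0):
            raise DataError("negative activity count")
        if self.inserted is None:
            self.inserted = np.zeros(len(self.timestamps), dtype=bool)

    @property
    def flagged(self) -> np.ndarray:
        """Rows whose status is outside the valid set (kept, never dropped)."""
        return ~np.isin(self.status, list(self.valid_status))


@dataclass
class FlyTimeSeries:
    """One tube's per-minute counts aligned to the light schedule.

    The window starts at a lights-on minute and spans an integer number
    of 24-hour cycles; ``zt`` is Zeitgeber time in hours and ``phase``
    labels every minute ``"day"`` or ``"night"``.
    """

    fly_id: str
    group: dict
    counts: np.ndarray
    zt: np.ndarray
    phase: np.ndarray
    window: tuple[pd.Timestamp, pd.Timestamp]
    flagged_minutes: int = 0

    def __post_init__(self) -> None:
        n = len(self.counts)
        if not (len(self.zt) == len(self.phase) == n):
            raise DataError("counts, zt and phase must have equal length")
        if n % 1440 != 0:
            raise DataError("window must span whole 24-hour cycles")
        if np.any(self.counts < 0):
            raise DataError("negative activity count")

    @property
    def n_days(self) -> int:
        return len(self.counts) // 1440

    @property
    def is_day(self) -> np.ndarray:
        return self.phase == "day"

    def day_index(self) -> np.ndarray:
        """Recording-day index (0-based) of every minute."""
        return np.arange(len(self.counts)) // 1440


def _parse_row_timestamp(date_str: str, time_str: str, lineno: int) -> _dt.datetime:
    try:
        d = _dt.datetime.strptime(date_str.strip(), _DATE_FORMAT).date()
        t = _dt.datetime.strptime(time_str.strip(), _TIME_FORMAT).time()
    except ValueError as exc:
        raise MonitorParseError(f"line {lineno}: bad date/time: {exc}") from exc
    return _dt.datetime.combine(d, t)


def read_monitor_file(
    path,
    layout: BeamLayout,
    *,
    monitor_id: str | None = None,
    valid_status: Sequence[int] = (1,),
    max_gap_minutes: int = 5,
) -> MonitorRecording:
    """Parse a DAM-style tab-separated monitor file.

    Rows with a status code outside ``valid_status`` are retained and
    flagged, never silently dropped.  Missing minutes (clock skips) of
    up to ``max_gap_minutes`` are repaired by inserting zero-count rows
    marked ``inserted``; longer gaps or backwards timestamps raise
    :class:`~damsleep.errors.AlignmentError`.
    """
    n_counts = layout.n_count_columns
    expected_cols = layout.count_columns_start + n_counts

    timestamps: list[_dt.datetime] = []
    status: list[int] = []
    light: list[int] = []
    rows: list[list[int]] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != expected_cols:
                raise MonitorParseError(
                    f"line {lineno}: expected {expected_cols} columns, "
                    f"found {len(fields)}"
                )
            timestamps.append(_parse_row_timestamp(fields[1], fields[2], lineno))
            try:
                status.append(int(fields[3]))
                light.append(int(fields[layout.count_columns_start - 1]))
                counts = [int(v) for v in fields[layout.count_columns_start:]]
            except ValueError as exc:
                raise MonitorParseError(
                    f"line {lineno}: non-integer field: {exc}"
                ) from exc
            if any(c < 0 for c in counts):
                raise DataError(f"line {lineno}: negative activity count")
            rows.append(counts)

    if not rows:
        raise MonitorParseError(f"{path}: empty monitor file")

    # Gap repair: insert zero-count rows for short clock skips.
    out_ts: list[_dt.datetime] = [timestamps[0]]
    out_status: list[int] = [status[0]]
    out_light: list[int] = [light[0]]
    out_rows: list[list[int]] = [rows[0]]
    inserted: list[bool] = [False]
    zero_row = [0] * n_counts
    for i in range(1, len(timestamps)):
        delta = (timestamps[i] - timestamps[i - 1]).total_seconds() / 60.0
        if delta == 1.0:
            pass
        elif delta <= 0 or delta != int(delta):
            raise AlignmentError(
                f"non-monotone or sub-minute timestamp at row {i + 1}: "
                f"{timestamps[i - 1]} -> {timestamps[i]}"
            )
        elif delta - 1 <= max_gap_minutes:
            for k in range(1, int(delta)):
                out_ts.append(timestamps[i - 1] + _dt.timedelta(minutes=k))
                out_status.append(status[i - 1])
                out_light.append(light[i - 1])
                out_rows.append(zero_row)
                inserted.append(True)
        else:
            raise AlignmentError(
                f"gap of {int(delta) - 1} min at {timestamps[i - 1]} exceeds "
                f"the repairable limit of {max_gap_minutes} min"
            )
        out_ts.append(timestamps[i])
        out_status.append(status[i])
        out_light.append(light[i])
        out_rows.append(rows[i])
        inserted.append(False)

    return MonitorRecording(
        monitor_id=monitor_id or str(path),
        timestamps=pd.DatetimeIndex(out_ts),
        status=np.asarray(out_status, dtype=int),
        counts=np.asarray(out_rows, dtype=np.int64),
        layout=layout,
        light_flag=np.asarray(out_light, dtype=int),
        inserted=np.asarray(inserted, dtype=bool),
        valid_status=frozenset(int(s) for s in valid_status),
    )


def sum_beams(rec: MonitorRecording) -> pd.DataFrame:
    """Sum per-beam counts into per-tube counts for every minute.

    Returns a DataFrame indexed by timestamp with one column per tube
    (1-based tube numbers).  The grand total of counts is conserved.
    """
    tube_of_col = rec.layout.tube_of_column()
    n_tubes = rec.layout.tubes_per_monitor
    sums = np.zeros((rec.counts.shape[0], n_tubes), dtype=np.int64)
    np.add.at(sums.T, tube_of_col, rec.counts.T)
    return pd.DataFrame(
        sums, index=rec.timestamps, columns=np.arange(1, n_tubes + 1)
    )


def extract_analysis_window(
    tube_series: pd.Series,
    schedule: LightSchedule,
    acclimation_hours: float = 24.0,
    window_hours: float = 48.0,
    *,
    fly_id: str = "fly",
    group: dict | None = None,
    flagged: pd.Series | None = None,
) -> FlyTimeSeries:
    """Extract the analysis window for one tube.

    The window begins at the first lights-on minute occurring at least
    ``acclimation_hours`` after the start of the recording and spans
    ``window_hours`` (a positive multiple of 24).  ``flagged`` may carry
    a per-minute boolean mask of invalid-status rows; the number of
    flagged minutes inside the window is reported on the result so the
    caller can exclude the fly.
    """
    if window_hours <= 0 or window_hours % 24 != 0:
        raise ParameterError("window_hours must be a positive multiple of 24")
    idx = tube_series.index
    if not isinstance(idx, pd.DatetimeIndex):
        raise DataError("tube_series must be indexed by timestamps")

    earliest = idx[0] + pd.Timedelta(hours=acclimation_hours)
    eligible = (idx >= earliest) & schedule.is_lights_on_minute(idx)
    positions = np.flatnonzero(eligible)
    n_window = int(window_hours * 60)
    if len(positions) == 0:
        raise WindowError(
            f"no lights-on minute at least {acclimation_hours} h after the "
            f"recording start {idx[0]}"
        )
    start = int(positions[0])
    if start + n_window > len(idx):
        raise WindowError(
            f"window needs {n_window} min from {idx[start]} but only "
            f"{len(idx) - start} min are available"
        )
    window_idx = idx[start : start + n_window]
    counts = np.asarray(tube_series.iloc[start : start + n_window], dtype=np.int64)
    zt = schedule.zt_hours(window_idx)
    phase = np.where(schedule.is_day(window_idx), "day", "night")
    n_flagged = 0
    if flagged is not None:
        n_flagged = int(np.asarray(flagged.iloc[start : start + n_window]).sum())
    return FlyTimeSeries(
        fly_id=fly_id,
        group=dict(group or {}),
        counts=counts,
        zt=zt,
        phase=phase,
        window=(window_idx[0], window_idx[-1]),
        flagged_minutes=n_flagged,
    )


def write_summed_file(table: pd.DataFrame, path) -> None:
    """Persist a per-tube count table in the per-tube monitor dialect.

    The written file round-trips through :func:`read_summed_file` to an
    identical table.
    """
    with open(path, "wt", encoding="utf-8") as fh:
        for i, (ts, row) in enumerate(table.iterrows(), start=1):
            ts = pd.Timestamp(ts)
            fields = [
                str(i),
                ts.strftime(_DATE_FORMAT),
                ts.strftime(_TIME_FORMAT),
                "1",
                *["0"] * 6,
                "0",
                *[str(int(v)) for v in row],
            ]
            fh.write("\t".join(fields) + "\n")


def read_summed_file(path, n_tubes: int) -> pd.DataFrame:
    """Read a per-tube summed count file written by :func:`write_summed_file`."""
    layout = BeamLayout(tubes_per_monitor=n_tubes, beams_per_tube=1)
    with open(path, "rt", encoding="utf-8") as fh:
        if not fh.read().strip():
            return pd.DataFrame(
                columns=np.arange(1, n_tubes + 1), index=pd.DatetimeIndex([])
            )
    rec = read_monitor_file(path, layout)
    return sum_beams(rec)
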