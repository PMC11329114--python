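"""Per-fly behavioural measures from per-minute activity counts.

Sleep is scored with the standard fly proxy: five or more consecutive
minutes with zero activity counts form one sleep bout.  From the scored
bouts the module derives, per recording day and averaged over days:

* activity counts (total / day / night),
* sleep minutes (total / day / night),
* sleep bout number and mean bout length (total / day / night),
* morning (dawn) and evening (dusk) anticipation indices, and
* a viability flag (flies that die during the recording are excluded).

The anticipation index is the ratio of activity in the hours
immediately preceding a light transition to activity in a longer
preceding window (default 3 h / 6 h); it is dimensionless and, when
defined, lies in [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from damsleep.dam_io import FlyTimeSeries
from damsleep.errors import ParameterError

MINUTES_PER_DAY = 1440

#: Measures produced by :func:`compute_fly_metrics`, in table order.
MEASURES = (
    "activity_total",
    "activity_day",
    "activity_night",
    "sleep_total",
    "sleep_day",
    "sleep_night",
    "bout_number_total",
    "bout_number_day",
    "bout_number_night",
    "bout_length_total",
    "bout_length_day",
    "bout_length_night",
    "morning_ai",
    "evening_ai",
)


@dataclass(frozen=True)
class SleepBout:
    """One maximal run of sleep-scored minutes."""

    start: int  # minute index within the analysis window
    duration: int  # minutes
    fragments: tuple[tuple[str, int], ...] = ()  # (phase, minutes) pieces

    def __post_init__(self) -> None:
        if self.fragments and sum(m for _, m in self.fragments) != self.duration:
            raise ValueError("fragment minutes must sum to the bout duration")

    @property
    def end(self) -> int:
        return self.start + self.duration


@dataclass(frozen=True)
class AnticipationWindows:
    """Numerator/denominator windows preceding a light transition."""

    numerator_hours: float = 3.0
    denominator_hours: float = 6.0
    transition: str = "lights-on"  # or "lights-off"

    def __post_init__(self) -> None:
        if not 0 < self.numerator_hours < self.denominator_hours:
            raise ParameterError("need 0 < numerator_hours < denominator_hours")
        if self.transition not in ("lights-on", "lights-off"):
            raise ParameterError("transition must be 'lights-on' or 'lights-off'")


@dataclass(frozen=True)
class MetricsConfig:
    """Parameters of the per-fly metric computation (defaults as published)."""

    sleep_threshold_minutes: int = 5
    ai_numerator_hours: float = 3.0
    ai_denominator_hours: float = 6.0
    viability_min_counts: int = 3
    viability_tail_minutes: int = 180
    bout_boundary_rule: str = "split"  # or "onset"


@dataclass
class FlyMetrics:
    """Per-day and day-averaged behavioural summary for one fly."""

    fly_id: str
    group: dict
    alive: bool
    per_day: pd.DataFrame  # rows = recording days, columns = MEASURES
    averaged: pd.Series  # day-averaged values (undefined days omitted)


def _phase_runs(phase: np.ndarray, start: int, end: int):
    """Contiguous (phase, minutes) fragments of ``phase[start:end]``."""
    frag = []
    seg = phase[start:end]
    boundaries = np.flatnonzero(seg[1:] != seg[:-1]) + 1
    edges = np.concatenate(([0], boundaries, [len(seg)]))
    for a, b in zip(edges[:-1], edges[1:]):
        frag.append((str(seg[a]), int(b - a)))
    return tuple(frag)


def detect_sleep_bouts(
    series: FlyTimeSeries, threshold_minutes: int = 5
) -> list[SleepBout]:
    """Score maximal runs of zero-count minutes of at least the threshold.

    Runs shorter than ``threshold_minutes`` contribute no sleep.  Runs
    truncated by the window edges count if their within-window length
    reaches the threshold (no look-ahead outside the window).
    """
    if threshold_minutes < 1:
        raise ParameterError("threshold_minutes must be >= 1")
    zero = np.concatenate(([False], series.counts == 0, [False]))
    starts = np.flatnonzero(zero[1:].astype(int) - zero[:-1].astype(int) == 1)
    ends = np.flatnonzero(zero[1:].astype(int) - zero[:-1].astype(int) == -1)
    bouts = []
    for s, e in zip(starts, ends):
        if e - s >= threshold_minutes:
            bouts.append(
                SleepBout(
                    start=int(s),
                    duration=int(e - s),
                    fragments=_phase_runs(series.phase, int(s), int(e)),
                )
            )
    return bouts


def sleep_minute_mask(series: FlyTimeSeries, threshold_minutes: int = 5) -> np.ndarray:
    """Boolean mask of minutes scored as sleep."""
    mask = np.zeros(len(series.counts), dtype=bool)
    for bout in detect_sleep_bouts(series, threshold_minutes):
        mask[bout.start : bout.end] = True
    return mask


def attribute_bouts_to_phase(
    bouts: list[SleepBout],
    series: FlyTimeSeries,
    boundary_rule: str = "split",
) -> dict:
    """Phase-resolved sleep minutes, bout counts and mean bout lengths.

    With the default ``"split"`` rule a bout crossing the lights-off (or
    lights-on) boundary is divided at the boundary: each phase receives
    its overlapped minutes and one bout tally, so day + night sleep
    minutes always equal total sleep minutes.  The alternative
    ``"onset"`` rule attributes the whole bout to the phase in which it
    began.  Mean bout length per phase is phase minutes / phase bouts
    (NaN when a phase has no bouts).
    """
    if boundary_rule not in ("split", "onset"):
        raise ParameterError("boundary_rule must be 'split' or 'onset'")
    minutes = {"day": 0, "night": 0}
    nbouts = {"day": 0, "night": 0}
    for bout in bouts:
        if boundary_rule == "onset":
            ph = str(series.phase[bout.start])
            minutes[ph] += bout.duration
            nbouts[ph] += 1
        else:
            seen = set()
            for ph, m in bout.fragments:
                minutes[ph] += m
                seen.add(ph)
            for ph in seen:
                nbouts[ph] += 1
    total_minutes = sum(b.duration for b in bouts)
    out = {
        "sleep_day": minutes["day"],
        "sleep_night": minutes["night"],
        "sleep_total": total_minutes,
        "bout_number_day": nbouts["day"],
        "bout_number_night": nbouts["night"],
        "bout_number_total": len(bouts),
    }
    for ph in ("day", "night"):
        out[f"bout_length_{ph}"] = (
            minutes[ph] / nbouts[ph] if nbouts[ph] else float("nan")
        )
    out["bout_length_total"] = (
        total_minutes / len(bouts) if bouts else float("nan")
    )
    return out


def phase_activity_totals(series: FlyTimeSeries) -> pd.DataFrame:
    """Day/night/total activity counts for each recording day."""
    day_idx = series.day_index()
    is_day = series.is_day
    n_days = series.n_days
    day_sum = np.zeros(n_days, dtype=np.int64)
    night_sum = np.zeros(n_days, dtype=np.int64)
    np.add.at(day_sum, day_idx[is_day], series.counts[is_day])
    np.add.at(night_sum, day_idx[~is_day], series.counts[~is_day])
    return pd.DataFrame(
        {
            "activity_day": day_sum,
            "activity_night": night_sum,
            "activity_total": day_sum + night_sum,
        },
        index=pd.RangeIndex(n_days, name="day"),
    )


def _per_fly_binned(
    series: FlyTimeSeries, bin_minutes: int, kind: str, sleep_threshold: int
) -> np.ndarray:
    values = (
        sleep_minute_mask(series, sleep_threshold).astype(float)
        if kind == "sleep"
        else series.counts.astype(float)
    )
    per_day = values.reshape(series.n_days, MINUTES_PER_DAY)
    n_bins = MINUTES_PER_DAY // bin_minutes
    binned = per_day.reshape(series.n_days, n_bins, bin_minutes).sum(axis=2)
    return binned.mean(axis=0)  # average days per fly first


def bin_trace(
    population: list[FlyTimeSeries],
    bin_minutes: int = 30,
    kind: str = "activity",
    sleep_threshold: int = 5,
) -> pd.DataFrame:
    """Population mean +/- SEM trace in fixed Zeitgeber-time bins.

    Per fly, each bin holds the summed activity counts (``kind=
    "activity"``) or the number of sleep-scored minutes (``kind=
    "sleep"``, so bin values lie in [0, bin_minutes]); recording days
    are averaged within fly before the population mean and standard
    error of the mean are taken across flies.  With a single fly the
    SEM is reported as 0 (with a warning).
    """
    if MINUTES_PER_DAY % bin_minutes != 0:
        raise ParameterError("bin_minutes must divide 1440")
    if kind not in ("activity", "sleep"):
        raise ParameterError("kind must be 'activity' or 'sleep'")
    if not population:
        raise ParameterError("population must contain at least one fly")
    per_fly = np.vstack(
        [_per_fly_binned(s, bin_minutes, kind, sleep_threshold) for s in population]
    )
    n = per_fly.shape[0]
    if n == 1:
        warnings.warn("SEM undefined for n=1; reporting 0", stacklevel=2)
        sem = np.zeros(per_fly.shape[1])
    else:
        sem = per_fly.std(axis=0, ddof=1) / np.sqrt(n)
    n_bins = MINUTES_PER_DAY // bin_minutes
    return pd.DataFrame(
        {
            "zt_bin_start": np.arange(n_bins) * bin_minutes / 60.0,
            "mean": per_fly.mean(axis=0),
            "sem": sem,
            "n": n,
        }
    )


def _infer_photoperiod_minutes(series: FlyTimeSeries) -> int:
    return int(np.sum(series.phase[:MINUTES_PER_DAY] == "day"))


def anticipation_index(
    series: FlyTimeSeries, windows: AnticipationWindows
) -> np.ndarray:
    """Anticipation index per recording day.

    AI = (activity in the ``numerator_hours`` immediately preceding the
    transition) / (activity in the ``denominator_hours`` immediately
    preceding it).  The morning index uses the lights-on transition (the
    window lies in the night ending each recording day); the evening
    index uses lights-off (the window lies in that day's photoperiod).
    A zero denominator yields NaN, which downstream averaging omits.
    """
    num_min = int(round(windows.numerator_hours * 60))
    den_min = int(round(windows.denominator_hours * 60))
    p_min = _infer_photoperiod_minutes(series)
    if windows.transition == "lights-off":
        if den_min > p_min:
            raise ParameterError(
                "denominator window exceeds the photoperiod preceding lights-off"
            )
        transition_offset = p_min  # lights-off, within each day
    else:
        if den_min > MINUTES_PER_DAY - p_min:
            raise ParameterError(
                "denominator window exceeds the night preceding lights-on"
            )
        transition_offset = MINUTES_PER_DAY  # lights-on ending each day
    per_day = series.counts.reshape(series.n_days, MINUTES_PER_DAY)
    den = per_day[:, transition_offset - den_min : transition_offset].sum(axis=1)
    num = per_day[:, transition_offset - num_min : transition_offset].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ai = np.where(den > 0, num / np.maximum(den, 1), np.nan)
    return ai


def viability_filter(
    series: FlyTimeSeries, min_counts: int = 3, tail_minutes: int = 180
) -> bool:
    """True (alive) iff the final ``tail_minutes`` hold >= ``min_counts`` counts.

    Flies failing this rule died during the recording and are excluded
    from all metric tables.
    """
    if len(series.counts) < tail_minutes:
        raise ParameterError("window shorter than the viability tail")
    return int(series.counts[-tail_minutes:].sum()) >= min_counts


def per_day_mean(values) -> float:
    """Arithmetic mean over recording days, omitting undefined (NaN) days."""
    arr = np.asarray(values, dtype=float)
    if len(arr) == 0 or np.all(np.isnan(arr)):
        return float("nan")
    return float(np.nanmean(arr))


def _per_day_sleep_table(
    series: FlyTimeSeries, threshold: int, boundary_rule: str
) -> pd.DataFrame:
    """Sleep minutes, bout number and bout length per (day, phase) cell.

    A bout overlapping several (day, phase) cells contributes its
    overlapped minutes and one bout tally to each cell under the
    ``split`` rule; under ``onset`` the whole bout goes to the cell of
    its first minute.
    """
    n_days = series.n_days
    day_idx = series.day_index()
    minutes = np.zeros((n_days, 2))  # columns: day, night
    nbouts = np.zeros((n_days, 2))
    bouts = detect_sleep_bouts(series, threshold)
    total_minutes = np.zeros(n_days)
    total_bouts = np.zeros(n_days)
    for bout in bouts:
        rng = np.arange(bout.start, bout.end)
        if boundary_rule == "onset":
            d = int(day_idx[bout.start])
            c = 0 if series.phase[bout.start] == "day" else 1
            minutes[d, c] += bout.duration
            nbouts[d, c] += 1
            total_minutes[d] += bout.duration
            total_bouts[d] += 1
        else:
            cols = np.where(series.is_day[rng], 0, 1)
            days = day_idx[rng]
            np.add.at(minutes, (days, cols), 1)
            for d, c in set(zip(days.tolist(), cols.tolist())):
                nbouts[d, c] += 1
            np.add.at(total_minutes, days, 1)
            for d in set(days.tolist()):
                total_bouts[d] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        length = np.where(nbouts > 0, minutes / np.maximum(nbouts, 1), np.nan)
        length_total = np.where(
            total_bouts > 0, total_minutes / np.maximum(total_bouts, 1), np.nan
        )
    return pd.DataFrame(
        {
            "sleep_day": minutes[:, 0],
            "sleep_night": minutes[:, 1],
            "sleep_total": total_minutes,
            "bout_number_day": nbouts[:, 0],
            "bout_number_night": nbouts[:, 1],
            "bout_number_total": total_bouts,
            "bout_length_day": length[:, 0],
            "bout_length_night": length[:, 1],
            "bout_length_total": length_total,
        },
        index=pd.RangeIndex(n_days, name="day"),
    )


def compute_fly_metrics(
    series: FlyTimeSeries, config: MetricsConfig = MetricsConfig()
) -> FlyMetrics:
    """All per-fly measures, per recording day and day-averaged.

    Conservation invariants (day + night = total for activity and sleep)
    hold by construction.  The viability flag is computed but not
    enforced here; pipelines exclude dead flies before tabulation.
    """
    alive = viability_filter(
        series, config.viability_min_counts, config.viability_tail_minutes
    )
    activity = phase_activity_totals(series)
    sleep = _per_day_sleep_table(
        series, config.sleep_threshold_minutes, config.bout_boundary_rule
    )
    morning = anticipation_index(
        series,
        AnticipationWindows(
            config.ai_numerator_hours, config.ai_denominator_hours, "lights-on"
        ),
    )
    evening = anticipation_index(
        series,
        AnticipationWindows(
            config.ai_numerator_hours, config.ai_denominator_hours, "lights-off"
        ),
    )
    per_day = pd.concat([activity, sleep], axis=1)
    per_day["morning_ai"] = morning
    per_day["evening_ai"] = evening
    per_day = per_day[list(MEASURES)]
    averaged = pd.Series(
        {m: per_day_mean(per_day[m].to_numpy()) for m in MEASURES}, name=series.fly_id
    )
    return FlyMetrics(
        fly_id=series.fly_id,
        group=dict(series.group),
        alive=alive,
        per_day=per_day,
        averaged=averaged,
    )
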