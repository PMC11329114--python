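"""Synthetic DAM cohorts with known ground truth.

The generator emulates the phenomenology of mated-fly activity-monitor
experiments: crepuscular activity with morning and evening peaks, a
mid-day siesta and consolidated night sleep, linear anticipation ramps
before both light transitions, a startle burst after each transition,
per-group (strain x sex x age) effect multipliers, dead-fly traces,
empty tubes, and Gompertz-distributed lifespans with right-censoring.

Sleep and wake alternate as a discrete-time alternating-renewal
process: run lengths are geometric with per-phase means, matching the
one-minute sampling of the monitors and making the expected bout
length analytic.  Every sleep minute emits zero counts; every wake
minute emits a Poisson count whose intensity follows the diel profile.
Each fly draws from its own named random stream, so adding flies to a
config never perturbs existing traces.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from damsleep.dam_io import BeamLayout, FlyTimeSeries, LightSchedule
from damsleep.errors import ParameterError
from damsleep.survival import SurvivalRecord

MINUTES_PER_DAY = 1440


@dataclass(frozen=True)
class GroupSpec:
    """One experimental condition and its effect multipliers."""

    strain: str
    sex: str
    age_weeks: int
    n_flies: int = 32
    activity_multiplier: float = 1.0  # scales wake-minute Poisson intensity
    sleep_run_multiplier: float = 1.0  # scales mean sleep-run durations
    ramp_multiplier: float = 1.0  # scales the anticipation ramp slope
    hazard_multiplier: float = 1.0  # scales the Gompertz baseline hazard

    @property
    def label(self) -> str:
        return f"{self.strain}_{self.sex}_{self.age_weeks}w"


@dataclass(frozen=True)
class SimConfig:
    """Full parameterisation of a synthetic cohort.

    Defaults describe a healthy young mated fly in a 12h:12h LD cycle:
    consolidated night sleep (mean sleep run 30 min at night vs 10 min
    by day), fragmented day wakefulness, a baseline wake intensity of
    2 counts/min with 3 counts/min crepuscular peaks expressed as
    anticipation ramps over the 6 h before each transition, and a
    post-transition startle that decays within half an hour.
    """

    seed: int = 0
    groups: tuple[GroupSpec, ...] = (GroupSpec("CS", "female", 2),)
    schedule: LightSchedule = field(default_factory=LightSchedule)
    recording_hours: float = 96.0
    # sleep-wake alternating-renewal process (minutes)
    mean_sleep_run_day: float = 10.0
    mean_sleep_run_night: float = 30.0
    mean_wake_run_day: float = 40.0
    mean_wake_run_night: float = 15.0
    min_sleep_run: int = 5  # sleep runs shorter than this are unobservable
    # wake-minute Poisson intensity (counts/min)
    baseline_rate: float = 2.0
    morning_peak: float = 3.0  # ramp amplitude reached at lights-on
    evening_peak: float = 3.0  # ramp amplitude reached at lights-off
    ramp_hours: float = 6.0  # pre-transition window carrying the ramp
    startle_amplitude: float = 4.0
    startle_decay_hours: float = 0.5
    # anticipation also manifests as earlier waking: sleep-run means are
    # shortened by up to this fraction as the relative ramp intensity
    # approaches saturation at the transition (0 disables the coupling)
    wake_ramp_coupling: float = 0.5
    # cohort composition
    beams_per_tube: int = 15
    tubes_per_monitor: int = 8
    dead_fly_fraction: float = 0.0
    empty_tube_fraction: float = 0.0
    # lifespan model: Gompertz hazard h(t) = a * exp(b t), t in days
    gompertz_a: float = 1.7e-4
    gompertz_b: float = 0.10
    censoring_rate: float = 0.02
    n_lifespan_per_group: int = 150

    def __post_init__(self) -> None:
        for name in (
            "mean_sleep_run_day",
            "mean_sleep_run_night",
            "mean_wake_run_day",
            "mean_wake_run_night",
        ):
            if getattr(self, name) < 1:
                raise ParameterError(f"{name} must be >= 1 minute")
        if self.baseline_rate < 0 or self.gompertz_a <= 0 or self.gompertz_b < 0:
            raise ParameterError("rates must be non-negative (gompertz_a > 0)")

    def to_json(self) -> str:
        def enc(obj):
            if dataclasses.is_dataclass(obj):
                return dataclasses.asdict(obj)
            return str(obj)

        return json.dumps(dataclasses.asdict(self), default=enc, indent=2)


def _fly_rng(config: SimConfig, stream: tuple) -> np.random.Generator:
    """Named per-fly random stream: independent of cohort composition."""
    # zlib.crc32 is a stable string hash (hash() is salted per process)
    hashed = [
        zlib.crc32(x.encode()) if isinstance(x, str) else int(x) for x in stream
    ]
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=tuple(hashed))
    )


def _ramp_contribution(
    config: SimConfig, group: GroupSpec, zt: np.ndarray
) -> np.ndarray:
    """Anticipation-ramp intensity (counts/min) at each Zeitgeber time."""
    p = config.schedule.photoperiod_hours
    cyc = config.schedule.cycle_hours
    ramp = config.ramp_hours
    out = np.zeros_like(zt, dtype=float)
    # evening ramp rises over [p - ramp, p), peaking at lights-off
    in_e = (zt >= p - ramp) & (zt < p)
    out[in_e] = (
        config.evening_peak * group.ramp_multiplier * (zt[in_e] - (p - ramp)) / ramp
    )
    # morning ramp rises over [cyc - ramp, cyc), peaking at lights-on
    in_m = zt >= cyc - ramp
    out[in_m] = (
        config.morning_peak * group.ramp_multiplier * (zt[in_m] - (cyc - ramp)) / ramp
    )
    return out


def _anticipation_strength(
    config: SimConfig, group: GroupSpec, zt: np.ndarray
) -> np.ndarray:
    """Wake-anticipation drive: ramp-slope multiplier x window position.

    Zero outside the pre-transition windows and whenever the matching
    peak amplitude is zero, so a flat intensity profile carries no
    anticipation of either kind; proportional to the group's ramp-slope
    multiplier, so weakening the ramp weakens the pre-transition waking
    in step.
    """
    p = config.schedule.photoperiod_hours
    cyc = config.schedule.cycle_hours
    ramp = config.ramp_hours
    out = np.zeros_like(zt, dtype=float)
    if config.evening_peak > 0:
        in_e = (zt >= p - ramp) & (zt < p)
        out[in_e] = group.ramp_multiplier * (zt[in_e] - (p - ramp)) / ramp
    if config.morning_peak > 0:
        in_m = zt >= cyc - ramp
        out[in_m] = group.ramp_multiplier * (zt[in_m] - (cyc - ramp)) / ramp
    return out


def intensity_profile(config: SimConfig, group: GroupSpec, zt: np.ndarray) -> np.ndarray:
    """Expected wake-minute Poisson intensity at each Zeitgeber time (hours)."""
    p = config.schedule.photoperiod_hours
    cyc = config.schedule.cycle_hours
    lam = np.full_like(zt, config.baseline_rate, dtype=float)
    lam += _ramp_contribution(config, group, zt)
    # startle decay after each transition
    for t0 in (0.0, p):
        dt = zt - t0
        mask = (dt >= 0) & (dt < 6 * config.startle_decay_hours)
        lam[mask] += config.startle_amplitude * np.exp(
            -dt[mask] / config.startle_decay_hours
        )
    return lam * group.activity_multiplier


def _sample_sleep_wake(
    config: SimConfig,
    group: GroupSpec,
    is_day: np.ndarray,
    rng: np.random.Generator,
    ramp_rel: np.ndarray | None = None,
) -> np.ndarray:
    """Boolean asleep-mask from alternating geometric runs.

    Run lengths take the mean of the phase in which the run begins.
    Wake runs are geometric (support >= 1).  Sleep runs are geometric
    shifted to a minimum of ``min_sleep_run`` minutes while keeping the
    configured mean: inactivity shorter than the scoring threshold is
    not sleep by definition, so generating sub-threshold "sleep" runs
    would silently bias every recovered bout statistic (a geometric run
    conditioned on reaching the threshold has mean threshold-1 above
    its nominal mean).

    ``ramp_rel`` is the relative anticipation intensity ramp / (baseline
    + ramp) in [0, 1); sleep runs starting inside a ramp window are
    shortened by up to ``wake_ramp_coupling`` of their mean as the ramp
    saturates, emulating the pre-transition waking that constitutes
    behavioural anticipation.
    """
    n = len(is_day)
    shift = config.min_sleep_run - 1
    asleep = np.zeros(n, dtype=bool)
    sleeping = bool(rng.random() < 0.5)
    i = 0
    while i < n:
        day = bool(is_day[i])
        if sleeping:
            mean = (
                config.mean_sleep_run_day if day else config.mean_sleep_run_night
            ) * group.sleep_run_multiplier
            if ramp_rel is not None:
                factor = 1.0 - config.wake_ramp_coupling * float(ramp_rel[i])
                mean *= max(factor, 0.15)
            run = shift + int(rng.geometric(1.0 / max(mean - shift, 1.0)))
        else:
            mean = config.mean_wake_run_day if day else config.mean_wake_run_night
            run = int(rng.geometric(1.0 / max(mean, 1.0)))
        end = min(i + run, n)
        if sleeping:
            asleep[i:end] = True
        i = end
        sleeping = not sleeping
    return asleep


def simulate_fly_minutes(
    config: SimConfig,
    group: GroupSpec,
    fly_index: int = 0,
    *,
    fly_id: str | None = None,
) -> tuple[FlyTimeSeries, dict]:
    """Simulate one fly's analysis-window trace with ground truth.

    Returns the per-minute series (an integer number of 24-h cycles,
    taken as ``recording_hours`` rounded down to whole cycles, starting
    at lights-on) together with ground truth: the asleep mask, the
    per-minute intensity, and the generating parameters.
    """
    n_days = max(1, int(config.recording_hours // 24))
    n = n_days * MINUTES_PER_DAY
    rng = _fly_rng(config, (group.strain, group.sex, group.age_weeks, fly_index))
    zt = (np.arange(n) / 60.0) % config.schedule.cycle_hours
    is_day = zt < config.schedule.photoperiod_hours
    asleep = _sample_sleep_wake(
        config, group, is_day, rng, _anticipation_strength(config, group, zt)
    )
    lam = intensity_profile(config, group, zt)
    counts = np.where(asleep, 0, rng.poisson(lam))
    # wake minutes may still emit 0 by Poisson chance; that is realistic
    start = pd.Timestamp("2024-01-01") + pd.Timedelta(
        hours=config.schedule.lights_on_clock_time.hour,
        minutes=config.schedule.lights_on_clock_time.minute,
    )
    series = FlyTimeSeries(
        fly_id=fly_id or f"{group.label}_f{fly_index}",
        group={
            "strain": group.strain,
            "sex": group.sex,
            "age_weeks": group.age_weeks,
        },
        counts=counts.astype(np.int64),
        zt=zt,
        phase=np.where(is_day, "day", "night"),
        window=(start, start + pd.Timedelta(minutes=n - 1)),
    )
    truth = {
        "asleep": asleep,
        "intensity": lam,
        "mean_sleep_run_day": config.mean_sleep_run_day * group.sleep_run_multiplier,
        "mean_sleep_run_night": config.mean_sleep_run_night
        * group.sleep_run_multiplier,
    }
    return series, truth


def _write_monitor_file(
    path: Path,
    start: pd.Timestamp,
    per_tube_counts: np.ndarray,  # minutes x tubes
    layout: BeamLayout,
    light: np.ndarray,
    rng: np.random.Generator,
) -> None:
    """Distribute per-tube counts over beams multinomially and write rows."""
    n_min, n_tubes = per_tube_counts.shape
    bpt = layout.beams_per_tube
    with open(path, "wt", encoding="utf-8") as fh:
        for i in range(n_min):
            ts = start + pd.Timedelta(minutes=i)
            beams = []
            for tube in range(n_tubes):
                c = int(per_tube_counts[i, tube])
                if c:
                    split = rng.multinomial(c, np.full(bpt, 1.0 / bpt))
                else:
                    split = np.zeros(bpt, dtype=int)
                beams.extend(int(v) for v in split)
            fields = [
                str(i + 1),
                ts.strftime("%d %b %y"),
                ts.strftime("%H:%M:%S"),
                "1",
                *["0"] * 6,
                str(int(light[i])),
                *[str(v) for v in beams],
            ]
            fh.write("\t".join(fields) + "\n")


def simulate_cohort_to_dam_files(
    config: SimConfig, out_dir
) -> tuple[list[Path], pd.DataFrame]:
    """Write per-beam monitor files for a whole cohort plus ground truth.

    Flies are packed into monitors of ``tubes_per_monitor`` tubes per
    group.  The recording covers ``recording_hours`` starting one full
    acclimation day before the analysis window, so downstream window
    extraction (24 h acclimation, then whole cycles from lights-on)
    sees realistic timing.  Configured fractions of tubes are dead
    (counts cease at a drawn death minute) or empty (all zero).
    Ground truth per tube is returned and written as CSV.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    n_min_total = int(config.recording_hours * 60)
    on = config.schedule.lights_on_clock_time
    start = pd.Timestamp("2024-01-01") + pd.Timedelta(
        hours=on.hour, minutes=on.minute
    )
    zt_all = (np.arange(n_min_total) / 60.0) % config.schedule.cycle_hours
    light = (zt_all < config.schedule.photoperiod_hours).astype(int)
    layout = BeamLayout(
        tubes_per_monitor=config.tubes_per_monitor,
        beams_per_tube=config.beams_per_tube,
    )
    acclimation_min = MINUTES_PER_DAY  # one cycle before the analysis window

    paths: list[Path] = []
    truth_rows = []
    monitor_no = 0
    for group in config.groups:
        fly = 0
        while fly < group.n_flies:
            monitor_no += 1
            n_tubes = min(config.tubes_per_monitor, group.n_flies - fly)
            per_tube = np.zeros((n_min_total, config.tubes_per_monitor), dtype=np.int64)
            beam_rng = _fly_rng(config, ("beams", monitor_no))
            for tube in range(n_tubes):
                idx = fly + tube
                frng = _fly_rng(
                    config, ("fate", group.strain, group.sex, group.age_weeks, idx)
                )
                fate_draw = frng.random()
                if fate_draw < config.empty_tube_fraction:
                    fate, death_minute = "empty", None
                elif fate_draw < config.empty_tube_fraction + config.dead_fly_fraction:
                    fate = "dead"
                    # dies somewhere inside the analysis portion
                    death_minute = int(
                        frng.integers(acclimation_min, n_min_total - 180)
                    )
                else:
                    fate, death_minute = "alive", None
                if fate != "empty":
                    rng = _fly_rng(
                        config, (group.strain, group.sex, group.age_weeks, idx)
                    )
                    is_day = light.astype(bool)
                    asleep = _sample_sleep_wake(
                        config,
                        group,
                        is_day,
                        rng,
                        _anticipation_strength(config, group, zt_all),
                    )
                    lam = intensity_profile(config, group, zt_all)
                    counts = np.where(asleep, 0, rng.poisson(lam))
                    if death_minute is not None:
                        counts[death_minute:] = 0
                    per_tube[:, tube] = counts
                truth_rows.append(
                    {
                        "monitor": f"M{monitor_no:03d}",
                        "tube": tube + 1,
                        "strain": group.strain,
                        "sex": group.sex,
                        "age_weeks": group.age_weeks,
                        "fate": fate,
                        "death_minute": death_minute,
                    }
                )
            path = out_dir / f"Monitor{monitor_no:03d}.txt"
            _write_monitor_file(path, start, per_tube, layout, light, beam_rng)
            paths.append(path)
            fly += n_tubes
    truth = pd.DataFrame(truth_rows)
    truth.to_csv(out_dir / "ground_truth.csv", index=False)
    (out_dir / "sim_config.json").write_text(config.to_json())
    return paths, truth


def gompertz_median(a: float, b: float) -> float:
    """Closed-form median of the Gompertz(a, b) lifetime distribution."""
    if b == 0:
        return float(np.log(2.0) / a)
    return float(np.log1p(b * np.log(2.0) / a) / b)


def simulate_lifespans(config: SimConfig) -> list[SurvivalRecord]:
    """Gompertz lifetimes per group by inverse transform, with censoring.

    The hazard is h(t) = a_g exp(b t) with a_g = ``gompertz_a`` times
    the group's hazard multiplier.  Each subject is independently
    censored with probability ``censoring_rate``, at a uniform fraction
    of its drawn lifetime.
    """
    records: list[SurvivalRecord] = []
    b = config.gompertz_b
    for group in config.groups:
        a = config.gompertz_a * group.hazard_multiplier
        rng = _fly_rng(config, ("lifespan", group.strain, group.sex, group.age_weeks))
        u = rng.random(config.n_lifespan_per_group)
        if b == 0:
            t = -np.log(u) / a
        else:
            t = np.log1p(-b * np.log(u) / a) / b
        censored = rng.random(config.n_lifespan_per_group) < config.censoring_rate
        cens_frac = rng.random(config.n_lifespan_per_group)
        for i in range(config.n_lifespan_per_group):
            if censored[i]:
                time = max(t[i] * cens_frac[i], 1e-6)
                event = "censor"
            else:
                time, event = t[i], "death"
            records.append(
                SurvivalRecord(
                    subject_id=f"{group.label}_s{i}",
                    time=float(time),
                    event=event,
                    strain=group.strain,
                    sex=group.sex,
                )
            )
    return records
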