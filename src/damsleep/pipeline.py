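"""End-to-end orchestration: parse -> per-fly metrics -> tables -> statistics.

A single declarative manifest drives a run: which monitor files to
read, which (strain, sex, age) group sits in each tube, the light
schedule and analysis window, every metric threshold, and the seed for
the Dunnett Monte Carlo.  Outputs are tidy CSV tables (one per
measure), an exclusion log listing every fly dropped by the viability
or status rules, per-measure statistics tables and a JSON run summary.
Given identical inputs and seed the outputs are byte-identical.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from damsleep import __version__
from damsleep.behaviour_metrics import (
    MEASURES,
    MetricsConfig,
    compute_fly_metrics,
)
from damsleep.dam_io import (
    BeamLayout,
    LightSchedule,
    extract_analysis_window,
    read_monitor_file,
    sum_beams,
)
from damsleep.errors import DataError, ParameterError
from damsleep.group_stats import (
    dunnett_test,
    significance_stars,
    two_way_anova,
)
from damsleep.survival import (
    SurvivalRecord,
    cox_ph_fit,
    kaplan_meier,
    log_rank_test,
    median_lifespan,
    percent_median_decrease,
)

logger = logging.getLogger("damsleep")


@dataclass
class MonitorEntry:
    path: Path
    tubes: int
    beams_per_tube: int
    assignments: dict[int, dict]  # tube number (1-based) -> group labels

    @property
    def layout(self) -> BeamLayout:
        return BeamLayout(
            tubes_per_monitor=self.tubes, beams_per_tube=self.beams_per_tube
        )


@dataclass
class ExperimentManifest:
    """Declarative description of one analysis run."""

    monitors: list[MonitorEntry]
    schedule: LightSchedule = field(default_factory=LightSchedule)
    acclimation_hours: float = 24.0
    window_hours: float = 48.0
    metrics: MetricsConfig = field(default_factory=MetricsConfig)
    seed: int = 0
    control_age_weeks: int = 2
    output_dir: Path | None = None

    @classmethod
    def from_yaml(cls, path) -> "ExperimentManifest":
        raw = yaml.safe_load(Path(path).read_text())
        base = Path(path).parent
        monitors = []
        for m in raw["monitors"]:
            monitors.append(
                MonitorEntry(
                    path=(base / m["path"]).resolve()
                    if not Path(m["path"]).is_absolute()
                    else Path(m["path"]),
                    tubes=int(m.get("tubes", 8)),
                    beams_per_tube=int(m.get("beams_per_tube", 15)),
                    assignments={
                        int(k): dict(v) for k, v in m.get("assignments", {}).items()
                    },
                )
            )
        sched = raw.get("schedule", {})
        on = sched.get("lights_on", "08:00")
        hh, mm = (int(x) for x in str(on).split(":")[:2])
        schedule = LightSchedule(
            lights_on_clock_time=_dt.time(hh, mm),
            photoperiod_hours=float(sched.get("photoperiod_hours", 12)),
            cycle_hours=float(sched.get("cycle_hours", 24)),
        )
        met = raw.get("metrics", {})
        metrics = MetricsConfig(
            sleep_threshold_minutes=int(met.get("sleep_threshold_minutes", 5)),
            ai_numerator_hours=float(met.get("ai_numerator_hours", 3)),
            ai_denominator_hours=float(met.get("ai_denominator_hours", 6)),
            viability_min_counts=int(met.get("viability_min_counts", 3)),
            viability_tail_minutes=int(met.get("viability_tail_minutes", 180)),
            bout_boundary_rule=str(met.get("bout_boundary_rule", "split")),
        )
        out = raw.get("output_dir")
        return cls(
            monitors=monitors,
            schedule=schedule,
            acclimation_hours=float(raw.get("acclimation_hours", 24)),
            window_hours=float(raw.get("window_hours", 48)),
            metrics=metrics,
            seed=int(raw.get("seed", 0)),
            control_age_weeks=int(raw.get("control_age_weeks", 2)),
            output_dir=(base / out).resolve() if out else None,
        )

    def validate(self) -> None:
        """Pre-flight checks; raises before any computation on failure."""
        if not self.monitors:
            raise ParameterError("manifest lists no monitor files")
        for m in self.monitors:
            if not m.path.exists():
                raise ParameterError(f"monitor file not found: {m.path}")
            for tube in m.assignments:
                if not 1 <= tube <= m.tubes:
                    raise ParameterError(
                        f"{m.path.name}: assigned tube {tube} outside 1..{m.tubes}"
                    )


@dataclass
class BehaviourResult:
    per_day: pd.DataFrame  # tidy: fly_id, monitor, tube, labels, day, measure, value
    averaged: pd.DataFrame  # one row per fly, one column per measure
    exclusions: pd.DataFrame  # fly_id, monitor, tube, reason
    anova: pd.DataFrame
    dunnett: pd.DataFrame
    summary: dict


def _manifest_hash(manifest: ExperimentManifest) -> str:
    h = hashlib.sha256()
    for m in manifest.monitors:
        h.update(m.path.read_bytes())
        h.update(json.dumps(m.assignments, sort_keys=True).encode())
    h.update(
        f"{manifest.acclimation_hours}|{manifest.window_hours}|{manifest.seed}|"
        f"{manifest.metrics}".encode()
    )
    return h.hexdigest()[:16]


def run_behaviour_pipeline(manifest: ExperimentManifest) -> BehaviourResult:
    """The three-script flow: sum beams, per-fly metrics, compiled tables.

    Flies failing the viability rule or holding flagged (invalid-status)
    minutes inside the analysis window are excluded from all tables and
    listed in the exclusion log with the reason.
    """
    manifest.validate()
    rows = []
    excl = []
    kept_metrics = []
    for entry in manifest.monitors:
        rec = read_monitor_file(
            entry.path, entry.layout, monitor_id=entry.path.stem
        )
        tube_table = sum_beams(rec)
        flagged = pd.Series(rec.flagged | rec.inserted, index=rec.timestamps)
        for tube, group in sorted(entry.assignments.items()):
            fly_id = f"{rec.monitor_id}_t{tube:02d}"
            series = extract_analysis_window(
                tube_table[tube],
                manifest.schedule,
                manifest.acclimation_hours,
                manifest.window_hours,
                fly_id=fly_id,
                group=group,
                flagged=flagged,
            )
            if series.flagged_minutes:
                excl.append(
                    {
                        "fly_id": fly_id,
                        "monitor": rec.monitor_id,
                        "tube": tube,
                        "reason": f"{series.flagged_minutes} flagged minutes in window",
                    }
                )
                continue
            fm = compute_fly_metrics(series, manifest.metrics)
            if not fm.alive:
                excl.append(
                    {
                        "fly_id": fly_id,
                        "monitor": rec.monitor_id,
                        "tube": tube,
                        "reason": "failed viability filter (dead or empty tube)",
                    }
                )
                continue
            kept_metrics.append((rec.monitor_id, tube, fm))
            for day, day_row in fm.per_day.iterrows():
                for measure in MEASURES:
                    rows.append(
                        {
                            "fly_id": fly_id,
                            "monitor": rec.monitor_id,
                            "tube": tube,
                            **group,
                            "day": day,
                            "measure": measure,
                            "value": day_row[measure],
                        }
                    )
    per_day = pd.DataFrame(rows)
    avg_rows = []
    for monitor, tube, fm in kept_metrics:
        avg_rows.append(
            {
                "fly_id": fm.fly_id,
                "monitor": monitor,
                "tube": tube,
                **fm.group,
                **fm.averaged.to_dict(),
            }
        )
    averaged = pd.DataFrame(avg_rows)
    exclusions = pd.DataFrame(excl, columns=["fly_id", "monitor", "tube", "reason"])
    anova, dunnett = run_group_stats(
        averaged,
        seed=manifest.seed,
        control_age_weeks=manifest.control_age_weeks,
    )
    summary = {
        "version": __version__,
        "manifest_hash": _manifest_hash(manifest),
        "seed": manifest.seed,
        "n_monitors": len(manifest.monitors),
        "n_flies_kept": len(kept_metrics),
        "n_flies_excluded": len(exclusions),
        "window_hours": manifest.window_hours,
    }
    logger.info("pipeline done: %s", summary)
    result = BehaviourResult(per_day, averaged, exclusions, anova, dunnett, summary)
    if manifest.output_dir is not None:
        write_behaviour_outputs(result, manifest.output_dir)
    return result


def run_group_stats(
    averaged: pd.DataFrame, *, seed: int = 0, control_age_weeks: int = 2
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """ANOVA and Dunnett tables over a day-averaged per-fly table.

    Per measure and strain stratum: a two-way age x sex ANOVA.  Per
    measure and (strain, sex) family: Dunnett comparisons of each age
    group against the control age.  Strata lacking the required factor
    levels are skipped.
    """
    anova_rows = []
    dunnett_rows = []
    if averaged.empty:
        return pd.DataFrame(), pd.DataFrame()
    for measure in MEASURES:
        if measure not in averaged.columns:
            continue
        for strain, sdf in averaged.groupby("strain"):
            sub = sdf.rename(columns={measure: "value"})[
                ["value", "age_weeks", "sex"]
            ].dropna()
            if sub.empty:
                continue
            try:
                tab = two_way_anova(sub, "value", "age_weeks", "sex")
            except (ParameterError, DataError):
                continue
            for effect, r in tab.iterrows():
                anova_rows.append(
                    {
                        "measure": measure,
                        "strain": strain,
                        "effect": effect,
                        "sum_sq": r["sum_sq"],
                        "df": r["df"],
                        "F": r["F"],
                        "p": r["p"],
                    }
                )
        for (strain, sex), sdf in averaged.groupby(["strain", "sex"]):
            sub = sdf.rename(columns={measure: "value"})[
                ["value", "age_weeks"]
            ].dropna()
            try:
                res = dunnett_test(
                    sub,
                    "value",
                    "age_weeks",
                    str(control_age_weeks),
                    seed=seed,
                )
            except (ParameterError, DataError):
                continue
            for level, r in res.comparisons.iterrows():
                dunnett_rows.append(
                    {
                        "measure": measure,
                        "strain": strain,
                        "sex": sex,
                        "age_weeks": level,
                        "vs_control": control_age_weeks,
                        "n": r["n"],
                        "mean_diff": r["mean_diff"],
                        "t": r["t"],
                        "p_adjusted": r["p_adjusted"],
                        "stars": significance_stars(r["p_adjusted"]),
                    }
                )
    return pd.DataFrame(anova_rows), pd.DataFrame(dunnett_rows)


def write_behaviour_outputs(result: BehaviourResult, out_dir) -> list[Path]:
    """One tidy CSV per measure plus exclusions, stats and a JSON summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for measure in MEASURES:
        sub = (
            result.per_day[result.per_day["measure"] == measure]
            .drop(columns=["measure"])
            .reset_index(drop=True)
            if not result.per_day.empty
            else pd.DataFrame()
        )
        p = out / f"measure_{measure}.csv"
        sub.to_csv(p, index=False)
        written.append(p)
    for name, df in (
        ("averaged", result.averaged),
        ("exclusions", result.exclusions),
        ("anova", result.anova),
        ("dunnett", result.dunnett),
    ):
        p = out / f"{name}.csv"
        df.to_csv(p, index=False)
        written.append(p)
    p = out / "run_summary.json"
    p.write_text(json.dumps(result.summary, indent=2, sort_keys=True) + "\n")
    written.append(p)
    return written


# ---------------------------------------------------------------------------
# survival pipeline


def read_survival_csv(path) -> list[SurvivalRecord]:
    """Read records from CSV columns id, time_days, event, strain, sex."""
    df = pd.read_csv(path)
    return [
        SurvivalRecord(
            subject_id=str(r["id"]),
            time=float(r["time_days"]),
            event=str(r["event"]),
            strain=str(r.get("strain", "")),
            sex=str(r.get("sex", "")),
        )
        for _, r in df.iterrows()
    ]


@dataclass
class SurvivalResult:
    medians: pd.DataFrame  # strain, sex, n, median
    percent_decreases: pd.DataFrame  # male vs female within strain
    log_rank: pd.DataFrame  # pairwise tests
    cox_interaction_p: float
    cox_summary: pd.DataFrame


def run_survival_pipeline(
    records: list[SurvivalRecord], *, interaction: bool = True
) -> SurvivalResult:
    """The full survival comparison set for a sexes x strains cohort.

    Produces per-group KM medians, within-strain male-versus-female
    percent decreases in median lifespan, all pairwise log-rank tests
    within strain (between sexes) and within sex (between strains), and
    the Cox proportional-hazards fit with the sex-by-strain interaction
    tested by likelihood ratio.
    """
    df_groups: dict[tuple[str, str], list[SurvivalRecord]] = {}
    for r in records:
        df_groups.setdefault((r.strain, r.sex), []).append(r)
    strains = sorted({s for s, _ in df_groups})
    sexes = sorted({x for _, x in df_groups})
    if interaction and (len(strains) < 2 or len(sexes) < 2):
        raise ParameterError(
            "sex-by-strain interaction needs >= 2 strains and >= 2 sexes"
        )

    med_rows = []
    for (strain, sex), recs in sorted(df_groups.items()):
        curve = kaplan_meier(recs)
        med_rows.append(
            {
                "strain": strain,
                "sex": sex,
                "n": curve.n_subjects,
                "n_deaths": int(curve.deaths.sum()),
                "median_days": median_lifespan(curve),
            }
        )
    medians = pd.DataFrame(med_rows)

    dec_rows = []
    if "female" in sexes and "male" in sexes:
        for strain in strains:
            f = medians.query("strain == @strain and sex == 'female'")[
                "median_days"
            ].iloc[0]
            m = medians.query("strain == @strain and sex == 'male'")[
                "median_days"
            ].iloc[0]
            if f > 0 and not (np.isnan(f) or np.isnan(m)):
                dec_rows.append(
                    {
                        "strain": strain,
                        "female_median": f,
                        "male_median": m,
                        "percent_decrease": percent_median_decrease(f, m),
                    }
                )
    percent_decreases = pd.DataFrame(dec_rows)

    lr_rows = []
    for strain in strains:  # between sexes within strain
        present = [x for x in sexes if (strain, x) in df_groups]
        for i in range(len(present)):
            for j in range(i + 1, len(present)):
                res = log_rank_test(
                    [df_groups[(strain, present[i])], df_groups[(strain, present[j])]]
                )
                lr_rows.append(
                    {
                        "comparison": f"{strain}: {present[i]} vs {present[j]}",
                        "scope": "within_strain",
                        "statistic": res.statistic,
                        "df": res.df,
                        "p": res.p_value,
                    }
                )
    for sex in sexes:  # between strains within sex
        present = [s for s in strains if (s, sex) in df_groups]
        for i in range(len(present)):
            for j in range(i + 1, len(present)):
                res = log_rank_test(
                    [df_groups[(present[i], sex)], df_groups[(present[j], sex)]]
                )
                lr_rows.append(
                    {
                        "comparison": f"{sex}: {present[i]} vs {present[j]}",
                        "scope": "within_sex",
                        "statistic": res.statistic,
                        "df": res.df,
                        "p": res.p_value,
                    }
                )
    log_rank = pd.DataFrame(lr_rows)

    if interaction:
        cox = cox_ph_fit(records, terms=("sex", "strain", "sex:strain"))
        cox_p = cox.interaction_p
        cox_summary = cox.fit.summary()
    else:
        cox_p = float("nan")
        cox_summary = pd.DataFrame()
    return SurvivalResult(
        medians=medians,
        percent_decreases=percent_decreases,
        log_rank=log_rank,
        cox_interaction_p=cox_p,
        cox_summary=cox_summary,
    )


def write_survival_outputs(result: SurvivalResult, out_dir) -> list[Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in (
        ("km_medians", result.medians),
        ("percent_decreases", result.percent_decreases),
        ("log_rank", result.log_rank),
        ("cox_summary", result.cox_summary.reset_index(names="term")),
    ):
        p = out / f"{name}.csv"
        df.to_csv(p, index=False)
        written.append(p)
    p = out / "cox_interaction.json"
    p.write_text(
        json.dumps({"interaction_p": result.cox_interaction_p}, indent=2) + "\n"
    )
    written.append(p)
    return written
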