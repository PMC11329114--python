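"""Generator determinism, degenerate limits and parameter recovery."""

import numpy as np
import pytest

from damsleep.behaviour_metrics import (
    AnticipationWindows,
    anticipation_index,
    attribute_bouts_to_phase,
    detect_sleep_bouts,
    viability_filter,
)
from damsleep.dam_io import BeamLayout, read_monitor_file, sum_beams
from damsleep.errors import DataError, ParameterError
from damsleep.survival import kaplan_meier, log_rank_test, median_lifespan
from damsleep.synthetic_data import (
    GroupSpec,
    SimConfig,
    gompertz_median,
    intensity_profile,
    simulate_cohort_to_dam_files,
    simulate_fly_minutes,
    simulate_lifespans,
)

GROUP = GroupSpec("CS", "female", 2, n_flies=4)


class TestSimulateFlyMinutes:
    def test_sleep_minutes_emit_zero_counts(self):
        cfg = SimConfig(seed=0, recording_hours=48)
        series, truth = simulate_fly_minutes(cfg, GROUP, 0)
        assert np.all(series.counts[truth["asleep"]] == 0)

    def test_zero_intensity_everywhere_scores_dead(self):
        cfg = SimConfig(
            seed=1,
            recording_hours=48,
            baseline_rate=0.0,
            morning_peak=0.0,
            evening_peak=0.0,
            startle_amplitude=0.0,
        )
        series, _ = simulate_fly_minutes(cfg, GROUP, 0)
        assert series.counts.sum() == 0
        assert viability_filter(series) is False

    def test_named_streams_independent_of_fly_index(self):
        cfg = SimConfig(seed=2, recording_hours=48)
        a1, _ = simulate_fly_minutes(cfg, GROUP, 0)
        a2, _ = simulate_fly_minutes(cfg, GROUP, 0)
        b, _ = simulate_fly_minutes(cfg, GROUP, 1)
        assert np.array_equal(a1.counts, a2.counts)
        assert not np.array_equal(a1.counts, b.counts)

    def test_invalid_run_means_rejected(self):
        with pytest.raises(ParameterError):
            SimConfig(mean_sleep_run_night=0.5)

    def test_intensity_profile_ramp_geometry(self):
        cfg = SimConfig(startle_amplitude=0.0)
        zt = np.array([0.0, 6.0, 9.0, 11.99, 12.0, 18.0, 21.0, 23.99])
        lam = intensity_profile(cfg, GROUP, zt)
        base = cfg.baseline_rate
        assert lam[0] == pytest.approx(base)  # no ramp at lights-on itself
        assert lam[1] == pytest.approx(base)  # evening ramp starts at ZT6
        assert lam[2] == pytest.approx(base + cfg.evening_peak * 0.5)
        assert lam[3] == pytest.approx(base + cfg.evening_peak, abs=0.01)
        assert lam[4] == pytest.approx(base)  # ramp resets after lights-off
        assert lam[6] == pytest.approx(base + cfg.morning_peak * 0.5)
        assert lam[7] == pytest.approx(base + cfg.morning_peak, abs=0.01)


class TestRecovery:
    def test_flat_intensity_gives_ai_half(self):
        cfg = SimConfig(
            seed=3,
            recording_hours=48,
            morning_peak=0.0,
            evening_peak=0.0,
            startle_amplitude=0.0,
        )
        vals = []
        for i in range(32):
            series, _ = simulate_fly_minutes(cfg, GROUP, i)
            ai = anticipation_index(series, AnticipationWindows(transition="lights-on"))
            vals.extend(ai[~np.isnan(ai)])
        assert np.mean(vals) == pytest.approx(0.5, abs=0.05)

    def test_night_bout_length_recovers_generator_mean(self):
        # flat intensity isolates the sleep process from the pre-dawn
        # waking that anticipation deliberately introduces
        cfg = SimConfig(
            seed=4,
            recording_hours=48,  # 2 recording days
            morning_peak=0.0,
            evening_peak=0.0,
            startle_amplitude=0.0,
        )
        lengths = []
        for i in range(32):
            series, _ = simulate_fly_minutes(cfg, GROUP, i)
            out = attribute_bouts_to_phase(detect_sleep_bouts(series), series)
            if not np.isnan(out["bout_length_night"]):
                lengths.append(out["bout_length_night"])
        measured = float(np.mean(lengths))
        assert abs(measured - cfg.mean_sleep_run_night) / cfg.mean_sleep_run_night < 0.10

    def test_measured_bouts_track_ground_truth_with_anticipation(self):
        # under the full diel profile the scorer still recovers the
        # generator's realised night run mean (which the wake-anticipation
        # coupling shortens below the nominal phase mean)
        cfg = SimConfig(seed=4, recording_hours=48)
        lengths = []
        truth_runs = []
        for i in range(32):
            series, truth = simulate_fly_minutes(cfg, GROUP, i)
            out = attribute_bouts_to_phase(detect_sleep_bouts(series), series)
            if not np.isnan(out["bout_length_night"]):
                lengths.append(out["bout_length_night"])
            a = truth["asleep"].astype(int)
            d = np.diff(np.concatenate(([0], a, [0])))
            for st, en in zip(np.flatnonzero(d == 1), np.flatnonzero(d == -1)):
                if series.phase[st] == "night":
                    truth_runs.append(en - st)
        measured = float(np.mean(lengths))
        truth_mean = float(np.mean(truth_runs))
        assert abs(measured - truth_mean) / truth_mean < 0.10

    def test_age_effect_power_with_halved_ramp(self):
        # aged cohort with a halved anticipation ramp: the ANOVA age
        # effect on morning AI should be significant in >= 90% of
        # seeded replicates at n = 32 flies per cell
        import damsleep.calibration as calib

        power = calib.morning_ai_age_effect_power(4000, n_replicates=100)
        assert power >= 0.90

    def test_ai_increases_with_ramp_slope(self):
        means = []
        for mult in (0.25, 1.0, 3.0):
            cfg = SimConfig(seed=5, recording_hours=48, startle_amplitude=0.0)
            grp = GroupSpec("CS", "female", 2, ramp_multiplier=mult)
            vals = []
            for i in range(32):
                series, _ = simulate_fly_minutes(cfg, grp, i)
                ai = anticipation_index(
                    series, AnticipationWindows(transition="lights-on")
                )
                vals.extend(ai[~np.isnan(ai)])
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]


class TestCohortFiles:
    def test_fixed_seed_byte_identical(self, tmp_path):
        cfg = SimConfig(seed=6, groups=(GROUP,), recording_hours=72)
        p1, _ = simulate_cohort_to_dam_files(cfg, tmp_path / "a")
        p2, _ = simulate_cohort_to_dam_files(cfg, tmp_path / "b")
        for a, b in zip(p1, p2):
            assert a.read_bytes() == b.read_bytes()

    def test_all_empty_tubes_parse_to_zero(self, tmp_path):
        cfg = SimConfig(
            seed=7, groups=(GROUP,), recording_hours=72, empty_tube_fraction=1.0
        )
        paths, truth = simulate_cohort_to_dam_files(cfg, tmp_path)
        assert (truth["fate"] == "empty").all()
        rec = read_monitor_file(paths[0], BeamLayout(8, 15))
        assert rec.counts.sum() == 0

    def test_beam_sums_conserve_grand_total(self, tmp_path):
        cfg = SimConfig(seed=8, groups=(GROUP,), recording_hours=72)
        paths, _ = simulate_cohort_to_dam_files(cfg, tmp_path)
        rec = read_monitor_file(paths[0], BeamLayout(8, 15))
        table = sum_beams(rec)
        assert table.to_numpy().sum() == rec.counts.sum()

    def test_dead_fly_trace_goes_silent(self, tmp_path):
        cfg = SimConfig(
            seed=9, groups=(GROUP,), recording_hours=72, dead_fly_fraction=1.0
        )
        paths, truth = simulate_cohort_to_dam_files(cfg, tmp_path)
        rec = read_monitor_file(paths[0], BeamLayout(8, 15))
        table = sum_beams(rec)
        for _, row in truth.iterrows():
            death = int(row["death_minute"])
            assert table[row["tube"]].to_numpy()[death:].sum() == 0


class TestLifespans:
    def test_exponential_limit_median(self):
        a = 0.02
        cfg = SimConfig(
            seed=10,
            groups=(GroupSpec("CS", "female", 2),),
            gompertz_a=a,
            gompertz_b=0.0,
            censoring_rate=0.0,
            n_lifespan_per_group=500,
        )
        records = simulate_lifespans(cfg)
        med = median_lifespan(kaplan_meier(records))
        assert abs(med - np.log(2) / a) / (np.log(2) / a) < 0.10

    def test_gompertz_median_closed_form(self):
        cfg = SimConfig(
            seed=11,
            groups=(GroupSpec("CS", "female", 2),),
            censoring_rate=0.0,
            n_lifespan_per_group=800,
        )
        med = median_lifespan(kaplan_meier(simulate_lifespans(cfg)))
        expected = gompertz_median(cfg.gompertz_a, cfg.gompertz_b)
        assert abs(med - expected) / expected < 0.10

    def test_doubled_male_hazard_shortens_median(self):
        positives = 0
        for seed in range(20):
            cfg = SimConfig(
                seed=100 + seed,
                groups=(
                    GroupSpec("CS", "female", 2),
                    GroupSpec("CS", "male", 2, hazard_multiplier=2.0),
                ),
                n_lifespan_per_group=125,
            )
            records = simulate_lifespans(cfg)
            med = {
                sex: median_lifespan(
                    kaplan_meier([r for r in records if r.sex == sex])
                )
                for sex in ("female", "male")
            }
            positives += med["male"] < med["female"]
        assert positives >= 19  # >= 95% of replicates

    def test_full_censoring_gives_no_deaths_error(self):
        cfg = SimConfig(
            seed=12,
            groups=(
                GroupSpec("CS", "female", 2),
                GroupSpec("CS", "male", 2),
            ),
            censoring_rate=1.0,
            n_lifespan_per_group=30,
        )
        records = simulate_lifespans(cfg)
        groups = [
            [r for r in records if r.sex == "female"],
            [r for r in records if r.sex == "male"],
        ]
        with pytest.raises(DataError):
            log_rank_test(groups)
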