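"""Sleep scoring, anticipation indices and per-fly metric invariants."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from damsleep.behaviour_metrics import (
    AnticipationWindows,
    MetricsConfig,
    anticipation_index,
    attribute_bouts_to_phase,
    bin_trace,
    compute_fly_metrics,
    detect_sleep_bouts,
    per_day_mean,
    phase_activity_totals,
    sleep_minute_mask,
    viability_filter,
)
from damsleep.errors import ParameterError

from conftest import make_series


def rle_sleep_oracle(counts, threshold):
    """Independent run-length-encoding oracle for sleep bouts."""
    bouts = []
    pos = 0
    for is_zero, grp in itertools.groupby(counts, key=lambda c: c == 0):
        run = len(list(grp))
        if is_zero and run >= threshold:
            bouts.append((pos, run))
        pos += run
    return bouts


def pad_day(prefix):
    """Embed a short count pattern at the start of a wake-filled day."""
    counts = np.ones(1440, dtype=int)
    counts[: len(prefix)] = prefix
    return counts


class TestDetectSleepBouts:
    def test_four_minute_run_is_not_sleep(self):
        series = make_series(pad_day([1, 0, 0, 0, 0, 1]))
        assert detect_sleep_bouts(series) == []

    def test_five_and_six_minute_runs(self):
        pattern = [1, 0, 0, 0, 0, 0, 1, 0, 0, 0, 0, 0, 0, 1]
        series = make_series(pad_day(pattern))
        bouts = detect_sleep_bouts(series)
        assert [(b.start, b.duration) for b in bouts] == [(1, 5), (7, 6)]
        assert sum(b.duration for b in bouts) == 11

    def test_all_zero_day_single_maximal_bout(self):
        series = make_series(np.zeros(1440, dtype=int))
        bouts = detect_sleep_bouts(series)
        assert len(bouts) == 1
        assert bouts[0].duration == 1440

    def test_edge_truncated_run_counts(self):
        counts = np.ones(1440, dtype=int)
        counts[-5:] = 0  # run ends at the window edge
        bouts = detect_sleep_bouts(make_series(counts))
        assert [(b.start, b.duration) for b in bouts] == [(1435, 5)]

    def test_threshold_below_one_rejected(self):
        with pytest.raises(ParameterError):
            detect_sleep_bouts(make_series(np.ones(1440, dtype=int)), 0)

    @given(
        st.lists(st.integers(0, 2), min_size=1440, max_size=1440),
        st.integers(1, 20),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_rle_oracle(self, counts, threshold):
        series = make_series(counts)
        got = [(b.start, b.duration) for b in detect_sleep_bouts(series, threshold)]
        assert got == rle_sleep_oracle(counts, threshold)

    @given(st.lists(st.integers(0, 1), min_size=1440, max_size=1440))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_raising_threshold_never_increases_sleep(self, counts):
        series = make_series(counts)
        totals = []
        nbouts = []
        for thr in (5, 8, 15, 30):
            bouts = detect_sleep_bouts(series, thr)
            totals.append(sum(b.duration for b in bouts))
            nbouts.append(len(bouts))
        assert totals == sorted(totals, reverse=True)
        assert nbouts == sorted(nbouts, reverse=True)


class TestPhaseAttribution:
    def test_boundary_spanning_bout_split(self):
        counts = np.ones(1440, dtype=int)
        counts[710:730] = 0  # ZT11:50 - ZT12:10, 20 minutes across lights-off
        series = make_series(counts)
        bouts = detect_sleep_bouts(series)
        out = attribute_bouts_to_phase(bouts, series)
        assert out["sleep_day"] == 10 and out["sleep_night"] == 10
        assert out["bout_number_day"] == 1 and out["bout_number_night"] == 1
        assert out["bout_number_total"] == 1

    def test_onset_rule_assigns_whole_bout(self):
        counts = np.ones(1440, dtype=int)
        counts[710:730] = 0
        series = make_series(counts)
        bouts = detect_sleep_bouts(series)
        out = attribute_bouts_to_phase(bouts, series, boundary_rule="onset")
        assert out["sleep_day"] == 20 and out["sleep_night"] == 0

    def test_night_only_bouts(self):
        counts = np.ones(1440, dtype=int)
        counts[800:830] = 0
        counts[1000:1010] = 0
        series = make_series(counts)
        out = attribute_bouts_to_phase(detect_sleep_bouts(series), series)
        assert out["sleep_day"] == 0
        assert out["sleep_night"] == 40
        assert out["bout_length_night"] == 20.0
        assert np.isnan(out["bout_length_day"])

    @given(st.lists(st.integers(0, 1), min_size=1440, max_size=1440))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_split_conserves_minutes(self, counts):
        series = make_series(counts)
        bouts = detect_sleep_bouts(series)
        out = attribute_bouts_to_phase(bouts, series)
        assert out["sleep_day"] + out["sleep_night"] == out["sleep_total"]
        # brute-force per-minute phase tally
        mask = sleep_minute_mask(series)
        assert out["sleep_day"] == int((mask & series.is_day).sum())
        assert out["sleep_night"] == int((mask & ~series.is_day).sum())


class TestPhaseActivity:
    def test_constant_one_count(self):
        series = make_series(np.ones(2880, dtype=int))
        tab = phase_activity_totals(series)
        assert (tab["activity_day"] == 720).all()
        assert (tab["activity_night"] == 720).all()
        assert (tab["activity_total"] == 1440).all()

    def test_all_zero(self):
        tab = phase_activity_totals(make_series(np.zeros(1440, dtype=int)))
        assert tab.to_numpy().sum() == 0

    def test_random_equals_bruteforce(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(0, 5, size=2880)
        series = make_series(counts)
        tab = phase_activity_totals(series)
        for day in (0, 1):
            sl = slice(day * 1440, (day + 1) * 1440)
            assert tab.loc[day, "activity_day"] == counts[sl][:720].sum()
            assert tab.loc[day, "activity_night"] == counts[sl][720:].sum()


class TestBinTrace:
    def test_48_bins_default(self):
        series = make_series(np.ones(1440, dtype=int))
        trace = bin_trace([series, series])
        assert len(trace) == 48

    def test_constant_two_counts_and_single_fly_sem(self):
        series = make_series(np.full(1440, 2, dtype=int))
        with pytest.warns(UserWarning, match="n=1"):
            trace = bin_trace([series])
        assert (trace["mean"] == 60).all()
        assert (trace["sem"] == 0).all()

    def test_fully_asleep_fly_hits_bin_ceiling(self):
        series = make_series(np.zeros(1440, dtype=int))
        with pytest.warns(UserWarning):
            trace = bin_trace([series], kind="sleep")
        assert (trace["mean"] == 30).all()

    def test_bad_bin_width_rejected(self):
        series = make_series(np.ones(1440, dtype=int))
        with pytest.raises(ParameterError):
            bin_trace([series, series], bin_minutes=7)


class TestAnticipationIndex:
    def test_flat_profile_is_half(self):
        series = make_series(np.ones(1440, dtype=int))
        for transition in ("lights-on", "lights-off"):
            ai = anticipation_index(series, AnticipationWindows(transition=transition))
            assert ai == pytest.approx([0.5])

    def test_all_activity_in_final_three_hours(self):
        counts = np.zeros(1440, dtype=int)
        counts[1440 - 180 :] = 5  # only the last 3 h before lights-on
        ai = anticipation_index(
            make_series(counts), AnticipationWindows(transition="lights-on")
        )
        assert ai == pytest.approx([1.0])

    def test_linear_ramp_discrete_oracle(self):
        counts = np.zeros(1440, dtype=int)
        ramp = np.arange(360)  # 0,1,...,359 over the 6 h before lights-off
        counts[720 - 360 : 720] = ramp
        ai = anticipation_index(
            make_series(counts), AnticipationWindows(transition="lights-off")
        )
        expected = sum(ramp[180:]) / sum(ramp)  # independent discrete sum
        assert ai == pytest.approx([expected])
        assert ai[0] == pytest.approx(0.75, abs=0.01)

    def test_zero_denominator_undefined(self):
        counts = np.ones(1440, dtype=int)
        counts[720 - 360 : 720] = 0
        ai = anticipation_index(
            make_series(counts), AnticipationWindows(transition="lights-off")
        )
        assert np.isnan(ai[0])

    def test_denominator_must_fit_phase(self):
        series = make_series(np.ones(1440, dtype=int), photoperiod_minutes=300)
        with pytest.raises(ParameterError):
            anticipation_index(
                series, AnticipationWindows(3, 6, transition="lights-off")
            )

    def test_bounds_on_random_traces(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            series = make_series(rng.integers(0, 4, size=1440))
            for transition in ("lights-on", "lights-off"):
                ai = anticipation_index(
                    series, AnticipationWindows(transition=transition)
                )
                defined = ai[~np.isnan(ai)]
                assert np.all((defined >= 0) & (defined <= 1))


class TestViabilityFilter:
    def test_two_counts_in_tail_is_dead(self):
        counts = np.ones(1440, dtype=int)
        counts[-180:] = 0
        counts[-5] = 2
        assert viability_filter(make_series(counts)) is False

    def test_exactly_three_counts_is_alive(self):
        counts = np.zeros(1440, dtype=int)
        counts[-10] = 3
        assert viability_filter(make_series(counts)) is True

    def test_fully_zero_trace_is_dead(self):
        assert viability_filter(make_series(np.zeros(1440, dtype=int))) is False


class TestPerDayMean:
    def test_two_days(self):
        assert per_day_mean([600, 700]) == 650

    def test_single_day_identity(self):
        assert per_day_mean([42.0]) == 42.0

    def test_undefined_day_omitted(self):
        assert per_day_mean([0.8, np.nan]) == 0.8

    def test_all_undefined_is_missing(self):
        assert np.isnan(per_day_mean([np.nan, np.nan]))


class TestComputeFlyMetrics:
    def test_fully_asleep_fly(self):
        fm = compute_fly_metrics(make_series(np.zeros(2880, dtype=int)))
        assert fm.alive is False
        assert fm.averaged["activity_total"] == 0
        assert fm.averaged["sleep_total"] == 1440
        assert fm.averaged["bout_number_total"] == 1
        assert fm.averaged["bout_length_total"] == 1440
        assert np.isnan(fm.averaged["morning_ai"])

    def test_fully_awake_constant_fly(self):
        fm = compute_fly_metrics(make_series(np.ones(2880, dtype=int)))
        assert fm.alive is True
        assert fm.averaged["sleep_total"] == 0
        assert fm.averaged["bout_number_total"] == 0
        assert np.isnan(fm.averaged["bout_length_total"])
        assert fm.averaged["morning_ai"] == pytest.approx(0.5)
        assert fm.averaged["evening_ai"] == pytest.approx(0.5)

    def test_conservation_on_random_fly(self):
        rng = np.random.default_rng(3)
        counts = (rng.random(2880) < 0.6) * rng.integers(1, 5, size=2880)
        fm = compute_fly_metrics(make_series(counts.astype(int)))
        pd_tab = fm.per_day
        assert np.allclose(
            pd_tab["activity_day"] + pd_tab["activity_night"],
            pd_tab["activity_total"],
        )
        assert np.allclose(
            pd_tab["sleep_day"] + pd_tab["sleep_night"], pd_tab["sleep_total"]
        )
        assert (pd_tab["sleep_day"] <= 720).all()
        assert (pd_tab["sleep_night"] <= 720).all()

    def test_onset_rule_config_respected(self):
        counts = np.ones(1440, dtype=int)
        counts[710:730] = 0
        fm = compute_fly_metrics(
            make_series(counts), MetricsConfig(bout_boundary_rule="onset")
        )
        assert fm.per_day.loc[0, "sleep_day"] == 20
        assert fm.per_day.loc[0, "sleep_night"] == 0
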