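import datetime as dt

import numpy as np
import pandas as pd
import pytest

from damsleep.dam_io import FlyTimeSeries, LightSchedule


@pytest.fixture
def schedule():
    return LightSchedule(lights_on_clock_time=dt.time(8, 0))


def make_series(counts, fly_id="fly", photoperiod_minutes=720, group=None):
    """Build a FlyTimeSeries from raw per-minute counts starting at lights-on."""
    counts = np.asarray(counts, dtype=np.int64)
    n = len(counts)
    assert n % 1440 == 0
    zt = (np.arange(n) / 60.0) % 24.0
    minute_of_day = np.arange(n) % 1440
    phase = np.where(minute_of_day < photoperiod_minutes, "day", "night")
    start = pd.Timestamp("2024-01-01 08:00:00")
    return FlyTimeSeries(
        fly_id=fly_id,
        group=dict(group or {"strain": "CS", "sex": "female", "age_weeks": 2}),
        counts=counts,
        zt=zt,
        phase=phase,
        window=(start, start + pd.Timedelta(minutes=n - 1)),
    )


@pytest.fixture
def make_fly():
    return make_series


def write_monitor_lines(path, counts_matrix, start="2024-01-01 08:00:00", status=1):
    """Write a per-beam monitor file in the default dialect."""
    start = pd.Timestamp(start)
    lines = []
    for i, row in enumerate(np.asarray(counts_matrix)):
        ts = start + pd.Timedelta(minutes=i)
        fields = [
            str(i + 1),
            ts.strftime("%d %b %y"),
            ts.strftime("%H:%M:%S"),
            str(status),
            *["0"] * 6,
            "0",
            *[str(int(v)) for v in row],
        ]
        lines.append("\t".join(fields))
    path.write_text("\n".join(lines) + "\n")
    return path
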