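"""Shared fixtures: a small simulated study and a hand-computed 3-day log."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from porpoisepam import detection, simulate

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_config():
    """Two sites, six months, denser than the study defaults so that the
    foraging and weekly stages have enough positive hours to exercise."""
    return simulate.SimulationConfig(
        site_ids=("A", "B"),
        start_date="2015-01-01",
        end_date="2015-07-01",
        baseline_rate=0.05,
        seasonal_amplitude=1.5,
        garma_phi=0.4,
        overdispersion_sigma=2.0,
        gap_schedule=[("B", ("2015-03-10", "2015-03-20"))],
        seed=42,
    )


@pytest.fixture(scope="session")
def small_truth(small_config):
    return simulate.simulate_occupancy(small_config)


@pytest.fixture(scope="session")
def small_trains(small_truth, small_config):
    return simulate.simulate_click_trains(small_truth, small_config)


@pytest.fixture(scope="session")
def small_effort(small_config):
    return simulate.build_effort(small_config)


@pytest.fixture(scope="session")
def small_hours(small_trains, small_effort):
    filtered = detection.filter_trains(small_trains)
    return detection.bin_hourly(filtered, small_effort)


def _train(site, start, icis_us, quality):
    return (site, pd.Timestamp(start), np.asarray(icis_us, dtype=float), quality)


@pytest.fixture(scope="session")
def handbuilt_log():
    """A 3.5-day single-site log whose every summary is hand-computed.

    Effort: 2015-03-01 00:00 to 2015-03-04 12:30 (the last half hour
    makes hour 12 of day 4 incomplete).  Detection layout:

    * day 1 (Sun, ISO week 2015-W09): hour 0 train spanning minutes 5-6,
      hour 10 train in minute 30 (carries a 9,500 us buzz ICI), hour 23
      train spanning minutes 58-59 and ending exactly on the midnight
      boundary (half-open => day 1 only).  3 PPHs.
    * day 2: nothing.  0 PPHs.
    * day 3: one train in each of hours 1-5, minute 0.  5 PPHs.
    * day 4: hour 0 train in minute 10; an extra train in the incomplete
      hour 12.  1 PPH from complete hours.
    * plus one Low-quality train and one bogus-quality train, both of
      which the filter must drop before binning.

    Expected monthly row (per-year mode): daily PPHs {3, 0, 5, 1} =>
    median 2, total 9, max 5, proportion 3/4, 4 recording days.
    Weekly: W09 3/24 positive complete hours; W10 6/60.
    """
    forty_s = [400_000.0] * 100               # 100 ICIs of 0.4 s = 40 s span
    two_s = [500_000.0] * 4                   # 2 s span
    one_s = [250_000.0] * 4                   # 1 s span
    sixty_one_s = [1_000_000.0] * 61          # exactly 61 s span
    trains = [
        _train("S", "2015-03-01 00:05:30", forty_s, "Hi"),            # minutes 5,6
        _train("S", "2015-03-01 10:30:10", [9_500.0] + two_s, "Med"),  # buzz hour
        _train("S", "2015-03-01 23:58:59", sixty_one_s, "Hi"),        # ends 00:00:00
        _train("S", "2015-03-03 01:00:05", one_s, "Hi"),
        _train("S", "2015-03-03 02:00:05", one_s, "Med"),
        _train("S", "2015-03-03 03:00:05", one_s, "Hi"),
        _train("S", "2015-03-03 04:00:05", one_s, "Med"),
        _train("S", "2015-03-03 05:00:05", one_s, "Hi"),
        _train("S", "2015-03-04 00:10:30", two_s, "Hi"),
        _train("S", "2015-03-04 12:05:00", two_s, "Med"),             # incomplete hour
        _train("S", "2015-03-02 12:00:05", one_s, "Low"),             # filtered out
        _train("S", "2015-03-02 13:00:05", one_s, "Junk"),            # unknown label
    ]
    trains_df = pd.DataFrame(trains, columns=["site", "start", "icis", "quality"])
    effort = pd.DataFrame(
        [("S", pd.Timestamp("2015-03-01 00:00"), pd.Timestamp("2015-03-04 12:30"))],
        columns=["site", "start", "end"],
    )
    return trains_df, effort
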