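"""Click-train log processing: from train records to analysis-ready series.

The C-POD-style log lists one row per detected click train (site, start
time, inter-click intervals in microseconds, classifier quality class).
This module reduces those logs, together with the recording-effort
table, to the series the downstream models consume:

* hourly detection-positive minutes (the GARMA response), restricted to
  hours with a complete 60 minutes of recording;
* porpoise-positive-hour (PPH) flags;
* monthly metrics (median / total / maximum PPHs per day, proportion of
  days present) used for the density-prediction comparison;
* ISO-8601 weekly proportions of porpoise-positive hours.

All timestamps are fixed-offset EST (UTC-5, no daylight saving), held as
naive datetimes.  Hours and minutes are half-open intervals
``[t, t + 1 unit)``: a train ending exactly on a boundary does not
occupy the following unit.
"""

from __future__ import annotations

import datetime as dt
import logging

import numpy as np
import pandas as pd

__all__ = [
    "filter_trains",
    "bin_hourly",
    "pph_flags",
    "monthly_metrics",
    "iso_week",
    "weekly_occurrence",
    "read_trains_csv",
    "write_trains_csv",
]

logger = logging.getLogger(__name__)

VALID_QUALITY = ("Hi", "Med", "Low")
DEFAULT_KEEP = frozenset({"Hi", "Med"})


def read_trains_csv(path) -> pd.DataFrame:
    """Read a click-train CSV (site, train_start_iso8601, ici_list_us, quality)."""
    df = pd.read_csv(path, dtype={"site": str, "quality": str})
    df["start"] = pd.to_datetime(df["train_start_iso8601"])
    df["icis"] = df["ici_list_us"].map(
        lambda s: np.array([float(v) for v in s.split(";")]) if isinstance(s, str) and s else np.array([])
    )
    return df[["site", "start", "icis", "quality"]]


def write_trains_csv(trains: pd.DataFrame, path) -> None:
    out = pd.DataFrame(
        {
            "site": trains["site"],
            "train_start_iso8601": trains["start"].dt.strftime("%Y-%m-%dT%H:%M:%S.%f"),
            "ici_list_us": trains["icis"].map(lambda a: ";".join(str(int(v)) for v in a)),
            "quality": trains["quality"],
        }
    )
    out.to_csv(path, index=False)


def filter_trains(trains: pd.DataFrame, keep_classes=DEFAULT_KEEP) -> pd.DataFrame:
    """Keep trains whose quality class is in ``keep_classes`` (order preserved).

    Records with an unknown quality label are rejected with a logged
    warning; the count of rejected records is attached to the result as
    ``result.attrs["n_unknown_quality"]``.
    """
    keep = set(keep_classes)
    quality = trains["quality"]
    known = quality.isin(VALID_QUALITY)
    n_unknown = int((~known).sum())
    if n_unknown:
        logger.warning("rejected %d train(s) with unknown quality label", n_unknown)
    out = trains[known & quality.isin(keep)].reset_index(drop=True)
    out.attrs["n_unknown_quality"] = n_unknown
    return out


def _effort_by_site(effort: pd.DataFrame) -> dict:
    """Sorted, merged (start, end) interval lists in epoch seconds per site."""
    by_site = {}
    for site, grp in effort.groupby("site"):
        ivs = sorted(
            (pd.Timestamp(s).value // 10**9, pd.Timestamp(e).value // 10**9)
            for s, e in zip(grp["start"], grp["end"])
        )
        merged = []
        for s, e in ivs:
            if e <= s:
                raise ValueError(f"empty effort interval for site {site}")
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        by_site[str(site)] = merged
    return by_site


def bin_hourly(trains: pd.DataFrame, effort: pd.DataFrame) -> pd.DataFrame:
    """Count detection-positive minutes per recorded hour.

    A minute is detection-positive iff at least one train overlaps any
    part of it; the train span runs from its start to start plus the sum
    of its inter-click intervals.  Every hour intersecting recording
    effort yields a row; ``complete`` marks hours fully covered by
    effort, and only those should enter any model.

    Raises if a train falls outside all effort intervals for its site.
    """
    effort_ivs = _effort_by_site(effort)

    # detection-positive minutes per site, as epoch-minute integers
    pos_minutes: dict[str, set] = {s: set() for s in effort_ivs}
    for site, start, icis in zip(trains["site"], trains["start"], trains["icis"]):
        site = str(site)
        if site not in effort_ivs:
            raise ValueError(f"train at site {site!r} has no effort intervals")
        t0 = pd.Timestamp(start).value / 1e9  # seconds, float
        span_s = float(np.sum(icis)) / 1e6
        t1 = t0 + span_s
        if not any(s <= t0 and t1 <= e for s, e in effort_ivs[site]):
            raise ValueError(
                f"train at site {site!r} starting {start} lies outside recording effort"
            )
        m0 = int(t0 // 60)
        m1 = int(t1 // 60)
        if t1 == m1 * 60 and m1 > m0:  # half-open: exact boundary excluded
            m1 -= 1
        pos_minutes[site].update(range(m0, m1 + 1))

    rows = []
    for site, ivs in effort_ivs.items():
        positives = pos_minutes[site]
        for s, e in ivs:
            h0 = s // 3600
            h_last = (e - 1) // 3600
            for h in range(h0, h_last + 1):
                hs, he = h * 3600, (h + 1) * 3600
                complete = s <= hs and he <= e
                base_min = h * 60
                count = sum(1 for m in range(base_min, base_min + 60) if m in positives)
                rows.append((site, h, count, complete))
    out = pd.DataFrame(rows, columns=["site", "hour_epoch", "minutes_detected", "complete"])
    out["hour_start"] = pd.to_datetime(out["hour_epoch"] * 3600, unit="s")
    out = out.sort_values(["site", "hour_start"]).reset_index(drop=True)
    n_incomplete = int((~out["complete"]).sum())
    if n_incomplete:
        logger.info("flagged %d incomplete hour(s); excluded from models", n_incomplete)
    return out[["site", "hour_start", "minutes_detected", "complete"]]


def pph_flags(hours: pd.DataFrame) -> pd.Series:
    """Porpoise-positive-hour flag: at least one detected train in the hour."""
    return hours["minutes_detected"] >= 1


def _complete(hours: pd.DataFrame) -> pd.DataFrame:
    return hours[hours["complete"]].copy()


def monthly_metrics(hours: pd.DataFrame, pool_years: bool = False) -> pd.DataFrame:
    """Monthly acoustic metrics from complete hours.

    Per day: the PPH count.  Per month: median, total and maximum of the
    daily PPH counts, and the proportion of recording days with at least
    one PPH.  A recording day is a calendar day with >= 1 complete hour.
    Months with zero recording days are omitted (logged).

    With ``pool_years=True``, days from the same calendar month of
    different years are pooled before aggregating (for comparison with
    climatological monthly density predictions).
    """
    hrs = _complete(hours)
    if hrs.empty:
        return pd.DataFrame(
            columns=["site", "year", "month", "median_pph", "total_pph",
                     "max_pph", "proportion_days", "n_recording_days"]
        )
    hrs["pph"] = pph_flags(hrs).astype(int)
    hrs["date"] = hrs["hour_start"].dt.normalize()
    daily = hrs.groupby(["site", "date"], as_index=False)["pph"].sum()
    daily["month"] = daily["date"].dt.month
    daily["year"] = daily["date"].dt.year
    keys = ["site", "month"] if pool_years else ["site", "year", "month"]
    rows = []
    for key, grp in daily.groupby(keys):
        pph = grp["pph"].to_numpy()
        rec = dict(zip(keys, key if isinstance(key, tuple) else (key,)))
        rec.update(
            median_pph=float(np.median(pph)),
            total_pph=int(np.sum(pph)),
            max_pph=int(np.max(pph)),
            proportion_days=float(np.mean(pph >= 1)),
            n_recording_days=int(len(pph)),
        )
        rows.append(rec)
    out = pd.DataFrame(rows)
    if not pool_years:
        out = out[["site", "year", "month", "median_pph", "total_pph",
                   "max_pph", "proportion_days", "n_recording_days"]]
    return out.reset_index(drop=True)


def iso_week(date) -> tuple[int, int]:
    """ISO-8601 (year, week) of a calendar date.

    Weeks start on Monday and week 1 is the week containing the first
    Thursday of the year, so early-January days can belong to the final
    week of the previous ISO year and vice versa.
    """
    if isinstance(date, (pd.Timestamp, dt.datetime)):
        date = date.date()
    iso = date.isocalendar()
    return int(iso[0]), int(iso[1])


def weekly_occurrence(hours: pd.DataFrame) -> pd.DataFrame:
    """Proportion of complete hours per ISO week that are porpoise-positive."""
    hrs = _complete(hours)
    if hrs.empty:
        return pd.DataFrame(
            columns=["site", "iso_year", "iso_week", "proportion_hours_present", "n_complete_hours"]
        )
    iso = hrs["hour_start"].dt.isocalendar()
    hrs["iso_year"] = iso["year"].astype(int)
    hrs["iso_week"] = iso["week"].astype(int)
    hrs["pph"] = pph_flags(hrs).astype(int)
    out = (
        hrs.groupby(["site", "iso_year", "iso_week"])
        .agg(
            proportion_hours_present=("pph", "mean"),
            n_complete_hours=("pph", "size"),
        )
        .reset_index()
    )
    return out
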