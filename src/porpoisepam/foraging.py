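"""Inter-click-interval foraging classification and its diel/seasonal GAM.

Porpoise echolocation during prey capture ends in a "buzz" of very fast
clicking; an inter-click interval (ICI) of 10 ms or less is the standard
threshold for inferring foraging from click-train logs.  An hour during
which porpoises were detected is classed foraging-positive when the
minimum ICI pooled over all of its (quality-filtered) trains is at or
below the threshold.  Presence/absence of foraging is then modelled
against hour of the day and Julian day with a binomial cyclic-spline
GAM, selected by AIC and scored with a confusion matrix and ROC AUC.

Serial dependence between hours of the (unevenly spaced) foraging
series is deliberately not modelled; hours are treated as independent.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .gam import SmoothTerm, confusion_matrix, fit_gam, roc_auc, select_by_aic

__all__ = [
    "subset_detection_hours",
    "classify_foraging",
    "buzz_support_summary",
    "foraging_gam",
    "monthly_foraging_proportions",
    "diel_foraging_proportions",
]

logger = logging.getLogger(__name__)

THRESHOLD_US = 10_000.0
MIN_HOURS_FOR_GAM = 24  # sites with fewer porpoise-positive hours are not modelled


def subset_detection_hours(hours: pd.DataFrame) -> pd.DataFrame:
    """Complete hours during which porpoises were detected (minutes >= 1)."""
    out = hours[(hours["complete"]) & (hours["minutes_detected"] >= 1)]
    return out.reset_index(drop=True)


def classify_foraging(
    trains: pd.DataFrame,
    positive_hours: pd.DataFrame,
    threshold_us: float = THRESHOLD_US,
) -> pd.DataFrame:
    """Classify each porpoise-positive hour as foraging or not.

    All ICIs of all trains within the hour are pooled; the hour is
    foraging-positive iff the minimum pooled ICI is at or below the
    threshold (inclusive).  ``n_buzz_icis`` counts ICIs at or below the
    threshold, supporting robustness summaries.

    Raises if a porpoise-positive hour has no trains (inconsistent inputs).
    """
    grouped = {}
    if len(trains):
        t = trains.copy()
        t["hour_start"] = t["start"].dt.floor("h")
        grouped = {
            key: np.concatenate(list(grp["icis"]))
            for key, grp in t.groupby(["site", "hour_start"])
        }
    rows = []
    for site, hour_start in zip(positive_hours["site"], positive_hours["hour_start"]):
        key = (site, hour_start)
        if key not in grouped:
            raise ValueError(
                f"porpoise-positive hour {hour_start} at site {site!r} has no trains"
            )
        icis = grouped[key]
        min_ici = float(np.min(icis))
        n_buzz = int(np.sum(icis <= threshold_us))
        rows.append((site, hour_start, min_ici, min_ici <= threshold_us, n_buzz))
    return pd.DataFrame(
        rows, columns=["site", "hour_start", "min_ici_us", "foraging", "n_buzz_icis"]
    )


def buzz_support_summary(foraging_hours: pd.DataFrame, min_icis: int = 5) -> pd.Series:
    """Per-site proportion of foraging-positive hours with >= `min_icis` buzz ICIs."""
    fpos = foraging_hours[foraging_hours["foraging"]]
    if fpos.empty:
        return pd.Series(dtype=float)
    return fpos.groupby("site")["n_buzz_icis"].apply(lambda v: float(np.mean(v >= min_icis)))


def _with_covariates(fhours: pd.DataFrame) -> pd.DataFrame:
    df = fhours.copy()
    df["hour"] = df["hour_start"].dt.hour.astype(float)
    df["jday"] = df["hour_start"].dt.dayofyear.astype(float)
    df["y"] = df["foraging"].astype(float)
    return df


def foraging_gam(
    fhours: pd.DataFrame,
    k: int = 10,
    min_hours: int = MIN_HOURS_FOR_GAM,
    threshold: float = 0.5,
):
    """Binomial cyclic-spline GAM of foraging presence on hour and Julian day.

    Candidate models {intercept}, {hour}, {jday}, {hour + jday} are
    compared by AIC with a 2-unit parsimony margin.  The Julian-day period is fixed at 366 so leap-year
    days are valid; day 366 wraps onto day 1.  Returns the selected
    :class:`~porpoisepam.gam.GamFit` with the confusion matrix and AUC
    attached in ``fit.score``, or ``None`` when the site has too few
    porpoise-positive hours or a single class.
    """
    df = _with_covariates(fhours)
    if len(df) < min_hours:
        logger.info("only %d porpoise-positive hours; foraging GAM skipped", len(df))
        return None
    if df["y"].nunique() < 2:
        raise ValueError("foraging series has a single class; cannot fit a binomial GAM")

    hour_term = SmoothTerm("hour", "cyclic", period=24.0, k=k)
    jday_term = SmoothTerm("jday", "cyclic", period=366.0, k=k)
    candidates = [[], [hour_term], [jday_term], [hour_term, jday_term]]
    fits = []
    for terms in candidates:
        try:
            fits.append(fit_gam(df, "y", terms, family="binomial"))
        except np.linalg.LinAlgError:  # pragma: no cover - degenerate designs
            continue
    best = select_by_aic(fits)
    prob = best.fitted
    best.score = confusion_matrix(df["y"].to_numpy(), prob, threshold=threshold)
    if df["y"].nunique() == 2 and len(best.terms) > 0:
        best.score["auc"] = roc_auc(df["y"].to_numpy(), prob)
    else:
        best.score["auc"] = np.nan
    return best


def monthly_foraging_proportions(fhours: pd.DataFrame) -> pd.DataFrame:
    """Proportion of porpoise-positive hours classed as foraging, per site-month."""
    df = fhours.copy()
    df["month"] = df["hour_start"].dt.month
    return (
        df.groupby(["site", "month"], as_index=False)
        .agg(proportion_foraging=("foraging", "mean"), n_hours=("foraging", "size"))
    )


def diel_foraging_proportions(fhours: pd.DataFrame) -> pd.DataFrame:
    """Proportion of porpoise-positive hours classed as foraging, per hour of day."""
    df = fhours.copy()
    df["hour"] = df["hour_start"].dt.hour
    return (
        df.groupby(["site", "hour"], as_index=False)
        .agg(proportion_foraging=("foraging", "mean"), n_hours=("foraging", "size"))
    )
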