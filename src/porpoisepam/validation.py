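"""Validation of habitat-based density predictions against acoustic metrics.

Monthly habitat-model density predictions (individuals per 100 km^2) are
compared with four acoustic detection metrics per site -- median PPHs
per day, total PPHs per month, maximum PPHs per day, and the proportion
of days per month with a detection -- using Spearman's rank correlation.
Months are aligned by site with pairwise deletion; by default multi-year
data are pooled into the 12 calendar months before ranking, matching the
climatological nature of the predictions (a per-year mode is available
through the metrics table handed in).  A metric that is constant across
months (e.g. a median of 0 everywhere) has no rank ordering and is
reported as degenerate (rho = NA).  p-values are reported raw, without
multiple-testing correction.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from scipy.stats import t as t_dist

__all__ = ["spearman", "validate", "METRICS"]

METRICS = {
    "median_pph": "median_pph",
    "total_pph": "total_pph",
    "max_pph": "max_pph",
    "proportion_days": "proportion_days",
}


def _rho_of_ranks(rx: np.ndarray, ry: np.ndarray) -> float:
    """Pearson correlation of midranks (Spearman's rho with tie correction)."""
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float(np.sum(rx**2)) * float(np.sum(ry**2)))
    return float(np.sum(rx * ry)) / denom


def spearman(x, y, exact_max_n: int = 8) -> tuple[float, float]:
    """Spearman rank correlation with a permutation-exact small-sample p.

    rho is the Pearson correlation of midranks.  For n <= ``exact_max_n``
    the two-sided p-value is exact: the proportion of the n! permutations
    of y whose |rho| is at least the observed |rho| (ties handled through
    midranks).  For larger n the usual t approximation with n - 2 degrees
    of freedom is used.

    Raises ``ValueError`` for constant input (no rank ordering exists).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant input: Spearman correlation is undefined")
    rx, ry = rankdata(x), rankdata(y)
    rho = _rho_of_ranks(rx, ry)
    if n <= exact_max_n:
        count = 0
        total = 0
        for perm in itertools.permutations(ry):
            r = _rho_of_ranks(rx, np.asarray(perm))
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
            total += 1
        p = count / total
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t_stat = rho * math.sqrt((n - 2) / (1.0 - rho**2))
            p = 2.0 * float(t_dist.sf(abs(t_stat), n - 2))
    return rho, p


def validate(metrics: pd.DataFrame, predictions: pd.DataFrame) -> pd.DataFrame:
    """Correlate the four monthly acoustic metrics with density predictions.

    ``metrics`` must carry one row per site-month (pooled across years,
    via ``monthly_metrics(..., pool_years=True)``, or per year-month for
    the per-year mode); ``predictions`` one density per site-month.
    Months present in only one table are dropped pairwise, identically
    for all four metrics.  Fewer than 3 aligned months, or a constant
    metric, yields a degenerate row with rho/p reported as NaN.
    """
    merged = metrics.merge(predictions, on=["site", "month"], how="inner")
    rows = []
    for site, grp in merged.groupby("site"):
        dens = grp["density_per_100km2"].to_numpy(dtype=float)
        for metric in METRICS:
            vals = grp[metric].to_numpy(dtype=float)
            row = {
                "site": site,
                "metric": metric,
                "n_months": len(grp),
                "rho": np.nan,
                "p_value": np.nan,
                "degenerate": False,
            }
            if len(grp) < 3 or np.all(vals == vals[0]) or np.all(dens == dens[0]):
                row["degenerate"] = True
            else:
                rho, p = spearman(vals, dens)
                row["rho"], row["p_value"] = rho, p
            rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["multiple_testing_correction"] = "none"
    return out
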