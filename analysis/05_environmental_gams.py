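#!/usr/bin/env python
"""Relate weekly porpoise occurrence to environmental covariates.

Joins ISO-weekly medians of SST, ln chlorophyll a and moon fraction onto
the weekly occurrence proportions, fits the Gaussian natural-spline GAM
per site with AICc subset selection, and writes fit summaries plus
centered response curves under ``results/models/``.
"""

import argparse
import json
import pathlib

import pandas as pd

from porpoisepam import environment


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=pathlib.Path, default=pathlib.Path("results/data"))
    ap.add_argument("--processed", type=pathlib.Path, default=pathlib.Path("results/processed"))
    ap.add_argument("--out", type=pathlib.Path, default=pathlib.Path("results/models"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    env = pd.read_csv(args.data / "environment.csv", parse_dates=["date"])
    weekly = pd.read_csv(args.processed / "weekly.csv", dtype={"site": str})
    records = environment.weekly_medians(env, weekly)

    results = {}
    for site, grp in records.groupby("site"):
        if len(grp) < 30:
            print(f"site {site}: only {len(grp)} weeks, skipped")
            continue
        fit = environment.env_gam(grp.reset_index(drop=True))
        results[site] = fit.summary()
        kept = [t.name for t in fit.terms]
        print(f"site {site}: retained {kept or ['intercept only']}, "
              f"deviance explained {100 * fit.deviance_explained:.1f}%, "
              f"adj. R2 {fit.r2_adj:.2f}")
        for cov in fit.slices:
            curve = environment.response_curve(fit, cov)
            curve.to_csv(args.out / f"env_curve_site{site}_{cov}.csv", index=False)
            peak = curve.loc[curve["effect"].idxmax(), "x"]
            print(f"  {cov}: partial effect peaks at {peak:.2f}")
    with open(args.out / "env_gams.json", "w") as fh:
        json.dump(results, fh, indent=1)


if __name__ == "__main__":
    main()
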