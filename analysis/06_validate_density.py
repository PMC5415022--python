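#!/usr/bin/env python
"""Compare monthly acoustic metrics with habitat-model density predictions.

Spearman rank correlations between each site's pooled monthly acoustic
metrics (median / total / max PPHs per day, proportion of days present)
and the monthly density predictions.  Writes the correlation table to
``results/validation/spearman_table.csv``.
"""

import argparse
import pathlib

import pandas as pd

from porpoisepam import validation


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=pathlib.Path, default=pathlib.Path("results/data"))
    ap.add_argument("--processed", type=pathlib.Path, default=pathlib.Path("results/processed"))
    ap.add_argument("--out", type=pathlib.Path, default=pathlib.Path("results/validation"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    metrics = pd.read_csv(args.processed / "monthly_metrics_pooled.csv", dtype={"site": str})
    density = pd.read_csv(args.data / "density.csv", dtype={"site": str})
    table = validation.validate(metrics, density)
    table.to_csv(args.out / "spearman_table.csv", index=False)

    for _, row in table.iterrows():
        if row["degenerate"]:
            print(f"site {row['site']} {row['metric']}: NA (constant metric)")
        else:
            print(f"site {row['site']} {row['metric']}: "
                  f"rho = {row['rho']:.2f} (p = {row['p_value']:.3f}, "
                  f"n = {row['n_months']} months)")


if __name__ == "__main__":
    main()
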