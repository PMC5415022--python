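#!/usr/bin/env python
"""Generate the synthetic C-POD study inputs.

Writes click-train logs, recording-effort intervals, daily environmental
series and monthly habitat-model density predictions under
``results/data/`` (plus the latent truth for downstream checks).
"""

import argparse
import pathlib

from porpoisepam import simulate


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", type=pathlib.Path, default=pathlib.Path("results/data"))
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()

    cfg = simulate.SimulationConfig(seed=args.seed)
    objs = simulate.write_all(cfg, args.out)
    trains = objs["trains"]
    hours = objs["truth"].hours
    print(f"wrote {args.out}/: {len(trains)} click trains over "
          f"{hours['site'].nunique()} sites, "
          f"{hours['hour_start'].nunique()} hours "
          f"({cfg.start_date} .. {cfg.end_date})")
    pos = hours[hours["in_effort"]]["minutes"] >= 1
    print(f"latent occupancy: {100 * pos.mean():.1f}% of in-effort hours positive")


if __name__ == "__main__":
    main()
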