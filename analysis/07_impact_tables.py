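#!/usr/bin/env python
"""Translate rate effects into person counts and percent reductions.

Reads the per-year effect table produced by the placebo-inference driver,
converts each year's effect into avoided deaths via the treated unit's
population, reports the significance-gated cumulative count, and prints the
standalone worked examples of the impact arithmetic.
"""

import argparse
from pathlib import Path

import pandas as pd

from scmort import avoided_deaths, percent_reduction


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--effects", type=Path, default=Path("results/effects.csv"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    table = pd.read_csv(args.effects, index_col="year")
    table["stars"] = table["stars"].fillna("")
    impact = table[["effect", "p", "stars", "avoided_deaths", "percent_reduction"]].copy()
    impact["avoided_deaths"] = impact["avoided_deaths"].round().astype(int)
    impact["percent_reduction"] = impact["percent_reduction"].round().astype(int)
    args.outdir.mkdir(parents=True, exist_ok=True)
    impact.to_csv(args.outdir / "impact_table.csv")
    print(impact.to_string())

    sig = impact.index[impact["p"] <= 0.10]
    if len(sig):
        cum = impact.loc[sig[0]:, "avoided_deaths"].sum()
        print(f"\ncumulative avoided deaths {sig[0]}-{impact.index[-1]}: {cum}")

    print("\nworked examples of the impact arithmetic:")
    print(f"  effect -2.20/100k on 39.5M people -> "
          f"{avoided_deaths(-2.20, 39_500_000):.0f} avoided deaths")
    print(f"  rates 4.53 vs 6.34  -> {percent_reduction(4.53, 6.34):.0f}% reduction")
    print(f"  rates 17.10 vs 20.62 -> {percent_reduction(17.10, 20.62):.0f}% reduction")


if __name__ == "__main__":
    main()
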