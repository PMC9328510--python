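#!/usr/bin/env python
"""Select the donor pool by pre-intervention closeness to the treated unit.

Prints the ranked candidate table (per-year signed gaps, close-year counts,
direction) and the selected pool — up to 9 most-often-close-from-below and 9
from-above units among candidates close in at least 4 of the 6 pre years —
and writes both as CSV.
"""

import argparse
from pathlib import Path

from scmort import StudyConfig, read_panel, select_donor_pool, yearly_closeness
from scmort.donors import closeness_radius


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--panel", type=Path, default=Path("results/panels/panel.csv"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    panel = read_panel(args.panel, population_col="population")
    cfg = StudyConfig(treated_unit="treated")
    radius = closeness_radius(panel, cfg)
    table = yearly_closeness(panel, cfg)
    pool = select_donor_pool(panel, cfg)

    args.outdir.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.outdir / "donor_closeness.csv")
    (args.outdir / "donor_pool.txt").write_text("\n".join(pool) + "\n")

    print(f"closeness radius: {radius:.3f} deaths/100k (2 x treated pre-period SD)")
    print(table[["n_close_below", "n_close_above", "mean_abs_gap", "direction"]]
          .sort_values("mean_abs_gap").to_string())
    below = [u for u in pool if table.loc[u, "direction"] == "below"]
    print(f"\nselected pool ({len(pool)}): {len(below)} below, {len(pool) - len(below)} above")
    print(", ".join(pool))


if __name__ == "__main__":
    main()
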