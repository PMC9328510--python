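#!/usr/bin/env python
"""Fit the synthetic control and report weights, fit quality, and gaps.

The synthetic control is the convex donor combination matching the treated
unit's pre-intervention outcomes (every pre year plus the pre-period mean,
equal predictor weights).  Writes the donor-weight table and the per-year
actual/synthetic/gap trajectory.
"""

import argparse
from pathlib import Path

import pandas as pd

from scmort import StudyConfig, build_predictors, fit_weights, read_panel, select_donor_pool


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--panel", type=Path, default=Path("results/panels/panel.csv"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("--plot", action="store_true",
                    help="write trajectory.png (requires matplotlib)")
    args = ap.parse_args()

    panel = read_panel(args.panel, population_col="population")
    cfg = StudyConfig(treated_unit="treated")
    donors = select_donor_pool(panel, cfg)
    pred = build_predictors(panel, cfg, donors)
    fit = fit_weights(pred, panel, cfg)

    args.outdir.mkdir(parents=True, exist_ok=True)
    fit.weights.round(4).to_csv(args.outdir / "donor_weights.csv")
    traj = pd.DataFrame(
        {"actual": panel.series("treated"), "synthetic": fit.synthetic, "gap": fit.gaps}
    )
    traj.to_csv(args.outdir / "trajectory.csv", index_label="year")

    if args.plot:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(7, 4))
        ax.plot(traj.index, traj["actual"], label="treated", color="black")
        ax.plot(traj.index, traj["synthetic"], label="synthetic control",
                color="black", linestyle="--")
        ax.axvline(cfg.intervention_year, color="grey", linewidth=0.8)
        ax.set_xlabel("year")
        ax.set_ylabel("deaths per 100,000")
        ax.legend()
        fig.tight_layout()
        fig.savefig(args.outdir / "trajectory.png", dpi=150)
        print(f"wrote {args.outdir}/trajectory.png")

    print(f"pre-period RMSPE: {fit.rmspe_pre:.4f} deaths/100k")
    active = fit.weights[fit.weights > 1e-4].sort_values(ascending=False)
    print("non-negligible donor weights:")
    print(active.round(3).to_string())
    print("\npost-period gaps (treated - synthetic):")
    print(traj.loc[cfg.post_years, "gap"].round(2).to_string())


if __name__ == "__main__":
    main()
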