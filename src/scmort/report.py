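"""Translate rate effects into avoided deaths and percent reductions.

A rate effect α_t (deaths/100,000) on a population of P_t persons is
−α_t × P_t / 100,000 avoided deaths (positive = deaths avoided); the percent
reduction compares actual with counterfactual rates, 100 × (synthetic −
actual) / synthetic.  Full precision is carried internally everywhere;
rounding (effects to 2 decimals, deaths to whole persons, percentages to
whole points) happens only at display time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import StudyConfig, star_tier
from .panel import MortalityPanel
from .placebo import PlaceboEnsemble, pseudo_p_series
from .scm import SCMFit

__all__ = [
    "EffectReport",
    "avoided_deaths",
    "percent_reduction",
    "cumulative_impact",
    "build_effect_report",
]


def avoided_deaths(effect: float, population: float) -> float:
    """Person-count equivalent of a rate effect: −effect × population / 1e5.

    Negative effects (mortality below counterfactual) give positive avoided
    deaths.  Display rounds to the nearest whole person.
    """
    if population <= 0:
        raise ValueError("population must be positive")
    return -effect * population / 100_000.0


def percent_reduction(actual_rate: float, synthetic_rate: float) -> float:
    """100 × (synthetic − actual) / synthetic; display rounds to integer."""
    if synthetic_rate <= 0:
        raise ValueError("synthetic rate must be positive")
    return 100.0 * (synthetic_rate - actual_rate) / synthetic_rate


def cumulative_impact(
    effects: pd.Series,
    from_year: int,
    to_year: int,
    populations: pd.Series,
) -> float:
    """Σ_t avoided_deaths(α_t, P_t) over [from_year, to_year] inclusive."""
    years = list(range(from_year, to_year + 1))
    missing = [y for y in years if y not in effects.index]
    if missing:
        raise ValueError(f"effects missing for years {missing}")
    missing_pop = [y for y in years if y not in populations.index or not np.isfinite(populations[y])]
    if missing_pop:
        raise ValueError(f"population missing for years {missing_pop}")
    return float(
        sum(avoided_deaths(float(effects[y]), float(populations[y])) for y in years)
    )


@dataclass(frozen=True)
class EffectReport:
    """Per-year effects with inference and person-count translation.

    ``table`` is indexed by post-intervention year with columns: actual,
    synthetic, effect (deaths/100k), p, stars, avoided_deaths (persons),
    percent_reduction.  ``cumulative_avoided`` sums avoided deaths over
    ``cumulative_range`` (by default the first significant year at the
    loosest tier through the last year; None when no year is significant).
    """

    table: pd.DataFrame
    cumulative_avoided: float | None
    cumulative_range: tuple[int, int] | None
    scenario: str = "baseline"

    def display_table(self) -> pd.DataFrame:
        """Rounded view matching conventional reporting precision."""
        disp = self.table.copy()
        for col in ("actual", "synthetic", "effect"):
            disp[col] = disp[col].round(2)
        disp["p"] = disp["p"].round(3)
        disp["avoided_deaths"] = disp["avoided_deaths"].round().astype(int)
        disp["percent_reduction"] = disp["percent_reduction"].round().astype(int)
        return disp


def build_effect_report(
    panel: MortalityPanel,
    cfg: StudyConfig,
    fit: SCMFit,
    ensemble: PlaceboEnsemble,
    scenario: str = "baseline",
    cumulative_from: int | None = None,
) -> EffectReport:
    """Assemble the per-year effect table for the post window.

    ``cumulative_from`` overrides the default significance-gated start of the
    cumulative window (used e.g. to compare re-dated scenarios over a common
    span).
    """
    years = cfg.post_years
    actual = panel.series(cfg.treated_unit)[years].astype(float)
    synthetic = fit.synthetic[years]
    effect = fit.gaps[years]
    p = pseudo_p_series(ensemble, fit.gaps, years)
    stars = p.map(lambda v: star_tier(v, cfg.alpha_tiers))
    pops = panel.population_series(cfg.treated_unit)[years].astype(float)
    avoided = pd.Series(
        [avoided_deaths(float(effect[y]), float(pops[y])) for y in years], index=years
    )
    pct = pd.Series(
        [percent_reduction(float(actual[y]), float(synthetic[y])) for y in years],
        index=years,
    )
    table = pd.DataFrame(
        {
            "actual": actual,
            "synthetic": synthetic,
            "effect": effect,
            "p": p,
            "stars": stars,
            "avoided_deaths": avoided,
            "percent_reduction": pct,
        }
    )

    if cumulative_from is None:
        sig_years = [y for y in years if p[y] <= cfg.alpha_tiers[0]]
        cumulative_from = sig_years[0] if sig_years else None
    if cumulative_from is None:
        cum, rng = None, None
    else:
        rng = (int(cumulative_from), years[-1])
        cum = cumulative_impact(effect, rng[0], rng[1], pops)
    return EffectReport(
        table=table, cumulative_avoided=cum, cumulative_range=rng, scenario=scenario
    )
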