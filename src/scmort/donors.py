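"""Closeness-based donor-pool selection.

A candidate donor qualifies by having a pre-intervention mortality rate
"close" to the treated unit's in at least ``min_similar_years`` of the pre
window (4 of 6 at the default study window).  Among qualifiers, up to
``k_below`` units that were most often close-from-below and, symmetrically,
up to ``k_above`` close-from-above units form the pool.  Restricting the pool
this way avoids interpolation bias from structurally dissimilar units while
keeping donors on both sides of the treated unit's level.

"Close" is operationalised as |donor − treated| ≤ radius in a given year,
with radius = closeness_multiplier × SD of the treated unit's pre-period
series — a scale-free band that adapts to how variable the treated series is.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import StudyConfig
from .panel import MortalityPanel, PanelError

__all__ = ["closeness_radius", "yearly_closeness", "select_donor_pool"]

log = logging.getLogger(__name__)


def closeness_radius(panel: MortalityPanel, cfg: StudyConfig) -> float:
    """Closeness band half-width: multiplier × treated pre-period SD."""
    treated = panel.series(cfg.treated_unit)[cfg.pre_years]
    sd = float(np.std(treated.to_numpy(), ddof=1))
    return cfg.closeness_multiplier * sd


def yearly_closeness(
    panel: MortalityPanel, cfg: StudyConfig, radius: float | None = None
) -> pd.DataFrame:
    """Per-candidate closeness table over the pre window.

    Returns a DataFrame indexed by candidate unit with one signed-gap column
    per pre year (donor − treated) plus:

    - ``n_close_below`` / ``n_close_above``: years with |gap| ≤ radius, split
      by the sign of the gap in that year (a zero gap counts as below);
    - ``n_close``: their sum;
    - ``mean_abs_gap``: mean |gap| over all pre years (ranking tie-break);
    - ``direction``: majority side among close years ("below" on exact ties).

    Candidates are all units except the treated unit, the policy-excluded
    units, and units with a missing cell in the pre window.
    """
    if radius is None:
        radius = closeness_radius(panel, cfg)
    pre = cfg.pre_years
    if not panel.is_complete(cfg.treated_unit, pre):
        raise PanelError(f"treated unit {cfg.treated_unit!r} incomplete over pre window")
    treated = panel.series(cfg.treated_unit)[pre].to_numpy()

    candidates = [
        u
        for u in panel.complete_units(pre)
        if u != cfg.treated_unit and u not in cfg.excluded_units
    ]
    if not candidates:
        raise PanelError("no eligible donor candidates")

    gaps = panel.outcome.loc[candidates, pre].to_numpy() - treated[None, :]
    close = np.abs(gaps) <= radius
    below = close & (gaps <= 0)
    above = close & (gaps > 0)
    n_below = below.sum(axis=1)
    n_above = above.sum(axis=1)

    table = pd.DataFrame(gaps, index=candidates, columns=pre)
    table["n_close_below"] = n_below
    table["n_close_above"] = n_above
    table["n_close"] = n_below + n_above
    table["mean_abs_gap"] = np.abs(gaps).mean(axis=1)
    table["direction"] = np.where(n_below >= n_above, "below", "above")
    return table


def _rank_side(table: pd.DataFrame, side: str, min_years: int, k: int) -> list[str]:
    count_col = f"n_close_{side}"
    eligible = table[table[count_col] >= min_years]
    # A unit qualifying on both sides goes to its majority side only.
    other = "above" if side == "below" else "below"
    both = eligible[f"n_close_{other}"] >= min_years
    eligible = eligible[~both | (eligible["direction"] == side)]
    ranked = eligible.sort_values(
        by=[count_col, "mean_abs_gap"],
        ascending=[False, True],
        kind="mergesort",  # stable; final tie-break = index order
    )
    return list(ranked.index[:k])


def select_donor_pool(
    panel: MortalityPanel, cfg: StudyConfig, radius: float | None = None
) -> list[str]:
    """Apply the closeness rule; returns below-pool then above-pool, each
    ranked by close-year count (ties by smaller mean |gap|, then unit id).

    Shrinks below/above quotas with a warning when fewer candidates qualify;
    raises only if no candidate qualifies at all.
    """
    table = yearly_closeness(panel, cfg, radius=radius)
    below = _rank_side(table, "below", cfg.min_similar_years, cfg.donor_k_below)
    above = _rank_side(table, "above", cfg.min_similar_years, cfg.donor_k_above)
    if not below and not above:
        raise PanelError(
            "no donor candidate meets the similarity floor "
            f"({cfg.min_similar_years} close years)"
        )
    if len(below) < cfg.donor_k_below or len(above) < cfg.donor_k_above:
        log.warning(
            "donor pool shrunk: %d below (target %d), %d above (target %d)",
            len(below), cfg.donor_k_below, len(above), cfg.donor_k_above,
        )
    pool = below + above
    assert not set(pool) & set(cfg.excluded_units)
    assert cfg.treated_unit not in pool
    return pool
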