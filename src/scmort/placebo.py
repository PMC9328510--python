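"""In-space placebo tests and pseudo p-values.

Each donor takes a turn as a pseudo-treated unit, fitted against the
remaining donors.  Since no donor experienced the intervention, the placebo
gaps are what chance alone produces; a treated-unit gap larger in magnitude
than most placebo gaps is evidence of a real effect.  The per-year pseudo
p-value is the finite-sample-corrected exceedance fraction

    p_t = (1 + #{placebos with |gap_d,t| ≥ |α_t|}) / (1 + N_included),

two-sided on absolute gaps by default; attainable values lie on the grid
k/(N+1), so p can never be exactly zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .config import StudyConfig
from .panel import MortalityPanel, PanelError
from .scm import ConvergenceError, SCMFit, build_predictors, fit_weights

__all__ = [
    "PlaceboEnsemble",
    "run_placebos",
    "pseudo_p",
    "pseudo_p_series",
    "prefit_filter",
    "rmspe_ratio",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PlaceboEnsemble:
    """Placebo gap matrix (one row per donor) with pre-fit diagnostics."""

    gaps: pd.DataFrame        # index: donor, columns: years
    rmspe_pre: pd.Series      # per-donor pre-period RMSPE
    included: pd.Series       # bool; False = excluded (non-convergence/filter)

    @property
    def n_included(self) -> int:
        return int(self.included.sum())

    def included_gaps(self) -> pd.DataFrame:
        return self.gaps.loc[self.included]


def run_placebos(
    panel: MortalityPanel, cfg: StudyConfig, donors: list[str]
) -> PlaceboEnsemble:
    """Fit one placebo per donor (pool = remaining donors).

    Individual non-convergence excludes that placebo with a warning rather
    than aborting the ensemble.
    """
    rows, rmspes, included = {}, {}, {}
    for d in donors:
        others = [u for u in donors if u != d]
        try:
            pred = build_predictors(panel, cfg, others, treated_unit=d)
            fit = fit_weights(pred, panel, cfg)
            rows[d] = fit.gaps
            rmspes[d] = fit.rmspe_pre
            included[d] = True
        except (ConvergenceError, PanelError) as err:
            log.warning("placebo for %s excluded: %s", d, err)
            rows[d] = pd.Series(np.nan, index=panel.years)
            rmspes[d] = np.nan
            included[d] = False
    return PlaceboEnsemble(
        gaps=pd.DataFrame(rows).T,
        rmspe_pre=pd.Series(rmspes, name="rmspe_pre"),
        included=pd.Series(included, name="included"),
    )


def pseudo_p(
    ensemble: PlaceboEnsemble,
    treated_gap: float,
    year: int,
    two_sided: bool = True,
) -> float:
    """Pseudo p-value for the treated gap in one year."""
    gaps = ensemble.included_gaps()[year].to_numpy(dtype=float)
    n = len(gaps)
    if n == 0:
        raise ValueError("no included placebos")
    if two_sided:
        exceed = int(np.sum(np.abs(gaps) >= abs(treated_gap)))
    else:
        exceed = int(np.sum(gaps <= treated_gap))
    return (1 + exceed) / (1 + n)


def pseudo_p_series(
    ensemble: PlaceboEnsemble,
    treated_gaps: pd.Series,
    years: list[int] | None = None,
    two_sided: bool = True,
) -> pd.Series:
    """Per-year pseudo p-values for a treated gap series."""
    if years is None:
        years = [int(y) for y in treated_gaps.index]
    return pd.Series(
        {y: pseudo_p(ensemble, float(treated_gaps[y]), y, two_sided) for y in years},
        name="p",
    )


def rmspe_ratio(gaps: pd.Series, cfg: StudyConfig) -> float:
    """Post/pre RMSPE ratio of a gap series — a supplementary whole-period
    effect diagnostic (large when post gaps dwarf the pre-period fit error).
    Per-year pseudo p-values remain the primary inference."""
    pre = np.sqrt(np.mean(gaps[cfg.pre_years].to_numpy() ** 2))
    post = np.sqrt(np.mean(gaps[cfg.post_years].to_numpy() ** 2))
    if pre == 0:
        return np.inf if post > 0 else np.nan
    return float(post / pre)


def prefit_filter(
    ensemble: PlaceboEnsemble, treated_rmspe: float, multiplier: float = 5.0
) -> PlaceboEnsemble:
    """Drop placebos whose pre-fit is poor (RMSPE > multiplier × treated's).

    A badly-fitting placebo has large gaps everywhere and washes out the
    test; this standard trimming is off by default in the pipeline.
    """
    keep = ensemble.included & (
        ensemble.rmspe_pre <= multiplier * treated_rmspe
    ).fillna(False)
    if not keep.any():
        raise ValueError(
            "pre-fit filter removed every placebo; use a larger multiplier"
        )
    dropped = ensemble.included & ~keep
    if dropped.any():
        log.info("pre-fit filter excluded placebos: %s", list(ensemble.gaps.index[dropped]))
    return replace(ensemble, included=keep)
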