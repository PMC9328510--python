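"""Robustness batteries: re-dating, leave-one-out, pool extension, bias
correction.

Each check perturbs one assumption of the main synthetic-control analysis —
the intervention date, the donor-pool membership, or the exactness of the
predictor match — and re-runs the pipeline, so conclusions can be shown not
to hinge on any single choice.  The alternative-outcome check (a broader
mortality definition) is a pure data substitution: run the same pipeline on
a panel whose outcome column differs, no code branch needed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .config import StudyConfig
from .donors import select_donor_pool, yearly_closeness
from .panel import MortalityPanel, PanelError
from .placebo import run_placebos
from .report import EffectReport, build_effect_report
from .scm import PredictorSet, SCMFit, build_predictors, fit_weights

__all__ = ["redate", "leave_one_out", "extend_pool", "bias_correct", "LeaveOneOutResult", "ExtendPoolResult"]

log = logging.getLogger(__name__)


def _run_study(
    panel: MortalityPanel,
    cfg: StudyConfig,
    donors: list[str] | None = None,
    scenario: str = "baseline",
    cumulative_from: int | None = None,
) -> tuple[list[str], SCMFit, EffectReport]:
    """Donor selection → fit → placebos → effect report, one pass."""
    if donors is None:
        donors = select_donor_pool(panel, cfg)
    pred = build_predictors(panel, cfg, donors)
    fit = fit_weights(pred, panel, cfg)
    ensemble = run_placebos(panel, cfg, donors)
    report = build_effect_report(
        panel, cfg, fit, ensemble, scenario=scenario, cumulative_from=cumulative_from
    )
    return donors, fit, report


def redate(
    panel: MortalityPanel,
    cfg: StudyConfig,
    new_t0: int,
    cumulative_from: int | None = None,
    donors: list[str] | None = None,
) -> EffectReport:
    """Re-run the full pipeline with the intervention moved to ``new_t0``.

    The pre window lengthens accordingly and the donor similarity floor
    scales proportionately (ceil of the same fraction of pre years).
    ``new_t0`` equal to the original intervention year reproduces the
    baseline analysis.  ``donors`` fixes the pool explicitly (skipping
    closeness selection), e.g. to hold membership constant across scenarios.
    """
    if new_t0 < cfg.intervention_year:
        raise ValueError("re-dating only moves the intervention later")
    cfg2 = cfg.redated(new_t0) if new_t0 != cfg.intervention_year else cfg
    if donors is not None:
        log.info("re-dating with fixed donor pool (%d donors)", len(donors))
    _, _, report = _run_study(
        panel, cfg2, donors=donors, scenario=f"T0={new_t0}",
        cumulative_from=cumulative_from,
    )
    return report


@dataclass(frozen=True)
class LeaveOneOutResult:
    """Per-omission refits plus the min/max gap envelope across omissions."""

    fits: dict[str, SCMFit]            # omitted donor -> refit
    envelope: pd.DataFrame             # columns: lo, hi (per year)
    full_fit: SCMFit


def leave_one_out(
    panel: MortalityPanel, cfg: StudyConfig, donors: list[str]
) -> LeaveOneOutResult:
    """Re-fit the synthetic control omitting each donor in turn."""
    if len(donors) < 3:
        raise PanelError("leave-one-out needs at least 3 donors")
    pred = build_predictors(panel, cfg, donors)
    full_fit = fit_weights(pred, panel, cfg)
    fits: dict[str, SCMFit] = {}
    for d in donors:
        rest = [u for u in donors if u != d]
        pred_d = build_predictors(panel, cfg, rest)
        fits[d] = fit_weights(pred_d, panel, cfg)
    gap_mat = pd.DataFrame({d: f.gaps for d, f in fits.items()})
    envelope = pd.DataFrame({"lo": gap_mat.min(axis=1), "hi": gap_mat.max(axis=1)})
    return LeaveOneOutResult(fits=fits, envelope=envelope, full_fit=full_fit)


@dataclass(frozen=True)
class ExtendPoolResult:
    """Outcome of widening the donor pool by one unit on each side."""

    report: EffectReport | None
    donors: list[str]
    added_below: bool
    added_above: bool

    @property
    def possible(self) -> bool:
        return self.added_below or self.added_above


def extend_pool(
    panel: MortalityPanel, cfg: StudyConfig, donors: list[str]
) -> ExtendPoolResult:
    """Re-run with the next most comparable donor added on each side.

    When no further candidate qualifies on a side, that side stays as-is; if
    neither side can grow the result is marked not-possible rather than an
    error.
    """
    cfg_ext = replace(
        cfg, donor_k_below=cfg.donor_k_below + 1, donor_k_above=cfg.donor_k_above + 1
    )
    extended = select_donor_pool(panel, cfg_ext)
    new = set(extended) - set(donors)
    if not new:
        log.info("pool extension not possible: no additional eligible candidates")
        return ExtendPoolResult(
            report=None, donors=list(donors), added_below=False, added_above=False
        )
    sides = yearly_closeness(panel, cfg)["direction"]
    added_below = any(sides[d] == "below" for d in new)
    added_above = any(sides[d] == "above" for d in new)
    _, _, report = _run_study(panel, cfg_ext, donors=extended, scenario="extended-pool")
    return ExtendPoolResult(
        report=report,
        donors=extended,
        added_below=added_below,
        added_above=added_above,
    )


def bias_correct(
    fit: SCMFit,
    pred: PredictorSet,
    panel: MortalityPanel,
    cfg: StudyConfig,
    years: list[int] | None = None,
) -> pd.Series:
    """Regression-based correction of gaps for imperfect predictor matching.

    For each year t, donor outcomes Y_d,t are regressed (ordinary least
    squares, intercept included) on donor predictor vectors to get an outcome
    model μ̂_t(·); the corrected gap is

        α̃_t = (Y_treated,t − μ̂_t(X_treated)) − Σ_j w_j (Y_j,t − μ̂_t(X_j)).

    When the synthetic control matches the treated predictors exactly and the
    outcome model is linear, α̃_t = α_t.  The pre-period-mean predictor is an
    exact linear combination of the pre-year columns, so it is dropped from
    the regression design; a remaining rank deficiency is handled by the
    minimum-norm least-squares solution.
    """
    if years is None:
        years = cfg.post_years
    donors = list(pred.donors)
    X = pred.X.drop(columns=["pre_mean"], errors="ignore")
    Xd = X.loc[donors].to_numpy(dtype=float)
    X1 = X.loc[pred.treated_unit].to_numpy(dtype=float)
    design = np.column_stack([np.ones(len(donors)), Xd])
    x1_row = np.concatenate([[1.0], X1])
    w = fit.weights.to_numpy()

    corrected = {}
    for t in years:
        yd = panel.outcome.loc[donors, t].to_numpy(dtype=float)
        beta, *_ = np.linalg.lstsq(design, yd, rcond=None)
        mu_d = design @ beta
        mu_1 = float(x1_row @ beta)
        y1 = float(panel.outcome.loc[fit.treated_unit, t])
        corrected[t] = (y1 - mu_1) - float(w @ (yd - mu_d))
    return pd.Series(corrected, name="corrected_gap")
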