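"""Synthetic-control engine: predictors, simplex-constrained weights, gaps.

The synthetic control is the convex combination of donor outcome histories
that best matches the treated unit's pre-intervention predictors:

    min_w  Σ_k V_k (X_treated,k − Σ_j w_j X_j,k)²
    s.t.   w_j ≥ 0,  Σ_j w_j = 1

Predictors default to the outcome in every pre-intervention year plus the
pre-period mean (the all-lagged-outcomes specification); predictor importance
weights V are equal.  The per-year treatment-effect estimate is the gap
α_t = Y_treated,t − Σ_j w_j Y_j,t, negative meaning mortality below the
counterfactual.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .config import StudyConfig
from .panel import MortalityPanel, PanelError

__all__ = ["PredictorSet", "SCMFit", "build_predictors", "fit_weights", "gap_series"]


class ConvergenceError(RuntimeError):
    """Weight optimisation failed; carries the best iterate found."""

    def __init__(self, message: str, best_w: np.ndarray, objective: float):
        super().__init__(message)
        self.best_w = best_w
        self.objective = objective


@dataclass(frozen=True)
class PredictorSet:
    """Per-unit predictor matrix X (treated + donors) and importance weights V."""

    X: pd.DataFrame          # rows: units (treated first), cols: predictors
    v: np.ndarray            # V_k ≥ 0, sums to 1
    treated_unit: str
    donors: tuple[str, ...]

    def __post_init__(self) -> None:
        if not np.isfinite(self.X.to_numpy()).all():
            raise PanelError("predictor matrix has missing entries")
        if (self.v < 0).any() or not np.isclose(self.v.sum(), 1.0):
            raise ValueError("V must be non-negative and sum to 1")
        if len(self.v) != self.X.shape[1]:
            raise ValueError("V length does not match predictor count")

    @property
    def treated_vector(self) -> np.ndarray:
        return self.X.loc[self.treated_unit].to_numpy(dtype=float)

    @property
    def donor_matrix(self) -> np.ndarray:
        """(n_predictors, n_donors) matrix of donor predictor columns."""
        return self.X.loc[list(self.donors)].to_numpy(dtype=float).T


@dataclass(frozen=True)
class SCMFit:
    """Fitted synthetic control for one (pseudo-)treated unit."""

    treated_unit: str
    weights: pd.Series            # indexed by donor, ≥ 0, sums to 1
    synthetic: pd.Series          # per-year synthetic rate, all panel years
    gaps: pd.Series               # per-year treated − synthetic
    rmspe_pre: float
    objective: float
    converged: bool

    @property
    def donors(self) -> list[str]:
        return list(self.weights.index)


def build_predictors(
    panel: MortalityPanel,
    cfg: StudyConfig,
    donors: list[str],
    treated_unit: str | None = None,
) -> PredictorSet:
    """Predictor matrix over the pre window.

    ``all_pre_years`` mode (default): the outcome in every pre year plus the
    pre-period mean — 7 predictors for a 6-year pre window.  ``lag_plus_mean``
    mode: only the outcome in the last pre year (the one-year lag at the
    intervention) plus the pre-period mean.
    """
    treated = treated_unit or cfg.treated_unit
    if len(donors) < 2:
        raise PanelError("need at least 2 donors")
    pre = cfg.pre_years
    units = [treated] + list(donors)
    for u in units:
        if not panel.is_complete(u, pre):
            missing = [y for y in pre if not np.isfinite(panel.outcome.loc[u, y])]
            raise PanelError(f"unit {u!r} missing pre-window years {missing}")
    block = panel.outcome.loc[units, pre].astype(float)
    if cfg.predictor_mode == "all_pre_years":
        X = block.copy()
        X.columns = [f"y{y}" for y in pre]
    else:  # lag_plus_mean
        X = block[[pre[-1]]].copy()
        X.columns = [f"y{pre[-1]}"]
    X["pre_mean"] = block.mean(axis=1)
    v = np.full(X.shape[1], 1.0 / X.shape[1])
    return PredictorSet(X=X, v=v, treated_unit=treated, donors=tuple(donors))


def _objective_terms(pred: PredictorSet) -> tuple[np.ndarray, np.ndarray]:
    """Return (A, b) with f(w) = ||A w − b||² (V absorbed as sqrt scaling)."""
    sq = np.sqrt(pred.v)[:, None]
    A = pred.donor_matrix * sq
    b = pred.treated_vector * sq.ravel()
    return A, b


def _solve_simplex_ls(A: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, float, bool]:
    """min ||Aw − b||² on the probability simplex, deterministically.

    SLSQP with analytic gradient from the uniform start; a cheap necessary
    check (no simplex vertex may beat the solution) triggers a restart from
    the best vertex; finally a min-norm polish picks the smallest-norm weight
    vector among (numerically) equal-objective optima, so collinear donors
    yield a reproducible answer.
    """
    n = A.shape[1]
    Q = A.T @ A
    c = A.T @ b

    def f(w: np.ndarray) -> float:
        r = A @ w - b
        return float(r @ r)

    def grad(w: np.ndarray) -> np.ndarray:
        return 2.0 * (Q @ w - c)

    cons = [{"type": "eq", "fun": lambda w: w.sum() - 1.0, "jac": lambda w: np.ones(n)}]
    bounds = [(0.0, 1.0)] * n
    opts = {"maxiter": 2000, "ftol": 1e-14}

    res = minimize(f, np.full(n, 1.0 / n), jac=grad, method="SLSQP",
                   bounds=bounds, constraints=cons, options=opts)
    w, fval, ok = res.x, f(res.x), res.success

    # Necessary condition: optimum cannot be worse than any single donor.
    vertex_f = np.sum((A - b[:, None]) ** 2, axis=0)
    jbest = int(np.argmin(vertex_f))
    if vertex_f[jbest] < fval - 1e-12:
        w0 = np.full(n, 1e-6)
        w0[jbest] = 1.0 - (n - 1) * 1e-6
        res2 = minimize(f, w0, jac=grad, method="SLSQP",
                        bounds=bounds, constraints=cons, options=opts)
        if f(res2.x) < fval:
            w, fval, ok = res2.x, f(res2.x), res2.success
        if vertex_f[jbest] < fval:
            w = np.zeros(n)
            w[jbest] = 1.0
            fval, ok = float(vertex_f[jbest]), True

    # Min-norm tie-break among equal-objective optima (collinear donors).
    slack = max(1e-12, 1e-9 * max(fval, 1.0))
    polish = minimize(
        lambda u: float(u @ u), w, jac=lambda u: 2.0 * u, method="SLSQP",
        bounds=bounds,
        constraints=cons + [{"type": "ineq", "fun": lambda u: fval + slack - f(u),
                             "jac": lambda u: -grad(u)}],
        options={"maxiter": 500, "ftol": 1e-14},
    )
    if polish.success and f(polish.x) <= fval + slack:
        w = polish.x

    w = np.clip(w, 0.0, None)
    if (w < -1e-9).any():  # pragma: no cover - clip precludes
        raise ConvergenceError("negative weight beyond tolerance", w, fval)
    w = w / w.sum()
    return w, f(w), ok


def fit_weights(
    pred: PredictorSet, panel: MortalityPanel, cfg: StudyConfig
) -> SCMFit:
    """Fit donor weights and assemble the synthetic trajectory and gaps."""
    A, b = _objective_terms(pred)
    w, fval, ok = _solve_simplex_ls(A, b)
    if not ok and fval > 1e-8:
        raise ConvergenceError(
            f"weight optimisation did not converge (objective {fval:.3g})", w, fval
        )
    weights = pd.Series(w, index=list(pred.donors), name="weight")

    years = panel.years
    donor_block = panel.outcome.loc[list(pred.donors), years].to_numpy(dtype=float)
    synthetic = pd.Series(w @ donor_block, index=years, name="synthetic")
    treated = panel.outcome.loc[pred.treated_unit, years].astype(float)
    gaps = pd.Series(
        treated.to_numpy() - synthetic.to_numpy(), index=years, name="gap"
    )
    pre = cfg.pre_years
    rmspe = float(np.sqrt(np.mean(gaps[pre].to_numpy() ** 2)))
    return SCMFit(
        treated_unit=pred.treated_unit,
        weights=weights,
        synthetic=synthetic,
        gaps=gaps,
        rmspe_pre=rmspe,
        objective=fval,
        converged=bool(ok),
    )


def gap_series(fit: SCMFit, panel: MortalityPanel, cfg: StudyConfig) -> pd.Series:
    """Recompute α_t = Y_treated,t − Σ_j w_j Y_j,t for every panel year."""
    years = panel.years
    donor_block = panel.outcome.loc[fit.donors, years].to_numpy(dtype=float)
    synth = fit.weights.to_numpy() @ donor_block
    treated = panel.outcome.loc[fit.treated_unit, years].to_numpy(dtype=float)
    return pd.Series(treated - synth, index=years, name="gap")
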