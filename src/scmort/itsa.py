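"""Interrupted time-series cross-check: two-group segmented regression.

The treated unit is contrasted with the unweighted mean of the donor pool
(the "collective control") in a single segmented regression:

    y_gt = β0 + β1·time_t + β2·post_t + β3·elapsed_t
         + β4·z_g + β5·z_g·time_t + β6·z_g·post_t + β7·z_g·elapsed_t + ε_gt

with time centred at the intervention (time = year − T0), post = 1 from the
intervention year, elapsed = years since intervention + 1 (0 pre), and z = 1
for the treated group.  β7 — the treated-vs-control difference in
post-intervention slope change — is the headline estimate.  Errors are
treated as AR(1) within each group's series and estimated by iterated
Prais–Winsten (the first observation of each group is retained with the
√(1−ρ²) transform); OLS with heteroskedasticity/autocorrelation-robust (HAC)
standard errors is available as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .config import StudyConfig
from .panel import MortalityPanel, PanelError

__all__ = ["ItsaFit", "fit_itsa", "itsa_predicted_series"]

PARAM_NAMES = [
    "const", "time", "post", "elapsed",
    "group", "group_time", "group_post", "group_elapsed",
]


@dataclass(frozen=True)
class ItsaFit:
    """Segmented-regression fit for treated vs collective control."""

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    rho: float
    predicted: pd.DataFrame     # index: year, columns: treated, control
    actual: pd.DataFrame        # same shape, observed series
    n_obs: int
    se_method: str

    @property
    def headline(self) -> tuple[float, float]:
        """(estimate, p-value) of the treated × post-trend interaction."""
        return float(self.params["group_elapsed"]), float(self.pvalues["group_elapsed"])


def _design(years: np.ndarray, t0: int, group: int) -> np.ndarray:
    time = years - t0
    post = (years >= t0).astype(float)
    elapsed = (years - t0 + 1) * post
    z = np.full_like(time, group, dtype=float)
    cols = [np.ones_like(time, dtype=float), time, post, elapsed]
    cols += [z, z * time, z * post, z * elapsed]
    return np.column_stack(cols)


def _pw_transform(X: np.ndarray, y: np.ndarray, rho: float) -> tuple[np.ndarray, np.ndarray]:
    """Prais–Winsten AR(1) quasi-differencing of one group's time series."""
    Xs, ys = X.copy(), y.copy()
    Xs[1:] = X[1:] - rho * X[:-1]
    ys[1:] = y[1:] - rho * y[:-1]
    scale = np.sqrt(1.0 - rho**2)
    Xs[0] *= scale
    ys[0] *= scale
    return Xs, ys


def _estimate_rho(residuals: list[np.ndarray]) -> float:
    """Pooled lag-1 autocorrelation across the groups' residual series."""
    num = sum(float(r[1:] @ r[:-1]) for r in residuals)
    den = sum(float(r @ r) for r in residuals)
    if den < 1e-12:
        return 0.0
    rho = num / den
    return float(np.clip(rho, -0.99, 0.99))


def fit_itsa(
    panel: MortalityPanel,
    cfg: StudyConfig,
    control_units: list[str],
    se: str = "prais",
    rho: float | None = None,
    population_weighted: bool = False,
    lagged_outcome: bool = False,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> ItsaFit:
    """Fit the two-group segmented regression.

    Parameters
    ----------
    se
        "prais" (iterated Prais–Winsten AR(1) correction, default) or "hac"
        (OLS with Newey–West standard errors).
    rho
        Fix the AR(1) coefficient instead of estimating it (prais only);
        ``rho=0`` reproduces ordinary least squares exactly.
    population_weighted
        Weight the control average by unit population instead of equally.
    lagged_outcome
        Add the previous year's outcome as a regressor (each group loses its
        first year).  Off by default: conditioning on the lagged outcome
        changes the estimand from a trend break to a one-year-ahead
        contrast, so this is a sensitivity variant, not the main model.
    """
    t0 = cfg.intervention_year
    years = np.array(cfg.all_years)
    if (years < t0).sum() < 3 or (years >= t0).sum() < 3:
        raise PanelError("need at least 3 pre and 3 post years")
    for u in [cfg.treated_unit] + list(control_units):
        if not panel.is_complete(u, list(years)):
            raise PanelError(f"unit {u!r} incomplete over study window")

    treated = panel.series(cfg.treated_unit)[list(years)].to_numpy(dtype=float)
    block = panel.outcome.loc[list(control_units), list(years)].to_numpy(dtype=float)
    if population_weighted:
        wpop = panel.population.loc[list(control_units), list(years)].to_numpy(dtype=float)
        control = (block * wpop).sum(axis=0) / wpop.sum(axis=0)
    else:
        control = block.mean(axis=0)

    Xc = _design(years, t0, group=0)
    Xt = _design(years, t0, group=1)
    param_names = list(PARAM_NAMES)
    pred_years = [int(t) for t in years]
    if lagged_outcome:
        Xc = np.column_stack([Xc[1:], control[:-1]])
        Xt = np.column_stack([Xt[1:], treated[:-1]])
        control, treated = control[1:], treated[1:]
        years = years[1:]
        param_names.append("lag_outcome")
        pred_years = [int(t) for t in years]
    X = np.vstack([Xc, Xt])
    y = np.concatenate([control, treated])
    n = len(years)

    if np.linalg.matrix_rank(X) < X.shape[1] or np.var(y) < 1e-24:
        raise PanelError("collinear/degenerate segmented design (constant series?)")

    if se == "hac":
        model = sm.OLS(y, X).fit(cov_type="HAC", cov_kwds={"maxlags": 2})
        rho_hat = 0.0
    elif se == "prais":
        ols = sm.OLS(y, X).fit()
        if rho is not None:
            rho_hat = float(rho)
        else:
            resid = ols.resid
            rho_hat = _estimate_rho([resid[:n], resid[n:]])
            for _ in range(max_iter):
                Xs1, ys1 = _pw_transform(Xc, control, rho_hat)
                Xs2, ys2 = _pw_transform(Xt, treated, rho_hat)
                fit_i = sm.OLS(np.concatenate([ys1, ys2]), np.vstack([Xs1, Xs2])).fit()
                # residuals on the ORIGINAL scale drive the rho update
                resid = y - X @ fit_i.params
                rho_new = _estimate_rho([resid[:n], resid[n:]])
                if abs(rho_new - rho_hat) < tol:
                    rho_hat = rho_new
                    break
                rho_hat = rho_new
        Xs1, ys1 = _pw_transform(Xc, control, rho_hat)
        Xs2, ys2 = _pw_transform(Xt, treated, rho_hat)
        model = sm.OLS(np.concatenate([ys1, ys2]), np.vstack([Xs1, Xs2])).fit()
    else:
        raise ValueError(f"unknown se method {se!r}")

    params = pd.Series(model.params, index=param_names)
    bse = pd.Series(model.bse, index=param_names)
    pvalues = pd.Series(model.pvalues, index=param_names)

    predicted = pd.DataFrame(
        {"treated": Xt @ params.to_numpy(), "control": Xc @ params.to_numpy()},
        index=pred_years,
    )
    actual = pd.DataFrame({"treated": treated, "control": control}, index=pred_years)
    return ItsaFit(
        params=params,
        bse=bse,
        pvalues=pvalues,
        rho=rho_hat,
        predicted=predicted,
        actual=actual,
        n_obs=2 * n,
        se_method=se,
    )


def itsa_predicted_series(fit: ItsaFit) -> pd.DataFrame:
    """Per-year model predictions for both groups (for gap/trajectory plots)."""
    return fit.predicted.copy()
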