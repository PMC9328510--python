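"""Synthetic-control engine: predictors, simplex optimisation, gaps."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from scmort import (
    StudyConfig,
    build_predictors,
    fit_weights,
    gap_series,
)
from scmort.simulate import default_effect_path
from .conftest import make_panel


def grid_search_objective(A, b, step=0.002):
    """Exhaustive simplex grid search for the 3-donor weighted LS problem.

    Independent oracle: enumerates w1, w2 on a lattice (w3 = 1 − w1 − w2)
    and returns the minimum of ||A w − b||².
    """
    ticks = np.arange(0.0, 1.0 + step / 2, step)
    w1, w2 = np.meshgrid(ticks, ticks, indexing="ij")
    keep = w1 + w2 <= 1.0 + 1e-12
    w = np.stack([w1[keep], w2[keep], 1.0 - w1[keep] - w2[keep]], axis=0)
    resid = A @ w - b[:, None]
    return float(np.min(np.sum(resid**2, axis=0)))


def grid_resolution_bound(A, step=0.002):
    """Worst-case objective excess of the grid optimum over the continuous
    optimum: ½·L·d² with L twice the largest pairwise donor-column distance
    squared and d the lattice spacing."""
    n = A.shape[1]
    pair = max(
        float(np.sum((A[:, i] - A[:, j]) ** 2))
        for i in range(n)
        for j in range(i + 1, n)
    )
    return pair * step**2


def random_instance(rng, n_pre=6, spread=0.75):
    """Panel in the study regime: 3 donors within ±spread of the treated."""
    years = 21
    rows = {"treated": list(10.0 + 0.1 * np.arange(years) + rng.normal(0, 0.3, years))}
    for i in range(3):
        base = 10.0 + rng.uniform(-spread, spread)
        rows[f"d{i}"] = list(base + 0.1 * np.arange(years) + rng.normal(0, 0.3, years))
    return make_panel(rows)


class TestBuildPredictors:
    def test_six_pre_years_give_seven_predictors(self, cfg, default_panel):
        donors = [u for u in default_panel.units if u != "treated"]
        pred = build_predictors(default_panel, cfg, donors)
        assert pred.X.shape[1] == 7
        assert list(pred.X.index) == ["treated"] + donors
        np.testing.assert_allclose(pred.v, 1 / 7)

    def test_constant_series_gives_constant_vector(self, cfg):
        panel = make_panel({u: [10.0] * 21 for u in ["treated", "a", "b"]})
        pred = build_predictors(panel, cfg, ["a", "b"])
        np.testing.assert_allclose(pred.X.to_numpy(), 10.0)

    def test_last_predictor_is_mean_of_pre_years(self, cfg, default_panel):
        donors = [u for u in default_panel.units if u != "treated"][:5]
        pred = build_predictors(default_panel, cfg, donors)
        np.testing.assert_allclose(
            pred.X["pre_mean"],
            default_panel.outcome.loc[pred.X.index, cfg.pre_years].mean(axis=1),
        )

    def test_lag_plus_mean_mode_gives_two_predictors(self, default_panel):
        cfg = StudyConfig(treated_unit="treated", predictor_mode="lag_plus_mean")
        donors = [u for u in default_panel.units if u != "treated"][:5]
        pred = build_predictors(default_panel, cfg, donors)
        assert list(pred.X.columns) == ["y2004", "pre_mean"]


class TestFitWeights:
    def test_identical_donor_takes_all_weight(self, cfg):
        rows = {
            "treated": [10.0 + 0.2 * j for j in range(21)],
            "twin": [10.0 + 0.2 * j for j in range(21)],
            "other": [13.0 + 0.2 * j for j in range(21)],
        }
        panel = make_panel(rows)
        fit = fit_weights(build_predictors(panel, cfg, ["twin", "other"]), panel, cfg)
        assert fit.weights["twin"] == pytest.approx(1.0, abs=1e-6)
        assert fit.rmspe_pre <= 1e-6

    def test_convex_hull_midpoint_recovered(self, cfg):
        rng = np.random.default_rng(0)
        a = 9.0 + 0.1 * np.arange(21) + rng.normal(0, 0.4, 21)
        b = 11.0 + 0.1 * np.arange(21) + rng.normal(0, 0.4, 21)
        panel = make_panel(
            {"treated": list(0.5 * a + 0.5 * b), "A": list(a), "B": list(b)}
        )
        fit = fit_weights(build_predictors(panel, cfg, ["A", "B"]), panel, cfg)
        np.testing.assert_allclose(fit.weights, [0.5, 0.5], atol=1e-4)
        assert fit.rmspe_pre == pytest.approx(0.0, abs=1e-6)

    def test_matches_grid_search_oracle(self, cfg):
        rng = np.random.default_rng(99)
        for _ in range(5):
            panel = random_instance(rng)
            pred = build_predictors(panel, cfg, ["d0", "d1", "d2"])
            fit = fit_weights(pred, panel, cfg)
            sq = np.sqrt(pred.v)[:, None]
            A = pred.donor_matrix * sq
            b = pred.treated_vector * sq.ravel()
            grid = grid_search_objective(A, b)
            assert fit.objective <= grid + 1e-6
            assert grid - fit.objective <= grid_resolution_bound(A)

    def test_simplex_vertices_never_beat_solution(self, cfg):
        rng = np.random.default_rng(17)
        panel = random_instance(rng)
        pred = build_predictors(panel, cfg, ["d0", "d1", "d2"])
        fit = fit_weights(pred, panel, cfg)
        sq = np.sqrt(pred.v)[:, None]
        A = pred.donor_matrix * sq
        b = pred.treated_vector * sq.ravel()
        for j in range(3):
            assert fit.objective <= np.sum((A[:, j] - b) ** 2) + 1e-9

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_weights_always_on_simplex(self, seed):
        cfg = StudyConfig(treated_unit="treated")
        panel = random_instance(np.random.default_rng(seed), spread=2.0)
        fit = fit_weights(build_predictors(panel, cfg, ["d0", "d1", "d2"]), panel, cfg)
        w = fit.weights.to_numpy()
        assert (w >= 0).all()
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
        assert fit.rmspe_pre >= 0

    def test_shift_equivariance(self, cfg):
        rng = np.random.default_rng(3)
        panel = random_instance(rng)
        pred = build_predictors(panel, cfg, ["d0", "d1", "d2"])
        fit = fit_weights(pred, panel, cfg)
        shifted = make_panel(
            {u: list(panel.outcome.loc[u] + 5.0) for u in panel.units}
        )
        fit2 = fit_weights(build_predictors(shifted, cfg, ["d0", "d1", "d2"]), shifted, cfg)
        np.testing.assert_allclose(fit2.weights, fit.weights, atol=1e-4)
        np.testing.assert_allclose(fit2.synthetic, fit.synthetic + 5.0, atol=1e-3)

    def test_min_norm_tie_break_on_duplicate_donors(self, cfg):
        rows = {
            "treated": [10.0 + 0.1 * j for j in range(21)],
            "d0": [10.5 + 0.1 * j for j in range(21)],
            "d1": [10.5 + 0.1 * j for j in range(21)],  # exact copy of d0
            "d2": [9.5 + 0.1 * j for j in range(21)],
        }
        panel = make_panel(rows)
        fit = fit_weights(build_predictors(panel, cfg, ["d0", "d1", "d2"]), panel, cfg)
        # duplicated donors share their weight equally in the min-norm optimum
        assert fit.weights["d0"] == pytest.approx(fit.weights["d1"], abs=1e-4)


class TestGapSeries:
    def test_zero_gap_when_synthetic_equals_treated(self, cfg):
        rows = {u: [10.0 + 0.2 * j for j in range(21)] for u in ["treated", "a", "b"]}
        panel = make_panel(rows)
        fit = fit_weights(build_predictors(panel, cfg, ["a", "b"]), panel, cfg)
        np.testing.assert_allclose(fit.gaps, 0.0, atol=1e-9)

    def test_recomputation_matches_independent_arithmetic(self, cfg):
        rng = np.random.default_rng(21)
        panel = random_instance(rng)
        fit = fit_weights(build_predictors(panel, cfg, ["d0", "d1", "d2"]), panel, cfg)
        gaps = gap_series(fit, panel, cfg)
        for y in panel.years:  # explicit loop oracle
            synth = sum(
                fit.weights[d] * panel.outcome.loc[d, y] for d in ["d0", "d1", "d2"]
            )
            expected = panel.outcome.loc["treated", y] - synth
            assert gaps[y] == pytest.approx(expected, abs=1e-12)
        pd.testing.assert_series_equal(gaps, fit.gaps, check_names=False)

    def test_noise_free_planted_ramp_recovered(self, cfg, spanning_panel):
        donors = ["lo_a", "lo_b", "hi_a", "hi_b"]
        fit = fit_weights(build_predictors(spanning_panel, cfg, donors), spanning_panel, cfg)
        path = default_effect_path()
        for y in cfg.post_years:
            assert fit.gaps[y] == pytest.approx(path[y], abs=1e-3)
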