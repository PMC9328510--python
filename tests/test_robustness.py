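"""Re-dating, leave-one-out, pool extension, and bias correction."""

import numpy as np
import pandas as pd
import pytest

from scmort import (
    GeneratorSpec,
    StudyConfig,
    bias_correct,
    build_predictors,
    extend_pool,
    fit_weights,
    generate_panel,
    leave_one_out,
    redate,
    run_placebos,
    select_donor_pool,
)
from scmort.report import build_effect_report
from scmort.simulate import default_effect_path
from .conftest import make_panel


class TestRedate:
    def test_same_date_reproduces_baseline(self, cfg, default_panel):
        donors = select_donor_pool(default_panel, cfg)
        fit = fit_weights(build_predictors(default_panel, cfg, donors), default_panel, cfg)
        ens = run_placebos(default_panel, cfg, donors)
        baseline = build_effect_report(default_panel, cfg, fit, ens, scenario="T0=2005")
        redated = redate(default_panel, cfg, 2005)
        pd.testing.assert_frame_equal(baseline.table, redated.table)

    def test_noise_free_planted_path_is_date_invariant(self, cfg, spanning_panel):
        path = default_effect_path()
        for t0 in (2005, 2006, 2007):
            report = redate(spanning_panel, cfg, t0)
            for y in range(2010, 2020):
                assert report.table.loc[y, "effect"] == pytest.approx(path[y], abs=1e-3)

    def test_earlier_date_rejected(self, cfg, default_panel):
        with pytest.raises(ValueError, match="later"):
            redate(default_panel, cfg, 2003)


class TestLeaveOneOut:
    @pytest.fixture
    def panel(self):
        rng = np.random.default_rng(14)
        rows = {"treated": list(10.0 + 0.1 * np.arange(21) + rng.normal(0, 0.2, 21))}
        for i in range(6):
            base = 10.0 + rng.uniform(-0.8, 0.8)
            rows[f"d{i}"] = list(base + 0.1 * np.arange(21) + rng.normal(0, 0.3, 21))
        return make_panel(rows)

    def test_omitting_zero_weight_donor_keeps_objective(self, cfg, panel):
        donors = [f"d{i}" for i in range(6)]
        res = leave_one_out(panel, cfg, donors)
        zero = [d for d in donors if res.full_fit.weights[d] < 1e-8]
        assert zero, "fixture should produce at least one zero-weight donor"
        for d in zero:
            assert res.fits[d].objective == pytest.approx(
                res.full_fit.objective, abs=1e-6
            )
            # envelope then contains the full-pool gap series
            gaps = res.full_fit.gaps
            assert (res.envelope["lo"] <= gaps + 1e-6).all()
            assert (res.envelope["hi"] >= gaps - 1e-6).all()

    def test_omission_equals_fresh_pipeline_run(self, cfg, panel):
        donors = [f"d{i}" for i in range(6)]
        res = leave_one_out(panel, cfg, donors)
        top = res.full_fit.weights.idxmax()
        rest = [d for d in donors if d != top]
        fresh = fit_weights(build_predictors(panel, cfg, rest), panel, cfg)
        pd.testing.assert_series_equal(res.fits[top].gaps, fresh.gaps)

    def test_identical_donors_make_every_omission_equal(self, cfg):
        rows = {"treated": [10.0 + 0.1 * j for j in range(21)]}
        rows |= {f"d{i}": [10.4 + 0.1 * j for j in range(21)] for i in range(4)}
        panel = make_panel(rows)
        res = leave_one_out(panel, cfg, [f"d{i}" for i in range(4)])
        series = list(res.fits.values())
        for fit in series[1:]:
            np.testing.assert_allclose(fit.gaps, series[0].gaps, atol=1e-9)

    def test_needs_three_donors(self, cfg, panel):
        with pytest.raises(Exception, match="3 donors"):
            leave_one_out(panel, cfg, ["d0", "d1"])


class TestExtendPool:
    def _offset_panel(self, offsets):
        rows = {"treated": [10.0 + 0.1 * j for j in range(21)]}
        for u, off in offsets.items():
            rows[u] = [v + off for v in rows["treated"]]
        return make_panel(rows)

    def test_exactly_full_pool_reports_not_possible(self):
        offsets = {f"b{i}": -0.05 * (i + 1) for i in range(9)}
        offsets |= {f"a{i}": 0.05 * (i + 1) for i in range(9)}
        panel = self._offset_panel(offsets)
        cfg = StudyConfig(treated_unit="treated", closeness_multiplier=10.0)
        donors = select_donor_pool(panel, cfg)
        res = extend_pool(panel, cfg, donors)
        assert not res.possible
        assert res.report is None
        assert res.donors == donors

    def test_twenty_two_candidates_extend_to_twenty(self):
        offsets = {f"b{i:02d}": -0.05 * (i + 1) for i in range(11)}
        offsets |= {f"a{i:02d}": 0.05 * (i + 1) for i in range(11)}
        panel = self._offset_panel(offsets)
        cfg = StudyConfig(treated_unit="treated", closeness_multiplier=10.0)
        donors = select_donor_pool(panel, cfg)
        assert len(donors) == 18
        res = extend_pool(panel, cfg, donors)
        assert res.possible and res.added_below and res.added_above
        assert len(res.donors) == 20
        # brute force: the next-closest candidate on each side joins
        assert set(res.donors) - set(donors) == {"b09", "a09"}

    def test_planted_effect_gap_stable_under_extension(self, cfg):
        panel = generate_panel(GeneratorSpec(seed=18, donor_baseline_range=(8.0, 10.5)))
        donors = select_donor_pool(panel, cfg)
        fit = fit_weights(build_predictors(panel, cfg, donors), panel, cfg)
        res = extend_pool(panel, cfg, donors)
        if res.possible:
            extended_gap = res.report.table.loc[2019, "effect"]
            assert abs(extended_gap - fit.gaps[2019]) < 0.5


class TestBiasCorrect:
    def test_identity_when_predictors_match_exactly(self, cfg, spanning_panel):
        donors = ["lo_a", "lo_b", "hi_a", "hi_b"]
        pred = build_predictors(spanning_panel, cfg, donors)
        fit = fit_weights(pred, spanning_panel, cfg)
        assert fit.rmspe_pre < 1e-6
        corrected = bias_correct(fit, pred, spanning_panel, cfg)
        for y in cfg.post_years:
            assert corrected[y] == pytest.approx(fit.gaps[y], abs=1e-6)

    def test_matches_manual_least_squares_arithmetic(self):
        """3 donors, 2 predictors: compare with normal-equation arithmetic
        done independently (different linear-algebra route than lstsq)."""
        cfg = StudyConfig(
            treated_unit="treated", pre_start=2003, intervention_year=2005,
            post_end=2006, predictor_mode="lag_plus_mean",
        )
        rows = {
            "treated": [10.0, 11.0, 10.0, 12.0],
            "a": [9.0, 10.5, 11.0, 13.0],
            "b": [11.0, 11.5, 10.0, 12.5],
            "c": [10.0, 12.0, 9.5, 11.0],
        }
        panel = make_panel(rows, start_year=2003)
        pred = build_predictors(panel, cfg, ["a", "b", "c"])
        fit = fit_weights(pred, panel, cfg)
        corrected = bias_correct(fit, pred, panel, cfg)

        X = pred.X.drop(columns=["pre_mean"]).loc[["a", "b", "c"]].to_numpy()
        D = np.column_stack([np.ones(3), X])
        for y in (2005, 2006):
            yd = np.array([rows["a"][y - 2003], rows["b"][y - 2003], rows["c"][y - 2003]])
            beta = np.linalg.solve(D.T @ D, D.T @ yd)
            mu = D @ beta
            x1 = np.concatenate([[1.0], pred.X.drop(columns=["pre_mean"]).loc["treated"].to_numpy()])
            alpha = (rows["treated"][y - 2003] - x1 @ beta) - float(
                fit.weights.to_numpy() @ (yd - mu)
            )
            assert corrected[y] == pytest.approx(alpha, abs=1e-9)

    def test_reduces_bias_with_offset_donors(self):
        """Donors all above the treated predictor region: raw gaps inherit the
        offset, regression-corrected gaps should not (averaged over seeds)."""
        cfg = StudyConfig(treated_unit="treated")
        raw_bias, corr_bias = [], []
        for seed in range(30):
            spec = GeneratorSpec(
                seed=seed, treated_baseline=9.0, donor_baseline_range=(10.0, 13.0),
                effect_path={},
            )
            panel = generate_panel(spec)
            donors = [u for u in panel.units if u != "treated"]
            pred = build_predictors(panel, cfg, donors)
            fit = fit_weights(pred, panel, cfg)
            corrected = bias_correct(fit, pred, panel, cfg)
            post = cfg.post_years
            raw_bias.append(np.mean(np.abs(fit.gaps[post].to_numpy())))
            corr_bias.append(np.mean(np.abs(corrected[post].to_numpy())))
        assert np.mean(corr_bias) < np.mean(raw_bias)
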