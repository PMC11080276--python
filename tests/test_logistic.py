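"""Logistic regression: IRLS fit, LR test, stepwise selection, odds ratios."""

import numpy as np
import pandas as pd
import pytest

from riskbn.codebook import default_codebook
from riskbn.logistic import (
    DesignMatrix,
    RankDeficientError,
    build_design,
    fit_logistic,
    lr_test,
    odds_ratios,
    stepwise_forward_lr,
)


def _design_from_arrays(y, columns: dict) -> DesignMatrix:
    X = pd.DataFrame(columns)
    return DesignMatrix(
        y=np.asarray(y, float), X=X, terms={c: [c] for c in X.columns}
    )


def _sim_logit(rng, n, betas, intercept):
    X = rng.normal(size=(n, len(betas)))
    eta = intercept + X @ np.asarray(betas)
    y = rng.random(n) < 1 / (1 + np.exp(-eta))
    return _design_from_arrays(
        y.astype(float), {f"x{i}": X[:, i] for i in range(len(betas))}
    )


class TestFitLogistic:
    def test_two_by_two_closed_form(self):
        """Saturated 2x2: slope = ln(ad/bc), intercept = ln(c/d)."""
        a, b, c, d = 40, 60, 25, 75  # exposed cases/noncases, unexposed c/d
        y = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
        x = np.r_[np.ones(a + b), np.zeros(c + d)]
        fit = fit_logistic(_design_from_arrays(y, {"x": x}))
        assert fit.converged
        assert fit.params["x"] == pytest.approx(np.log(a * d / (b * c)),
                                                abs=1e-8)
        assert fit.params["intercept"] == pytest.approx(np.log(c / d),
                                                        abs=1e-8)

    def test_null_predictor_balanced(self):
        rng = np.random.default_rng(0)
        n = 4000
        y = rng.random(n) < 0.3
        x = rng.normal(size=n)
        fit = fit_logistic(_design_from_arrays(y.astype(float), {"x": x}))
        assert fit.params["x"] == pytest.approx(0.0, abs=0.1)
        assert fit.params["intercept"] == pytest.approx(
            np.log(y.mean() / (1 - y.mean())), abs=0.05
        )

    def test_wald_chi2_formula(self):
        """Wald chi2 = (beta/se)^2; the published FHx row gives ~51.19."""
        assert (1.617 / 0.226) ** 2 == pytest.approx(51.19, abs=0.01)
        rng = np.random.default_rng(5)
        design = _sim_logit(rng, 2000, [0.8], -1.0)
        fit = fit_logistic(design)
        w = fit.wald_chi2["x0"]
        assert w == pytest.approx(
            (fit.params["x0"] / fit.bse["x0"]) ** 2
        )

    def test_matches_statsmodels(self):
        """Independent IRLS oracle: statsmodels Logit on the same data."""
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(17)
        design = _sim_logit(rng, 1500, [0.8, -0.5], -0.7)
        fit = fit_logistic(design)
        X = np.column_stack([np.ones(1500), design.X.to_numpy()])
        ref = sm.Logit(design.y, X).fit(disp=0)
        np.testing.assert_allclose(fit.params.to_numpy(), ref.params,
                                   atol=1e-6)
        np.testing.assert_allclose(fit.bse.to_numpy(), ref.bse, atol=1e-5)
        assert fit.llf == pytest.approx(ref.llf, abs=1e-6)

    def test_rank_deficiency_names_columns(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=200)
        y = (rng.random(200) < 0.5).astype(float)
        # either member of the collinear pair may be reported
        with pytest.raises(RankDeficientError, match="x[12]"):
            fit_logistic(_design_from_arrays(y, {"x1": x, "x2": 2 * x}))

    def test_separation_flagged(self):
        y = np.r_[np.ones(50), np.zeros(50)]
        x = np.r_[np.ones(50), np.zeros(50)]  # perfect separation
        fit = fit_logistic(_design_from_arrays(y, {"x": x}))
        assert not fit.converged
        assert "x" in fit.separable_terms


class TestLrTest:
    def test_equal_models_give_zero(self):
        rng = np.random.default_rng(3)
        design = _sim_logit(rng, 500, [0.5], 0.0)
        fit = fit_logistic(design)
        res = lr_test(fit, fit)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_nonnegative_and_powerful_for_strong_effect(self):
        rng = np.random.default_rng(4)
        hits = 0
        for _ in range(20):
            design = _sim_logit(rng, 1000, [np.log(3.0)], -0.5)
            full = fit_logistic(design)
            null = fit_logistic(design.subset([]))
            res = lr_test(full, null)
            assert res.statistic >= 0.0
            hits += res.p_value < 0.001
        assert hits >= 19

    def test_non_nested_rejected(self):
        rng = np.random.default_rng(6)
        d1 = _sim_logit(rng, 300, [0.5], 0.0)
        d2 = _sim_logit(rng, 200, [0.5], 0.0)
        with pytest.raises(ValueError, match="nested"):
            lr_test(fit_logistic(d1), fit_logistic(d2))


class TestStepwise:
    def _null_design(self, rng, n=400, k=4):
        y = (rng.random(n) < 0.4).astype(float)
        return _design_from_arrays(
            y, {f"x{i}": rng.normal(size=n) for i in range(k)}
        )

    def test_null_candidates_usually_give_intercept_only(self):
        rng = np.random.default_rng(8)
        empty = 0
        for _ in range(25):
            fit, trace = stepwise_forward_lr(self._null_design(rng))
            empty += len(fit.params) == 1
        assert empty >= 20  # ~alpha-level false entries only

    def test_dominant_predictor_enters_first(self):
        rng = np.random.default_rng(9)
        n = 1500
        strong = rng.normal(size=n)
        weak = rng.normal(size=n)
        eta = -0.5 + np.log(5.0) * strong + 0.3 * weak
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        design = _design_from_arrays(y, {"weak": weak, "strong": strong})
        fit, trace = stepwise_forward_lr(design)
        assert trace[0].action == "enter"
        assert trace[0].variable == "strong"
        # brute force: the step-1 LR statistic of 'strong' beats 'weak'
        null = fit_logistic(design.subset([]))
        lr_strong = lr_test(fit_logistic(design.subset(["strong"])), null)
        lr_weak = lr_test(fit_logistic(design.subset(["weak"])), null)
        assert lr_strong.statistic > lr_weak.statistic

    def test_p_enter_zero_gives_intercept_only(self):
        rng = np.random.default_rng(10)
        design = _sim_logit(rng, 500, [1.0], 0.0)
        fit, trace = stepwise_forward_lr(design, p_enter=0.0)
        assert list(fit.params.index) == ["intercept"]
        assert trace == []

    def test_thresholds_one_include_everything(self):
        rng = np.random.default_rng(11)
        design = _sim_logit(rng, 600, [0.5, 0.0, -0.3], 0.2)
        fit, _ = stepwise_forward_lr(design, p_enter=1.0, p_remove=1.0)
        full = fit_logistic(design)
        assert set(fit.params.index) == set(full.params.index)
        assert fit.llf == pytest.approx(full.llf, abs=1e-8)

    def test_categorical_blocks_enter_whole(self, codebook):
        rng = np.random.default_rng(13)
        n = 1200
        area = rng.choice([1, 2, 3], size=n, p=[0.3, 0.3, 0.4])
        eta = -1.0 + 1.2 * (area == 1)
        y = rng.random(n) < 1 / (1 + np.exp(-eta))
        cohort = pd.DataFrame({
            "area": area,
            "group": np.where(y, "T2DM", "control"),
        })
        design = build_design(cohort, "T2DM", ["area"], codebook)
        assert design.terms["area"] == ["area[suburban]", "area[urban]"]
        fit, trace = stepwise_forward_lr(design)
        assert {"area[suburban]", "area[urban]"} <= set(fit.params.index)


class TestOddsRatios:
    def test_published_fhx_row_arithmetic(self):
        """exp(1.617) ~ 5.04 with CI lower exp(1.617 - 1.96*0.226) ~ 3.235."""
        assert np.exp(1.617) == pytest.approx(5.038, abs=2e-3)
        assert np.exp(1.617 - 1.959964 * 0.226) == pytest.approx(3.235,
                                                                 abs=1e-3)

    def test_reciprocal_reference_reversal(self):
        assert 1 / 0.110 == pytest.approx(9.091, abs=1e-3)

    def test_zero_beta_spans_one(self):
        rng = np.random.default_rng(14)
        design = _sim_logit(rng, 3000, [0.0], 0.0)
        table = odds_ratios(fit_logistic(design))
        row = table.loc["x0"]
        assert row["ci_low"] < 1 < row["ci_high"]

    def test_or_is_exp_beta(self):
        rng = np.random.default_rng(15)
        fit = fit_logistic(_sim_logit(rng, 800, [0.7], -0.3))
        table = odds_ratios(fit)
        assert table.loc["x0", "or"] == pytest.approx(
            np.exp(fit.params["x0"])
        )
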