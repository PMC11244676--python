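"""Multinomial score models and (log-)linear metric regressions."""

import numpy as np
import pandas as pd
import pytest

from metartiq import (
    ReaderScoreTable,
    coefficients_as_percent_change,
    fit_metric_model,
    fit_multinomial,
    fit_ordinal_model,
)
from metartiq.stats import stepwise_aic, _metric_design
from metartiq.synthetic_checks import check_loglinear_exact, check_ordinal_recovery


class TestMultinomial:
    def test_saturated_two_by_two_closed_form(self):
        # counts: x=0 -> (a, b) = (30, 10); x=1 -> (c, d) = (12, 24)
        rows = ([{"score": 1, "x": 0.0}] * 30 + [{"score": 2, "x": 0.0}] * 10
                + [{"score": 1, "x": 1.0}] * 12 + [{"score": 2, "x": 1.0}] * 24)
        fit = fit_multinomial(pd.DataFrame(rows), "score", ["x"])
        expected_slope = np.log((24 / 12) / (10 / 30))
        expected_intercept = np.log(10 / 30)
        assert fit.coefficients.loc["x", "2_vs_1"] == pytest.approx(expected_slope, abs=1e-6)
        assert fit.coefficients.loc["Intercept", "2_vs_1"] == pytest.approx(expected_intercept, abs=1e-6)

    def test_zero_variance_predictor_dropped_to_intercept_only(self):
        rows = [{"score": 1, "x": 5.0}] * 40 + [{"score": 3, "x": 5.0}] * 20
        with pytest.warns(UserWarning, match="zero-variance"):
            fit = fit_multinomial(pd.DataFrame(rows), "score", ["x"])
        assert fit.dropped_terms == ("x",)
        assert fit.coefficients.loc["Intercept", "3_vs_1"] == pytest.approx(np.log(20 / 40), abs=1e-6)

    def test_unobserved_category_flagged(self):
        rows = [{"score": 1, "x": v} for v in np.linspace(0, 1, 20)]
        rows += [{"score": 5, "x": v} for v in np.linspace(1, 2, 20)]
        with pytest.warns(UserWarning, match="not observed"):
            fit = fit_multinomial(pd.DataFrame(rows), "score", ["x"])
        assert fit.missing_categories == (2, 3, 4)

    def test_coefficient_recovery_within_two_se(self):
        res = check_ordinal_recovery(seed=11)
        assert res.passed, res.detail

    def test_log_likelihood_nesting(self, rng):
        # adding a term can never lower the maximised log-likelihood
        n = 120
        df = pd.DataFrame({
            "x1": rng.normal(0, 1, n),
            "x2": rng.normal(0, 1, n),
            "score": rng.integers(1, 4, n),
        })
        ll1 = fit_multinomial(df, "score", ["x1"]).log_likelihood
        ll2 = fit_multinomial(df, "score", ["x1", "x2"]).log_likelihood
        assert ll2 >= ll1 - 1e-8

    def test_ordinal_model_reference_levels(self):
        rng = np.random.default_rng(0)
        meta, scores = {}, {}
        for i in range(24):
            cid = f"c{i}"
            meta[cid] = {"kvp": 120.0, "iq": 80.0, "slice_mm": 0.4,
                         "vmi": "110" if i % 2 else "40",
                         "imar": "Pacemaker" if i % 3 else "None",
                         "kernel": "Qr40f" if (i // 2) % 2 else "Qr36f"}
            for j in range(4):
                scores[(cid, f"r{j}", "Q1")] = int(rng.integers(1, 6))
        fit = fit_ordinal_model(ReaderScoreTable(scores=scores, metadata=meta), "Q1")
        assert fit.reference_category == 1
        assert fit.reference_levels == {"imar": "None", "vmi": "40", "kernel": "Qr36f"}
        assert any("T.110" in t for t in fit.coefficients.index)


def _factor_cases(rng, n=24):
    kernel = np.where(np.arange(n) % 2 == 0, "Qr36f", "Bv56f")
    y = np.exp(1.0 - 0.4 * (kernel == "Bv56f") + rng.normal(0, 0.05, n))
    return pd.DataFrame({
        "kvp": 120.0, "iq": 80.0, "vmi": "110", "slice_mm": 0.4,
        "kernel": kernel, "imar": "Pacemaker", "bloom_vol": y,
    })


class TestMetricModel:
    def test_noiseless_loglinear_recovery_machine_precision(self):
        res = check_loglinear_exact(seed=2)
        assert res.passed, res.detail

    def test_factor_coefficient_is_log_ratio_of_geometric_means(self, rng):
        df = _factor_cases(rng)
        fit = fit_metric_model(df, "bloom_vol", link="log", candidate_terms=["kernel"])
        g36 = np.exp(np.log(df[df.kernel == "Qr36f"].bloom_vol).mean())
        g56 = np.exp(np.log(df[df.kernel == "Bv56f"].bloom_vol).mean())
        coef = fit.coefficients["C(kernel, Treatment('Qr36f'))[T.Bv56f]"]
        assert coef == pytest.approx(np.log(g56 / g36), abs=1e-10)

    def test_signed_response_fit_on_absolute_value(self, rng):
        df = _factor_cases(rng)
        df["diff_hu"] = -df["bloom_vol"]
        fit = fit_metric_model(df, "diff_hu", link="log", candidate_terms=["kernel"])
        assert "absolute value" in fit.response_transform

    def test_non_numeric_kev_cases_excluded(self, rng):
        df = _factor_cases(rng)
        df.loc[df.index[:3], "vmi"] = "T3D"
        fit = fit_metric_model(df, "bloom_vol", link="log", candidate_terms=["kernel"])
        assert fit.n_used == len(df) - 3
        assert len(fit.excluded_cases) == 3

    def test_stepwise_noise_rarely_keeps_terms(self, rng):
        # pure-noise response with 10 spurious candidates: the selected
        # model should stay small in a clear majority of replicates
        n_reps, small = 100, 0
        for _ in range(n_reps):
            n = 60
            df = pd.DataFrame(rng.normal(0, 1, (n, 10)), columns=[f"x{i}" for i in range(10)])
            df["_y"] = rng.normal(0, 1, n)
            terms, _ = stepwise_aic(df, [], [f"x{i}" for i in range(10)], link="linear")
            small += len(terms) <= 2
        assert small >= 60

    def test_marginality_keeps_interaction_parents(self, rng):
        n = 80
        df = pd.DataFrame({
            "x0": rng.normal(0, 1, n),
            "x1": rng.normal(0, 1, n),
        })
        df["_y"] = 2.0 * df.x0 * df.x1 + rng.normal(0, 0.1, n)
        terms, _ = stepwise_aic(df, ["x0", "x1"], ["x0", "x1", "x0:x1"], link="linear")
        assert "x0:x1" in terms and "x0" in terms and "x1" in terms

    def test_log_link_requires_positive_response(self):
        df = _factor_cases(np.random.default_rng(0))
        df.loc[df.index[0], "bloom_vol"] = 0.0
        with pytest.raises(ValueError, match="strictly positive"):
            _metric_design(df, "bloom_vol", "log")


class TestPercentChange:
    def test_closed_forms(self, rng):
        df = _factor_cases(rng)
        fit = fit_metric_model(df, "bloom_vol", link="log", candidate_terms=["kernel"])
        pct = coefficients_as_percent_change(fit)
        coef = fit.coefficients["C(kernel, Treatment('Qr36f'))[T.Bv56f]"]
        assert pct["C(kernel, Treatment('Qr36f'))[T.Bv56f]"] == pytest.approx((np.exp(coef) - 1) * 100)
        # beta = ln 2 -> +100 %; beta = -0.105 -> -9.97 %
        assert (np.exp(np.log(2.0)) - 1) * 100 == pytest.approx(100.0)
        assert (np.exp(-0.105) - 1) * 100 == pytest.approx(-9.97, abs=0.005)

    def test_linear_link_reports_response_units(self, rng):
        df = _factor_cases(rng)
        fit = fit_metric_model(df, "bloom_vol", link="linear", candidate_terms=["kernel"])
        pct = coefficients_as_percent_change(fit)
        assert pct.name == "bloom_vol_units"
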