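"""Curve fitting: recovery, goodness-of-fit identities, ranking, evaluation."""

import numpy as np
import pytest

from mammodrl.curves import (
    FAMILIES,
    DRLCurve,
    DRLCurveModel,
    fit_all,
    fit_model,
    gof_metrics,
    rank_models,
)
from mammodrl.estimator import binned_drl_table

T8 = np.array([25.0, 35.0, 45.0, 55.0, 65.0, 75.0, 85.0, 95.0])
EXP2_TRUE = np.array([0.94, 1 / 118.65, 7.30e-4, 1 / 15.85])


class TestFitModel:
    def test_exact_linear_recovery(self):
        y = 0.7 + 0.013 * T8
        fit = fit_model((T8, y), "linear", seed=0)
        np.testing.assert_allclose(fit.params, [0.7, 0.013], rtol=1e-9)
        assert fit.sse <= 1e-18

    def test_noiseless_exp2_self_consistency(self):
        y = FAMILIES["exp2"](T8, EXP2_TRUE)
        fit = fit_model((T8, y), "exp2", seed=0)
        np.testing.assert_allclose(fit.params, EXP2_TRUE, rtol=1e-4)
        assert fit.converged

    def test_nested_sse_inequalities(self):
        rng = np.random.default_rng(3)
        y = FAMILIES["exp1"](T8, [0.9, 0.01]) * np.exp(rng.normal(0, 0.05, 8))
        f1 = fit_model((T8, y), "exp1", seed=0)
        f2 = fit_model(
            (T8, y), "exp2", seed=0,
            nested_start=np.array([f1.params[0], f1.params[1], 0.0, f1.params[1]]),
        )
        assert f2.sse <= f1.sse + 1e-10
        p1 = fit_model((T8, y), "power1", seed=0)
        p2 = fit_model(
            (T8, y), "power2", seed=0,
            nested_start=np.array([p1.params[0], p1.params[1], 0.0]),
        )
        assert p2.sse <= p1.sse + 1e-10

    def test_determinism_bit_identical(self):
        rng = np.random.default_rng(9)
        y = FAMILIES["exp2"](T8, EXP2_TRUE) * np.exp(rng.normal(0, 0.05, 8))
        a = fit_model((T8, y), "exp2", seed=123)
        b = fit_model((T8, y), "exp2", seed=123)
        assert a.params.tobytes() == b.params.tobytes()

    def test_too_few_points_raises(self):
        with pytest.raises(ValueError):
            fit_model((T8[:4], np.ones(4)), "exp2", seed=0)

    def test_power_family_requires_positive_cbt(self):
        with pytest.raises(ValueError, match="CBT > 0"):
            fit_model((np.array([-1.0, 1, 2, 3]), np.ones(4)), "power1", seed=0)

    def test_exp2_canonical_rate_order(self):
        y = FAMILIES["exp2"](T8, EXP2_TRUE)
        fit = fit_model((T8, y), "exp2", seed=0)
        assert fit.params[1] <= fit.params[3]

    def test_value_recovery_under_noise(self):
        # 5% lognormal noise on 8 points: curve VALUES (not params, which are
        # weakly identified) recovered to <= 5% median abs relative error
        grid = np.arange(25.0, 96.0)
        truth_vals = FAMILIES["exp2"](grid, EXP2_TRUE)
        medians = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            y = FAMILIES["exp2"](T8, EXP2_TRUE) * np.exp(rng.normal(0, 0.05, 8))
            fit = fit_model((T8, y), "exp2", seed=seed)
            rel = np.abs(fit.predict(grid) - truth_vals) / truth_vals
            medians.append(np.median(rel))
        assert np.median(medians) <= 0.05


class TestGofMetrics:
    # printed combined-data GOF cells: the identities RMSE = sqrt(SSE/(n-p))
    # and adjR2 = 1-(1-R2)(n-1)/(n-p) reconstruct one column from the other
    # at n = 8 fitted points
    @pytest.mark.parametrize(
        "sse,p,rmse",
        [(0.015, 4, 0.061), (0.020, 3, 0.063), (0.024, 2, 0.063),
         (0.054, 2, 0.095), (0.090, 2, 0.122)],
    )
    def test_rmse_identity_cc(self, sse, p, rmse):
        assert np.sqrt(sse / (8 - p)) == pytest.approx(rmse, abs=1e-3)

    @pytest.mark.parametrize(
        "r2,p,adj",
        [(0.988, 4, 0.979), (0.984, 3, 0.978), (0.981, 2, 0.978),
         (0.957, 2, 0.950), (0.928, 2, 0.916)],
    )
    def test_adj_r2_identity_cc(self, r2, p, adj):
        assert 1 - (1 - r2) * 7 / (8 - p) == pytest.approx(adj, abs=1e-3)

    def test_identities_hold_exactly_on_fits(self):
        rng = np.random.default_rng(2)
        y = FAMILIES["exp2"](T8, EXP2_TRUE) * np.exp(rng.normal(0, 0.1, 8))
        for fam in FAMILIES:
            fit = fit_model((T8, y), fam, seed=0)
            g, n, p = fit.gof, fit.n_points, fit.family.n_params
            assert g["rmse"] == pytest.approx(np.sqrt(g["sse"] / (n - p)), rel=1e-12)
            assert g["adj_r2"] == pytest.approx(
                1 - (1 - g["r2"]) * (n - 1) / (n - p), rel=1e-12
            )

    def test_perfect_fit(self):
        y = 1.0 + 0.01 * T8
        g = gof_metrics(y, y, 2)
        assert g["sse"] == 0 and g["rmse"] == 0 and g["r2"] == 1 and g["adj_r2"] == 1


class TestRanking:
    def _fake(self, sse, p=2, adj=0.9, conv=True):
        from mammodrl.curves import ModelFit, ModelFamily

        fam = {2: FAMILIES["exp1"], 3: FAMILIES["power2"], 4: FAMILIES["exp2"]}[p]
        return ModelFit(fam, np.zeros(p), {"sse": sse, "rmse": 0, "r2": 0, "adj_r2": adj},
                        8, conv, 0)

    def test_ascending_sse(self):
        fits = [self._fake(s) for s in (0.054, 0.015, 0.090, 0.024, 0.020)]
        assert [f.sse for f in rank_models(fits)] == [0.015, 0.020, 0.024, 0.054, 0.090]

    def test_tie_prefers_fewer_params(self):
        a, b = self._fake(0.02, p=2), self._fake(0.02, p=4)
        assert rank_models([b, a])[0] is a

    def test_nonconverged_last_even_with_best_sse(self):
        good, bad = self._fake(0.05), self._fake(0.001, conv=False)
        assert rank_models([bad, good])[0] is good


class TestDRLCurve:
    def test_published_style_tau_form_evaluation(self):
        curve = DRLCurve.from_coefficients(
            "CC", "exp2", [0.94, 118.65, 7.30e-4, 15.85], tau_form=True
        )
        assert curve.evaluate(50.0) == pytest.approx(1.45, abs=0.005)
        assert not curve.is_extrapolation(50.0)
        assert curve.is_extrapolation(110.0)

    def test_exp2_with_zero_c_equals_exp1(self):
        e1 = DRLCurve.from_coefficients("CC", "exp1", [0.9, 0.012])
        e2 = DRLCurve.from_coefficients("CC", "exp2", [0.9, 0.012, 0.0, 0.05])
        grid = np.linspace(20, 100, 30)
        np.testing.assert_allclose(e1.evaluate(grid), e2.evaluate(grid), rtol=1e-12)

    def test_positive_curve_is_valid_drl(self):
        curve = DRLCurve.from_coefficients("CC", "linear", [5.0, -0.04])
        assert curve.is_valid_drl()  # 5 - 4 = 1 > 0 at 100 mm
        bad = DRLCurve.from_coefficients("CC", "linear", [1.0, -0.02])
        assert not bad.is_valid_drl()  # hits zero at 50 mm

    def test_equation_string_tau_presentation(self):
        curve = DRLCurve.from_coefficients(
            "CC", "exp2", [0.94, 118.65, 7.30e-4, 15.85], tau_form=True
        )
        s = curve.fit.equation_string(sig=5).replace(" ", "")
        assert "exp(CBT/118.65" in s and "exp(CBT/15.85" in s


class TestModelResultsSurface:
    def test_fit_all_selects_truth_family_on_clean_points(self):
        y = FAMILIES["exp2"](T8, EXP2_TRUE)
        model = DRLCurveModel(T8, y, view="CC")
        res = model.fit(seed=0)
        assert res.best.family.name == "exp2"
        assert res.predict(58.0) == pytest.approx(
            FAMILIES["exp2"](np.array([58.0]), EXP2_TRUE)[0], rel=1e-6
        )
        assert "selected: exp2" in res.summary()

    def test_straight_line_ranks_linear_no_worse_than_power1(self):
        y = 0.5 + 0.015 * T8
        res = DRLCurveModel(T8, y, view="CC").fit(seed=0)
        order = [f.family.name for f in res.fits]
        assert order.index("linear") < order.index("power1")

    def test_fit_all_needs_five_bins(self, small_cohort):
        from mammodrl.estimator import BinScheme

        table, _ = small_cohort
        binned = binned_drl_table(table, "CC", BinScheme(lo=40, hi=80, width=10))
        with pytest.raises(ValueError, match="merg"):
            fit_all(binned)

    def test_stratified_fit_is_same_operation_on_filtered_table(self, small_cohort):
        from mammodrl.records import CohortTable

        table, _ = small_cohort
        vendor = table.df["manufacturer"].iloc[0]
        sub = CohortTable(table.df[table.df["manufacturer"] == vendor].reset_index(drop=True))
        binned = binned_drl_table(sub, "CC")
        fits, curve = fit_all(binned, seed=0)
        assert len(fits) == 5
        assert curve.view == "CC"
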