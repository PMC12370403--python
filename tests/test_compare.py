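"""Approach-comparison statistics and the Wilcoxon signed-rank test."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from mammodrl.compare import (
    LimitCurves,
    classify_against_limits,
    compare_equation_vs_ranges,
    compare_to_simplest,
    percent_diff,
    signed_rank_test,
)
from mammodrl.curves import DRLCurve
from mammodrl.estimator import binned_drl_table


class TestPercentDiff:
    # printed approach values at CBT 50/80/100 and their difference cells
    @pytest.mark.parametrize(
        "rng_val,eq_val,expected,half_step",
        [
            (1.55, 1.45, 6.9, 0.05),
            (2.15, 1.96, 9.7, 0.05),
            (1.77, 1.59, 11.0, 0.5),  # printed as "11%"
            (2.38, 2.24, 6.3, 0.05),
            (3.03, 4.72, 35.8, 0.05),
        ],
    )
    def test_printed_difference_cells(self, rng_val, eq_val, expected, half_step):
        assert percent_diff(rng_val, eq_val) == pytest.approx(expected, abs=half_step + 1e-9)

    def test_cc_100_cell_printed_inputs(self):
        # printed inputs (2.37, 2.58) give 8.14%; the published table shows
        # 8.2%, evidently computed from unrounded values — one rounding step
        assert percent_diff(2.37, 2.58) == pytest.approx(8.14, abs=0.01)

    def test_identity_is_zero(self):
        assert percent_diff(1.49, 1.49) == 0.0

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            percent_diff(1.0, 0.0)


class TestCompareToSimplest:
    @pytest.mark.parametrize(
        "value,simplest,expected",
        [(2.37, 1.49, 59), (3.03, 1.69, 79), (2.58, 1.49, 73), (4.72, 1.69, 179)],
    )
    def test_discussion_ratios(self, value, simplest, expected):
        assert round(compare_to_simplest(value, simplest)) == expected


class TestSignedRank:
    def test_all_positive_six(self):
        r = signed_rank_test([1, 2, 3, 4, 5, 6])
        assert r.statistic == 0.0
        assert r.p_value == pytest.approx(0.03125)

    def test_symmetric_p_is_one(self):
        r = signed_rank_test([-1, 1, -2, 2, -3, 3])
        assert r.statistic == pytest.approx(10.5)  # mid-ranked ties
        assert r.p_value == 1.0

    def test_sign_flip_invariance(self):
        d = [0.4, -1.2, 2.2, 0.7, -0.3, 1.9, 0.9]
        assert signed_rank_test(d).p_value == pytest.approx(
            signed_rank_test([-x for x in d]).p_value
        )

    def test_all_zero_degenerate(self):
        r = signed_rank_test([0.0] * 10)
        assert r.degenerate and r.p_value == 1.0 and r.n_pairs == 0

    def test_matches_scipy_exact_on_tie_free_data(self):
        rng = np.random.default_rng(1)
        for n in (7, 12, 18, 25):
            d = rng.normal(0.4, 1.0, n)
            ours = signed_rank_test(d)
            ref = stats.wilcoxon(d, mode="exact")
            assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-10)

    @given(st.lists(st.integers(-5, 5), min_size=6, max_size=10))
    @settings(max_examples=60, deadline=None)
    def test_matches_enumeration_oracle_with_ties(self, diffs):
        d = np.array([x for x in diffs if x != 0], dtype=float)
        if len(d) < 6:
            return
        ours = signed_rank_test(d)
        # brute force over all sign patterns at the observed mid-ranks
        ranks = stats.rankdata(np.abs(d))
        w_obs = min(ranks[d > 0].sum(), ranks[d < 0].sum())
        count = sum(
            sum(r for s, r in zip(signs, ranks) if s > 0) <= w_obs + 1e-9
            for signs in itertools.product([1, -1], repeat=len(d))
        )
        expected = min(1.0, 2 * count / 2 ** len(d))
        assert ours.p_value == pytest.approx(expected, rel=1e-12)

    def test_normal_approximation_above_exact_cutoff(self):
        rng = np.random.default_rng(0)
        d = rng.normal(0.5, 1.0, 60)
        r = signed_rank_test(d)
        ref = stats.wilcoxon(d, mode="approx", correction=True)
        assert r.method == "normal"
        assert r.p_value == pytest.approx(ref.pvalue, rel=0.02)


class TestEquationVsRanges:
    def test_report_invariants_and_bin_convention(self, small_cohort):
        from mammodrl.filtering import apply_exclusions
        from mammodrl.curves import DRLCurveModel

        table, _ = small_cohort
        filt, _ = apply_exclusions(table)
        binned = binned_drl_table(filt, "CC")
        res = DRLCurveModel.from_binned_table(binned).fit(seed=0)
        rep = compare_equation_vs_ranges(res.curve, binned, simplest=1.5)
        assert rep.grid[0] == 20 and rep.grid[-1] == 100 and len(rep.grid) == 81
        # grid point 50 uses the [50, 60) bin
        i50 = int(np.where(rep.grid == 50)[0][0])
        assert rep.range_drl[i50] == binned.rows[3].drl
        # pointwise invariant: |range - eq| / eq * 100
        ok = ~np.isnan(rep.range_drl)
        np.testing.assert_allclose(
            rep.pct_diff_range[ok],
            np.abs(rep.range_drl[ok] - rep.eq_drl[ok]) / rep.eq_drl[ok] * 100,
        )
        np.testing.assert_allclose(
            rep.pct_diff_simplest, np.abs(rep.eq_drl - 1.5) / 1.5 * 100
        )
        assert rep.wilcoxon.n_pairs > 0 and 0 <= rep.wilcoxon.p_value <= 1

    def test_systematic_offset_detected_as_significant(self, small_cohort):
        # a curve biased 5% below every bin DRL must give a tiny two-sided p
        from mammodrl.filtering import apply_exclusions
        from mammodrl.curves import DRLCurveModel, DRLCurve

        table, _ = small_cohort
        filt, _ = apply_exclusions(table)
        binned = binned_drl_table(filt, "CC")
        res = DRLCurveModel.from_binned_table(binned).fit(seed=0)
        low = DRLCurve(
            view="CC",
            fit=type(res.best)(
                family=res.best.family,
                params=res.best.params * np.array([0.95, 1, 0.95, 1]),
                gof=res.best.gof, n_points=res.best.n_points,
                converged=True, n_restarts_used=0,
            ),
            domain=res.curve.domain,
        )
        rep = compare_equation_vs_ranges(low, binned)
        assert rep.wilcoxon.p_value < 0.001

    def test_view_mismatch_rejected(self, small_cohort):
        table, _ = small_cohort
        binned = binned_drl_table(table, "CC")
        curve = DRLCurve.from_coefficients("MLO", "exp1", [1.0, 0.01])
        with pytest.raises(ValueError, match="view"):
            compare_equation_vs_ranges(curve, binned)

    def test_step_equal_to_curve_degenerate(self, small_cohort):
        # a constant curve against bins built from a constant cohort: all
        # differences zero -> degenerate test with p = 1 and zero pairs
        from conftest import make_table

        rows = [
            {"center_id": c, "exam_id": f"{c}{i}", "agd": 1.5, "cbt": cbt}
            for c in ("C1", "C2") for i, cbt in enumerate([25.0, 45.0, 65.0, 85.0, 95.0])
        ]
        binned = binned_drl_table(make_table(rows), "CC")
        curve = DRLCurve.from_coefficients("CC", "linear", [1.5, 0.0])
        rep = compare_equation_vs_ranges(curve, binned)
        assert rep.wilcoxon.degenerate and rep.wilcoxon.p_value == 1.0


class TestLimits:
    def _limits(self):
        acceptable = np.array([[20.0, 2.0], [100.0, 4.0]])
        achievable = np.array([[20.0, 1.0], [100.0, 2.0]])
        return LimitCurves(acceptable=acceptable, achievable=achievable)

    def test_achievable_must_not_exceed_acceptable(self):
        with pytest.raises(ValueError):
            LimitCurves(
                acceptable=np.array([[20.0, 1.0], [100.0, 1.0]]),
                achievable=np.array([[20.0, 2.0], [100.0, 2.0]]),
            )

    def test_strictly_below_achievable(self):
        curve = DRLCurve.from_coefficients("CC", "linear", [0.5, 0.0])
        cls = classify_against_limits(curve, self._limits())
        assert set(cls.labels) == {"below_achievable"}

    def test_boundary_inclusive_downward(self):
        # curve exactly on the acceptable limit -> between
        curve = DRLCurve.from_coefficients("CC", "linear", [1.5, 0.025])
        cls = classify_against_limits(curve, self._limits())
        assert set(cls.labels) == {"between"}

    def test_single_crossing_two_regions(self):
        # constant 1.5 mGy crosses the achievable line (1 -> 2) at CBT = 60
        curve = DRLCurve.from_coefficients("CC", "linear", [1.5, 0.0])
        cls = classify_against_limits(curve, self._limits())
        labels = [r[0] for r in cls.regions]
        assert labels == ["between", "below_achievable"]
        assert cls.regions[1][1] == 60.0

    def test_uncovered_grid_points_flagged(self):
        lim = LimitCurves(
            acceptable=np.array([[40.0, 2.0], [80.0, 3.0]]),
            achievable=np.array([[40.0, 1.0], [80.0, 2.0]]),
        )
        curve = DRLCurve.from_coefficients("CC", "linear", [1.5, 0.0])
        cls = classify_against_limits(curve, lim)
        assert cls.labels[0] == "uncovered" and cls.labels[-1] == "uncovered"

    def test_grid_refinement_moves_boundaries_less_than_step(self):
        curve = DRLCurve.from_coefficients("CC", "linear", [1.5, 0.0])
        coarse = classify_against_limits(curve, self._limits(), grid_step=2.0)
        fine = classify_against_limits(curve, self._limits(), grid_step=0.5)
        b_coarse = coarse.regions[1][1]
        b_fine = fine.regions[1][1]
        assert abs(b_coarse - b_fine) < 2.0
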