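"""Closed-form sensitivity metrics: examples, identities and properties."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hctsens import (
    ConfounderStrength,
    DegenerateDesignError,
    DesignRatios,
    EffectEstimate,
    approximate_rr,
    bias_factor_bound,
    confounding_threshold,
    e_value,
    fold_ratio,
    frontier,
    hc_value,
    hc_value_ci,
    rd_bound,
    rd_value,
)

ratios = st.floats(min_value=1e-3, max_value=1e3)
etas = st.floats(min_value=0.05, max_value=50.0)


class TestFoldRatio:
    @pytest.mark.parametrize(
        "x, expected",
        [(0.81, 1.234568), (1.0, 1.0), (1.5, 1.5)],
    )
    def test_examples(self, x, expected):
        assert fold_ratio(x) == pytest.approx(expected, abs=5e-7)

    @given(ratios)
    def test_idempotent_symmetric_and_at_least_one(self, x):
        f = fold_ratio(x)
        assert f >= 1.0
        assert fold_ratio(f) == f
        assert fold_ratio(1.0 / x) == pytest.approx(f, rel=1e-12)

    @pytest.mark.parametrize("bad", [0.0, -1.0, math.inf, math.nan])
    def test_invalid_input(self, bad):
        with pytest.raises(ValueError):
            fold_ratio(bad)


class TestEValue:
    @pytest.mark.parametrize(
        "rr, expected",
        [(1.0, 1.0), (2.0, 2.0 + math.sqrt(2.0)), (0.5, 2.0 + math.sqrt(2.0))],
    )
    def test_examples(self, rr, expected):
        assert e_value(rr) == pytest.approx(expected, rel=1e-12)

    @given(ratios)
    def test_equals_one_iff_null_and_matches_rd_value(self, rr):
        ev = e_value(rr)
        assert (ev == 1.0) == (rr == 1.0)
        # shared closed form with the RD-value
        assert rd_value(rr) == ev


class TestBiasFactorBound:
    @pytest.mark.parametrize(
        "su, uy, eta, expected",
        [
            (1.0, 7.0, 3.0, 1.0),  # no inclusion association => no bias
            (2.0, 2.0, 1.0, 8.0 / 7.0),
            (7.0, 1.0, 3.0, 1.0),  # symmetric cancellation
        ],
    )
    def test_examples(self, su, uy, eta, expected):
        assert bias_factor_bound((su, uy), eta) == pytest.approx(expected, rel=1e-12)

    def test_accepts_domain_types(self):
        strength = ConfounderStrength(rr_su=2.0, rr_uy=2.0)
        design = DesignRatios(alpha=2.0, eta=1.0)
        assert bias_factor_bound(strength, design) == pytest.approx(8.0 / 7.0)

    def test_requires_folded_components(self):
        with pytest.raises(ValueError, match="fold"):
            bias_factor_bound((0.9, 2.0), 1.0)

    @given(st.floats(1.0, 50.0), st.floats(1.0, 50.0), etas)
    def test_bounded_by_one_plus_eta(self, su, uy, eta):
        b = bias_factor_bound((su, uy), eta)
        assert 1.0 - 1e-12 <= b <= 1.0 + eta + 1e-9

    def test_saturates_as_confounding_grows(self):
        assert bias_factor_bound((1e9, 1e9), 3.0) == pytest.approx(4.0, rel=1e-6)


class TestConfoundingThreshold:
    def test_null_bias_factor(self):
        assert confounding_threshold(1.0, 2.0) == pytest.approx(1.0)

    def test_infinite_beyond_saturation(self):
        assert math.isinf(confounding_threshold(2.2, 1.0))

    def test_derived_value_via_round_trip(self):
        v = confounding_threshold(1.653, 5.0)
        assert v == pytest.approx(3.211, abs=1e-3)
        assert bias_factor_bound((v, v), 5.0) == pytest.approx(1.653, rel=1e-10)

    def test_degenerate_design_rejected(self):
        with pytest.raises(DegenerateDesignError):
            confounding_threshold(1.5, 0.0)


class TestHCValue:
    def test_printed_asthma_value(self):
        # medium-dose arm: folded 1/0.81 at equal-size borrowing
        assert round(hc_value(0.81, 1.0), 2) == 2.61

    def test_null_effect(self):
        assert hc_value(1.0, 3.0) == pytest.approx(1.0)

    def test_large_eta_recovers_e_value(self):
        assert hc_value(1.653, 1e6) == pytest.approx(e_value(1.653), abs=1e-3)

    @given(st.floats(0.02, 0.999) | st.floats(1.001, 50.0), etas)
    def test_folding_symmetry(self, rr, eta):
        assert hc_value(rr, eta) == pytest.approx(hc_value(1.0 / rr, eta), rel=1e-9)

    @given(st.floats(1.001, 20.0), etas)
    def test_at_least_e_value(self, rr, eta):
        hv = hc_value(rr, eta)
        assert hv >= e_value(rr) - 1e-9

    def test_strictly_increasing_in_folded_rr(self):
        eta = 3.0
        grid = np.linspace(1.01, 1.0 + eta - 0.05, 40)
        vals = hc_value(grid, eta)
        assert np.all(np.diff(vals) > 0)

    def test_strictly_decreasing_in_eta(self):
        etas_ = np.array([0.5, 1.0, 2.0, 5.0, 20.0])
        vals = [hc_value(1.3, e) for e in etas_]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    @given(st.floats(1.0001, 10.0), st.floats(0.1, 20.0))
    @settings(max_examples=200)
    def test_round_trip_with_bias_bound(self, rr, eta):
        """Tipping threshold plugged back into the bias bound recovers the
        folded effect (the bound is attained iff rr_su = rr_uy)."""
        if rr >= 1.0 + eta:
            rr = 1.0 + eta * 0.9
        v = hc_value(rr, eta)
        assert bias_factor_bound((v, v), eta) == pytest.approx(fold_ratio(rr), abs=1e-10)


class TestHCValueCI:
    def test_significant_interval_uses_limit_closer_to_null(self):
        est = EffectEstimate(0.65, 0.54, 0.76)
        # closer-to-null limit is 0.76 (smaller folded ratio)
        assert hc_value_ci(est, 1.0) == pytest.approx(hc_value(0.76, 1.0))
        assert hc_value_ci(est, 1.0) == pytest.approx(3.26, abs=5e-3)

    def test_ci_including_null_gives_one(self):
        assert hc_value_ci(EffectEstimate(1.10, 0.85, 1.40), 2.0) == 1.0

    def test_ci_touching_null_counts_as_including(self):
        assert hc_value_ci(EffectEstimate(1.2, 1.0, 1.4), 2.0) == 1.0

    def test_protective_interval(self):
        est = EffectEstimate(0.81, 0.70, 0.94)
        assert hc_value_ci(est, 1.0) == pytest.approx(1.53, abs=5e-3)


class TestRDBound:
    @pytest.mark.parametrize("x", [1.0, 2.5, 40.0])
    def test_no_association_no_rd(self, x):
        assert rd_bound((1.0, x)) == pytest.approx(1.0)
        assert rd_bound((x, 1.0)) == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        assert rd_bound((2.0, 2.0)) == pytest.approx(4.0 / 3.0)

    @given(st.floats(1.0, 50.0), st.floats(1.0, 50.0))
    def test_symmetric_and_below_weaker_association(self, su, uy):
        b = rd_bound((su, uy))
        assert b == pytest.approx(rd_bound((uy, su)), rel=1e-12)
        assert b <= min(su, uy) + 1e-12


class TestRDValue:
    def test_printed_ci_limit_value(self):
        assert round(rd_value(0.92), 2) == 1.39

    def test_null(self):
        assert rd_value(1.0) == 1.0

    def test_point_estimate_value(self):
        assert rd_value(0.79) == pytest.approx(1.85, abs=5e-3)

    @given(st.floats(1.0001, 50.0))
    @settings(max_examples=200)
    def test_round_trip_with_rd_bound(self, rd):
        v = rd_value(rd)
        assert rd_bound((v, v)) == pytest.approx(fold_ratio(rd), abs=1e-10)


class TestFrontier:
    def test_rd_frontier_point(self):
        curve = frontier("induce_rd", 4.0 / 3.0, grid=[2.0])
        assert curve.points == pytest.approx(np.array([[2.0, 2.0]]))

    def test_effect_frontier_threshold_point(self):
        eta = 1.0
        v = hc_value(0.81, eta)
        curve = frontier("explain_away_effect", 0.81, eta, grid=[v])
        assert curve.points[0] == pytest.approx([v, v], rel=1e-9)

    @pytest.mark.parametrize(
        "kind, value, eta",
        [
            ("explain_away_effect", 0.81, 1.0),
            ("explain_away_effect", 1.4, 5.0),
            ("explain_away_significance", 0.76, 1.0),
            ("induce_rd", 0.79, None),
            ("induce_rd", 1.6, None),
        ],
    )
    def test_equality_on_frontier(self, kind, value, eta):
        """Every returned point satisfies the corresponding bound with
        equality at the folded input value."""
        curve = frontier(kind, value, eta)
        assert curve.feasible and len(curve.points) >= 100
        su, uy = curve.points[:, 0], curve.points[:, 1]
        if kind == "induce_rd":
            achieved = rd_bound((su, uy))
        else:
            achieved = bias_factor_bound((su, uy), eta)
        assert np.max(np.abs(achieved - fold_ratio(value))) < 1e-8
        # rr_uy non-increasing as rr_su increases
        assert np.all(np.diff(uy) <= 1e-12)

    def test_infeasible_effect_returns_flag_not_exception(self):
        curve = frontier("explain_away_effect", 2.5, 1.0)
        assert not curve.feasible
        assert len(curve.points) == 0
        assert math.isinf(curve.threshold)

    def test_null_value_degenerates_to_unit_point(self):
        curve = frontier("induce_rd", 1.0)
        assert curve.threshold == 1.0
        assert curve.points.tolist() == [[1.0, 1.0]]


class TestApproximateRR:
    @pytest.mark.parametrize(
        "effect, measure, expected",
        [
            (1.0, "odds_ratio", 1.0),
            (4.0, "odds_ratio", 2.0),
            (0.0, "std_mean_diff", 1.0),
            (1.0, "hazard_ratio", 1.0),
            (2.0, "risk_ratio", 2.0),
            (1.0, "std_mean_diff", math.exp(0.91)),
        ],
    )
    def test_conversions(self, effect, measure, expected):
        assert approximate_rr(effect, measure) == pytest.approx(expected, rel=1e-12)

    def test_hazard_ratio_formula(self):
        hr = 2.0
        expected = (1 - 0.5 ** math.sqrt(2.0)) / (1 - 0.5 ** math.sqrt(0.5))
        assert approximate_rr(hr, "hazard_ratio") == pytest.approx(expected)

    def test_unknown_measure(self):
        with pytest.raises(ValueError, match="measure"):
            approximate_rr(2.0, "rate_ratio")


class TestDomainTypes:
    def test_design_ratios_from_counts(self):
        d = DesignRatios.from_counts(200, 100, 500)
        assert (d.alpha, d.eta) == (2.0, 5.0)

    @pytest.mark.parametrize("alpha, eta", [(0.0, 1.0), (-1.0, 1.0), (1.0, -0.5)])
    def test_design_ratio_validation(self, alpha, eta):
        with pytest.raises(ValueError):
            DesignRatios(alpha=alpha, eta=eta)

    def test_effect_estimate_ordering_enforced(self):
        with pytest.raises(ValueError):
            EffectEstimate(rr=1.5, ci_lower=1.6, ci_upper=2.0)

    def test_confounder_strength_must_be_folded(self):
        with pytest.raises(ValueError):
            ConfounderStrength(rr_su=0.8, rr_uy=2.0)
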