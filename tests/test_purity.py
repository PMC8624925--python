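"""Purity statistic, classification bands and the copies-per-ng screen."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dna_accounting import (
    CalibrationModel,
    Category,
    Tier,
    classify,
    percent_purity,
    population_rule,
    screen_by_ratio,
)


def exact_model(sigma2=0.0025, dof=70):
    """Identity-line model with constant-CV variance and no coefficient
    uncertainty, so interval bounds are analytically known."""
    return CalibrationModel(
        intercept=0.0, slope=1.0, variance_power=2.0, sigma2=sigma2,
        dof=dof, coefficient_covariance=np.zeros((2, 2)), n_points=dof + 2,
    )


class TestPercentPurity:
    @pytest.fixture
    def model(self):
        return exact_model()

    def test_interior_point_is_pure(self, model):
        from dna_accounting.calibration import prediction_interval

        pi = prediction_interval(model, 1e4)
        res = percent_purity((pi.lower + pi.upper) / 2, 1e4, model, "mid")
        assert res.purity == 1.0
        assert res.category is Category.NON_SUSPICIOUS
        assert res.tier is Tier.WITHIN_INTERVAL

    def test_below_interval_divides_by_lower_bound(self, model):
        from dna_accounting.calibration import prediction_interval

        pi = prediction_interval(model, 1e4)
        res = percent_purity(pi.lower / 2, 1e4, model)
        assert res.purity == pytest.approx(0.5, rel=1e-12)
        assert res.category is Category.SUSPICIOUS and res.tier is Tier.LOW_BAND

    def test_above_interval_denominator_convention(self, model):
        from dna_accounting.calibration import prediction_interval

        pi = prediction_interval(model, 1e4)
        res = percent_purity(1.25 * pi.upper, 1e4, model)
        assert res.purity == pytest.approx(1.25, rel=1e-12)
        as_printed = percent_purity(1.25 * pi.upper, 1e4, model, upper_denominator="lce")
        assert as_printed.purity == pytest.approx(1.25 * pi.upper / pi.lower, rel=1e-12)
        assert as_printed.purity > res.purity  # same side of the band, inflated
        assert as_printed.category is Category.SUSPICIOUS

    def test_piecewise_branches_and_continuity(self, model):
        """purity < 1 iff cm < lCe; > 1 iff cm > uCe; continuous at bounds."""
        from dna_accounting.calibration import prediction_interval

        ce = 2e4
        pi = prediction_interval(model, ce)
        eps = 1e-9 * pi.upper
        for cm, expect in [
            (pi.lower - eps, "below"), (pi.lower, "in"), (pi.upper, "in"),
            (pi.upper + eps, "above"),
        ]:
            p = percent_purity(cm, ce, model).purity
            if expect == "in":
                assert p == 1.0
            elif expect == "below":
                assert p < 1 and p == pytest.approx(1.0, rel=1e-6)
            else:
                assert p > 1 and p == pytest.approx(1.0, rel=1e-6)

    @settings(max_examples=200, deadline=None)
    @given(cm=st.floats(0, 1e6), ce=st.floats(1e2, 1e5))
    def test_purity_monotone_in_cm(self, cm, ce):
        model = exact_model()
        p1 = percent_purity(cm, ce, model).purity
        p2 = percent_purity(cm * 1.01 + 1.0, ce, model).purity
        assert p2 >= p1

    def test_below_quantification_range_flagged(self):
        # enormous intercept uncertainty drives the lower bound negative
        model = CalibrationModel(
            intercept=0.0, slope=1.0, variance_power=2.0, sigma2=0.0025,
            dof=10, coefficient_covariance=np.array([[1e9, 0.0], [0.0, 0.0]]),
            n_points=12,
        )
        res = percent_purity(50.0, 10.0, model, "tiny")
        assert math.isnan(res.purity)
        assert res.category is None and res.tier is None
        assert "below_quantification_range" in res.flags


@pytest.mark.parametrize(
    "purity, category, tier",
    [
        (1.00, Category.NON_SUSPICIOUS, Tier.WITHIN_INTERVAL),
        (0.80, Category.NON_SUSPICIOUS, Tier.WITHIN_ACCEPTANCE),
        (1.20, Category.NON_SUSPICIOUS, Tier.WITHIN_ACCEPTANCE),
        (0.95, Category.NON_SUSPICIOUS, Tier.WITHIN_ACCEPTANCE),
        (0.799, Category.SUSPICIOUS, Tier.HIGH_BAND),
        (0.70, Category.SUSPICIOUS, Tier.HIGH_BAND),
        (1.21, Category.SUSPICIOUS, Tier.HIGH_BAND),
        (0.699, Category.SUSPICIOUS, Tier.LOW_BAND),
        (0.0009, Category.SUSPICIOUS, Tier.LOW_BAND),  # near-total substitution
        (0.0, Category.SUSPICIOUS, Tier.LOW_BAND),
    ],
)
def test_classification_bands(purity, category, tier):
    assert classify(purity) == (category, tier)


class TestPopulationRule:
    def test_market_rule_bounds(self):
        """Mean 143 / SD 40 copies per ng: lower bound rounds to 65."""
        rule = population_rule(143.0, 40.0)
        assert rule.low == pytest.approx(64.6, abs=1e-9)
        assert round(rule.low) == 65
        assert rule.high == pytest.approx(221.4, abs=1e-9)

    def test_degenerate_spread_and_z_zero(self):
        rule = population_rule(100.0, 1e-4)
        assert rule.low == pytest.approx(100.0, abs=1e-3)
        rule = population_rule(100.0, 40.0, z=0.0)
        assert (rule.low, rule.high) == (100.0, 100.0)

    def test_invalid_sd_rejected(self):
        with pytest.raises(ValueError):
            population_rule(143.0, 0.0)

    @pytest.mark.parametrize(
        "ratio, expected",
        [(143.0, True), (30.0, False), (64.6, True), (64.59, False),
         (221.4, True), (222.0, False)],
    )
    def test_screen_by_ratio_inclusive_bounds(self, ratio, expected):
        rule = population_rule(143.0, 40.0)
        passed, r = screen_by_ratio(ratio * 10.0, 10.0, rule)
        assert r == pytest.approx(ratio)
        assert passed is expected

    def test_zero_dna_rejected(self):
        with pytest.raises(ValueError):
            screen_by_ratio(100.0, 0.0, population_rule(143.0, 40.0))


def test_interval_and_ratio_rules_agree_on_pure_population(rng):
    """Both screens pass ~95% of pure samples when the ratio rule's mean/SD
    come from the same population the calibration saw."""
    from dna_accounting import (
        SAFFRON,
        SimulationConfig,
        calibrate_from_counts,
        simulate_market,
    )
    from dna_accounting.pipeline import ratio_screen_samples, screen_samples

    cfg = SimulationConfig(seed=99, dna_ng_range=(8.0, 800.0))
    cal = simulate_market(60, 143.0, 0.10, cfg)
    model = calibrate_from_counts(cal.counts, SAFFRON)
    new_cfg = SimulationConfig(seed=100, dna_ng_range=(8.0, 800.0))
    new = simulate_market(400, 143.0, 0.10, new_cfg)
    interval_pass = np.mean(
        [r.purity == 1.0 for r in screen_samples(new.counts, model, SAFFRON)]
    )
    ratios = [r for _, _, r in ratio_screen_samples(new.counts, population_rule(1, 1))]
    rule = population_rule(float(np.mean(ratios)), float(np.std(ratios, ddof=1)))
    ratio_pass = np.mean([rule.low <= r <= rule.high for r in ratios])
    assert abs(interval_pass - 0.95) < 0.04
    assert abs(ratio_pass - 0.95) < 0.04
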