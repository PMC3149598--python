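"""Minimum detectable difference and maximum achievable power at fixed k."""
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from crctdesign import (
    EffectSpec,
    NoFeasibleMddError,
    TestParams,
    ceil_2dp,
    design_limits,
    max_achievable_power,
    mdd_binary,
    mdd_continuous,
)


@pytest.mark.parametrize("x, expected", [
    (0.1160, 0.12),
    (0.1341, 0.14),   # plain rounding would give 0.13
    (0.12, 0.12),     # exact values stay put
])
def test_ceil_2dp_is_conservative(x, expected):
    assert ceil_2dp(x) == pytest.approx(expected, abs=1e-12)


class TestMddContinuous:
    def test_zero_icc_means_no_floor(self, t80):
        assert mdd_continuous(1.0, t80, k=10, rho=0.0) == 0.0

    def test_hand_value(self, t80):
        d = mdd_continuous(1.0, t80, k=10, rho=0.02)
        assert d == pytest.approx(t80.z_total * math.sqrt(0.004), rel=1e-12)
        assert d == pytest.approx(0.1772, abs=5e-5)

    def test_quadrupling_k_halves_the_mdd(self, t80):
        d1 = mdd_continuous(1.0, t80, k=10, rho=0.05)
        d4 = mdd_continuous(1.0, t80, k=40, rho=0.05)
        assert d4 == pytest.approx(d1 / 2, rel=1e-12)


class TestMddBinary:
    @pytest.mark.parametrize("power, rounded, upper", [
        (0.80, 0.12, 0.5160),
        (0.90, 0.14, 0.5341),
    ])
    def test_worked_example_values(self, power, rounded, upper):
        test = TestParams(alpha=0.05, power=power)
        res = mdd_binary(0.4, test, k=20, rho=0.07)
        assert res.d_mdd_rounded == pytest.approx(rounded, abs=1e-12)
        assert res.pi2_upper == pytest.approx(upper, abs=5e-5)

    def test_lower_root_brackets_baseline(self, t80):
        res = mdd_binary(0.4, t80, k=20, rho=0.07)
        assert res.pi2_lower == pytest.approx(0.2894, abs=5e-5)
        assert res.pi2_lower < 0.4 < res.pi2_upper

    def test_roots_satisfy_defining_relation(self, t80):
        """Oracle: each root must satisfy d^2 = w (pi1(1-pi1)+pi2(1-pi2))."""
        res = mdd_binary(0.4, t80, k=20, rho=0.07)
        for root in (res.pi2_lower, res.pi2_upper):
            d = root - 0.4
            resid = d * d - res.w * (0.4 * 0.6 + root * (1 - root))
            assert abs(resid) < 1e-10

    def test_zero_icc_collapses_roots_on_baseline(self, t80):
        res = mdd_binary(0.4, t80, k=20, rho=0.0)
        assert res.pi2_lower == pytest.approx(0.4, abs=1e-7)
        assert res.pi2_upper == pytest.approx(0.4, abs=1e-7)
        assert res.d_mdd == pytest.approx(0.0, abs=1e-7)

    def test_no_detectable_increase_raises_with_diagnostics(self, t80):
        # baseline 0.9 with a huge w pushes the upper root past 1
        with pytest.raises(NoFeasibleMddError) as exc:
            mdd_binary(0.9, TestParams(0.05, 0.9), k=3, rho=0.4)
        assert exc.value.w > 0

    def test_small_baseline_large_w_still_returns_increase(self, t80):
        # here no *decrease* is detectable (lower root < 0), but the
        # detectable increase is perfectly valid
        res = mdd_binary(0.05, t80, k=10, rho=0.1)
        assert res.pi2_lower < 0.05 < res.pi2_upper < 1.0


class TestMaxAchievablePower:
    def test_null_effect_gives_alpha_half(self):
        null = EffectSpec(kind="continuous", d=0.0, sigma_sq=1.0)
        assert max_achievable_power(null, 0.05, 20, 0.05) == pytest.approx(
            0.025, abs=1e-12)

    def test_zero_icc_gives_full_power(self, breastfeeding):
        assert max_achievable_power(breastfeeding, 0.05, 20, 0.0) == 1.0

    def test_discussion_scenario_value(self, breastfeeding):
        # 15 clusters, ICC 0.05, 40% vs 50%
        assert max_achievable_power(breastfeeding, 0.05, 15, 0.05) == \
            pytest.approx(0.6965, abs=5e-5)

    def test_monotone_in_k_effect_and_icc(self, breastfeeding):
        base = max_achievable_power(breastfeeding, 0.05, 15, 0.05)
        assert max_achievable_power(breastfeeding, 0.05, 30, 0.05) > base
        assert max_achievable_power(breastfeeding, 0.05, 15, 0.02) > base
        bigger = EffectSpec.binary(0.4, 0.55)
        assert max_achievable_power(bigger, 0.05, 15, 0.05) > base


@settings(deadline=None, derandomize=True, max_examples=80)
@given(
    p=st.floats(0.05, 0.99),
    k=st.integers(2, 200),
    rho=st.floats(1e-4, 0.4),
    cv=st.floats(0.0, 1.2),
    sigma_sq=st.floats(0.01, 5.0),
)
def test_continuous_map_mdd_duality(p, k, rho, cv, sigma_sq):
    """MAP evaluated at the MDD for power p returns exactly p."""
    test = TestParams(alpha=0.05, power=p)
    d = mdd_continuous(sigma_sq, test, k, rho, cv)
    effect = EffectSpec.continuous(d, sigma_sq=sigma_sq)
    assert max_achievable_power(effect, 0.05, k, rho, cv) == pytest.approx(
        p, abs=1e-10)


@settings(deadline=None, derandomize=True, max_examples=60)
@given(
    p=st.floats(0.2, 0.99),
    pi1=st.floats(0.1, 0.6),
    k=st.integers(10, 150),
    rho=st.floats(1e-4, 0.1),
    cv=st.floats(0.0, 0.5),
)
def test_binary_map_mdd_duality_via_quadratic_root(p, pi1, k, rho, cv):
    """MAP at (pi1, pi2_upper) recovers the target power to 1e-8."""
    test = TestParams(alpha=0.05, power=p)
    res = mdd_binary(pi1, test, k, rho, cv)
    effect = EffectSpec.binary(pi1, res.pi2_upper)
    assert max_achievable_power(effect, 0.05, k, rho, cv) == pytest.approx(
        p, abs=1e-8)
    # residual oracle on both roots
    for root in (res.pi2_lower, res.pi2_upper):
        d = root - pi1
        resid = d * d - res.w * (pi1 * (1 - pi1) + root * (1 - root))
        assert abs(resid) < 1e-10


def test_design_limits_bundles_map_and_mdd(t80, breastfeeding):
    lim = design_limits(breastfeeding, t80, k=20, rho=0.07)
    assert lim.d_mdd_rounded == 0.12
    assert lim.map == pytest.approx(
        max_achievable_power(breastfeeding, 0.05, 20, 0.07), abs=1e-15)
    cont = design_limits(EffectSpec.continuous(0.2, sd=1.0), t80, k=10,
                         rho=0.02)
    assert cont.pi2_upper is None
    assert cont.d_mdd == pytest.approx(0.1772, abs=5e-5)
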