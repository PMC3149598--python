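"""Fixed-k sample size, rounding conventions and the feasibility boundary."""
import math

import pytest
from hypothesis import given, settings, strategies as st

from crctdesign import (
    ClusterStructure,
    EffectSpec,
    InfeasibleDesignError,
    TestParams,
    crct_power,
    feasibility_check,
    required_clusters_fixed_m,
    required_sample_size_fixed_k,
    rct_sample_size,
)


class TestFeasibilityCheck:
    def test_low_icc_product_feasible(self, t80, breastfeeding):
        rep = feasibility_check(breastfeeding, t80, k=20, rho=0.005)
        assert rep.product == pytest.approx(1.925, abs=1e-12)
        assert rep.feasible
        assert rep.margin == pytest.approx(20 - 1.925, abs=1e-12)

    def test_high_icc_product_infeasible(self, t80, breastfeeding):
        rep = feasibility_check(breastfeeding, t80, k=20, rho=0.07)
        assert rep.product == pytest.approx(26.95, abs=1e-12)
        assert not rep.feasible
        assert not rep.feasible_if_equal  # already infeasible at cv=0

    def test_zero_icc_always_feasible(self, t80, breastfeeding):
        rep = feasibility_check(breastfeeding, t80, k=1, rho=0.0)
        assert rep.product == 0.0
        assert rep.feasible

    def test_unequal_clusters_can_flip_verdict(self, t80, breastfeeding):
        # raw product 384.6 * 0.045 = 17.3 < 20, but *1.4225 = 24.6 > 20
        rep = feasibility_check(breastfeeding, t80, k=20, rho=0.045, cv=0.65)
        assert not rep.feasible
        assert rep.feasible_if_equal


class TestRequiredSampleSizeFixedK:
    @pytest.mark.parametrize("pi2, power, rho, m, n_C", [
        (0.50, 0.80, 0.005, 22, 440),
        (0.50, 0.90, 0.005, 30, 600),
        (0.52, 0.80, 0.07, 189, 3780),
        (0.54, 0.90, 0.07, 146, 2920),
    ])
    def test_worked_example_cluster_sizes(self, pi2, power, rho, m, n_C):
        effect = EffectSpec.binary(0.4, pi2)
        test = TestParams(alpha=0.05, power=power)
        res = required_sample_size_fixed_k(effect, test, k=20, rho=rho)
        assert res.m == m
        assert res.n_C == n_C
        assert res.total == 2 * n_C

    def test_rho_zero_is_pure_rounding(self, t80, breastfeeding):
        res = required_sample_size_fixed_k(breastfeeding, t80, k=20, rho=0.0)
        n_raw = rct_sample_size(breastfeeding, t80).n_raw
        assert res.m == math.ceil(n_raw / 20)
        assert res.n_C == 20 * res.m

    def test_result_invariants(self, t80, breastfeeding):
        res = required_sample_size_fixed_k(breastfeeding, t80, k=20, rho=0.005)
        assert res.n_C == 20 * res.m
        assert res.n_C >= res.n_C_raw
        assert res.n_C - res.n_C_raw < 20
        assert res.n_C >= res.n_I
        assert res.n_C >= res.n_I_raw * res.vif_at_solution - 1e-9

    def test_returned_design_meets_target_power(self, t80, breastfeeding):
        res = required_sample_size_fixed_k(breastfeeding, t80, k=20, rho=0.005)
        s = ClusterStructure(k=20, rho=0.005, m=res.m)
        assert crct_power(s, breastfeeding, 0.05) >= 0.8
        smaller = ClusterStructure(k=20, rho=0.005, m=res.m - 1)
        # m-1 either misses the power target or violates ceiling-to-k rounding
        assert (crct_power(smaller, breastfeeding, 0.05) < 0.8
                or 20 * (res.m - 1) >= res.n_C_raw)

    def test_infeasible_raises_with_report(self, t80, breastfeeding):
        with pytest.raises(InfeasibleDesignError) as exc:
            required_sample_size_fixed_k(breastfeeding, t80, k=20, rho=0.07)
        assert exc.value.report.product == pytest.approx(26.95, abs=1e-12)

    def test_inversion_with_fixed_m_solver(self, t80, breastfeeding):
        res = required_sample_size_fixed_k(breastfeeding, t80, k=20, rho=0.005)
        k_back = required_clusters_fixed_m(breastfeeding, t80, m=res.m,
                                           rho=0.005)
        assert k_back <= 20


class TestRequiredClustersFixedM:
    @pytest.mark.parametrize("m, rho, expected_k", [
        (22, 0.005, 20),
        (50, 0.07, 35),
    ])
    def test_hand_values(self, t80, breastfeeding, m, rho, expected_k):
        assert required_clusters_fixed_m(breastfeeding, t80, m=m,
                                         rho=rho) == expected_k

    def test_single_individual_clusters_recover_n_I(self, t80, breastfeeding):
        n_I = rct_sample_size(breastfeeding, t80).n
        assert required_clusters_fixed_m(breastfeeding, t80, m=1,
                                         rho=0.0) == n_I


class TestFeasibilityBoundary:
    def test_cluster_size_diverges_towards_boundary(self, t80):
        effect = EffectSpec.continuous(0.2, sd=1.0)
        n_raw = rct_sample_size(effect, t80).n_raw
        rho_star = 20 / n_raw  # the boundary ICC for k=20
        sizes = []
        for frac in (0.5, 0.9, 0.99, 0.999, 0.9999):
            res = required_sample_size_fixed_k(effect, t80, k=20,
                                               rho=rho_star * frac)
            sizes.append(res.m)
        assert sizes == sorted(sizes)
        assert sizes[-1] > 100 * sizes[0]

    def test_boundary_and_beyond_raise(self, t80):
        effect = EffectSpec.continuous(0.2, sd=1.0)
        n_raw = rct_sample_size(effect, t80).n_raw
        rho_star = 20 / n_raw
        for rho in (rho_star, rho_star * 1.01, rho_star * 2):
            with pytest.raises(InfeasibleDesignError):
                required_sample_size_fixed_k(effect, t80, k=20, rho=rho)


@settings(deadline=None, derandomize=True, max_examples=60)
@given(
    k=st.integers(2, 150),
    rho=st.floats(0.0, 0.15),
    cv=st.floats(0.0, 1.0),
    d=st.floats(0.1, 1.0),
    power=st.floats(0.5, 0.95),
)
def test_solver_invariants_across_random_designs(k, rho, cv, d, power):
    effect = EffectSpec.continuous(d, sd=1.0)
    test = TestParams(alpha=0.05, power=power)
    rep = feasibility_check(effect, test, k, rho, cv)
    if not rep.feasible:
        with pytest.raises(InfeasibleDesignError):
            required_sample_size_fixed_k(effect, test, k, rho, cv)
        return
    res = required_sample_size_fixed_k(effect, test, k, rho, cv)
    assert res.n_C == k * res.m
    assert 0 <= res.n_C - res.n_C_raw < k
    assert res.n_C >= res.n_I
    assert res.m >= 1
    # the fixed-m inverse never needs more than the k we started with
    assert required_clusters_fixed_m(effect, test, res.m, rho, cv) <= k
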