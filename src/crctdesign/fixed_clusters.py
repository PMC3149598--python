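"""Per-cluster sample size and feasibility when the number of clusters is fixed.

The standard cluster-trial formula fixes the cluster size m and solves
for the number of clusters k.  Here the roles are reversed: k is fixed
(the midwifery teams, practices or villages available) and the cluster
size is solved for.  Substituting m = n_C / k into
n_C = n_I * (1 + ((cv^2+1) m - 1) rho) and solving for n_C gives the
closed form

    n_C = n_I (1 - rho) / (1 - n_I rho (cv^2 + 1) / k),

with n_I the *unrounded* individual-randomisation per-arm size.  The
denominator vanishes as n_I rho (cv^2+1) approaches k: the required
cluster size diverges, and at or beyond that boundary no finite cluster
size achieves the target power.  Hence the feasibility check

    n_I * rho * (cv^2 + 1) < k   (strict).

Rounding conventions: the per-arm total n_C is rounded up to a multiple
of k (ceiling), so clusters are equal-sized integers; n_I enters the
closed form unrounded, while the feasibility *product* is displayed with
the integer n_I (the number a reader computes by hand), the boolean
using the unrounded value.  The two can disagree only within one unit of
the boundary.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

from .core import EffectSpec, TestParams, rct_sample_size
from .design_effect import vif

__all__ = [
    "FeasibilityReport",
    "SampleSizeResult",
    "InfeasibleDesignError",
    "feasibility_check",
    "required_sample_size_fixed_k",
    "required_clusters_fixed_m",
]


@dataclass(frozen=True)
class FeasibilityReport:
    """Outcome of the fixed-k feasibility check.

    ``product`` is n_I * rho * (cv^2+1) with the integer (rounded-up)
    n_I, matching what is quoted in design reports; ``product_raw`` uses
    the unrounded n_I and drives the ``feasible`` boolean, which is the
    exact condition for the fixed-k solver to admit a finite solution.
    """

    product: float
    product_raw: float
    k: int
    feasible: bool
    margin: float
    feasible_if_equal: bool

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        verdict = "feasible" if self.feasible else "NOT feasible"
        return (f"n_I*rho*(cv^2+1) = {self.product:g} vs k = {self.k}: "
                f"{verdict} (margin {self.margin:g})")


@dataclass(frozen=True)
class SampleSizeResult:
    """Per-arm sample size for a fixed number of clusters.

    Attributes
    ----------
    n_I_raw, n_I : float, int
        Unrounded and rounded-up individual-randomisation per-arm sizes.
    n_C_raw : float
        Unrounded fixed-k per-arm size from the closed form.
    n_C : int
        n_C_raw rounded up to a multiple of k.
    m : int
        Individuals per cluster, n_C / k (average when cv > 0).
    vif_at_solution : float
        Variance inflation factor evaluated at the returned m.
    total : int
        2 * n_C, both arms.
    """

    n_I_raw: float
    n_I: int
    vif_at_solution: float
    n_C_raw: float
    n_C: int
    m: int
    total: int


class InfeasibleDesignError(Exception):
    """No finite cluster size achieves the target power with k clusters.

    Carries the :class:`FeasibilityReport` as ``.report``.
    """

    def __init__(self, report: FeasibilityReport):
        self.report = report
        super().__init__(
            f"design infeasible: n_I*rho*(cv^2+1) = {report.product_raw:.4g} "
            f">= k = {report.k}; no finite cluster size attains the target "
            f"power (consider the minimum detectable difference / maximum "
            f"achievable power)"
        )


def feasibility_check(effect: EffectSpec, test: TestParams, k: int,
                      rho: float, cv: float = 0.0) -> FeasibilityReport:
    """Check whether k clusters per arm can ever reach the target power.

    Feasible iff n_I * rho * (cv^2 + 1) < k strictly (equality would
    require infinitely large clusters).  ``feasible_if_equal`` repeats
    the check at cv = 0, the rescue of equalising cluster sizes.
    """
    n_raw, n_int = rct_sample_size(effect, test)
    infl = cv * cv + 1.0
    product_raw = n_raw * rho * infl
    product = n_int * rho * infl
    return FeasibilityReport(
        product=product,
        product_raw=product_raw,
        k=k,
        feasible=product_raw < k,
        margin=k - product,
        feasible_if_equal=n_raw * rho < k,
    )


def required_sample_size_fixed_k(effect: EffectSpec, test: TestParams, k: int,
                                 rho: float, cv: float = 0.0) -> SampleSizeResult:
    """Per-arm sample size and cluster size for k fixed clusters per arm.

    Applies the closed form n_C = n_I(1-rho)/(1 - n_I rho (cv^2+1)/k)
    with the unrounded n_I, then rounds n_C up to a multiple of k.
    Raises :class:`InfeasibleDesignError` outside the feasible region.
    """
    report = feasibility_check(effect, test, k, rho, cv)
    if not report.feasible:
        raise InfeasibleDesignError(report)
    n_raw, n_int = rct_sample_size(effect, test)
    denom = 1.0 - n_raw * rho * (cv * cv + 1.0) / k
    n_c_raw = n_raw * (1.0 - rho) / denom
    n_c = k * math.ceil(n_c_raw / k)
    m = n_c // k
    return SampleSizeResult(
        n_I_raw=n_raw,
        n_I=n_int,
        vif_at_solution=vif(m, rho, cv),
        n_C_raw=n_c_raw,
        n_C=n_c,
        m=m,
        total=2 * n_c,
    )


def required_clusters_fixed_m(effect: EffectSpec, test: TestParams, m: int,
                              rho: float, cv: float = 0.0) -> int:
    """Clusters per arm required for fixed cluster size m: ceil(n_I VIF / m)."""
    n_raw, _ = rct_sample_size(effect, test)
    return math.ceil(n_raw * vif(m, rho, cv) / m)
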