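"""Minimum detectable difference and maximum achievable power for fixed k.

With k clusters per arm fixed, the variance of the estimated difference
cannot fall below the precision bound 2 sigma^2 rho (cv^2+1)/k however
large the clusters.  Two limiting quantities follow:

* the minimum detectable difference (MDD) at a given power,

      d_MDD = (z_{alpha/2} + z_beta) sqrt(2 sigma^2 rho (cv^2+1) / k),

* the maximum achievable power (MAP) for a given difference d,

      1 - beta_MAP = Phi( |d| / sqrt(2 sigma^2 rho (cv^2+1)/k) - z_{alpha/2} ).

They are duals: the MAP evaluated at d = d_MDD(power=p) equals p.

For binary outcomes the variance itself depends on the unknown limiting
proportion pi2, so the MDD is the root of a quadratic in pi2.  From the
defining relation d^2 = w (pi1(1-pi1) + pi2(1-pi2)) with
w = rho (cv^2+1) (z_{alpha/2}+z_beta)^2 / k and d = pi2 - pi1, the
quadratic a pi2^2 + b pi2 + c = 0 has

    a = -(1 + w),    b = 2 pi1 + w,    c = w pi1 - pi1^2 (1 + w),

and its two roots bracket pi1: the upper root is the smallest detectable
increase, the lower root the smallest detectable decrease.

Both bounds are suprema/infima: no finite cluster size attains them.
Quoted MDD proportions are conventionally rounded *up* at two decimal
places (conservative); raw and rounded values are both returned.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from .core import (
    DomainError,
    EffectSpec,
    TestParams,
    binary_pooled_variance,
    normal_cdf,
)
from .design_effect import precision_bound_variance

__all__ = [
    "LimitsResult",
    "NoFeasibleMddError",
    "ceil_2dp",
    "mdd_continuous",
    "mdd_binary",
    "max_achievable_power",
    "design_limits",
]


def ceil_2dp(x: float) -> float:
    """Round up at two decimal places (conservative MDD quoting)."""
    return math.ceil(x * 100.0 - 1e-9) / 100.0


class NoFeasibleMddError(DomainError):
    """The binary MDD quadratic has no valid root in (0, 1)."""

    def __init__(self, message: str, *, w: float, a: float, b: float,
                 c: float, discriminant: float):
        super().__init__(
            f"{message} (w={w:.6g}, a={a:.6g}, b={b:.6g}, c={c:.6g}, "
            f"discriminant={discriminant:.6g})"
        )
        self.w, self.a, self.b, self.c = w, a, b, c
        self.discriminant = discriminant


@dataclass(frozen=True)
class LimitsResult:
    """Limiting quantities of a fixed-k design.

    ``map`` is the maximum achievable power; for results produced by
    :func:`mdd_binary` it is evaluated at the upper root and therefore
    equals the target power by duality.  Quadratic coefficients
    (w, a, b, c) and both roots are exposed for binary outcomes.
    """

    bound_variance: float
    d_mdd: float
    d_mdd_rounded: float
    map: float
    pi2_lower: Optional[float] = None
    pi2_upper: Optional[float] = None
    w: Optional[float] = None
    a: Optional[float] = None
    b: Optional[float] = None
    c: Optional[float] = None


def mdd_continuous(sigma_sq: float, test: TestParams, k: int, rho: float,
                   cv: float = 0.0) -> float:
    """Minimum detectable difference for a continuous outcome.

    (z_{alpha/2}+z_beta) * sqrt(2 sigma^2 rho (cv^2+1) / k); zero when
    rho = 0 (precision is then unbounded).
    """
    bound = precision_bound_variance(sigma_sq, k, rho, cv)
    return test.z_total * math.sqrt(bound)


def mdd_binary(pi1: float, test: TestParams, k: int, rho: float,
               cv: float = 0.0) -> LimitsResult:
    """Minimum detectable difference for a binary outcome at baseline pi1.

    Solves the quadratic in pi2 described in the module docstring and
    reports the increase d_mdd = pi2_upper - pi1 together with both
    roots.  rho -> 0 collapses both roots onto pi1.
    """
    if not 0.0 < pi1 < 1.0:
        raise DomainError(f"pi1 must lie in (0, 1); got {pi1!r}")
    if not 0.0 <= rho < 1.0:
        raise DomainError(f"rho must lie in [0, 1); got {rho!r}")
    w = rho * (cv * cv + 1.0) * test.z_total ** 2 / k
    a = -(1.0 + w)
    b = 2.0 * pi1 + w
    c = w * pi1 - pi1 * pi1 * (1.0 + w)
    disc = b * b - 4.0 * a * c
    if -1e-12 < disc < 0.0:  # rho ~ 0: double root at pi1, up to rounding
        disc = 0.0
    if disc < 0.0:
        raise NoFeasibleMddError(
            "no real detectable proportion: negative discriminant",
            w=w, a=a, b=b, c=c, discriminant=disc)
    sqrt_disc = math.sqrt(disc)
    r1 = (-b + sqrt_disc) / (2.0 * a)
    r2 = (-b - sqrt_disc) / (2.0 * a)
    lower, upper = min(r1, r2), max(r1, r2)
    # the upper root is the detectable increase and must be a proportion;
    # a lower root <= 0 simply means no decrease is detectable at this w
    # and is reported as-is for diagnostics
    if not pi1 <= upper < 1.0:
        raise NoFeasibleMddError(
            "no detectable increase exists in (pi1, 1): the ICC is too "
            "large for this baseline and k",
            w=w, a=a, b=b, c=c, discriminant=disc)
    d = upper - pi1
    sigma_sq_at_root = binary_pooled_variance(pi1, upper) if upper != pi1 \
        else pi1 * (1.0 - pi1)
    return LimitsResult(
        bound_variance=precision_bound_variance(sigma_sq_at_root, k, rho, cv),
        d_mdd=d,
        d_mdd_rounded=ceil_2dp(d),
        map=test.power,  # by duality, the MAP at the root is the target power
        pi2_lower=lower,
        pi2_upper=upper,
        w=w, a=a, b=b, c=c,
    )


def max_achievable_power(effect: EffectSpec, alpha: float, k: int, rho: float,
                         cv: float = 0.0) -> float:
    """Maximum achievable power for difference d with k clusters per arm.

    Phi( |d| / sqrt(2 sigma^2 rho (cv^2+1)/k) - z_{alpha/2} ).  With
    rho = 0 power is unbounded: returns 1 for d != 0 and alpha/2 at d = 0.
    A supremum over cluster size, approached but never attained.
    """
    z_a = TestParams(alpha=alpha, power=0.5).z_alpha_half
    if rho == 0.0:
        return 1.0 if effect.d != 0.0 else normal_cdf(-z_a)
    bound = precision_bound_variance(effect.sigma_sq, k, rho, cv)
    return normal_cdf(abs(effect.d) / math.sqrt(bound) - z_a)


def design_limits(effect: EffectSpec, test: TestParams, k: int, rho: float,
                  cv: float = 0.0) -> LimitsResult:
    """MDD at the target power and MAP at the stated effect, together.

    For binary effects the MDD comes from the quadratic at the stated
    baseline pi1; the MAP is evaluated at the stated (pi1, pi2).
    """
    power = max_achievable_power(effect, test.alpha, k, rho, cv)
    if effect.kind == "binary":
        root = mdd_binary(effect.pi1, test, k, rho, cv)
        return LimitsResult(
            bound_variance=root.bound_variance,
            d_mdd=root.d_mdd,
            d_mdd_rounded=root.d_mdd_rounded,
            map=power,
            pi2_lower=root.pi2_lower,
            pi2_upper=root.pi2_upper,
            w=root.w, a=root.a, b=root.b, c=root.c,
        )
    d = mdd_continuous(effect.sigma_sq, test, k, rho, cv)
    return LimitsResult(
        bound_variance=precision_bound_variance(effect.sigma_sq, k, rho, cv),
        d_mdd=d,
        d_mdd_rounded=ceil_2dp(d),
        map=power,
    )
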