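"""Standard-normal machinery and individually randomised trial formulas.

Everything in this package is built on the classical two-arm,
equal-allocation, common-variance, two-sided normal-approximation
machinery: the detectable difference, the power, and the per-arm sample
size of an individually randomised trial.  Binary outcomes enter through
the pooled variance approximation
``sigma^2 = (pi1(1-pi1) + pi2(1-pi2)) / 2``.

Normal quantiles are carried at full double precision (z_{0.975} =
1.959964..., not 1.96); two-decimal z-values shift borderline sample
sizes by one or two individuals.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Optional

from scipy.stats import norm

__all__ = [
    "DomainError",
    "InfeasibleEffectError",
    "TestParams",
    "EffectSpec",
    "RctSampleSize",
    "z_quantile",
    "normal_cdf",
    "binary_pooled_variance",
    "rct_sample_size",
    "rct_detectable_difference",
    "rct_power",
]


class DomainError(ValueError):
    """An input lies outside the mathematical domain of a formula."""


class InfeasibleEffectError(DomainError):
    """A zero difference cannot be targeted by a sample-size formula."""


def z_quantile(p: float) -> float:
    """Inverse standard-normal CDF, Phi^{-1}(p), for p in (0, 1)."""
    if not 0.0 < p < 1.0:
        raise DomainError(f"quantile argument must lie in (0, 1); got {p!r}")
    return float(norm.ppf(p))


def normal_cdf(x: float) -> float:
    """Standard-normal CDF Phi(x)."""
    return float(norm.cdf(x))


@dataclass(frozen=True)
class TestParams:
    """Two-sided significance level and target power.

    Attributes
    ----------
    alpha : float
        Two-sided significance level, in (0, 1).
    power : float
        Target power 1 - beta, in (0, 1).
    """

    alpha: float = 0.05
    power: float = 0.80

    __test__ = False  # not a test case despite the name

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise DomainError(f"alpha must lie in (0, 1); got {self.alpha!r}")
        if not 0.0 < self.power < 1.0:
            raise DomainError(f"power must lie in (0, 1); got {self.power!r}")

    @property
    def z_alpha_half(self) -> float:
        """Upper 100*alpha/2 standard-normal centile, Phi^{-1}(1 - alpha/2)."""
        return z_quantile(1.0 - self.alpha / 2.0)

    @property
    def z_beta(self) -> float:
        """Upper 100*beta standard-normal centile, Phi^{-1}(power)."""
        return z_quantile(self.power)

    @property
    def z_total(self) -> float:
        """z_{alpha/2} + z_{beta}, the multiplier in every sample-size formula."""
        return self.z_alpha_half + self.z_beta


def binary_pooled_variance(pi1: float, pi2: float) -> float:
    """Pooled normal-approximation variance for a difference of proportions.

    Returns ``(pi1(1-pi1) + pi2(1-pi2)) / 2``.
    """
    for name, p in (("pi1", pi1), ("pi2", pi2)):
        if not 0.0 < p < 1.0:
            raise DomainError(f"{name} must lie in (0, 1); got {p!r}")
    return (pi1 * (1.0 - pi1) + pi2 * (1.0 - pi2)) / 2.0


@dataclass(frozen=True)
class EffectSpec:
    """The difference a trial is designed to detect.

    Either continuous (difference ``d`` on the outcome scale with outcome
    variance ``sigma_sq``) or binary (control and intervention proportions
    ``pi1``, ``pi2``; ``d = pi2 - pi1`` and ``sigma_sq`` is the pooled
    approximation).  Use the :meth:`continuous` / :meth:`binary`
    constructors rather than the raw dataclass fields.
    """

    kind: str
    d: float
    sigma_sq: float
    pi1: Optional[float] = None
    pi2: Optional[float] = None

    @classmethod
    def continuous(cls, d: float, sd: Optional[float] = None,
                   sigma_sq: Optional[float] = None) -> "EffectSpec":
        """Continuous effect: difference ``d`` with SD ``sd`` (or variance)."""
        if (sd is None) == (sigma_sq is None):
            raise DomainError("supply exactly one of sd or sigma_sq")
        var = float(sd) ** 2 if sd is not None else float(sigma_sq)
        if var <= 0.0:
            raise DomainError(f"outcome variance must be positive; got {var!r}")
        return cls(kind="continuous", d=float(d), sigma_sq=var)

    @classmethod
    def binary(cls, pi1: float, pi2: float) -> "EffectSpec":
        """Binary effect: control proportion ``pi1`` vs intervention ``pi2``."""
        var = binary_pooled_variance(pi1, pi2)
        return cls(kind="binary", d=float(pi2) - float(pi1), sigma_sq=var,
                   pi1=float(pi1), pi2=float(pi2))

    @property
    def standardised(self) -> float:
        """|d| / sigma, the standardised effect size."""
        return abs(self.d) / math.sqrt(self.sigma_sq)


class RctSampleSize(NamedTuple):
    """Per-arm sample size under individual randomisation."""

    n_raw: float  # unrounded solution of the sample-size equation
    n: int        # ceil(n_raw), the reported per-arm size


def rct_sample_size(effect: EffectSpec, test: TestParams) -> RctSampleSize:
    """Per-arm sample size for an individually randomised trial.

    n_raw = (z_{alpha/2} + z_beta)^2 * 2 sigma^2 / d^2; the integer size is
    ceil(n_raw).  The unrounded n_raw is returned as well because the
    fixed-cluster formulas consume it unrounded.
    """
    if effect.d == 0.0:
        raise InfeasibleEffectError("cannot size a trial for a zero difference")
    n_raw = test.z_total ** 2 * 2.0 * effect.sigma_sq / effect.d ** 2
    return RctSampleSize(n_raw=n_raw, n=math.ceil(n_raw))


def rct_detectable_difference(n: float, sigma_sq: float,
                              test: TestParams) -> float:
    """Detectable difference with n individuals per arm.

    d = (z_{alpha/2} + z_beta) * sqrt(2 sigma^2 / n).  ``n`` may be a
    non-integer (unrounded) size; it must be >= 1.
    """
    if n < 1:
        raise DomainError(f"per-arm sample size must be >= 1; got {n!r}")
    if sigma_sq <= 0:
        raise DomainError(f"variance must be positive; got {sigma_sq!r}")
    return test.z_total * math.sqrt(2.0 * sigma_sq / n)


def rct_power(n: float, effect: EffectSpec, alpha: float = 0.05) -> float:
    """Power of an individually randomised trial with n per arm.

    Phi( |d| sqrt(n / (2 sigma^2)) - z_{alpha/2} ).  The opposite-tail
    term is omitted, as is conventional; |d| makes arm labelling
    irrelevant.
    """
    if n < 1:
        raise DomainError(f"per-arm sample size must be >= 1; got {n!r}")
    z_a = TestParams(alpha=alpha, power=0.5).z_alpha_half
    return normal_cdf(abs(effect.d) * math.sqrt(n / (2.0 * effect.sigma_sq)) - z_a)
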