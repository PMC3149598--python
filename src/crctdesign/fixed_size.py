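"""Detectable difference and power for a fully fixed cluster design.

When both the number of clusters per arm (k) and the cluster size (m) are
fixed, the detectable difference is the individual-randomisation one
inflated by sqrt(VIF), and the power is the individual-randomisation
power at an effect size deflated by sqrt(VIF).
"""
from __future__ import annotations

import math

from .core import (
    DomainError,
    EffectSpec,
    TestParams,
    normal_cdf,
    rct_detectable_difference,
)
from .design_effect import ClusterStructure, vif

__all__ = ["crct_detectable_difference", "crct_power"]


def crct_detectable_difference(structure: ClusterStructure, sigma_sq: float,
                               test: TestParams) -> float:
    """Detectable difference d_C for fixed (k, m): d_I(n = k m) * sqrt(VIF)."""
    if structure.m is None:
        raise DomainError("cluster size m is required")
    n = structure.k * structure.m
    f = vif(structure.m, structure.rho, structure.cv)
    return rct_detectable_difference(n, sigma_sq, test) * math.sqrt(f)


def crct_power(structure: ClusterStructure, effect: EffectSpec,
               alpha: float = 0.05) -> float:
    """Power for fixed (k, m): Phi( |d| sqrt(k m / (2 sigma^2 VIF)) - z_{alpha/2} ).

    Uses |d| so arm labelling never flips the result; strictly below the
    maximum achievable power of the same (k, rho, cv) for every finite m
    when rho > 0.
    """
    if structure.m is None:
        raise DomainError("cluster size m is required")
    n = structure.k * structure.m
    f = vif(structure.m, structure.rho, structure.cv)
    z_a = TestParams(alpha=alpha, power=0.5).z_alpha_half
    return normal_cdf(
        abs(effect.d) * math.sqrt(n / (2.0 * effect.sigma_sq * f)) - z_a
    )
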