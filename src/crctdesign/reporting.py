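"""Reference tables and parameter grids.

``reproduce_table1`` recomputes the breastfeeding worked example (40%
baseline, 20 clusters per arm, ICC 0.005 or 0.07, 80% or 90% power)
cell by cell and flags each against its published value.
``compute_grid`` evaluates the limiting quantities (maximum achievable
power, minimum detectable difference) over grids of k, ICC and effect
size — the grids behind the usual "how many clusters do I need" figures.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import DomainError, EffectSpec, TestParams
from .fixed_clusters import required_sample_size_fixed_k
from .limits import max_achievable_power, mdd_binary, mdd_continuous

__all__ = ["reproduce_table1", "GridSpec", "compute_grid", "TABLE1_PRINTED"]

# Published reference values for the 40%-baseline worked example,
# k = 20 clusters per arm.  MDD quoted on the proportion scale,
# ceiling-rounded at 2 d.p.
TABLE1_PRINTED: dict[tuple[float, float, str], float] = {
    (0.005, 0.80, "n_I"): 385,
    (0.005, 0.80, "n_C"): 440,
    (0.005, 0.80, "m"): 22,
    (0.005, 0.90, "n_I"): 515,
    (0.005, 0.90, "n_C"): 600,
    (0.005, 0.90, "m"): 30,
    (0.07, 0.80, "mdd"): 0.12,
    (0.07, 0.80, "n_I"): 267,
    (0.07, 0.80, "n_C"): 3780,
    (0.07, 0.80, "m"): 189,
    (0.07, 0.90, "mdd"): 0.14,
    (0.07, 0.90, "n_I"): 262,
    (0.07, 0.90, "n_C"): 2920,
    (0.07, 0.90, "m"): 146,
}

_K_TABLE1 = 20
_PI1_TABLE1 = 0.40


def reproduce_table1(alpha: float = 0.05) -> pd.DataFrame:
    """Recompute every cell of the 40%-baseline reference table.

    For ICC 0.005 the 40% vs 50% design is feasible and the cells are
    the sample sizes (n_I, n_C, m).  For ICC 0.07 it is infeasible: the
    cells are the MDD (ceiling at 2 d.p.) and the sample sizes for the
    design re-targeted at baseline + MDD (40% vs 52% at 80% power,
    40% vs 54% at 90%).  Returns one row per cell with the computed and
    printed values and a match flag.
    """
    rows = []
    for power in (0.80, 0.90):
        test = TestParams(alpha=alpha, power=power)
        # feasible low-ICC design: 40% vs 50%
        res = required_sample_size_fixed_k(
            EffectSpec.binary(_PI1_TABLE1, 0.50), test, _K_TABLE1, 0.005)
        computed_low = {"n_I": res.n_I, "n_C": res.n_C, "m": res.m}
        for q, v in computed_low.items():
            rows.append((0.005, power, q, v))
        # infeasible high-ICC design: MDD, then size at baseline + MDD
        lim = mdd_binary(_PI1_TABLE1, test, _K_TABLE1, 0.07)
        rows.append((0.07, power, "mdd", lim.d_mdd_rounded))
        pi2 = _PI1_TABLE1 + lim.d_mdd_rounded
        res = required_sample_size_fixed_k(
            EffectSpec.binary(_PI1_TABLE1, pi2), test, _K_TABLE1, 0.07)
        for q, v in (("n_I", res.n_I), ("n_C", res.n_C), ("m", res.m)):
            rows.append((0.07, power, q, v))
    frame = pd.DataFrame(rows, columns=["icc", "power", "quantity", "computed"])
    frame["printed"] = [
        TABLE1_PRINTED[(icc, power, q)]
        for icc, power, q in zip(frame.icc, frame.power, frame.quantity)
    ]
    frame["match"] = np.isclose(frame.computed, frame.printed)
    return frame


_QUANTITIES = ("map_continuous", "map_binary", "mdd_continuous", "mdd_binary")


@dataclass(frozen=True)
class GridSpec:
    """A grid of fixed-k limiting quantities.

    ``effect_values`` are standardised effect sizes (sigma = 1) for the
    continuous quantities and baseline proportions pi1 for the binary
    ones; ``binary_increase`` is the increase whose achievable power is
    evaluated (map_binary only).  The defaults cover the ranges usually
    plotted: k in {10, 20, 30, 50, 100}, ICC 0 to 0.1 (step 0.005 — the
    step itself is a package choice), standardised effects 0.05-0.30 and
    baselines 0.05-0.5 with a 0.1 increase.
    """

    quantity: str
    k_values: Sequence[int] = (10, 20, 30, 50, 100)
    rho_values: Sequence[float] = field(
        default_factory=lambda: tuple(np.round(np.arange(0.0, 0.1005, 0.005), 4)))
    effect_values: Optional[Sequence[float]] = None
    binary_increase: float = 0.10

    def __post_init__(self) -> None:
        if self.quantity not in _QUANTITIES:
            raise DomainError(f"quantity must be one of {_QUANTITIES}; "
                              f"got {self.quantity!r}")
        if len(self.k_values) == 0 or len(self.rho_values) == 0:
            raise DomainError("grids must be non-empty")

    @property
    def effects(self) -> Sequence[float]:
        if self.effect_values is not None:
            return self.effect_values
        if self.quantity.endswith("continuous"):
            return tuple(np.round(np.arange(0.05, 0.305, 0.05), 4))
        return tuple(np.round(np.arange(0.05, 0.505, 0.05), 4))


def compute_grid(spec: GridSpec, test: TestParams) -> pd.DataFrame:
    """One row per (quantity, k, rho, effect) with the computed value.

    Deterministic; "effect" holds the standardised effect size
    (continuous) or the baseline proportion pi1 (binary).  For the MDD
    quantities the effect column is only meaningful for binary outcomes
    (the continuous MDD does not depend on the target difference); the
    continuous MDD grid therefore spans (k, rho) with effect = NaN.
    """
    rows = []
    q = spec.quantity
    for k in spec.k_values:
        for rho in spec.rho_values:
            if q == "mdd_continuous":
                value = mdd_continuous(1.0, test, k, float(rho))
                rows.append((q, k, float(rho), np.nan, value))
                continue
            for eff in spec.effects:
                if q == "map_continuous":
                    e = EffectSpec.continuous(float(eff), sigma_sq=1.0)
                    value = max_achievable_power(e, test.alpha, k, float(rho))
                elif q == "map_binary":
                    e = EffectSpec.binary(float(eff),
                                          float(eff) + spec.binary_increase)
                    value = max_achievable_power(e, test.alpha, k, float(rho))
                else:  # mdd_binary
                    if rho == 0.0:
                        value = 0.0
                    else:
                        value = mdd_binary(float(eff), test, k, float(rho)).d_mdd
                rows.append((q, k, float(rho), float(eff), value))
    return pd.DataFrame(rows, columns=["quantity", "k", "rho", "effect",
                                       "value"])
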