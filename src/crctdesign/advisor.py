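"""Structured design advice for a fixed-k cluster trial.

Wraps the whole workflow a trialist walks through when the number of
clusters is fixed:

(a) baseline individual-randomisation size n_I;
(b) feasibility check at the stated cluster-size cv;
(c) if infeasible and cv > 0, re-check with equal clusters (cv = 0);
(d) if still infeasible, report the maximum achievable power and the
    minimum detectable difference, each as a concrete remediation
    suggestion;
(e) if feasible, the required individuals per cluster.

Designs with fewer than 5 clusters per arm get a warning: regulatory
guidance (UK Medical Research Council) regards such trials as
inadvisable, and the normal approximations underlying every formula here
degrade badly at that size.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Any, Optional

from .core import EffectSpec, TestParams, rct_sample_size
from .fixed_clusters import (
    FeasibilityReport,
    InfeasibleDesignError,
    SampleSizeResult,
    feasibility_check,
    required_sample_size_fixed_k,
)
from .limits import LimitsResult, design_limits

__all__ = ["Suggestion", "DesignReport", "advise"]

SMALL_K_WARNING = (
    "fewer than 5 clusters per arm: regulatory guidance regards such "
    "trials as inadvisable, and the normal approximations used here are "
    "unreliable at this size"
)


@dataclass(frozen=True)
class Suggestion:
    """One remediation option for an infeasible design.

    ``attainable`` is False when the value is a supremum (e.g. the MAP
    itself, never reached at finite cluster size); when True, the
    suggestion was verified to yield a feasible design, whose per-cluster
    size is in ``details``.
    """

    kind: str
    description: str
    value: float
    attainable: bool
    details: dict = field(default_factory=dict)


@dataclass(frozen=True)
class DesignReport:
    """Full advisory report; exactly one of feasible_design / limits is set."""

    effect: EffectSpec
    test: TestParams
    k: int
    rho: float
    cv: float
    n_I: int
    feasibility: FeasibilityReport
    feasible_design: Optional[SampleSizeResult]
    limits: Optional[LimitsResult]
    suggestions: tuple[Suggestion, ...]
    warnings: tuple[str, ...]

    def to_dict(self) -> dict[str, Any]:
        eff: dict[str, Any] = {"kind": self.effect.kind, "d": self.effect.d,
                               "sigma_sq": self.effect.sigma_sq}
        if self.effect.kind == "binary":
            eff.update(pi1=self.effect.pi1, pi2=self.effect.pi2)
        out: dict[str, Any] = {
            "effect": eff,
            "alpha": self.test.alpha,
            "power": self.test.power,
            "k": self.k,
            "rho": self.rho,
            "cv": self.cv,
            "n_I": self.n_I,
            "feasibility": {
                "product": self.feasibility.product,
                "product_raw": self.feasibility.product_raw,
                "k": self.feasibility.k,
                "feasible": self.feasibility.feasible,
                "margin": self.feasibility.margin,
                "feasible_if_equal": self.feasibility.feasible_if_equal,
            },
            "warnings": list(self.warnings),
            "suggestions": [
                {"kind": s.kind, "description": s.description,
                 "value": s.value, "attainable": s.attainable,
                 "details": s.details}
                for s in self.suggestions
            ],
        }
        if self.feasible_design is not None:
            d = self.feasible_design
            out["feasible_design"] = {
                "n_I_raw": d.n_I_raw, "n_I": d.n_I, "n_C_raw": d.n_C_raw,
                "n_C": d.n_C, "m": d.m, "total": d.total,
                "vif_at_solution": d.vif_at_solution,
            }
        if self.limits is not None:
            lim = self.limits
            out["limits"] = {
                "bound_variance": lim.bound_variance, "d_mdd": lim.d_mdd,
                "d_mdd_rounded": lim.d_mdd_rounded, "map": lim.map,
                "pi2_lower": lim.pi2_lower, "pi2_upper": lim.pi2_upper,
            }
        return out

    def to_json(self, **kwargs: Any) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def to_text(self) -> str:
        lines = []
        if self.effect.kind == "binary":
            lines.append(f"Design: detect {self.effect.pi1:.0%} vs "
                         f"{self.effect.pi2:.0%}, alpha={self.test.alpha:g} "
                         f"(two-sided), power={self.test.power:.0%}")
        else:
            lines.append(f"Design: detect d={self.effect.d:g} "
                         f"(sigma^2={self.effect.sigma_sq:g}), "
                         f"alpha={self.test.alpha:g}, "
                         f"power={self.test.power:.0%}")
        lines.append(f"Clusters per arm k={self.k}, ICC rho={self.rho:g}, "
                     f"cluster-size cv={self.cv:g}")
        lines.append(f"(a) individual randomisation: n_I = {self.n_I} per arm")
        fr = self.feasibility
        lines.append(f"(b) feasibility: n_I*rho*(cv^2+1) = {fr.product:g} "
                     f"{'<' if fr.feasible else '>='} k = {fr.k} -> "
                     f"{'feasible' if fr.feasible else 'NOT feasible'}")
        if not fr.feasible and self.cv > 0:
            lines.append(f"(c) with equal clusters (cv=0): "
                         f"{'feasible' if fr.feasible_if_equal else 'still infeasible'}")
        if self.feasible_design is not None:
            d = self.feasible_design
            lines.append(f"(e) required size: m = {d.m} per cluster, "
                         f"n_C = {d.n_C} per arm, {d.total} in total")
        if self.limits is not None:
            lim = self.limits
            lines.append(f"(d-i) maximum achievable power: {lim.map:.1%} "
                         f"(supremum as cluster size -> infinity)")
            lines.append(f"(d-ii) minimum detectable difference: "
                         f"{lim.d_mdd_rounded:.2f} (raw {lim.d_mdd:.4f})")
        for s in self.suggestions:
            lines.append(f"suggestion [{s.kind}]: {s.description}")
        for w in self.warnings:
            lines.append(f"WARNING: {w}")
        return "\n".join(lines)


def _next_step_above(x: float, granularity: float) -> float:
    """Smallest multiple of granularity strictly greater than x."""
    n = math.floor(x / granularity + 1e-9) + 1
    return n * granularity


def advise(effect: EffectSpec, test: TestParams, k: int, rho: float,
           cv: float = 0.0, power_margin: float = 0.0,
           difference_granularity: Optional[float] = None) -> DesignReport:
    """Run the full fixed-k design workflow and return a structured report.

    Infeasibility is an outcome, not an error.  For infeasible designs
    two suggestions are always produced: lower the power (to the MAP
    minus ``power_margin``; with the default margin 0 the value is the
    MAP itself, flagged as unattainable), and raise the target
    difference to the smallest multiple of ``difference_granularity``
    (default one percentage point for binary, 0.01 standardised units
    for continuous) strictly above the MDD that admits a finite design.
    Every suggestion flagged attainable is verified by actually solving
    the suggested design.
    """
    n_I = rct_sample_size(effect, test).n
    report = feasibility_check(effect, test, k, rho, cv)
    warnings: list[str] = []
    if k < 5:
        warnings.append(SMALL_K_WARNING)

    suggestions: list[Suggestion] = []
    feasible_design: Optional[SampleSizeResult] = None
    limits: Optional[LimitsResult] = None

    if report.feasible:
        feasible_design = required_sample_size_fixed_k(effect, test, k, rho, cv)
    else:
        limits = design_limits(effect, test, k, rho, cv)
        if cv > 0 and report.feasible_if_equal:
            equal_design = required_sample_size_fixed_k(effect, test, k, rho, 0.0)
            suggestions.append(Suggestion(
                kind="equalise_clusters",
                description=(f"equal cluster sizes (cv=0) rescue the design: "
                             f"m = {equal_design.m} per cluster"),
                value=float(equal_design.m),
                attainable=True,
                details={"m": equal_design.m, "n_C": equal_design.n_C},
            ))
        # (d-i) lower the power
        target_power = limits.map - power_margin
        if power_margin > 0 and 0.0 < target_power < 1.0:
            reduced = TestParams(alpha=test.alpha, power=target_power)
            design = required_sample_size_fixed_k(effect, reduced, k, rho, cv)
            suggestions.append(Suggestion(
                kind="reduce_power",
                description=(f"lower the power to {target_power:.1%} "
                             f"(MAP {limits.map:.1%} minus margin): "
                             f"m = {design.m} per cluster"),
                value=target_power,
                attainable=True,
                details={"m": design.m, "n_C": design.n_C},
            ))
        else:
            suggestions.append(Suggestion(
                kind="reduce_power",
                description=(f"power is bounded by the MAP {limits.map:.1%}, "
                             f"a supremum never attained at finite cluster "
                             f"size; choose a target strictly below it"),
                value=limits.map,
                attainable=False,
            ))
        # (d-ii) raise the difference
        gran = difference_granularity or 0.01
        if effect.kind == "binary":
            pi2 = _next_step_above(limits.pi2_upper, gran)
            while pi2 < 1.0:
                cand = EffectSpec.binary(effect.pi1, pi2)
                if feasibility_check(cand, test, k, rho, cv).feasible:
                    break
                pi2 = _next_step_above(pi2, gran)
            if pi2 < 1.0:
                cand = EffectSpec.binary(effect.pi1, pi2)
                design = required_sample_size_fixed_k(cand, test, k, rho, cv)
                suggestions.append(Suggestion(
                    kind="raise_difference",
                    description=(f"raise the target to {effect.pi1:.0%} vs "
                                 f"{pi2:.0%} (MDD {limits.d_mdd_rounded:.2f}):"
                                 f" m = {design.m} per cluster"),
                    value=pi2 - effect.pi1,
                    attainable=True,
                    details={"pi2": pi2, "m": design.m, "n_C": design.n_C},
                ))
        else:
            d = _next_step_above(limits.d_mdd, gran)
            cand = EffectSpec.continuous(d, sigma_sq=effect.sigma_sq)
            while not feasibility_check(cand, test, k, rho, cv).feasible:
                d = _next_step_above(d, gran)
                cand = EffectSpec.continuous(d, sigma_sq=effect.sigma_sq)
            design = required_sample_size_fixed_k(cand, test, k, rho, cv)
            suggestions.append(Suggestion(
                kind="raise_difference",
                description=(f"raise the target difference to {d:g} "
                             f"(MDD {limits.d_mdd:.4f}): m = {design.m} "
                             f"per cluster"),
                value=d,
                attainable=True,
                details={"d": d, "m": design.m, "n_C": design.n_C},
            ))

    return DesignReport(
        effect=effect, test=test, k=k, rho=rho, cv=cv, n_I=n_I,
        feasibility=report, feasible_design=feasible_design, limits=limits,
        suggestions=tuple(suggestions), warnings=tuple(warnings),
    )
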