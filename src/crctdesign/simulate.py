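"""Monte-Carlo validation of the analytic power formulas.

The closed-form power, MDD and MAP expressions all rest on normal
approximations.  This module makes those assumptions concrete: it
generates synthetic cluster-correlated trials whose intra-cluster
correlation is exactly the design rho, analyses each replicate with a
two-sample z-test on cluster means, and compares the empirical rejection
rate with the analytic power.

Data-generating models
----------------------
continuous
    Random-intercept model: each cluster draws a shared effect with
    variance rho*sigma^2, individuals add independent noise with
    variance (1-rho)*sigma^2, so the total variance is sigma^2 and the
    within-cluster correlation exactly rho.  The intervention arm mean
    is shifted by d.
binary
    Beta-binomial: cluster-level event probabilities are drawn from a
    beta distribution with mean pi and ICC rho on the proportion scale
    (shape parameters pi*(1-rho)/rho and (1-pi)*(1-rho)/rho), then each
    individual is a Bernoulli draw at the cluster's probability.

Reproducibility: a single master seed; replicate r uses the numpy
SeedSequence substream (seed, r), so results do not depend on execution
order.  The analysis model is deliberately the cluster-mean z-test —
the same normal-theory variance structure the analytic formulas assume —
not a mixed model.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import DomainError, EffectSpec, TestParams
from .design_effect import ClusterStructure
from .fixed_size import crct_power

__all__ = ["SimConfig", "SimResult", "simulate_trial", "empirical_power",
           "results_to_frame"]


@dataclass(frozen=True)
class SimConfig:
    """One Monte-Carlo scenario: a fixed (k, m, rho) design and an effect."""

    k: int
    m: int
    rho: float
    effect: EffectSpec
    alpha: float = 0.05
    n_sims: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        ClusterStructure(k=self.k, rho=self.rho, m=self.m)  # domain checks
        if self.n_sims < 1:
            raise DomainError(f"n_sims must be >= 1; got {self.n_sims!r}")
        if self.seed < 0:
            raise DomainError(f"seed must be non-negative; got {self.seed!r}")


@dataclass(frozen=True)
class SimResult:
    """Empirical vs analytic power for one scenario."""

    empirical_power: float
    mc_se: float
    analytic_power: float
    z_discrepancy: float
    n_sims: int


def _replicate_rng(seed: int, replicate_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, replicate_index)))


def _beta_params(pi: float, rho: float) -> tuple[float, float]:
    a = pi * (1.0 - rho) / rho
    b = (1.0 - pi) * (1.0 - rho) / rho
    if a <= 0.0 or b <= 0.0:
        raise DomainError(
            f"no beta distribution has mean {pi!r} and ICC {rho!r}")
    return a, b


def simulate_trial(config: SimConfig,
                   replicate_index: int) -> tuple[np.ndarray, np.ndarray]:
    """Generate one synthetic trial: (control, intervention) outcome arrays.

    Each array has shape (k, m): one row per cluster.  Deterministic
    given (config.seed, replicate_index).
    """
    rng = _replicate_rng(config.seed, replicate_index)
    k, m, rho = config.k, config.m, config.rho
    eff = config.effect
    if eff.kind == "continuous":
        sigma = math.sqrt(eff.sigma_sq)
        cluster_sd = math.sqrt(rho) * sigma
        indiv_sd = math.sqrt(1.0 - rho) * sigma
        means = np.array([0.0, eff.d])  # control, intervention
        cluster_fx = rng.normal(0.0, cluster_sd, size=(2, k))
        noise = rng.normal(0.0, indiv_sd, size=(2, k, m))
        data = means[:, None, None] + cluster_fx[:, :, None] + noise
    else:
        pis = np.array([eff.pi1, eff.pi2])
        if rho == 0.0:
            p = np.broadcast_to(pis[:, None], (2, k))
        else:
            p = np.empty((2, k))
            for arm, pi in enumerate(pis):
                a, b = _beta_params(pi, rho)
                p[arm] = rng.beta(a, b, size=k)
        data = rng.binomial(1, p[:, :, None], size=(2, k, m)).astype(float)
    return data[0], data[1]


def _reject(control: np.ndarray, treat: np.ndarray, z_crit: float) -> bool:
    """Two-sided z-test on cluster means, variance from their dispersion."""
    m0 = control.mean(axis=1)
    m1 = treat.mean(axis=1)
    k = m0.size
    se = math.sqrt((m0.var(ddof=1) + m1.var(ddof=1)) / k)
    if se == 0.0:
        return False
    return abs(m1.mean() - m0.mean()) / se > z_crit


def empirical_power(config: SimConfig) -> SimResult:
    """Rejection proportion over n_sims replicates vs the analytic power."""
    z_crit = TestParams(alpha=config.alpha, power=0.5).z_alpha_half
    rejections = sum(
        _reject(*simulate_trial(config, r), z_crit)
        for r in range(config.n_sims)
    )
    p_hat = rejections / config.n_sims
    mc_se = math.sqrt(p_hat * (1.0 - p_hat) / config.n_sims)
    structure = ClusterStructure(k=config.k, rho=config.rho, m=config.m)
    analytic = crct_power(structure, config.effect, config.alpha)
    z_disc = (p_hat - analytic) / mc_se if mc_se > 0 else math.inf
    return SimResult(empirical_power=p_hat, mc_se=mc_se,
                     analytic_power=analytic, z_discrepancy=z_disc,
                     n_sims=config.n_sims)


def results_to_frame(scenarios_and_results):
    """Tabulate (SimConfig, SimResult) pairs as a pandas DataFrame."""
    import pandas as pd

    rows = []
    for cfg, res in scenarios_and_results:
        row = {
            "k": cfg.k, "m": cfg.m, "rho": cfg.rho, "kind": cfg.effect.kind,
            "d": cfg.effect.d, "sigma_sq": cfg.effect.sigma_sq,
            "alpha": cfg.alpha, "n_sims": cfg.n_sims, "seed": cfg.seed,
            "empirical_power": res.empirical_power, "mc_se": res.mc_se,
            "analytic_power": res.analytic_power,
            "z_discrepancy": res.z_discrepancy,
        }
        if cfg.effect.kind == "binary":
            row["pi1"], row["pi2"] = cfg.effect.pi1, cfg.effect.pi2
        rows.append(row)
    return pd.DataFrame(rows)
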