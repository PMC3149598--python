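"""Variance inflation and the precision of a cluster-randomised estimate.

Randomising intact clusters inflates the variance of the treatment-effect
estimate by the design effect (variance inflation factor, VIF).  For
equal clusters of size m with intra-cluster correlation rho,

    VIF = 1 + (m - 1) rho,

and for unequal clusters with coefficient of variation cv of the cluster
sizes (m the average size),

    VIF = 1 + ((cv^2 + 1) m - 1) rho.

As m grows the variance of the estimated difference, 2 sigma^2 VIF / (k m),
does not shrink to zero: it approaches the precision bound
2 sigma^2 rho (cv^2 + 1) / k, obtained by letting m -> infinity in the
expressions above.  That bound is what limits designs with a fixed number
of clusters.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .core import DomainError

__all__ = [
    "ClusterStructure",
    "vif",
    "difference_variance",
    "precision_bound_variance",
    "cv_of_sizes",
]


@dataclass(frozen=True)
class ClusterStructure:
    """Clustering layout of one arm of a cluster-randomised trial.

    Attributes
    ----------
    k : int
        Clusters per arm.
    rho : float
        Intra-cluster correlation, in [0, 1).  Negative ICCs are rejected:
        the design-effect framework assumes variance inflation.
    cv : float
        Coefficient of variation of cluster sizes (SD/mean); 0 means
        equal clusters.
    m : int, optional
        Individuals per cluster (the average when cv > 0).  Optional
        because fixed-cluster designs solve for it.
    """

    k: int
    rho: float
    cv: float = 0.0
    m: Optional[int] = None

    def __post_init__(self) -> None:
        if self.k < 1:
            raise DomainError(f"k must be >= 1; got {self.k!r}")
        if not 0.0 <= self.rho < 1.0:
            raise DomainError(f"rho must lie in [0, 1); got {self.rho!r}")
        if self.cv < 0.0:
            raise DomainError(f"cv must be >= 0; got {self.cv!r}")
        if self.m is not None and self.m < 1:
            raise DomainError(f"m must be >= 1 when given; got {self.m!r}")


def vif(m: float, rho: float, cv: float = 0.0) -> float:
    """Variance inflation factor 1 + ((cv^2 + 1) m - 1) rho.

    With cv = 0 this is exactly the equal-cluster 1 + (m - 1) rho.
    """
    if m < 1:
        raise DomainError(f"cluster size must be >= 1; got {m!r}")
    if not 0.0 <= rho < 1.0:
        raise DomainError(f"rho must lie in [0, 1); got {rho!r}")
    if cv < 0.0:
        raise DomainError(f"cv must be >= 0; got {cv!r}")
    return 1.0 + ((cv * cv + 1.0) * m - 1.0) * rho


def difference_variance(sigma_sq: float, structure: ClusterStructure) -> float:
    """Variance of the estimated difference, 2 sigma^2 VIF / (k m)."""
    if structure.m is None:
        raise DomainError("cluster size m is required to evaluate the variance")
    f = vif(structure.m, structure.rho, structure.cv)
    return 2.0 * sigma_sq * f / (structure.k * structure.m)


def precision_bound_variance(sigma_sq: float, k: int, rho: float,
                             cv: float = 0.0) -> float:
    """Limiting variance 2 sigma^2 rho (cv^2 + 1) / k as m -> infinity.

    This is the infimum of :func:`difference_variance` over the cluster
    size: substitute the VIF into 2 sigma^2 VIF/(k m) and let m grow,
    leaving 2 sigma^2 rho (cv^2+1)/k.  No finite cluster size attains it
    when rho > 0.
    """
    if k < 1:
        raise DomainError(f"k must be >= 1; got {k!r}")
    if not 0.0 <= rho < 1.0:
        raise DomainError(f"rho must lie in [0, 1); got {rho!r}")
    if cv < 0.0:
        raise DomainError(f"cv must be >= 0; got {cv!r}")
    return 2.0 * sigma_sq * rho * (cv * cv + 1.0) / k


def cv_of_sizes(sizes: Sequence[float]) -> float:
    """Coefficient of variation (population SD / mean) of planned cluster sizes.

    Convenience for feeding a concrete list of cluster sizes into the
    cv-approximation formulas.  Uses the population SD (ddof=0) since the
    list is the full census of planned clusters.
    """
    arr = np.asarray(sizes, dtype=float)
    if arr.size == 0 or np.any(arr <= 0):
        raise DomainError("cluster sizes must be a non-empty positive sequence")
    mean = arr.mean()
    return float(arr.std(ddof=0) / mean)
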