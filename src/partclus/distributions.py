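"""Cluster-size distributions for partially clustered two-arm trials.

A partially clustered design mixes independent observations (clusters of
size 1) with pre-existing clusters of size up to ``K``.  Two equivalent
descriptions of the cluster-size mix are used throughout:

* ``gamma`` -- :math:`\\gamma_k`, the proportion of *observational units*
  that belong to a cluster of size ``k`` (:math:`\\gamma_k = k M_k / N`);
* ``delta`` -- :math:`\\delta_k`, the proportion of *clusters* that are of
  size ``k`` (:math:`\\delta_k = M_k / M`).

Both sum to one.  :func:`gamma_from_delta` and :func:`delta_from_gamma`
convert between them; :func:`clusters_from_observations` converts an
observation (recruitment) target into a cluster target.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .errors import InvalidDistributionError

__all__ = [
    "ClusterSizeDistribution",
    "gamma_from_delta",
    "delta_from_gamma",
    "clusters_from_observations",
]

#: Acceptable departure of a user-supplied proportion vector from sum 1.
_SUM_TOL = 1e-8


def _as_proportions(values: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise InvalidDistributionError(f"{name} must be a non-empty 1-d vector")
    if not np.all(np.isfinite(arr)):
        raise InvalidDistributionError(f"{name} contains non-finite entries")
    if np.any(arr < 0):
        raise InvalidDistributionError(f"{name} contains negative entries")
    total = arr.sum()
    if total <= 0:
        raise InvalidDistributionError(f"{name} sums to zero")
    if abs(total - 1.0) > _SUM_TOL:
        raise InvalidDistributionError(
            f"{name} must sum to 1 (got {total:.10g}); normalise the input first"
        )
    # Renormalise exactly so downstream identities hold to machine precision.
    return arr / total


def _trim_trailing_zeros(arr: np.ndarray) -> np.ndarray:
    nz = np.nonzero(arr)[0]
    if nz.size == 0:
        raise InvalidDistributionError("distribution has no positive entries")
    return arr[: nz[-1] + 1]


def gamma_from_delta(delta: Sequence[float]) -> np.ndarray:
    """Convert cluster-level proportions ``delta`` to unit-level ``gamma``.

    ``gamma_k = k * delta_k / sum_j(j * delta_j)``.
    """
    d = _as_proportions(delta, "delta")
    k = np.arange(1, d.size + 1, dtype=float)
    weighted = k * d
    return weighted / weighted.sum()


def delta_from_gamma(gamma: Sequence[float]) -> np.ndarray:
    """Convert unit-level proportions ``gamma`` to cluster-level ``delta``.

    ``delta_k = (gamma_k / k) / sum_j(gamma_j / j)``; inverse of
    :func:`gamma_from_delta`.
    """
    g = _as_proportions(gamma, "gamma")
    k = np.arange(1, g.size + 1, dtype=float)
    weighted = g / k
    return weighted / weighted.sum()


@dataclass(frozen=True)
class ClusterSizeDistribution:
    """The cluster-size mix of a partially clustered design.

    Stores both parameterisations (``gamma`` over observational units and
    ``delta`` over clusters) at full precision, plus optional realised
    cluster counts ``counts`` (:math:`M_k`).

    Construct through :meth:`from_gamma`, :meth:`from_delta` or
    :meth:`from_counts`.
    """

    gamma: np.ndarray
    delta: np.ndarray
    counts: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        g = _trim_trailing_zeros(_as_proportions(self.gamma, "gamma"))
        d = _as_proportions(self.delta, "delta")[: g.size]
        object.__setattr__(self, "gamma", g)
        object.__setattr__(self, "delta", d / d.sum())
        if not np.allclose(gamma_from_delta(self.delta), g, atol=1e-10):
            raise InvalidDistributionError("gamma and delta are inconsistent")
        if self.counts is not None:
            c = np.asarray(self.counts, dtype=int)
            if c.size != g.size or np.any(c < 0) or c.sum() == 0:
                raise InvalidDistributionError("counts incompatible with distribution")
            object.__setattr__(self, "counts", c)

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_gamma(cls, gamma: Sequence[float]) -> "ClusterSizeDistribution":
        g = _trim_trailing_zeros(_as_proportions(gamma, "gamma"))
        return cls(gamma=g, delta=delta_from_gamma(g))

    @classmethod
    def from_delta(cls, delta: Sequence[float]) -> "ClusterSizeDistribution":
        d = _trim_trailing_zeros(_as_proportions(delta, "delta"))
        return cls(gamma=gamma_from_delta(d), delta=d)

    @classmethod
    def from_counts(cls, counts: Sequence[int]) -> "ClusterSizeDistribution":
        """Build from realised numbers of clusters of each size ``M_k``."""
        c = np.asarray(counts, dtype=int)
        if c.ndim != 1 or c.size == 0 or np.any(c < 0) or c.sum() == 0:
            raise InvalidDistributionError("counts must be non-negative with a positive sum")
        c = _trim_trailing_zeros(c.astype(float)).astype(int)
        delta = c / c.sum()
        return cls(gamma=gamma_from_delta(delta), delta=delta, counts=c)

    @classmethod
    def from_mapping(cls, mapping: Mapping[int, float], kind: str = "gamma") -> "ClusterSizeDistribution":
        """Build from a ``{cluster_size: proportion}`` mapping (JSON/YAML style)."""
        sizes = sorted(int(k) for k in mapping)
        if sizes[0] < 1:
            raise InvalidDistributionError("cluster sizes must be >= 1")
        vec = np.zeros(sizes[-1])
        for k in sizes:
            vec[k - 1] = float(mapping[k])
        if kind == "gamma":
            return cls.from_gamma(vec)
        if kind == "delta":
            return cls.from_delta(vec)
        raise InvalidDistributionError(f"unknown kind {kind!r}")

    # -- properties -------------------------------------------------------

    @property
    def max_size(self) -> int:
        """Largest cluster size ``K`` with positive mass."""
        return int(self.gamma.size)

    @property
    def sizes(self) -> np.ndarray:
        return np.arange(1, self.max_size + 1)

    @property
    def n_clusters(self) -> Optional[int]:
        return None if self.counts is None else int(self.counts.sum())

    @property
    def n_units(self) -> Optional[int]:
        if self.counts is None:
            return None
        return int((self.sizes * self.counts).sum())

    @property
    def units_per_size(self) -> Optional[np.ndarray]:
        """Realised ``N_k = k * M_k`` when counts are present."""
        return None if self.counts is None else self.sizes * self.counts

    @property
    def clusters_per_unit(self) -> float:
        """``sum_k gamma_k / k``: expected clusters per observational unit."""
        return float((self.gamma / self.sizes).sum())

    def to_mapping(self, kind: str = "gamma") -> dict:
        vec = self.gamma if kind == "gamma" else self.delta
        return {int(k): float(v) for k, v in zip(self.sizes, vec)}


def clusters_from_observations(
    n_observations: int,
    dist: ClusterSizeDistribution,
    policy: str = "total-ceiling",
) -> int:
    """Number of clusters that must be recruited to yield ``n_observations``.

    The expected number of clusters per observational unit is
    ``sum_k gamma_k / k``, so the cluster target is the ceiling of
    ``N * sum_k gamma_k / k``.

    Policies
    --------
    ``total-ceiling``
        Apply the ceiling once to the supplied total (default).
    ``per-group-ceiling``
        Split ``n_observations`` 1:1, apply the ceiling per group and sum;
        never smaller than the default, and what a per-arm recruitment
        bookkeeping would produce.
    """
    if n_observations < 1:
        raise InvalidDistributionError("n_observations must be >= 1")
    rate = dist.clusters_per_unit
    if policy == "total-ceiling":
        return int(np.ceil(n_observations * rate - 1e-12))
    if policy == "per-group-ceiling":
        half = n_observations / 2.0
        return int(2 * np.ceil(half * rate - 1e-12))
    raise InvalidDistributionError(f"unknown rounding policy {policy!r}")
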