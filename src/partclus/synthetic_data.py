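"""Synthetic partially clustered trial data.

Builds designs (fixed or multinomial cluster counts), randomises
treatment at the cluster or individual level under strict or relaxed
balance, and simulates outcomes with exchangeable within-cluster
correlation:

* continuous: random-intercept model ``y = b0 + b1 x + alpha_i + eps_ij``
  with ``var(alpha) + var(eps) = total_var`` and ICC
  ``rho = var(alpha) / total_var``;
* binary: sequential conditional-linear construction giving each member
  its arm's marginal prevalence and pairwise correlation ``rho`` within
  the cluster (a single exchangeable ``rho``, including across arms in
  mixed clusters).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations
from typing import Optional, Sequence, Tuple

import numpy as np

from .design_effects import AllocationTable
from .distributions import ClusterSizeDistribution
from .errors import ConfigurationError, FeasibilityError
from .gee_engine import TrialDataset

__all__ = [
    "GenerationConfig",
    "build_design",
    "randomize",
    "gen_continuous",
    "gen_binary",
    "binary_correlation_bounds",
    "derive_seed",
]


def derive_seed(master_seed: int, label: str) -> int:
    """Stable per-scenario seed from a master seed and a text label."""
    import hashlib

    digest = hashlib.sha256(f"{master_seed}:{label}".encode()).digest()
    return int.from_bytes(digest[:8], "little") % (2**63)


@dataclass(frozen=True)
class GenerationConfig:
    """Everything needed to generate one synthetic trial dataset.

    Either ``counts`` (fixed numbers of clusters of sizes 1..K) or
    ``n_clusters`` together with ``delta`` (multinomial cluster sizes)
    must be supplied.
    """

    randomization: str
    outcome: str
    rho: float
    counts: Optional[Tuple[int, ...]] = None
    n_clusters: Optional[int] = None
    delta: Optional[Tuple[float, ...]] = None
    balance: str = "strict"
    beta0: float = 0.0
    beta1: float = 0.25
    total_var: float = 1.0
    pi_i: Optional[float] = None
    pi_c: Optional[float] = None

    def __post_init__(self) -> None:
        if self.randomization not in ("cluster", "individual"):
            raise ConfigurationError(f"unknown randomization {self.randomization!r}")
        if self.outcome not in ("continuous", "binary"):
            raise ConfigurationError(f"unknown outcome {self.outcome!r}")
        if self.balance not in ("strict", "relaxed"):
            raise ConfigurationError(f"unknown balance mode {self.balance!r}")
        if self.counts is None and (self.n_clusters is None or self.delta is None):
            raise ConfigurationError("supply counts, or n_clusters with delta")
        if self.counts is not None and sum(self.counts) == 0:
            raise ConfigurationError("counts must include at least one cluster")
        if self.n_clusters is not None and self.n_clusters < 1:
            raise ConfigurationError("n_clusters must be >= 1")
        if self.outcome == "continuous":
            if not 0.0 <= self.rho < 1.0:
                raise ConfigurationError("continuous generation needs 0 <= rho < 1")
            if self.total_var <= 0:
                raise ConfigurationError("total_var must be positive")
        else:
            if self.pi_i is None or self.pi_c is None:
                raise ConfigurationError("binary generation needs pi_i and pi_c")


def build_design(config: GenerationConfig, rng: Optional[np.random.Generator] = None) -> ClusterSizeDistribution:
    """Realise the cluster counts ``M_k`` for one dataset.

    Fixed mode returns exactly ``config.counts``; multinomial mode draws
    ``M_k ~ Multinomial(M, delta)`` so the total number of observations
    varies across replicates.
    """
    if config.counts is not None:
        return ClusterSizeDistribution.from_counts(np.asarray(config.counts, dtype=int))
    if rng is None:
        raise ConfigurationError("multinomial design mode needs an rng")
    counts = rng.multinomial(config.n_clusters, np.asarray(config.delta, dtype=float))
    if (np.arange(1, counts.size + 1) * counts).sum() == 0:
        raise ConfigurationError("drawn design has no observations")
    return ClusterSizeDistribution.from_counts(counts)


def _expand_sizes(counts: np.ndarray) -> np.ndarray:
    return np.repeat(np.arange(1, counts.size + 1), counts)


def randomize(
    design: ClusterSizeDistribution,
    method: str,
    balance: str = "strict",
    rng: Optional[np.random.Generator] = None,
) -> AllocationTable:
    """Randomise members of a realised design to the two arms.

    Cluster method assigns whole clusters; strict balance puts exactly
    half of the clusters of each size on each arm (each ``M_k`` must be
    even), relaxed balance puts half of all clusters on each arm without
    stratifying by size.  Individual method assigns members; strict
    balance splits the units of each size 1:1 (each ``N_k`` must be
    even), relaxed balance splits all units 1:1 overall.  The expected
    allocation-pattern proportions within clusters are never forced per
    dataset; they hold on average over replicates.
    """
    if design.counts is None:
        raise ConfigurationError("randomize needs a design with realised counts")
    if rng is None:
        rng = np.random.default_rng()
    counts = design.counts
    sizes = _expand_sizes(counts)
    m_total = sizes.size

    if method == "cluster":
        treat_cluster = np.zeros(m_total, dtype=bool)
        if balance == "strict":
            offset = 0
            for k, mk in zip(design.sizes, counts):
                if mk % 2:
                    raise ConfigurationError(
                        f"strict cluster balance needs an even number of size-{k} clusters (got {mk})"
                    )
                pick = rng.permutation(mk)[: mk // 2]
                treat_cluster[offset + pick] = True
                offset += mk
        else:
            if m_total % 2:
                raise ConfigurationError("relaxed cluster balance needs an even total number of clusters")
            treat_cluster[rng.permutation(m_total)[: m_total // 2]] = True
        t = np.where(treat_cluster, sizes, 0)
        return AllocationTable(n=sizes, t=t)

    if method != "individual":
        raise ConfigurationError(f"unknown randomization {method!r}")

    t = np.zeros(m_total, dtype=int)
    if balance == "strict":
        offset = 0
        for k, mk in zip(design.sizes, counts):
            nk = int(k) * int(mk)
            if nk == 0:
                continue
            if nk % 2:
                raise ConfigurationError(
                    f"strict individual balance needs an even number of size-{k} units (got {nk})"
                )
            member_cluster = np.repeat(np.arange(mk), k)
            chosen = rng.permutation(nk)[: nk // 2]
            t[offset : offset + mk] = np.bincount(member_cluster[chosen], minlength=mk)
            offset += mk
    else:
        n_total = int(sizes.sum())
        if n_total % 2:
            raise ConfigurationError("relaxed individual balance needs an even total number of units")
        member_cluster = np.repeat(np.arange(m_total), sizes)
        chosen = rng.permutation(n_total)[: n_total // 2]
        t = np.bincount(member_cluster[chosen], minlength=m_total)
    return AllocationTable(n=sizes, t=t)


# ---------------------------------------------------------------------------
# outcome generation


def _member_layout(alloc: AllocationTable):
    """Member-level arrays (cluster id, member id, arm) for an allocation.

    Within each cluster the first ``t_i`` members are on the intervention
    arm; member order within a cluster is exchangeable so this loses no
    generality.
    """
    sizes = alloc.n
    cluster_id = np.repeat(np.arange(sizes.size), sizes)
    member_id = np.concatenate([np.arange(1, k + 1) for k in sizes])
    pos = member_id - 1
    arm = (pos < np.repeat(alloc.t, sizes)).astype(float)
    return cluster_id, member_id, arm


def gen_continuous(
    alloc: AllocationTable,
    rho: float,
    beta0: float = 0.0,
    beta1: float = 0.25,
    total_var: float = 1.0,
    rng: Optional[np.random.Generator] = None,
) -> TrialDataset:
    """Random-intercept normal outcomes with marginal variance ``total_var``."""
    if not 0.0 <= rho < 1.0:
        raise ConfigurationError("continuous generation needs 0 <= rho < 1")
    if rng is None:
        rng = np.random.default_rng()
    cluster_id, member_id, arm = _member_layout(alloc)
    sd_alpha = np.sqrt(rho * total_var)
    sd_eps = np.sqrt((1.0 - rho) * total_var)
    alpha = rng.normal(0.0, sd_alpha, size=alloc.n_clusters)
    eps = rng.normal(0.0, sd_eps, size=cluster_id.size)
    y = beta0 + beta1 * arm + alpha[cluster_id] + eps
    return TrialDataset(cluster_id, member_id, arm, y, outcome="continuous")


def binary_correlation_bounds(p1: float, p2: float) -> Tuple[float, float]:
    """Attainable correlation range for a Bernoulli pair with means p1, p2."""
    q1, q2 = 1.0 - p1, 1.0 - p2
    hi = min(np.sqrt(p1 * q2 / (p2 * q1)), np.sqrt(p2 * q1 / (p1 * q2)))
    lo = max(-np.sqrt(p1 * p2 / (q1 * q2)), -np.sqrt(q1 * q2 / (p1 * p2)))
    return float(lo), float(hi)


@lru_cache(maxsize=None)
def _clf_ordering(k: int, t: int, pi_i: float, pi_c: float, rho: float):
    """Choose a within-cluster arm ordering for the sequential construction.

    The conditional-linear step ``j`` has mean
    ``m_j + c_j sqrt(v_j) sum_{i<j} (y_i - m_i)/sqrt(v_i)`` with
    ``c_j = rho / (1 + (j-2) rho)``.  Its extremes over binary histories
    are attained at all-zero / all-one histories (rho >= 0).  Orderings
    of the ``t`` intervention and ``k - t`` control members differ in
    whether those extremes stay inside [0, 1]; return the ordering with
    the smallest total violation (0 for a feasible one) together with its
    violation magnitude.
    """
    arms_base = (1,) * t + (0,) * (k - t)
    best = None
    for arms in sorted(set(permutations(arms_base))):
        means = np.where(np.array(arms) == 1, pi_i, pi_c)
        sd = np.sqrt(means * (1.0 - means))
        violation = 0.0
        for j in range(1, k):
            c_j = rho / (1.0 + (j - 1.0) * rho)
            up = means[j] + c_j * sd[j] * float(((1.0 - means[:j]) / sd[:j]).sum())
            lo = means[j] - c_j * sd[j] * float((means[:j] / sd[:j]).sum())
            violation += max(0.0, up - 1.0) + max(0.0, -lo)
        if best is None or violation < best[1] - 1e-15:
            best = (arms, violation)
        if best[1] == 0.0:
            break
    return best


def gen_binary(
    alloc: AllocationTable,
    pi_i: float,
    pi_c: float,
    rho: float,
    rng: Optional[np.random.Generator] = None,
) -> TrialDataset:
    """Exchangeable correlated Bernoulli outcomes with arm-specific means.

    Members are drawn sequentially within each cluster from the
    conditional-linear family, which preserves the marginal means and
    gives every within-cluster pair correlation ``rho`` whenever the
    conditional probabilities remain in [0, 1].  A ``rho`` beyond the
    pairwise attainable bound for any arm pattern present raises
    :class:`FeasibilityError`.  Rare conditional-probability excursions
    in mixed-arm clusters (possible for extreme ``rho``) are clamped and
    counted in ``dataset.diagnostics['clamped']``.
    """
    for name, p in (("pi_i", pi_i), ("pi_c", pi_c)):
        if not 0.0 < p < 1.0:
            raise ConfigurationError(f"{name} must lie strictly in (0, 1)")
    if not -1.0 < rho < 1.0:
        raise ConfigurationError("binary generation needs -1 < rho < 1")
    if rng is None:
        rng = np.random.default_rng()
    if rho < 0 and int(alloc.n.max()) > 2:
        raise ConfigurationError("negative rho is only supported for clusters of size <= 2")

    mixed = (alloc.t > 0) & (alloc.c > 0)
    if np.any(mixed) and rho != 0.0:
        lo, hi = binary_correlation_bounds(pi_i, pi_c)
        if rho > hi + 1e-12 or rho < lo - 1e-12:
            raise FeasibilityError(
                f"rho={rho} outside the attainable cross-arm range [{lo:.6f}, {hi:.6f}] "
                f"for prevalences ({pi_i}, {pi_c})"
            )

    cluster_id, member_id, arm = _member_layout(alloc)
    y = np.empty(cluster_id.size)
    clamped = 0

    # group clusters by (size, treated) pattern; within a pattern all
    # clusters share an ordering and the per-step coefficients.
    pattern_key = alloc.n * (alloc.n.max() + 1) + alloc.t
    order_by_pattern = {}
    starts = np.concatenate([[0], np.cumsum(alloc.n)[:-1]])
    for key in np.unique(pattern_key):
        k = int(key // (alloc.n.max() + 1))
        t = int(key % (alloc.n.max() + 1))
        arms, violation = _clf_ordering(k, t, pi_i, pi_c, rho if rho > 0 else 0.0)
        order_by_pattern[int(key)] = np.array(arms, dtype=float)

    for key, arms_order in order_by_pattern.items():
        idx = np.flatnonzero(pattern_key == key)
        k = arms_order.size
        means = np.where(arms_order == 1.0, pi_i, pi_c)
        sd = np.sqrt(means * (1.0 - means))
        n_cl = idx.size
        draws = rng.random((n_cl, k))
        ys = np.empty((n_cl, k))
        running = np.zeros(n_cl)  # sum of (y_i - m_i)/sd_i over previous members
        for j in range(k):
            if j == 0:
                cond = np.full(n_cl, means[0])
            else:
                c_j = rho / (1.0 + (j - 1.0) * rho)
                cond = means[j] + c_j * sd[j] * running
                low = cond < 0.0
                high = cond > 1.0
                clamped += int(low.sum() + high.sum())
                if low.any() or high.any():
                    cond = np.clip(cond, 0.0, 1.0)
            ys[:, j] = draws[:, j] < cond
            running += (ys[:, j] - means[j]) / sd[j]
        # write back: members of each cluster in this pattern's order
        positions = starts[idx][:, None] + np.arange(k)[None, :]
        y[positions.ravel()] = ys.ravel()
        arm[positions.ravel()] = np.tile(arms_order, n_cl)

    data = TrialDataset(cluster_id, member_id, arm, y, outcome="binary")
    data.diagnostics = {"clamped": clamped}
    return data
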