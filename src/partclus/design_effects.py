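"""Design effects for two-arm partially clustered trials analysed by GEE.

The design effect (DEFF) is the ratio of the variance of the estimated
treatment effect under a clustering-aware GEE analysis (robust sandwich
variance, independence or exchangeable working correlation) to the
variance assuming all observations are independent.

Three routes to a DEFF are provided:

* :func:`deff_closed_form` -- randomisation-specific closed forms that
  depend only on the ICC, the cluster-size mix ``gamma`` and (for binary
  outcomes under individual randomisation) the two arm prevalences;
* :func:`deff_general_independence` / :func:`deff_general_exchangeable`
  -- allocation-level formulas for a continuous outcome, taking the
  realised per-cluster treated/control split;
* :func:`deff_matrix_oracle` -- direct per-cluster matrix evaluation of
  the sandwich covariance at the true parameters.  This is the normative
  implementation: the closed forms and allocation-level formulas are
  validated against it.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Optional, Sequence

import numpy as np

from .distributions import ClusterSizeDistribution
from .errors import ConfigurationError, DegenerateDesignError

__all__ = [
    "DesignSpec",
    "AllocationTable",
    "h_term",
    "deff_closed_form",
    "deff_general_independence",
    "deff_general_exchangeable",
    "deff_matrix_oracle",
    "deff_expected_individual",
    "expected_allocation_weights",
]

_RANDOMIZATIONS = {"cluster", "individual"}
_WORKINGS = {"independence", "exchangeable"}
_OUTCOMES = {"continuous", "binary"}
_LINKS = {"identity", "logit", "log"}


@dataclass(frozen=True)
class DesignSpec:
    """Analysis/design specification for a DEFF computation.

    Parameters
    ----------
    randomization:
        ``"cluster"`` (whole clusters share an arm) or ``"individual"``
        (members randomised independently).
    working_correlation:
        GEE working structure, ``"independence"`` or ``"exchangeable"``.
    outcome:
        ``"continuous"`` (identity link) or ``"binary"`` (logit/log link).
    rho:
        Intracluster correlation coefficient of the true exchangeable
        correlation structure.
    pi_i, pi_c:
        Marginal outcome prevalences in the intervention and control arms
        (binary outcomes only), each in (0, 1).
    sigma2:
        Outcome variance for continuous outcomes (cancels in every DEFF).
    """

    randomization: str
    working_correlation: str
    outcome: str
    rho: float
    link: Optional[str] = None
    pi_i: Optional[float] = None
    pi_c: Optional[float] = None
    sigma2: float = 1.0

    def __post_init__(self) -> None:
        if self.randomization not in _RANDOMIZATIONS:
            raise ConfigurationError(f"unknown randomization {self.randomization!r}")
        if self.working_correlation not in _WORKINGS:
            raise ConfigurationError(f"unknown working correlation {self.working_correlation!r}")
        if self.outcome not in _OUTCOMES:
            raise ConfigurationError(f"unknown outcome {self.outcome!r}")
        link = self.link
        if link is None:
            link = "identity" if self.outcome == "continuous" else "logit"
            object.__setattr__(self, "link", link)
        if link not in _LINKS:
            raise ConfigurationError(f"unknown link {link!r}")
        if self.outcome == "continuous" and link != "identity":
            raise ConfigurationError("continuous outcomes use the identity link")
        if self.outcome == "binary":
            if link not in ("logit", "log"):
                raise ConfigurationError("binary outcomes use the logit or log link")
            if self.pi_i is None or self.pi_c is None:
                raise ConfigurationError("binary outcomes require pi_i and pi_c")
            for name, p in (("pi_i", self.pi_i), ("pi_c", self.pi_c)):
                if not 0.0 < p < 1.0:
                    raise ConfigurationError(f"{name} must lie strictly in (0, 1)")
        if self.sigma2 <= 0:
            raise ConfigurationError("sigma2 must be positive")


@dataclass(frozen=True)
class AllocationTable:
    """Per-cluster treated/control split ``(n_i, t_i, c_i)``.

    ``n`` holds cluster sizes, ``t`` the number of members on the
    intervention arm and ``c = n - t`` the number on control.
    """

    n: np.ndarray
    t: np.ndarray

    def __post_init__(self) -> None:
        n = np.asarray(self.n, dtype=int)
        t = np.asarray(self.t, dtype=int)
        if n.ndim != 1 or n.size == 0 or t.shape != n.shape:
            raise ConfigurationError("n and t must be matching non-empty 1-d vectors")
        if np.any(n < 1) or np.any(t < 0) or np.any(t > n):
            raise ConfigurationError("require 1 <= n_i and 0 <= t_i <= n_i")
        object.__setattr__(self, "n", n)
        object.__setattr__(self, "t", t)

    @property
    def c(self) -> np.ndarray:
        return self.n - self.t

    @property
    def n_clusters(self) -> int:
        return int(self.n.size)

    @property
    def n_units(self) -> int:
        return int(self.n.sum())

    @property
    def n_intervention(self) -> int:
        return int(self.t.sum())

    @property
    def n_control(self) -> int:
        return int(self.c.sum())

    def per_size_totals(self) -> dict:
        """``{k: (N_Ik, N_Ck)}`` treated/control unit totals by cluster size."""
        out: dict = {}
        for k in np.unique(self.n):
            mask = self.n == k
            out[int(k)] = (int(self.t[mask].sum()), int(self.c[mask].sum()))
        return out


def expected_allocation_weights(k: int) -> np.ndarray:
    """Probabilities of ``t = 0..k`` treated members in a size-``k`` cluster.

    Under 1:1 individual randomisation with exchangeable members the
    allocation pattern ``t`` occurs with probability ``C(k, t) / 2**k``.
    """
    if k < 1:
        raise ConfigurationError("cluster size must be >= 1")
    return np.array([comb(k, t) for t in range(k + 1)], dtype=float) / 2.0**k


def h_term(pi_i: float, pi_c: float, link: str = "logit") -> float:
    """Prevalence term entering binary individual-randomisation DEFFs.

    ``sqrt(pi_i pi_c (1-pi_i)(1-pi_c)) / (pi_i(1-pi_i) + pi_c(1-pi_c))``
    for the logit link; the log link replaces the denominator with
    ``pi_i(1-pi_c) + pi_c(1-pi_i)``.  Equals 1/2 iff ``pi_i == pi_c`` or
    ``pi_i == 1 - pi_c``, in which case the binary DEFFs coincide with the
    continuous ones.
    """
    for name, p in (("pi_i", pi_i), ("pi_c", pi_c)):
        if not 0.0 < p < 1.0:
            raise ConfigurationError(f"{name} must lie strictly in (0, 1)")
    num = np.sqrt(pi_i * pi_c * (1.0 - pi_i) * (1.0 - pi_c))
    if link == "logit":
        den = pi_i * (1.0 - pi_i) + pi_c * (1.0 - pi_c)
    elif link == "log":
        den = pi_i * (1.0 - pi_c) + pi_c * (1.0 - pi_i)
    else:
        raise ConfigurationError(f"h_term is defined for logit/log links, not {link!r}")
    return float(num / den)


def _check_rho_closed_form(rho: float, working: str) -> None:
    if not 0.0 <= rho < 1.0:
        if rho == 1.0 and working == "independence":
            return
        raise ConfigurationError(
            "closed-form DEFFs require 0 <= rho < 1 (exchangeable) or 0 <= rho <= 1"
        )


def deff_closed_form(spec: DesignSpec, dist: ClusterSizeDistribution) -> float:
    """Randomisation-specific closed-form DEFF.

    Implements the eight outcome x randomisation x working-correlation
    combinations.  Binary outcomes under cluster randomisation share the
    continuous forms; under individual randomisation they involve
    :func:`h_term`.
    """
    rho = spec.rho
    if spec.working_correlation == "exchangeable" and not 0.0 <= rho < 1.0:
        raise ConfigurationError("exchangeable closed forms require 0 <= rho < 1")
    if not 0.0 <= rho <= 1.0:
        raise ConfigurationError("closed forms assume 0 <= rho <= 1")
    g = dist.gamma
    k = dist.sizes.astype(float)
    denom = 1.0 + (k - 1.0) * rho

    if spec.randomization == "cluster":
        if spec.working_correlation == "independence":
            return float(1.0 + rho * ((k - 1.0) * g).sum())
        return float(1.0 / (g / denom).sum())

    # individual randomisation
    if spec.outcome == "continuous":
        if spec.working_correlation == "independence":
            return 1.0
        terms = g * (1.0 + (k - 2.0) * rho) / ((1.0 - rho) * denom)
        return float(1.0 / terms.sum())

    h = h_term(spec.pi_i, spec.pi_c, spec.link)
    if spec.working_correlation == "independence":
        return float(1.0 + rho * (0.5 - h) * ((k - 1.0) * g).sum())
    s1 = (g / denom).sum()
    s2 = ((k - 1.0) * g / denom).sum()
    r = rho / (1.0 - rho)
    return float((s1 + (0.5 - h) * r * s2) / (s1**2 + r * s1 * s2))


def deff_general_independence(alloc: AllocationTable, rho: float) -> float:
    """Allocation-level DEFF, independence working correlation, continuous outcome.

    ``1 + rho * ((sum n_i^2 - 4 sum t_i c_i) / N - 1)``.  Derived under
    overall treatment balance (``N_I = N_C``).
    """
    n = alloc.n.astype(float)
    t = alloc.t.astype(float)
    c = alloc.c.astype(float)
    big_n = n.sum()
    return float(1.0 + rho * (((n**2).sum() - 4.0 * (t * c).sum()) / big_n - 1.0))


def deff_general_exchangeable(alloc: AllocationTable, rho: float) -> float:
    """Allocation-level DEFF, exchangeable working correlation, continuous outcome.

    ``N A / (4 (A B - C^2))`` with

    * ``A = sum n_i / (1 + (n_i - 1) rho)``
    * ``B = sum t_i (1 + (c_i - 1) rho) / ((1 - rho)(1 + (n_i - 1) rho))``
    * ``C = sum t_i / (1 + (n_i - 1) rho)``

    (the grouping of the denominator and of ``B`` is fixed by requiring
    exact agreement with :func:`deff_matrix_oracle`).  Derived under
    overall treatment balance.
    """
    if not 0.0 <= rho < 1.0:
        raise ConfigurationError("exchangeable DEFF requires 0 <= rho < 1")
    n = alloc.n.astype(float)
    t = alloc.t.astype(float)
    c = alloc.c.astype(float)
    w = 1.0 + (n - 1.0) * rho
    big_n = n.sum()
    a = (n / w).sum()
    b = (t * (1.0 + (c - 1.0) * rho) / ((1.0 - rho) * w)).sum()
    cc = (t / w).sum()
    det = a * b - cc**2
    if det <= 0:
        raise DegenerateDesignError("allocation admits no treatment-effect information")
    return float(big_n * a / (4.0 * det))


# ---------------------------------------------------------------------------
# Matrix oracle: direct evaluation of the sandwich covariance


def _cluster_matrices(k: int, t: int, spec: DesignSpec):
    """Bread/meat/independence-information contributions of one cluster.

    Builds ``D_i`` (mean derivatives), ``A_i`` (marginal variances), the
    true exchangeable covariance of the responses and the working
    covariance at the true parameters, and returns

    ``(D'V^-1 D,  D'V^-1 cov(Y) V^-1 D,  D'A^-1 D)``.
    """
    x = np.zeros(k)
    x[:t] = 1.0
    ones = np.ones(k)
    design = np.column_stack([ones, x])
    if spec.outcome == "continuous":
        mu = None
        var = np.full(k, spec.sigma2)
        deriv = design
    else:
        mu = np.where(x == 1.0, spec.pi_i, spec.pi_c)
        var = mu * (1.0 - mu)
        weight = var if spec.link == "logit" else mu
        deriv = weight[:, None] * design
    rho = spec.rho
    corr = np.full((k, k), rho)
    np.fill_diagonal(corr, 1.0)
    sd = np.sqrt(var)
    cov_y = corr * np.outer(sd, sd)
    if spec.working_correlation == "exchangeable":
        v_work = cov_y
    else:
        v_work = np.diag(var)
    try:
        v_inv = np.linalg.inv(v_work)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded by rho checks
        raise DegenerateDesignError("working covariance is singular") from exc
    dtvi = deriv.T @ v_inv
    bread = dtvi @ deriv
    meat = dtvi @ cov_y @ dtvi.T
    info_ind = deriv.T @ np.diag(1.0 / var) @ deriv
    return bread, meat, info_ind


def _deff_from_sums(bread: np.ndarray, meat: np.ndarray, info_ind: np.ndarray) -> float:
    try:
        bread_inv = np.linalg.inv(bread)
        cov = bread_inv @ meat @ bread_inv
        var_ind = np.linalg.inv(info_ind)[1, 1]
    except np.linalg.LinAlgError as exc:
        raise DegenerateDesignError("allocation admits no treatment-effect information") from exc
    if var_ind <= 0:
        raise DegenerateDesignError("independence variance is not positive")
    return float(cov[1, 1] / var_ind)


def deff_matrix_oracle(alloc: AllocationTable, spec: DesignSpec) -> float:
    """DEFF from direct matrix evaluation of the sandwich covariance.

    Assembles the per-cluster estimating-function matrices at the true
    parameter values, forms the sandwich covariance of the GEE estimator
    and the model-based covariance of the independence ML estimator, and
    returns the ratio of the treatment-effect variances.

    Accepts any ``rho > -1/(K-1)`` keeping the true correlation positive
    definite; intended for small designs (exact algebra per cluster).
    """
    kmax = int(alloc.n.max())
    if kmax > 1 and spec.rho <= -1.0 / (kmax - 1.0):
        raise ConfigurationError("rho leaves the true correlation non-positive-definite")
    if spec.working_correlation == "exchangeable" and spec.rho >= 1.0:
        raise ConfigurationError("exchangeable working correlation requires rho < 1")
    bread = np.zeros((2, 2))
    meat = np.zeros((2, 2))
    info_ind = np.zeros((2, 2))
    pairs, counts = np.unique(np.column_stack([alloc.n, alloc.t]), axis=0, return_counts=True)
    for (k, t), m in zip(pairs, counts):
        b, mt, ii = _cluster_matrices(int(k), int(t), spec)
        bread += m * b
        meat += m * mt
        info_ind += m * ii
    return _deff_from_sums(bread, meat, info_ind)


def deff_expected_individual(spec: DesignSpec, dist: ClusterSizeDistribution) -> float:
    """Oracle DEFF under the expected-proportions allocation assumption.

    For individual randomisation the closed forms assume that, within
    clusters of size ``k``, the allocation patterns ``t = 0..k`` occur in
    proportions ``C(k, t)/2**k``.  This mixes the per-cluster matrix
    contributions of :func:`deff_matrix_oracle` with those weights (and
    cluster-level weights ``delta_k``), giving the exact expected-design
    DEFF that the closed forms summarise.
    """
    bread = np.zeros((2, 2))
    meat = np.zeros((2, 2))
    info_ind = np.zeros((2, 2))
    for k, dk in zip(dist.sizes, dist.delta):
        if dk == 0.0:
            continue
        weights = expected_allocation_weights(int(k))
        for t, w in enumerate(weights):
            b, mt, ii = _cluster_matrices(int(k), t, spec)
            bread += dk * w * b
            meat += dk * w * mt
            info_ind += dk * w * ii
    return _deff_from_sums(bread, meat, info_ind)
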