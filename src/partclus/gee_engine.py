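"""Marginal-model fitting for two-arm trial data with clustering.

Fits the unadjusted mean model ``g(mu_ij) = b0 + b1 x_ij`` by estimating
equations with an independence or exchangeable working correlation, and
computes the robust sandwich covariance

``B^-1 (sum_i D_i' V_i^-1 S_i S_i' V_i^-1 D_i) B^-1``,
``B = sum_i D_i' V_i^-1 D_i``, ``S_i = Y_i - mu_i``,

alongside the classical (model-based) covariance of the corresponding
independence maximum-likelihood fit.  The observed design effect is the
ratio of the two treatment-effect variances.

Implementation notes: with a single binary covariate the independence
estimating equations are solved in closed form by the per-arm means for
all three links, so iteration is only needed for the exchangeable
structure.  Per-cluster sums use ``np.add.reduceat`` over contiguous
cluster blocks, keeping fits fast enough for large simulation studies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .design_effects import AllocationTable
from .errors import ConfigurationError

__all__ = [
    "TrialDataset",
    "GEEFit",
    "IndependentFit",
    "fit_gee",
    "fit_independent",
    "observed_deff",
    "wald_test",
]

_MAX_ITER = 50
_TOL = 1e-8


@dataclass
class TrialDataset:
    """Long-format trial data: one row per observational unit.

    Rows are stored sorted by ``cluster_id`` (members of a cluster are
    contiguous), with ``arm`` coded 1 = intervention, 0 = control.
    """

    cluster_id: np.ndarray
    member_id: np.ndarray
    arm: np.ndarray
    y: np.ndarray
    outcome: str = "continuous"

    def __post_init__(self) -> None:
        cid = np.asarray(self.cluster_id)
        order = np.argsort(cid, kind="stable")
        if not np.array_equal(order, np.arange(cid.size)):
            for name in ("cluster_id", "member_id", "arm", "y"):
                object.__setattr__(self, name, np.asarray(getattr(self, name))[order])
        self.cluster_id = np.asarray(self.cluster_id)
        self.member_id = np.asarray(self.member_id)
        self.arm = np.asarray(self.arm, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not np.all(np.isin(self.arm, (0.0, 1.0))):
            raise ConfigurationError("arm must be coded 0/1")
        if self.outcome == "binary" and not np.all(np.isin(self.y, (0.0, 1.0))):
            raise ConfigurationError("binary outcomes must be coded 0/1")
        change = np.flatnonzero(np.diff(self.cluster_id)) + 1
        self._starts = np.concatenate([[0], change])
        self._sizes = np.diff(np.concatenate([self._starts, [self.y.size]]))

    # -- structure --------------------------------------------------------

    @property
    def n_obs(self) -> int:
        return int(self.y.size)

    @property
    def n_clusters(self) -> int:
        return int(self._starts.size)

    @property
    def cluster_sizes(self) -> np.ndarray:
        return self._sizes

    def allocation(self) -> AllocationTable:
        t = np.add.reduceat(self.arm, self._starts).astype(int)
        return AllocationTable(n=self._sizes, t=t)

    # -- i/o --------------------------------------------------------------

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, outcome: str = "continuous") -> "TrialDataset":
        return cls(
            cluster_id=df["cluster_id"].to_numpy(),
            member_id=df["member_id"].to_numpy(),
            arm=df["arm"].to_numpy(),
            y=df["y"].to_numpy(),
            outcome=outcome,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cluster_id": self.cluster_id,
                "member_id": self.member_id,
                "arm": self.arm.astype(int),
                "y": self.y,
            }
        )

    @classmethod
    def from_csv(cls, path, outcome: str = "continuous") -> "TrialDataset":
        return cls.from_dataframe(pd.read_csv(path), outcome=outcome)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


@dataclass
class IndependentFit:
    """Maximum-likelihood fit ignoring clustering, classical covariance."""

    beta: np.ndarray
    cov: np.ndarray
    link: str
    converged: bool
    phi_hat: float = 1.0

    @property
    def var_treatment(self) -> float:
        return float(self.cov[1, 1])


@dataclass
class GEEFit:
    """GEE fit with robust (sandwich) and model-based covariances."""

    beta: np.ndarray
    cov_sandwich: np.ndarray
    cov_model: np.ndarray
    rho_hat: float
    phi_hat: float
    converged: bool
    non_positive_definite: bool
    n_iter: int
    link: str
    working: str

    @property
    def var_treatment(self) -> float:
        return float(self.cov_sandwich[1, 1])

    @property
    def se_treatment(self) -> float:
        return float(np.sqrt(self.cov_sandwich[1, 1]))

    def to_dict(self) -> dict:
        return {
            "beta": [float(b) for b in self.beta],
            "cov_sandwich": np.asarray(self.cov_sandwich).tolist(),
            "cov_model": np.asarray(self.cov_model).tolist(),
            "rho_hat": float(self.rho_hat),
            "phi_hat": float(self.phi_hat),
            "converged": self.converged,
            "non_positive_definite": self.non_positive_definite,
            "n_iter": self.n_iter,
            "link": self.link,
            "working": self.working,
        }


# ---------------------------------------------------------------------------
# link helpers


def _check_link(link: str, outcome: str) -> None:
    if outcome == "continuous" and link != "identity":
        raise ConfigurationError("continuous outcomes use the identity link")
    if outcome == "binary" and link not in ("logit", "log"):
        raise ConfigurationError("binary outcomes use the logit or log link")


def _beta_from_means(mean_c: float, mean_i: float, link: str) -> np.ndarray:
    if link == "identity":
        return np.array([mean_c, mean_i - mean_c])
    if link == "logit":
        b0 = np.log(mean_c / (1.0 - mean_c))
        b1 = np.log(mean_i / (1.0 - mean_i)) - b0
        return np.array([b0, b1])
    b0 = np.log(mean_c)
    return np.array([b0, np.log(mean_i) - b0])


def _mu_from_beta(beta: np.ndarray, x: np.ndarray, link: str) -> np.ndarray:
    eta = beta[0] + beta[1] * x
    if link == "identity":
        return eta
    if link == "logit":
        return 1.0 / (1.0 + np.exp(-eta))
    return np.exp(eta)


def _variance_weight(mu: np.ndarray, x: np.ndarray, link: str):
    """Marginal variance function a(mu) and mean-derivative weight w(mu).

    ``D_i`` rows are ``w_j * (1, x_j)``.  For identity a = 1 (the scale
    sits in phi), for logit w = a = mu(1-mu), for log w = mu.
    """
    if link == "identity":
        return np.ones_like(mu), np.ones_like(mu)
    a = mu * (1.0 - mu)
    w = a if link == "logit" else mu
    return a, w


def _degenerate(y: np.ndarray, x: np.ndarray, link: str) -> bool:
    if link == "identity":
        return False
    for arm in (0.0, 1.0):
        m = y[x == arm].mean()
        if m <= 0.0 or m >= 1.0:
            return True
    return False


# ---------------------------------------------------------------------------
# core fitters (array level)


def _fit_independent_core(y, x, starts, link):
    n = y.size
    n_i = int(x.sum())
    n_c = n - n_i
    if n_i == 0 or n_c == 0 or n < 4:
        raise ConfigurationError("both arms must be present and N >= 4")
    mean_i = y[x == 1.0].mean()
    mean_c = y[x == 0.0].mean()
    if _degenerate(y, x, link):
        return IndependentFit(np.full(2, np.nan), np.full((2, 2), np.nan), link, False)
    beta = _beta_from_means(mean_c, mean_i, link)
    if link == "identity":
        resid = y - (beta[0] + beta[1] * x)
        sigma2 = float(resid @ resid) / (n - 2)
        cov = sigma2 * np.array(
            [[1.0 / n_c, -1.0 / n_c], [-1.0 / n_c, 1.0 / n_c + 1.0 / n_i]]
        )
        return IndependentFit(beta, cov, link, True, phi_hat=sigma2)
    # Fisher information of the saturated-in-arm GLM: block sums of
    # w^2/a per arm; invert the per-arm information directly.
    if link == "logit":
        info_c = n_c * mean_c * (1.0 - mean_c)
        info_i = n_i * mean_i * (1.0 - mean_i)
    else:  # log
        info_c = n_c * mean_c / (1.0 - mean_c)
        info_i = n_i * mean_i / (1.0 - mean_i)
    var_c = 1.0 / info_c
    var_i = 1.0 / info_i
    cov = np.array([[var_c, -var_c], [-var_c, var_c + var_i]])
    return IndependentFit(beta, cov, link, True)


def _cluster_sums(vals: np.ndarray, starts: np.ndarray) -> np.ndarray:
    return np.add.reduceat(vals, starts)


def _assemble(y, x, starts, sizes, beta, link, rho):
    """One pass of estimating-equation sums at (beta, rho).

    Returns bread (2x2), rhs (2), per-cluster score vectors m_i (M x 2)
    and the Pearson-residual moment sums needed for (phi, rho) updates.
    """
    mu = _mu_from_beta(beta, x, link)
    a, w = _variance_weight(mu, x, link)
    sqrt_a = np.sqrt(a)
    g0 = w / sqrt_a
    g1 = g0 * x
    r = (y - mu) / sqrt_a
    # exchangeable R^-1 = c1 (I - c2 J), c1 = 1/(1-rho), c2 = rho/(1+(n-1)rho)
    if rho == 0.0:
        c1 = 1.0
        c2 = np.zeros(sizes.size)
    else:
        c1 = 1.0 / (1.0 - rho)
        c2 = rho / (1.0 + (sizes - 1.0) * rho)
    G0 = _cluster_sums(g0, starts)
    G1 = _cluster_sums(g1, starts)
    R = _cluster_sums(r, starts)
    s00 = float(g0 @ g0)
    s01 = float(g0 @ g1)
    s11 = float(g1 @ g1)
    bread = c1 * np.array(
        [
            [s00 - float(c2 @ (G0 * G0)), s01 - float(c2 @ (G0 * G1))],
            [s01 - float(c2 @ (G0 * G1)), s11 - float(c2 @ (G1 * G1))],
        ]
    )
    m0 = c1 * (_cluster_sums(g0 * r, starts) - c2 * G0 * R)
    m1 = c1 * (_cluster_sums(g1 * r, starts) - c2 * G1 * R)
    rhs = np.array([m0.sum(), m1.sum()])
    return bread, rhs, m0, m1, r, R


def _pearson_moments(y, x, starts, sizes, beta, link):
    """(phi, rho) moment estimates from Pearson residuals at beta."""
    mu = _mu_from_beta(beta, x, link)
    a, _ = _variance_weight(mu, x, link)
    r = (y - mu) / np.sqrt(a)
    R = _cluster_sums(r, starts)
    return _moment_estimates(r, R, starts, sizes)


def _moment_estimates(r, R, starts, sizes, n_params=2):
    """geepack-convention moment estimators of phi and rho."""
    n = r.size
    phi = float(r @ r) / (n - n_params)
    r2 = _cluster_sums(r * r, starts)
    pair_sum = float(((R * R) - r2).sum()) / 2.0
    n_pairs = float((sizes * (sizes - 1)).sum()) / 2.0
    denom = n_pairs - n_params
    if denom <= 0:
        return phi, 0.0
    return phi, pair_sum / (phi * denom)


def _solvable_rho(rho: float, sizes: np.ndarray) -> float:
    """Nudge rho away from exact singularities of the working matrix.

    The estimate is plugged into the variance formulas unchanged even
    when the implied working correlation is not positive definite (such
    fits are retained, only flagged); the exchangeable inverse exists
    whenever ``rho != 1`` and ``1 + (k-1) rho != 0`` for every cluster
    size present, so only those points are avoided.
    """
    if rho >= 1.0 - 1e-8:
        return 1.0 - 1e-8
    for k in np.unique(sizes):
        if k > 1:
            pivot = -1.0 / (k - 1.0)
            if abs(rho - pivot) < 1e-8:
                return float(pivot + np.copysign(1e-8, rho - pivot or 1.0))
    return float(rho)


def _fit_gee_core(y, x, starts, sizes, link, working):
    ind = _fit_independent_core(y, x, starts, link)
    if not ind.converged:
        nan2 = np.full((2, 2), np.nan)
        return GEEFit(ind.beta, nan2, nan2, np.nan, np.nan, False, False, 0, link, working)
    beta = ind.beta.copy()

    if working == "independence":
        bread, rhs, m0, m1, r, R = _assemble(y, x, starts, sizes, beta, link, 0.0)
        phi, rho_hat = _moment_estimates(r, R, starts, sizes)
        n_iter = 0
        converged = True
    else:
        converged = False
        n_iter = 0
        rho_hat = 0.0
        for n_iter in range(1, _MAX_ITER + 1):
            # moment update of (phi, rho) from residuals at the current beta,
            # then one Fisher-scoring step at the updated working correlation
            phi, rho_hat = _pearson_moments(y, x, starts, sizes, beta, link)
            bread, rhs, m0, m1, r, R = _assemble(
                y, x, starts, sizes, beta, link, _solvable_rho(rho_hat, sizes)
            )
            try:
                step = np.linalg.solve(bread, rhs)
            except np.linalg.LinAlgError:
                break
            beta = beta + step
            if not np.all(np.isfinite(beta)):
                beta = np.full(2, np.nan)
                break
            if np.max(np.abs(step)) < _TOL:
                converged = True
                break
        if not np.all(np.isfinite(beta)):
            nan2 = np.full((2, 2), np.nan)
            return GEEFit(beta, nan2, nan2, np.nan, np.nan, False, False, n_iter, link, working)
        # final covariance at the final (beta, rho_hat)
        phi, rho_hat = _pearson_moments(y, x, starts, sizes, beta, link)
        bread, rhs, m0, m1, r, R = _assemble(
            y, x, starts, sizes, beta, link, _solvable_rho(rho_hat, sizes)
        )

    try:
        bread_inv = np.linalg.inv(bread)
    except np.linalg.LinAlgError:
        nan2 = np.full((2, 2), np.nan)
        return GEEFit(beta, nan2, nan2, rho_hat, phi, False, False, n_iter, link, working)
    meat = np.array(
        [
            [float(m0 @ m0), float(m0 @ m1)],
            [float(m0 @ m1), float(m1 @ m1)],
        ]
    )
    cov_sandwich = bread_inv @ meat @ bread_inv
    cov_model = phi * bread_inv
    non_pd = bool(working == "exchangeable" and (rho_hat < -1.0 or rho_hat > 1.0))
    return GEEFit(
        beta,
        cov_sandwich,
        cov_model,
        float(rho_hat),
        float(phi),
        converged,
        non_pd,
        n_iter,
        link,
        working,
    )


# ---------------------------------------------------------------------------
# public API


def fit_independent(data: TrialDataset, link: str = "identity") -> IndependentFit:
    """ML fit ignoring clustering, with the classical covariance.

    Identity link: ordinary least squares.  Logit/log link: logistic or
    log-binomial regression (exact per-arm solution for this saturated
    two-parameter model).
    """
    _check_link(link, data.outcome)
    return _fit_independent_core(data.y, data.arm, data._starts, link)


def fit_gee(data: TrialDataset, link: str = "identity", working: str = "independence") -> GEEFit:
    """Fit the marginal model by GEE and return sandwich/model covariances.

    The exchangeable correlation parameter is estimated by the moment
    estimator on Pearson residuals (pair cross-products over
    ``sum n_i (n_i - 1)/2 - 2``, geepack convention), updated at each
    iteration.  A fit whose ``rho_hat`` falls outside ``[-1, 1]`` is
    flagged ``non_positive_definite`` but its results are retained.
    Degenerate binary outcomes (an arm with all 0s or all 1s) yield a
    non-converged fit rather than an exception.
    """
    _check_link(link, data.outcome)
    if working not in ("independence", "exchangeable"):
        raise ConfigurationError(f"unknown working correlation {working!r}")
    return _fit_gee_core(data.y, data.arm, data._starts, data.cluster_sizes, link, working)


def observed_deff(data: TrialDataset, link: str = "identity", working: str = "independence") -> float:
    """Observed DEFF: sandwich GEE variance over classical ML variance."""
    gee = fit_gee(data, link=link, working=working)
    ind = fit_independent(data, link=link)
    if not (gee.converged and ind.converged):
        raise ConfigurationError("observed_deff requires converged fits")
    return float(gee.var_treatment / ind.var_treatment)


def wald_test(fit: GEEFit) -> float:
    """Two-sided p-value for the treatment effect, normal reference."""
    if not fit.converged:
        raise ConfigurationError("fit did not converge")
    se = fit.se_treatment
    if not se > 0:
        raise ConfigurationError("zero standard error")
    z = fit.beta[1] / se
    return float(2.0 * stats.norm.sf(abs(z)))
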