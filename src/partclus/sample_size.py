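"""Sample-size planning for partially clustered trials.

The workflow: (1) compute the per-group sample size assuming all
observations are independent (two-sample t-test for continuous outcomes,
chi-square test with or without continuity correction for binary ones);
(2) multiply by the appropriate design effect; (3) optionally convert the
observation target into a cluster (recruitment) target; (4) report the
power expected at an achieved sample size via the effective sample size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil
from typing import Optional

import numpy as np
from scipy import optimize, stats

from .design_effects import DesignSpec, deff_closed_form
from .distributions import ClusterSizeDistribution, clusters_from_observations
from .errors import ConfigurationError

__all__ = [
    "EffectSpec",
    "SampleSizePlan",
    "n_independent_continuous",
    "n_independent_binary",
    "apply_deff",
    "expected_power",
    "plan",
]


@dataclass(frozen=True)
class EffectSpec:
    """Target effect, error rates and nuisance parameters.

    For a continuous outcome supply ``delta`` (mean difference) and
    ``sigma`` (common SD); for a binary outcome supply the control and
    intervention prevalences ``pi_c`` and ``pi_i``.
    """

    outcome: str
    delta: Optional[float] = None
    sigma: Optional[float] = None
    pi_i: Optional[float] = None
    pi_c: Optional[float] = None
    alpha: float = 0.05
    power: float = 0.80

    def __post_init__(self) -> None:
        if self.outcome not in ("continuous", "binary"):
            raise ConfigurationError(f"unknown outcome {self.outcome!r}")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError("alpha must lie in (0, 1)")
        if not 0.0 < self.power < 1.0:
            raise ConfigurationError("power must lie in (0, 1)")
        if self.outcome == "continuous":
            if self.delta is None or self.sigma is None:
                raise ConfigurationError("continuous effects need delta and sigma")
            if self.delta == 0:
                raise ConfigurationError("delta must be non-zero")
            if self.sigma <= 0:
                raise ConfigurationError("sigma must be positive")
        else:
            if self.pi_i is None or self.pi_c is None:
                raise ConfigurationError("binary effects need pi_i and pi_c")
            for name, p in (("pi_i", self.pi_i), ("pi_c", self.pi_c)):
                if not 0.0 < p < 1.0:
                    raise ConfigurationError(f"{name} must lie strictly in (0, 1)")
            if self.pi_i == self.pi_c:
                raise ConfigurationError("pi_i and pi_c must differ")


def n_independent_continuous(effect: EffectSpec, method: str = "normal") -> int:
    """Per-group sample size for a two-sample comparison of means.

    ``method="normal"``: ceiling of
    ``2 sigma^2 (z_{1-alpha/2} + z_{power})^2 / delta^2``.
    ``method="t"`` solves the noncentral-t power equation exactly.
    """
    if effect.outcome != "continuous":
        raise ConfigurationError("effect is not continuous")
    za = stats.norm.ppf(1.0 - effect.alpha / 2.0)
    zb = stats.norm.ppf(effect.power)
    n_norm = 2.0 * effect.sigma**2 * (za + zb) ** 2 / effect.delta**2
    if method == "normal":
        return int(ceil(n_norm - 1e-12))
    if method != "t":
        raise ConfigurationError(f"unknown method {method!r}")

    def gap(n: float) -> float:
        return _power_continuous_t(2.0 * n, 1.0, effect) - effect.power

    lo, hi = 2.0, max(4.0, 4.0 * n_norm)
    while gap(hi) < 0:
        hi *= 2.0
    n_exact = optimize.brentq(gap, lo, hi, xtol=1e-9)
    return int(ceil(n_exact - 1e-9))


def n_independent_binary(effect: EffectSpec, continuity_correction: bool = True) -> int:
    """Per-group sample size for a two-sample comparison of proportions.

    Uncorrected chi-square (normal approximation with pooled null
    variance) or its Fleiss continuity-corrected version; the correction
    is applied to the unrounded uncorrected size and the ceiling is taken
    last.
    """
    if effect.outcome != "binary":
        raise ConfigurationError("effect is not binary")
    pi_i, pi_c = effect.pi_i, effect.pi_c
    diff = abs(pi_c - pi_i)
    pbar = (pi_i + pi_c) / 2.0
    qbar = 1.0 - pbar
    za = stats.norm.ppf(1.0 - effect.alpha / 2.0)
    zb = stats.norm.ppf(effect.power)
    n = (
        za * np.sqrt(2.0 * pbar * qbar)
        + zb * np.sqrt(pi_i * (1.0 - pi_i) + pi_c * (1.0 - pi_c))
    ) ** 2 / diff**2
    if continuity_correction:
        n = (n / 4.0) * (1.0 + np.sqrt(1.0 + 4.0 / (n * diff))) ** 2
    return int(ceil(n - 1e-9))


def apply_deff(n_per_group: int, deff: float, policy: str = "round-2dp") -> int:
    """Inflate an independent-data per-group size by a design effect.

    Default policy rounds the DEFF to 2 decimal places before
    multiplying (planning convention: the DEFF is quoted at 2 dp), then
    takes the ceiling.  ``policy="exact"`` multiplies at full precision.
    """
    if n_per_group < 1:
        raise ConfigurationError("n_per_group must be >= 1")
    if deff <= 0:
        raise ConfigurationError("deff must be positive")
    if policy == "round-2dp":
        factor = round(deff, 2)
    elif policy == "exact":
        factor = deff
    else:
        raise ConfigurationError(f"unknown rounding policy {policy!r}")
    return int(ceil(n_per_group * factor - 1e-9))


# ---------------------------------------------------------------------------
# Expected power at an achieved sample size


def _power_continuous_t(n_total: float, deff: float, effect: EffectSpec) -> float:
    n_eff = n_total / deff
    n_group = n_eff / 2.0
    df = n_eff - 2.0
    if df <= 0:
        raise ConfigurationError("effective sample size too small for a t-test")
    ncp = abs(effect.delta) / (effect.sigma * np.sqrt(2.0 / n_group))
    tcrit = stats.t.ppf(1.0 - effect.alpha / 2.0, df)
    return float(1.0 - stats.nct.cdf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp))


def _power_normal(z_effect: float, alpha: float) -> float:
    za = stats.norm.ppf(1.0 - alpha / 2.0)
    return float(stats.norm.cdf(z_effect - za) + stats.norm.cdf(-z_effect - za))


def _power_continuous_normal(n_total: float, deff: float, effect: EffectSpec) -> float:
    n_group = n_total / deff / 2.0
    se = effect.sigma * np.sqrt(2.0 / n_group)
    return _power_normal(abs(effect.delta) / se, effect.alpha)


def _power_binary_wald(n_total: float, deff: float, effect: EffectSpec, link: str) -> float:
    n_group = n_total / 2.0
    pi_i, pi_c = effect.pi_i, effect.pi_c
    qi, qc = 1.0 - pi_i, 1.0 - pi_c
    if link == "logit":
        eff = abs(np.log(pi_i / qi) - np.log(pi_c / qc))
        var = deff * (1.0 / (n_group * pi_i * qi) + 1.0 / (n_group * pi_c * qc))
    elif link == "log":
        eff = abs(np.log(pi_i / pi_c))
        var = deff * (qi / (n_group * pi_i) + qc / (n_group * pi_c))
    else:
        raise ConfigurationError(f"binary power needs a logit or log link, not {link!r}")
    return _power_normal(eff / np.sqrt(var), effect.alpha)


def expected_power(
    n_total: float,
    deff: float,
    effect: EffectSpec,
    method: Optional[str] = None,
    link: str = "logit",
) -> float:
    """Power expected at total size ``n_total`` given a design effect.

    Uses the effective sample size ``n_total / deff`` split 1:1 and a
    test for independent data: a noncentral-t two-sample test for
    continuous outcomes (``method="noncentral_t"``, default) or a Wald
    test on the log odds ratio / log relative risk for binary outcomes
    (``method="wald_normal"``, default).  ``method="wald_normal"`` is
    also available for continuous outcomes.
    """
    if deff <= 0:
        raise ConfigurationError("deff must be positive")
    if n_total / deff < 4:
        raise ConfigurationError("effective sample size must be at least 4")
    if effect.outcome == "continuous":
        method = method or "noncentral_t"
        if method == "noncentral_t":
            return _power_continuous_t(n_total, deff, effect)
        if method == "wald_normal":
            return _power_continuous_normal(n_total, deff, effect)
        raise ConfigurationError(f"unknown method {method!r}")
    method = method or "wald_normal"
    if method != "wald_normal":
        raise ConfigurationError(f"unknown method {method!r} for binary outcomes")
    return _power_binary_wald(n_total, deff, effect, link)


# ---------------------------------------------------------------------------
# Full planning workflow


@dataclass(frozen=True)
class SampleSizePlan:
    """Result of the planning workflow, with the assumptions recorded."""

    n_independent_per_group: int
    deff: float
    deff_rounded: float
    n_observations_per_group: int
    n_observations_total: int
    n_clusters_per_group: int
    n_clusters_total: int
    expected_power: float
    spec: DesignSpec = field(repr=False)
    dist: ClusterSizeDistribution = field(repr=False)
    effect: EffectSpec = field(repr=False)
    rounding_policy: str = "round-2dp"
    cluster_policy: str = "total-ceiling"
    continuity_correction: bool = True

    def to_dict(self) -> dict:
        return {
            "n_independent_per_group": self.n_independent_per_group,
            "deff": self.deff,
            "deff_rounded": self.deff_rounded,
            "n_observations_per_group": self.n_observations_per_group,
            "n_observations_total": self.n_observations_total,
            "n_clusters_per_group": self.n_clusters_per_group,
            "n_clusters_total": self.n_clusters_total,
            "expected_power": self.expected_power,
            "assumptions": {
                "randomization": self.spec.randomization,
                "working_correlation": self.spec.working_correlation,
                "outcome": self.spec.outcome,
                "link": self.spec.link,
                "rho": self.spec.rho,
                "gamma": [float(g) for g in self.dist.gamma],
                "delta": [float(d) for d in self.dist.delta],
                "alpha": self.effect.alpha,
                "target_power": self.effect.power,
                "rounding_policy": self.rounding_policy,
                "cluster_policy": self.cluster_policy,
                "continuity_correction": self.continuity_correction,
            },
        }


def plan(
    spec: DesignSpec,
    dist: ClusterSizeDistribution,
    effect: EffectSpec,
    rounding_policy: str = "round-2dp",
    cluster_policy: str = "total-ceiling",
    continuity_correction: bool = True,
    base_method: str = "normal",
) -> SampleSizePlan:
    """Compose the full planning workflow into a :class:`SampleSizePlan`."""
    if spec.outcome != effect.outcome:
        raise ConfigurationError("design spec and effect spec disagree on the outcome")
    if spec.outcome == "binary" and (spec.pi_i != effect.pi_i or spec.pi_c != effect.pi_c):
        raise ConfigurationError("design spec and effect spec disagree on the prevalences")
    if effect.outcome == "continuous":
        n_base = n_independent_continuous(effect, method=base_method)
    else:
        n_base = n_independent_binary(effect, continuity_correction=continuity_correction)
    deff = deff_closed_form(spec, dist)
    n_group = apply_deff(n_base, deff, policy=rounding_policy)
    # cluster targets: each figure converts the count it describes, so the
    # total can be one less than twice the per-group target after rounding
    clusters_group = clusters_from_observations(n_group, dist, policy=cluster_policy)
    clusters_total = clusters_from_observations(2 * n_group, dist, policy=cluster_policy)
    power = expected_power(2.0 * n_group, deff, effect, link=spec.link if spec.outcome == "binary" else None)
    return SampleSizePlan(
        n_independent_per_group=n_base,
        deff=deff,
        deff_rounded=round(deff, 2),
        n_observations_per_group=n_group,
        n_observations_total=2 * n_group,
        n_clusters_per_group=clusters_group,
        n_clusters_total=clusters_total,
        expected_power=power,
        spec=spec,
        dist=dist,
        effect=effect,
        rounding_policy=rounding_policy,
        cluster_policy=cluster_policy,
        continuity_correction=continuity_correction,
    )
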