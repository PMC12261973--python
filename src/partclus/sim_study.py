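"""Simulation study: observed versus expected design effects and power.

Replicates the validation protocol: generate many datasets for a
scenario, analyse each with GEEs (independence and exchangeable working
correlations, sandwich variance) and with standard regression, form the
per-dataset observed DEFF, and aggregate:

* median observed DEFF (over converged replicates);
* median percent relative difference ``100 (obs - exp)/exp``;
* observed power (share of replicates with Wald p <= alpha);
* expected DEFF (closed form) and expected power (effective sample
  size);
* non-convergence and non-positive-definite rates.

Non-positive-definite exchangeable fits are retained; non-converged
replicates are excluded from every summary except the rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import synthetic_data
from .design_effects import DesignSpec, deff_closed_form
from .distributions import ClusterSizeDistribution
from .errors import ConfigurationError
from .gee_engine import (
    TrialDataset,
    fit_gee,
    fit_independent,
    wald_test,
)
from .sample_size import EffectSpec, expected_power
from .synthetic_data import GenerationConfig, build_design, derive_seed, gen_binary, gen_continuous, randomize

__all__ = ["ScenarioResult", "run_scenario", "run_grid", "power_comparison"]

_WORKINGS = ("independence", "exchangeable")


@dataclass
class ScenarioResult:
    """Aggregated simulation output for one scenario x working structure."""

    randomization: str
    n_units: int
    distribution_label: str
    rho: float
    outcome: str
    link: str
    working: str
    reps: int
    seed: int
    observed_deffs: np.ndarray = field(repr=False)
    p_values: np.ndarray = field(repr=False)
    expected_deff: float = np.nan
    expected_power: float = np.nan
    n_nonconverged: int = 0
    n_non_positive_definite: int = 0
    alpha: float = 0.05

    @property
    def median_observed_deff(self) -> float:
        return float(np.median(self.observed_deffs)) if self.observed_deffs.size else np.nan

    @property
    def median_relative_difference(self) -> float:
        """Median of per-replicate ``100 (obs - exp)/exp``."""
        if not self.observed_deffs.size:
            return np.nan
        rel = 100.0 * (self.observed_deffs - self.expected_deff) / self.expected_deff
        return float(np.median(rel))

    @property
    def observed_power(self) -> float:
        if not self.p_values.size:
            return np.nan
        return float(np.mean(self.p_values <= self.alpha))

    @property
    def nonconvergence_rate(self) -> float:
        return self.n_nonconverged / self.reps

    @property
    def non_positive_definite_rate(self) -> float:
        return self.n_non_positive_definite / self.reps

    def to_row(self) -> dict:
        return {
            "randomization": self.randomization,
            "n_units": self.n_units,
            "distribution": self.distribution_label,
            "rho": self.rho,
            "outcome": self.outcome,
            "link": self.link,
            "working": self.working,
            "reps": self.reps,
            "seed": self.seed,
            "observed_deff": self.median_observed_deff,
            "observed_deff_2dp": round(self.median_observed_deff, 2),
            "expected_deff": self.expected_deff,
            "expected_deff_2dp": round(self.expected_deff, 2),
            "relative_difference_pct": self.median_relative_difference,
            "observed_power": 100.0 * self.observed_power,
            "expected_power": 100.0 * self.expected_power,
            "power_difference": power_comparison(self),
            "nonconvergence_rate": self.nonconvergence_rate,
            "non_positive_definite_rate": self.non_positive_definite_rate,
        }


def power_comparison(result: ScenarioResult) -> float:
    """Observed minus expected power, in percentage points."""
    return float(100.0 * result.observed_power - 100.0 * result.expected_power)


def _expected_quantities(
    config: GenerationConfig,
    link: str,
    working: str,
    dist: ClusterSizeDistribution,
    n_units: int,
    effect: EffectSpec,
) -> Tuple[float, float]:
    spec = DesignSpec(
        randomization=config.randomization,
        working_correlation=working,
        outcome=config.outcome,
        link=link,
        rho=config.rho,
        pi_i=config.pi_i,
        pi_c=config.pi_c,
    )
    exp_deff = deff_closed_form(spec, dist)
    exp_power = expected_power(n_units, exp_deff, effect, link=link)
    return exp_deff, exp_power


def _effect_from_config(config: GenerationConfig, alpha: float) -> EffectSpec:
    if config.outcome == "continuous":
        return EffectSpec(
            outcome="continuous",
            delta=config.beta1,
            sigma=float(np.sqrt(config.total_var)),
            alpha=alpha,
            power=0.5,
        )
    return EffectSpec(outcome="binary", pi_i=config.pi_i, pi_c=config.pi_c, alpha=alpha, power=0.5)


def run_scenario(
    config: GenerationConfig,
    reps: int,
    seed: int,
    link: Optional[str] = None,
    workings: Sequence[str] = _WORKINGS,
    alpha: float = 0.05,
    distribution_label: str = "",
) -> Dict[str, ScenarioResult]:
    """Simulate one scenario; returns one :class:`ScenarioResult` per working."""
    if reps < 1:
        raise ConfigurationError("reps must be >= 1")
    link = link or ("identity" if config.outcome == "continuous" else "logit")
    rng = np.random.default_rng(seed)
    effect = _effect_from_config(config, alpha)

    deffs: Dict[str, List[float]] = {w: [] for w in workings}
    pvals: Dict[str, List[float]] = {w: [] for w in workings}
    nonconv = {w: 0 for w in workings}
    nonpd = {w: 0 for w in workings}

    for _ in range(reps):
        design = build_design(config, rng)
        alloc = randomize(design, config.randomization, config.balance, rng)
        if config.outcome == "continuous":
            data = gen_continuous(
                alloc, config.rho, config.beta0, config.beta1, config.total_var, rng
            )
        else:
            data = gen_binary(alloc, config.pi_i, config.pi_c, config.rho, rng)
        ind = fit_independent(data, link=link)
        for w in workings:
            gee = fit_gee(data, link=link, working=w)
            if not (gee.converged and ind.converged):
                nonconv[w] += 1
                continue
            if gee.non_positive_definite:
                nonpd[w] += 1
            deffs[w].append(gee.var_treatment / ind.var_treatment)
            pvals[w].append(wald_test(gee))

    # expected quantities use the nominal design (fixed counts or delta)
    if config.counts is not None:
        nominal = ClusterSizeDistribution.from_counts(np.asarray(config.counts, dtype=int))
        n_units = nominal.n_units
    else:
        nominal = ClusterSizeDistribution.from_delta(np.asarray(config.delta, dtype=float))
        n_units = int(round(config.n_clusters / nominal.clusters_per_unit))

    out: Dict[str, ScenarioResult] = {}
    for w in workings:
        exp_deff, exp_power = _expected_quantities(config, link, w, nominal, n_units, effect)
        out[w] = ScenarioResult(
            randomization=config.randomization,
            n_units=n_units,
            distribution_label=distribution_label,
            rho=config.rho,
            outcome=config.outcome,
            link=link,
            working=w,
            reps=reps,
            seed=seed,
            observed_deffs=np.asarray(deffs[w]),
            p_values=np.asarray(pvals[w]),
            expected_deff=exp_deff,
            expected_power=exp_power,
            n_nonconverged=nonconv[w],
            n_non_positive_definite=nonpd[w],
            alpha=alpha,
        )
    return out


def run_grid(
    scenarios: Iterable[dict],
    reps: int,
    seed: int,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Run a grid of scenarios and return one row per scenario x working.

    Each scenario dict provides :class:`GenerationConfig` keyword
    arguments plus optional ``label`` and ``link``.  Per-scenario seeds
    are derived from the master seed and the scenario label, so results
    do not depend on grid order.
    """
    rows = []
    for sc in scenarios:
        sc = dict(sc)
        label = sc.pop("label", None)
        link = sc.pop("link", None)
        config = GenerationConfig(**sc)
        if label is None:
            label = (
                f"{config.randomization}-{config.outcome}-rho{config.rho}-"
                f"counts{config.counts}-delta{config.delta}-M{config.n_clusters}"
            )
        results = run_scenario(
            config,
            reps=reps,
            seed=derive_seed(seed, label),
            link=link,
            alpha=alpha,
            distribution_label=label,
        )
        for res in results.values():
            rows.append(res.to_row())
    return pd.DataFrame(rows)
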