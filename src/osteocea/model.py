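"""Run-level facade: a model object built from inputs, whose ``fit`` runs the
base-case microsimulation and returns a results object with the decision
outputs.

Typical use::

    from osteocea import OsteoporosisCEA

    model = OsteoporosisCEA.with_synthetic_inputs(entry_age=55)
    res = model.fit(n=20_000, seed=1)
    print(res.summary())
    tornado = model.sensitivity_oneway(n=5_000, seed=1)
    psa = model.psa(n_iterations=200, inner_n=2_000, seed=1)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cea
from .cea import CEATable, PSAOutput, TornadoEntry
from .microsim import CohortRandoms, SimulationModels, StrategyResult, run_cohort
from .natural_history import MortalityModel, calibrated_incidence_models
from .parameters import ParameterError, ParameterSet, default_parameters, load_parameters
from .synthetic_inputs import (
    DEFAULT_EXCESS_HIP_MORTALITY_RR,
    default_incidence_targets,
    default_life_table,
)

__all__ = ["OsteoporosisCEA", "CEAResults"]


class OsteoporosisCEA:
    """Markov microsimulation cost-effectiveness model of osteoporosis
    treatment strategies.

    Parameters
    ----------
    params
        Full parameter set (defaults to the shipped fixture).
    models
        Calibrated natural-history inputs (incidence + mortality).
    entry_age
        Cohort starting age; one of the BMD bands' lower ages (55/60/65/70).
    strategies
        Strategy keys to compare; defaults to every treatment in ``params``.
    """

    def __init__(
        self,
        params: ParameterSet,
        models: SimulationModels,
        entry_age: int = 55,
        strategies: list[str] | None = None,
        reference: str = "no_treatment",
    ) -> None:
        params.validate()
        params.band_for_age(entry_age)  # raises if uncovered
        self.params = params
        self.models = models
        self.entry_age = int(entry_age)
        self.strategies = strategies or sorted(params.treatments)
        if reference not in self.strategies:
            raise ParameterError(f"reference {reference!r} not among strategies")
        self.reference = reference
        self.targets = None  # set by with_synthetic_inputs for validation runs

    # -- constructors ------------------------------------------------------

    @classmethod
    def with_synthetic_inputs(
        cls,
        params: ParameterSet | None = None,
        entry_age: int = 55,
        excess_hip_rr: float = DEFAULT_EXCESS_HIP_MORTALITY_RR,
        **kwargs,
    ) -> "OsteoporosisCEA":
        """Build the model on the synthetic baseline scenario.

        Generates the synthetic life table and incidence targets, calibrates
        the per-site incidence models against the entry band, and wires up
        mortality with the synthetic excess post-hip-fracture ratio.
        """
        params = params or default_parameters()
        band = params.band_for_age(entry_age)
        targets = default_incidence_targets(reference_bmd=band.mean_bmd)
        incidence = calibrated_incidence_models(targets, band)
        mortality = MortalityModel(
            default_life_table(params.analysis.max_age), excess_hip_rr=excess_hip_rr
        )
        obj = cls(params, SimulationModels(incidence, mortality), entry_age, **kwargs)
        obj.targets = targets
        return obj

    @classmethod
    def from_config(cls, path: str | Path | None, entry_age: int = 55, **kwargs):
        """Synthetic-baseline model with parameters loaded from a config file."""
        return cls.with_synthetic_inputs(load_parameters(path), entry_age, **kwargs)

    # -- base case ---------------------------------------------------------

    def fit(self, n: int | None = None, seed: int | None = None) -> "CEAResults":
        """Run the first-order Monte Carlo base case for every strategy.

        All strategies share one common-random-numbers block drawn from
        ``seed`` (default: the parameter set's ``rng_seed``).
        """
        n = n or self.params.analysis.n_individuals
        seed = self.params.analysis.rng_seed if seed is None else seed
        T = self.params.analysis.max_age - self.entry_age + 1
        randoms = CohortRandoms.draw(seed, n, T)
        results = {
            s: run_cohort(n, self.entry_age, s, self.params, self.models, randoms=randoms)
            for s in self.strategies
        }
        table = cea.compute_icers(list(results.values()), self.reference)
        return CEAResults(self, results, table, n=n, seed=seed)

    # -- sensitivity analyses ---------------------------------------------

    def sensitivity_oneway(
        self,
        strategy: str | None = None,
        n: int = 10_000,
        seed: int = 0,
        param_paths: list[str] | None = None,
    ) -> list[TornadoEntry]:
        strategy = strategy or next(s for s in self.strategies if s != self.reference)
        return cea.one_way_dsa(
            self.params, self.models, self.entry_age, strategy, self.reference,
            n=n, seed=seed, param_paths=param_paths,
        )

    def psa(
        self,
        n_iterations: int | None = None,
        inner_n: int = 10_000,
        seed: int = 0,
    ) -> PSAOutput:
        n_iterations = n_iterations or self.params.analysis.n_psa_iterations
        return cea.run_psa(
            self.params, self.models, self.entry_age, self.strategies,
            n_iterations=n_iterations, inner_n=inner_n, seed=seed,
        )

    def ceac(self, psa: PSAOutput, wtp_grid=None) -> pd.DataFrame:
        return cea.ceac(psa, cea.default_wtp_grid() if wtp_grid is None else wtp_grid)

    def validate(self, n: int = 20_000, seed: int = 0, site: str = "hip") -> pd.DataFrame:
        """Compare simulated no-treatment incidence against the calibration
        targets (requires a model built with synthetic/calibration targets)."""
        if self.targets is None:
            raise ParameterError("no incidence targets attached to this model")
        res = run_cohort(
            n, self.entry_age, self.reference, self.params, self.models, seed=seed
        )
        return cea.validate_incidence(res, self.targets[site])


@dataclass
class CEAResults:
    """Base-case results: per-strategy cohort summaries and the ICER table."""

    model: OsteoporosisCEA
    strategy_results: dict[str, StrategyResult]
    cea_table: CEATable
    n: int
    seed: int
    _reductions: pd.DataFrame | None = field(default=None, repr=False)

    def relative_reductions(self) -> pd.DataFrame:
        """Percent reduction in lifetime fracture proportions vs reference."""
        if self._reductions is None:
            ref = self.strategy_results[self.model.reference]
            rows = []
            for key, r in self.strategy_results.items():
                if key == self.model.reference:
                    continue
                for site in ("hip", "vertebral", "other"):
                    rows.append(
                        {
                            "strategy": key,
                            "site": site,
                            "p_reference": ref.prop_fracture[site],
                            "p_strategy": r.prop_fracture[site],
                            "reduction_pct": cea.relative_reduction(
                                ref.prop_fracture[site], r.prop_fracture[site]
                            ),
                        }
                    )
            self._reductions = pd.DataFrame(rows)
        return self._reductions

    def strategy_frame(self) -> pd.DataFrame:
        rows = []
        for key, r in self.strategy_results.items():
            rows.append(
                {
                    "strategy": key,
                    "label": r.label,
                    "n": r.n,
                    "mean_cost": r.mean_cost,
                    "se_cost": r.se_cost,
                    "mean_qalys": r.mean_qalys,
                    "se_qalys": r.se_qalys,
                    "prop_hip_fracture": r.prop_fracture["hip"],
                    "prop_vertebral_fracture": r.prop_fracture["vertebral"],
                    "prop_other_fracture": r.prop_fracture["other"],
                    "mean_years_survived": r.mean_years_survived,
                }
            )
        return pd.DataFrame(rows)

    def net_monetary_benefit(self, wtp: float | None = None) -> pd.Series:
        wtp = wtp or self.model.params.analysis.wtp_threshold
        return pd.Series(
            {
                k: wtp * r.mean_qalys - r.mean_cost
                for k, r in self.strategy_results.items()
            }
        )

    def summary(self) -> str:
        a = self.model.params.analysis
        lines = [
            "Osteoporosis treatment cost-effectiveness — microsimulation base case",
            f"  entry age {self.model.entry_age}, n = {self.n:,} per strategy, "
            f"seed = {self.seed}",
            f"  discounting {a.discount_rate_cost:.0%} (costs) / "
            f"{a.discount_rate_qaly:.0%} (QALYs); WTP ${a.wtp_threshold:,.0f}/QALY",
            "",
            self.cea_table.frame.to_string(
                index=False,
                formatters={
                    "cost": "{:,.2f}".format,
                    "qalys": "{:,.4f}".format,
                    "incremental_cost": "{:,.2f}".format,
                    "incremental_qalys": "{:,.4f}".format,
                    "icer": "{:,.0f}".format,
                },
            ),
            "",
            "Lifetime fracture proportion reductions vs reference (%):",
            self.relative_reductions().to_string(
                index=False,
                formatters={
                    "p_reference": "{:.4f}".format,
                    "p_strategy": "{:.4f}".format,
                    "reduction_pct": "{:.2f}".format,
                },
            ),
        ]
        return "\n".join(lines)
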