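"""Decision outputs: ICER tables, tornado (one-way) sensitivity, second-order
probabilistic sensitivity, acceptability curves and incidence validation.

The incremental cost-effectiveness ratio between strategy j and reference r
is ICER = (C_j - C_r) / (Q_j - Q_r); a strategy is dominated when another is
both cheaper and more effective, extended-dominated when a convex
combination of two others beats it on the cost-effectiveness frontier.
Acceptability curves report, at each willingness-to-pay lambda, the fraction
of probabilistic iterations in which a strategy has the strictly highest net
monetary benefit NMB = lambda * Q - C (ties split equally).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .microsim import CohortRandoms, SimulationModels, StrategyResult, run_cohort
from .parameters import (
    PARAMETER_MANIFEST,
    ParameterError,
    ParameterSet,
    sample_psa_parameter_set,
    set_value,
)
from .synthetic_inputs import IncidenceTargets

__all__ = [
    "CEATable",
    "TornadoEntry",
    "PSAOutput",
    "compute_icers",
    "relative_reduction",
    "one_way_dsa",
    "run_psa",
    "ceac",
    "validate_incidence",
    "default_wtp_grid",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# ICER table
# ---------------------------------------------------------------------------


@dataclass
class CEATable:
    """Ordered cost-effectiveness table (ascending cost; reference has blank
    incrementals; ICER flagged undefined when the QALY increment is <= 0)."""

    frame: pd.DataFrame
    reference: str

    def icer(self, strategy: str) -> float:
        row = self.frame.loc[self.frame["strategy"] == strategy]
        if row.empty:
            raise KeyError(strategy)
        return float(row["icer"].iloc[0])

    def __str__(self) -> str:
        return self.frame.to_string(index=False)


def _dominance_flags(costs: np.ndarray, qalys: np.ndarray) -> list[str]:
    k = len(costs)
    flags = ["none"] * k
    for i in range(k):
        for j in range(k):
            if j != i and costs[j] <= costs[i] and qalys[j] >= qalys[i] and (
                costs[j] < costs[i] or qalys[j] > qalys[i]
            ):
                flags[i] = "dominated"
                break
    # extended dominance on the remaining frontier: sort by cost, walk the
    # sequential ICERs and drop strategies whose ICER exceeds the next one's.
    order = [i for i in np.argsort(costs, kind="stable") if flags[i] == "none"]
    changed = True
    while changed and len(order) > 2:
        changed = False
        for m in range(1, len(order) - 1):
            a, b, c = order[m - 1], order[m], order[m + 1]
            dq_ab, dq_bc = qalys[b] - qalys[a], qalys[c] - qalys[b]
            if dq_ab <= 0 or dq_bc <= 0:
                continue
            icer_ab = (costs[b] - costs[a]) / dq_ab
            icer_bc = (costs[c] - costs[b]) / dq_bc
            if icer_ab > icer_bc:
                flags[b] = "extended-dominated"
                order.pop(m)
                changed = True
                break
    return flags


def compute_icers(
    results: list[StrategyResult] | dict[str, StrategyResult],
    reference: str,
) -> CEATable:
    """Cost-effectiveness table with each strategy compared to *reference*.

    Each non-reference row reports incremental cost/QALYs and ICER against
    the stated reference strategy; dominance flags follow the standard rules
    over the whole strategy set.  Use :func:`frontier_icers` for the
    sequential (frontier) comparison.
    """
    if isinstance(results, dict):
        results = list(results.values())
    if len(results) < 2:
        raise ParameterError("need at least 2 strategies")
    keys = [r.strategy for r in results]
    if reference not in keys:
        raise ParameterError(f"reference strategy {reference!r} not among {keys}")
    ref = next(r for r in results if r.strategy == reference)

    order = np.argsort([r.mean_cost for r in results], kind="stable")
    rows = []
    costs = np.array([r.mean_cost for r in results])
    qalys = np.array([r.mean_qalys for r in results])
    flags = _dominance_flags(costs, qalys)
    for i in order:
        r = results[i]
        if r.strategy == reference:
            inc_c = inc_q = icer = math.nan
            note = "Ref"
        else:
            inc_c = r.mean_cost - ref.mean_cost
            inc_q = r.mean_qalys - ref.mean_qalys
            if inc_q <= 0:
                icer = math.nan
                note = "dominated vs ref" if inc_c >= 0 else "cost-saving, QALY-losing"
            else:
                icer = inc_c / inc_q
                note = ""
        rows.append(
            {
                "strategy": r.strategy,
                "label": r.label,
                "cost": r.mean_cost,
                "qalys": r.mean_qalys,
                "incremental_cost": inc_c,
                "incremental_qalys": inc_q,
                "icer": icer,
                "dominance": flags[i],
                "note": note,
            }
        )
    return CEATable(pd.DataFrame(rows), reference)


def frontier_icers(results: list[StrategyResult] | dict[str, StrategyResult]) -> pd.DataFrame:
    """Sequential ICERs along the efficiency frontier (secondary view)."""
    if isinstance(results, dict):
        results = list(results.values())
    costs = np.array([r.mean_cost for r in results])
    qalys = np.array([r.mean_qalys for r in results])
    flags = _dominance_flags(costs, qalys)
    order = [i for i in np.argsort(costs, kind="stable") if flags[i] == "none"]
    rows = []
    for prev, cur in zip([None] + order[:-1], order):
        r = results[cur]
        if prev is None:
            icer = math.nan
            comparator = ""
        else:
            dq = qalys[cur] - qalys[prev]
            icer = (costs[cur] - costs[prev]) / dq if dq > 0 else math.nan
            comparator = results[prev].strategy
        rows.append(
            {"strategy": r.strategy, "cost": r.mean_cost, "qalys": r.mean_qalys,
             "comparator": comparator, "icer": icer}
        )
    return pd.DataFrame(rows)


def relative_reduction(p_control: float, p_treated: float) -> float:
    """Percent reduction 100 * (p_control - p_treated) / p_control.

    Returns NaN (undefined) when the control probability is zero.
    """
    if p_control == 0:
        return math.nan
    return 100.0 * (p_control - p_treated) / p_control


# ---------------------------------------------------------------------------
# One-way deterministic sensitivity analysis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    label: str
    low_input: float
    high_input: float
    icer_low: float
    icer_high: float
    icer_base: float
    flagged: bool = False  # non-finite ICER at an extreme

    @property
    def width(self) -> float:
        if not (math.isfinite(self.icer_low) and math.isfinite(self.icer_high)):
            return math.inf
        return abs(self.icer_high - self.icer_low)


def _icer_for(
    params: ParameterSet,
    models: SimulationModels,
    entry_age: int,
    strategy: str,
    reference: str,
    n: int,
    randoms_by_strategy: dict[str, CohortRandoms],
) -> float:
    res = [
        run_cohort(n, entry_age, s, params, models, randoms=randoms_by_strategy[s],
                   keep_individual_totals=False)
        for s in (reference, strategy)
    ]
    table = compute_icers(res, reference)
    return table.icer(strategy)


def one_way_dsa(
    params: ParameterSet,
    models: SimulationModels,
    entry_age: int,
    strategy: str,
    reference: str = "no_treatment",
    n: int = 10_000,
    seed: int = 0,
    param_paths: list[str] | None = None,
) -> list[TornadoEntry]:
    """One-way sweep: each parameter to its low and high bound in turn.

    All cohort reruns share one common-random-numbers block (same seed), so
    the ICER movement reflects only the swept parameter.  Entries are sorted
    by |ICER_high - ICER_low| descending; a non-finite ICER at an extreme
    flags the entry rather than dropping it.
    """
    defs = [
        d for d in PARAMETER_MANIFEST
        if d.swept and (param_paths is None or d.path in param_paths)
    ]
    if param_paths is not None:
        known = {d.path for d in defs}
        missing = set(param_paths) - known
        if missing:
            raise ParameterError(f"not sweepable (no printed range): {sorted(missing)}")

    T = params.analysis.max_age - entry_age + 1
    # one shared block for both strategies = common random numbers
    shared = CohortRandoms.draw(seed, n, T)
    randoms = {strategy: shared, reference: shared}

    base_icer = _icer_for(params, models, entry_age, strategy, reference, n, randoms)
    entries = []
    for d in defs:
        icers = {}
        for bound, val in (("low", d.dsa_low), ("high", d.dsa_high)):
            ps = params.copy()
            set_value(ps, d.path, val)
            icers[bound] = _icer_for(ps, models, entry_age, strategy, reference, n, randoms)
        flagged = not (math.isfinite(icers["low"]) and math.isfinite(icers["high"]))
        if flagged:
            logger.warning("non-finite ICER sweeping %s", d.path)
        entries.append(
            TornadoEntry(
                parameter=d.path,
                label=d.label,
                low_input=float(d.dsa_low),
                high_input=float(d.dsa_high),
                icer_low=icers["low"],
                icer_high=icers["high"],
                icer_base=base_icer,
                flagged=flagged,
            )
        )
    entries.sort(key=lambda e: e.width, reverse=True)
    return entries


def tornado_frame(entries: list[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "parameter": e.parameter,
                "label": e.label,
                "low_input": e.low_input,
                "high_input": e.high_input,
                "icer_low": e.icer_low,
                "icer_high": e.icer_high,
                "icer_base": e.icer_base,
                "width": e.width,
                "flagged": e.flagged,
            }
            for e in entries
        ]
    )


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis + CEAC
# ---------------------------------------------------------------------------


@dataclass
class PSAOutput:
    """Per-iteration (cost, QALY) per strategy from second-order Monte Carlo."""

    strategies: list[str]
    costs: np.ndarray   # (n_iterations, n_strategies)
    qalys: np.ndarray   # (n_iterations, n_strategies)
    inner_n: int
    skipped: int = 0

    def frame(self) -> pd.DataFrame:
        rows = []
        for it in range(self.costs.shape[0]):
            for j, s in enumerate(self.strategies):
                rows.append(
                    {"iteration": it, "strategy": s,
                     "cost": self.costs[it, j], "qalys": self.qalys[it, j]}
                )
        return pd.DataFrame(rows)


def run_psa(
    params: ParameterSet,
    models: SimulationModels,
    entry_age: int,
    strategies: list[str],
    n_iterations: int = 1_000,
    inner_n: int = 10_000,
    seed: int = 0,
) -> PSAOutput:
    """Second-order Monte Carlo: redraw parameters each iteration, re-simulate.

    Every iteration draws one parameter set from the distributions, then runs
    all strategies at ``inner_n`` individuals.  One uniform block is drawn up
    front and shared by all strategies *and* all iterations: within an
    iteration this gives common random numbers across strategies, and across
    iterations it holds first-order noise fixed so the (cost, QALY) cloud
    reflects parameter uncertainty only.  Iterations whose parameter draw
    fails validation are logged and skipped; the count is reported on the
    output.
    """
    if n_iterations < 1:
        raise ParameterError("n_iterations must be >= 1")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_iterations + 1)
    T = params.analysis.max_age - entry_age + 1
    inner_seed = int(children[-1].generate_state(1, dtype=np.uint32)[0] % (2**31))
    randoms = CohortRandoms.draw(inner_seed, inner_n, T)
    costs = np.full((n_iterations, len(strategies)), np.nan)
    qalys = np.full((n_iterations, len(strategies)), np.nan)
    skipped = 0
    kept = []
    for it, child in enumerate(children[:-1]):
        rng = np.random.default_rng(child)
        try:
            ps = sample_psa_parameter_set(params, rng)
        except ParameterError as exc:
            logger.warning("PSA iteration %d skipped: %s", it, exc)
            skipped += 1
            continue
        for j, s in enumerate(strategies):
            res = run_cohort(
                inner_n, entry_age, s, ps, models, randoms=randoms,
                keep_individual_totals=False,
            )
            costs[it, j] = res.mean_cost
            qalys[it, j] = res.mean_qalys
        kept.append(it)
    return PSAOutput(
        strategies=list(strategies),
        costs=costs[kept],
        qalys=qalys[kept],
        inner_n=inner_n,
        skipped=skipped,
    )


def default_wtp_grid() -> np.ndarray:
    """0-60,000 USD/QALY in 500-unit steps (covers 3,000; 24,000; 38,223)."""
    return np.arange(0.0, 60_000.0 + 1, 500.0)


def ceac(psa: PSAOutput, wtp_grid: np.ndarray | list[float]) -> pd.DataFrame:
    """Cost-effectiveness acceptability curves over a willingness-to-pay grid.

    At each lambda, a strategy's probability is the fraction of iterations
    in which its net monetary benefit is maximal; exact ties split their
    iteration's weight equally, so the probabilities sum to one.
    """
    wtp = np.asarray(list(wtp_grid), dtype=float)
    if wtp.size == 0:
        raise ParameterError("wtp_grid must be nonempty")
    n_it, k = psa.costs.shape
    out = np.zeros((wtp.size, k))
    for w, lam in enumerate(wtp):
        nmb = lam * psa.qalys - psa.costs  # (n_it, k)
        best = nmb.max(axis=1, keepdims=True)
        winners = nmb == best
        weights = winners / winners.sum(axis=1, keepdims=True)
        out[w] = weights.mean(axis=0)
    df = pd.DataFrame(out, columns=psa.strategies)
    df.insert(0, "wtp", wtp)
    return df


# ---------------------------------------------------------------------------
# Incidence validation
# ---------------------------------------------------------------------------


def validate_incidence(
    result: StrategyResult,
    targets: IncidenceTargets,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Simulated age-specific incidence vs targets, with binomial bands.

    Uses the no-treatment cohort's per-cycle event counts and at-risk
    denominators; each target age present in the simulated range is compared
    to the Wilson (1 - alpha) interval of the simulated incidence, and rows
    where the target falls outside the band are flagged.  Ages with zero
    person-years are omitted with a log note.
    """
    if result.n == 0 or result.at_risk_by_cycle.sum() == 0:
        raise ParameterError("validation needs a non-empty simulated cohort")
    events = result.events_by_cycle[targets.site]
    rows = []
    for age, target in zip(targets.ages, targets.incidences):
        t = int(round(age)) - result.entry_age
        if t < 0 or t >= len(result.at_risk_by_cycle):
            continue
        n_risk = int(result.at_risk_by_cycle[t])
        if n_risk == 0:
            logger.info("age %s omitted: zero person-years at risk", age)
            continue
        x = int(events[t])
        lo, hi = proportion_confint(x, n_risk, alpha=alpha, method="wilson")
        rows.append(
            {
                "age": float(age),
                "events": x,
                "person_years": n_risk,
                "incidence": x / n_risk,
                "ci_low": lo,
                "ci_high": hi,
                "target": float(target),
                "outside_band": not (lo <= target <= hi),
            }
        )
    return pd.DataFrame(rows)
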