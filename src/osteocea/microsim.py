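"""First-order Monte Carlo engine: annual individual-level state transitions.

Each simulated woman enters fracture-free at her band's lower age with a
femoral-neck BMD drawn from the band's truncated normal, then moves through
annual cycles until death: a death draw first (no payoffs accrue in the
death cycle), then — unless bedridden — a competing-risk fracture draw over
hip / vertebral / other, a bedridden draw upon a hip event, and cost/QALY
accrual discounted at the end-of-cycle convention.  The bedridden state is
absorbing except to death and carries no further fracture events; nobody
returns to the fracture-free state after any fracture.

Randomness is pre-drawn as one uniform block (one BMD uniform per individual
plus four uniforms per individual-cycle: death, fracture, site, bedridden).
Two engines consume the block identically: a vectorized numpy engine
(:func:`run_cohort`, the production path) and a per-individual reference
engine (:func:`simulate_individual`, which also records full trajectories).
Sharing the block across strategies yields common random numbers, so
strategy contrasts are paired at the individual level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import economics
from .natural_history import IncidenceModel, MortalityModel
from .parameters import (
    FRACTURE_SITES,
    ParameterError,
    ParameterSet,
    TreatmentParams,
)
from .synthetic_inputs import sample_bmd

__all__ = [
    "SimulationModels",
    "CohortRandoms",
    "Individual",
    "CycleRecord",
    "Trajectory",
    "StrategyResult",
    "apply_treatment_effect",
    "step_cycle",
    "simulate_individual",
    "run_cohort",
]

_NEVER = -(10**9)  # sentinel cycle index for "no fracture of this site yet"


@dataclass
class SimulationModels:
    """The calibrated natural-history inputs of one simulation run."""

    incidence: dict[str, IncidenceModel]
    mortality: MortalityModel

    def __post_init__(self) -> None:
        missing = set(FRACTURE_SITES) - set(self.incidence)
        if missing:
            raise ParameterError(f"missing incidence models for sites: {sorted(missing)}")


@dataclass
class CohortRandoms:
    """Pre-drawn uniforms for one cohort; sharing across strategies gives CRN."""

    bmd_u: np.ndarray  # (n,)
    u: np.ndarray      # (n, n_cycles, 4): death, fracture, site, bedridden

    @classmethod
    def draw(cls, seed: int, n: int, n_cycles: int) -> "CohortRandoms":
        rng = np.random.default_rng(seed)
        return cls(bmd_u=rng.uniform(size=n), u=rng.uniform(size=(n, n_cycles, 4)))

    @property
    def n(self) -> int:
        return len(self.bmd_u)

    @property
    def n_cycles(self) -> int:
        return self.u.shape[1]


def _resolve_strategy(strategy, params: ParameterSet) -> TreatmentParams:
    if isinstance(strategy, TreatmentParams):
        return strategy
    try:
        return params.treatments[strategy]
    except KeyError:
        raise ParameterError(
            f"unknown strategy {strategy!r}; available: {sorted(params.treatments)}"
        ) from None


def _n_cycles(entry_age: int, max_age: int) -> int:
    return int(max_age) - int(entry_age) + 1


# ---------------------------------------------------------------------------
# Individual-level reference engine
# ---------------------------------------------------------------------------


@dataclass
class Individual:
    """State of one simulated woman."""

    current_age: float
    bmd: float
    entry_age: float = 55.0
    state: str = "no_fracture"
    alive: bool = True
    bedridden: bool = False
    fracture_counts: dict[str, int] = field(
        default_factory=lambda: {s: 0 for s in FRACTURE_SITES}
    )
    last_fracture_cycle: dict[str, int] = field(
        default_factory=lambda: {s: _NEVER for s in FRACTURE_SITES}
    )
    years_since_last_fracture: float | None = None
    complex_fracture_flag: bool = False
    discounted_cost: float = 0.0
    discounted_qalys: float = 0.0

    @property
    def total_fractures(self) -> int:
        return sum(self.fracture_counts.values())

    @property
    def any_prior_fracture(self) -> bool:
        return self.total_fractures > 0


@dataclass(frozen=True)
class CycleRecord:
    age: float
    state: str
    event: str | None
    cost: float
    utility: float
    discount_factor_cost: float
    discount_factor_qaly: float


@dataclass
class Trajectory:
    """Per-cycle audit trail of one individual; ends with a terminal record."""

    records: list[CycleRecord] = field(default_factory=list)
    discounted_cost: float = 0.0
    discounted_qalys: float = 0.0
    years_survived: int = 0
    ever_fractured: dict[str, bool] = field(
        default_factory=lambda: {s: False for s in FRACTURE_SITES}
    )


def apply_treatment_effect(
    ind: Individual, treatment: TreatmentParams, cycle_index: int
) -> Individual:
    """Add the treatment's BMD increment during cycle 0.

    The 6-month course completes within the first annual cycle, so the full
    increment is attained at the start of cycle 0 and persists thereafter
    (an untreated annual decline, if configured, is applied separately).
    """
    if cycle_index < 0:
        raise ParameterError("cycle_index must be >= 0")
    if cycle_index == 0:
        ind.bmd += treatment.bmd_increment
    return ind


def step_cycle(
    ind: Individual,
    strategy,
    params: ParameterSet,
    models: SimulationModels,
    u4: np.ndarray,
    cycle_index: int,
) -> tuple[Individual, str | None]:
    """One annual update of *ind*; returns (ind, event) with event in
    {'death', 'hip', 'vertebral', 'other', None}.

    Consumes exactly the four uniforms in ``u4`` (death, fracture, site,
    bedridden) whether or not each draw is reached, keeping streams aligned
    with the vectorized engine.
    """
    if not ind.alive:
        raise ParameterError("step_cycle called on a dead individual")
    treatment = _resolve_strategy(strategy, params)
    if cycle_index == 0:
        apply_treatment_effect(ind, treatment, cycle_index)
    elif params.analysis.annual_bmd_decline:
        ind.bmd = max(ind.bmd - params.analysis.annual_bmd_decline, 1e-6)

    age = ind.current_age
    u_death, u_frac, u_site, u_bed = (float(x) for x in u4)

    # --- death first: decedents accrue nothing this cycle
    last_hip = ind.last_fracture_cycle["hip"]
    ysf = (cycle_index - last_hip - 1) if last_hip != _NEVER else None
    from .natural_history import annual_death_prob  # local import, no cycle

    p_death = annual_death_prob(models.mortality, age, ysf, ind.bedridden)
    if u_death < p_death:
        ind.alive = False
        ind.state = "dead"
        return ind, "death"

    # --- fracture competing risks (bedridden individuals are not at risk)
    event: str | None = None
    if not ind.bedridden:
        from .natural_history import adjust_for_history

        probs = {}
        for site in FRACTURE_SITES:
            p = models.incidence[site].annual_prob(age, ind.bmd)
            probs[site] = float(
                adjust_for_history(p, ind.any_prior_fracture, params.fracture_risk, site)
            )
        p_any = 1.0 - math.prod(1.0 - p for p in probs.values())
        if p_any > 0.0 and u_frac < p_any:
            total = sum(probs.values())
            cum = 0.0
            for site in FRACTURE_SITES:
                cum += probs[site] / total
                if u_site < cum:
                    event = site
                    break
            else:  # numerical guard
                event = FRACTURE_SITES[-1]

    new_bedridden = False
    if event == "hip" and u_bed < params.fracture_risk.p_bedridden_after_hip:
        new_bedridden = True

    # --- bookkeeping
    if event is not None:
        ind.fracture_counts[event] += 1
        ind.last_fracture_cycle[event] = cycle_index
        ind.years_since_last_fracture = 0.0
    elif ind.years_since_last_fracture is not None:
        ind.years_since_last_fracture += 1.0
    ind.complex_fracture_flag = ind.total_fractures >= 2
    ind.bedridden = ind.bedridden or new_bedridden

    if ind.bedridden:
        ind.state = "bedridden"
    elif event is not None:
        ind.state = f"acute_fracture({event})"
    elif ind.any_prior_fracture:
        # most recent site defines the post-fracture label
        site = max(FRACTURE_SITES, key=lambda s: ind.last_fracture_cycle[s])
        ind.state = f"post_fracture({site})"
    else:
        ind.state = "no_fracture"

    # --- accrual
    cost = economics.cycle_cost(
        event,
        ind.bedridden,
        ind.any_prior_fracture,
        treatment,
        params.costs,
        params.analysis,
        cycle_index,
    )
    utility = economics.cycle_utility(
        age,
        ind.bedridden,
        {s: ind.last_fracture_cycle[s] == cycle_index for s in FRACTURE_SITES},
        {s: ind.fracture_counts[s] > 0 for s in FRACTURE_SITES},
        params.utilities,
    )
    df_c = 1.0 / (1.0 + params.analysis.discount_rate_cost) ** (cycle_index + 1)
    df_q = 1.0 / (1.0 + params.analysis.discount_rate_qaly) ** (cycle_index + 1)
    ind.discounted_cost += cost * df_c
    ind.discounted_qalys += utility * df_q
    ind.current_age = age + 1.0
    return ind, event


def simulate_individual(
    entry_age: int,
    strategy,
    params: ParameterSet,
    models: SimulationModels,
    rng: np.random.Generator | None = None,
    randoms: CohortRandoms | None = None,
    index: int = 0,
) -> Trajectory:
    """Simulate one woman to death, recording her full trajectory.

    Randomness comes either from ``rng`` (a fresh uniform block is drawn) or
    from row ``index`` of a shared :class:`CohortRandoms` block.
    """
    band = params.band_for_age(entry_age)
    T = _n_cycles(entry_age, params.analysis.max_age)
    if randoms is None:
        if rng is None:
            raise ParameterError("supply rng or randoms")
        randoms = CohortRandoms(bmd_u=rng.uniform(size=1), u=rng.uniform(size=(1, T, 4)))
        index = 0
    bmd0 = float(sample_bmd(band, np.array([randoms.bmd_u[index]]))[0])
    ind = Individual(current_age=float(entry_age), bmd=bmd0, entry_age=float(entry_age))
    traj = Trajectory()
    treatment = _resolve_strategy(strategy, params)

    for t in range(randoms.n_cycles):
        age_before = ind.current_age
        ind, event = step_cycle(ind, treatment, params, models, randoms.u[index, t], t)
        if event == "death":
            traj.records.append(
                CycleRecord(age_before, "dead", "death", 0.0, 0.0, 0.0, 0.0)
            )
            break
        rec_cost = economics.cycle_cost(
            None if event is None else event,
            ind.bedridden,
            ind.any_prior_fracture,
            treatment,
            params.costs,
            params.analysis,
            t,
        )
        df_c = 1.0 / (1.0 + params.analysis.discount_rate_cost) ** (t + 1)
        df_q = 1.0 / (1.0 + params.analysis.discount_rate_qaly) ** (t + 1)
        utility = economics.cycle_utility(
            age_before,
            ind.bedridden,
            {s: ind.last_fracture_cycle[s] == t for s in FRACTURE_SITES},
            {s: ind.fracture_counts[s] > 0 for s in FRACTURE_SITES},
            params.utilities,
        )
        traj.records.append(
            CycleRecord(age_before, ind.state, event, rec_cost, utility, df_c, df_q)
        )
        traj.years_survived += 1
        for s in FRACTURE_SITES:
            traj.ever_fractured[s] = traj.ever_fractured[s] or ind.fracture_counts[s] > 0

    traj.discounted_cost = ind.discounted_cost
    traj.discounted_qalys = ind.discounted_qalys
    return traj


# ---------------------------------------------------------------------------
# Vectorized cohort engine
# ---------------------------------------------------------------------------


@dataclass
class StrategyResult:
    """Cohort summary for one strategy."""

    strategy: str
    label: str
    entry_age: int
    n: int
    mean_cost: float
    mean_qalys: float
    sd_cost: float
    sd_qalys: float
    prop_fracture: dict[str, float]
    prop_any_fracture: float
    mean_years_survived: float
    sd_years_survived: float
    events_by_cycle: dict[str, np.ndarray]
    at_risk_by_cycle: np.ndarray
    # per-individual totals, retained for paired (CRN) contrasts
    costs: np.ndarray | None = None
    qalys: np.ndarray | None = None

    @classmethod
    def from_summary(
        cls,
        strategy: str,
        mean_cost: float,
        mean_qalys: float,
        entry_age: int = 55,
        n: int = 1,
        label: str | None = None,
        prop_fracture: dict[str, float] | None = None,
    ) -> "StrategyResult":
        """Build a summary-only result, e.g. from a published table, so that
        the ICER arithmetic can be applied to external numbers."""
        prop = prop_fracture or {s: math.nan for s in FRACTURE_SITES}
        return cls(
            strategy=strategy,
            label=label or strategy,
            entry_age=entry_age,
            n=n,
            mean_cost=mean_cost,
            mean_qalys=mean_qalys,
            sd_cost=0.0,
            sd_qalys=0.0,
            prop_fracture=prop,
            prop_any_fracture=math.nan,
            mean_years_survived=math.nan,
            sd_years_survived=0.0,
            events_by_cycle={s: np.zeros(1, dtype=np.int64) for s in FRACTURE_SITES},
            at_risk_by_cycle=np.zeros(1, dtype=np.int64),
        )

    @property
    def se_cost(self) -> float:
        return self.sd_cost / math.sqrt(self.n)

    @property
    def se_qalys(self) -> float:
        return self.sd_qalys / math.sqrt(self.n)

    @property
    def se_years_survived(self) -> float:
        return self.sd_years_survived / math.sqrt(self.n)


def run_cohort(
    n: int,
    entry_age: int,
    strategy,
    params: ParameterSet,
    models: SimulationModels,
    seed: int | None = None,
    randoms: CohortRandoms | None = None,
    keep_individual_totals: bool = True,
) -> StrategyResult:
    """Simulate *n* independent women under one strategy (vectorized).

    Pass the same ``seed`` (or the same pre-drawn ``randoms``) for every
    strategy to obtain common random numbers: individual *i* then has the
    same baseline BMD and the same event uniforms under every strategy.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    treatment = _resolve_strategy(strategy, params)
    band = params.band_for_age(entry_age)
    T = _n_cycles(entry_age, params.analysis.max_age)
    if randoms is None:
        if seed is None:
            raise ParameterError("supply seed or randoms")
        randoms = CohortRandoms.draw(seed, n, T)
    if randoms.n != n or randoms.n_cycles < T:
        raise ParameterError("randoms block does not match (n, n_cycles)")

    A = params.analysis
    FR = params.fracture_risk
    U = params.utilities
    C = params.costs
    lt = models.mortality.life_table
    excess_rr = models.mortality.excess_hip_rr
    excess_dur = models.mortality.excess_duration
    decline = A.annual_bmd_decline

    bmd = sample_bmd(band, randoms.bmd_u).astype(float)
    bmd = bmd + treatment.bmd_increment  # course completes within cycle 0

    alive = np.ones(n, dtype=bool)
    bedridden = np.zeros(n, dtype=bool)
    last_frac = {s: np.full(n, _NEVER, dtype=np.int64) for s in FRACTURE_SITES}
    ever = {s: np.zeros(n, dtype=bool) for s in FRACTURE_SITES}
    any_frac = np.zeros(n, dtype=bool)
    cost_total = np.zeros(n)
    qaly_total = np.zeros(n)
    years = np.zeros(n, dtype=np.int64)
    events_by_cycle = {s: np.zeros(T, dtype=np.int64) for s in FRACTURE_SITES}
    at_risk_by_cycle = np.zeros(T, dtype=np.int64)

    mult_y1 = {s: U.multipliers(s)[0] for s in FRACTURE_SITES}
    mult_later = {s: U.multipliers(s)[1] for s in FRACTURE_SITES}
    rr_hist = {s: FR.rr_for_site(s) for s in FRACTURE_SITES}
    drug0 = economics.drug_cost_cycle0(treatment, A)

    for t in range(T):
        if not alive.any():
            break
        age = entry_age + t
        if t >= 1 and decline:
            np.maximum(bmd - decline, 1e-6, out=bmd)

        # death draw (uniform 0)
        q = float(lt.q(age))
        ysf = t - last_frac["hip"] - 1  # completed years since hip event
        recent_hip = ever["hip"] & (ysf >= 0) & (ysf < excess_dur)
        p_death = np.where(bedridden | recent_hip, min(q * excess_rr, 1.0), q)
        dying = alive & (randoms.u[:, t, 0] < p_death)
        alive = alive & ~dying
        if not alive.any():
            break

        # fracture draw (uniforms 1, 2); bedridden are not at risk
        at_risk = alive & ~bedridden
        at_risk_by_cycle[t] = int(at_risk.sum())
        p_site = {}
        for s in FRACTURE_SITES:
            p = models.incidence[s].annual_prob(age, bmd)
            p_site[s] = np.clip(np.where(any_frac, p * rr_hist[s], p), 0.0, 1.0)
        p_any = 1.0 - (1.0 - p_site["hip"]) * (1.0 - p_site["vertebral"]) * (
            1.0 - p_site["other"]
        )
        frac = at_risk & (randoms.u[:, t, 1] < p_any)
        total = p_site["hip"] + p_site["vertebral"] + p_site["other"]
        total = np.where(total > 0, total, 1.0)
        c_hip = p_site["hip"] / total
        c_vert = c_hip + p_site["vertebral"] / total
        u_site = randoms.u[:, t, 2]
        ev = {
            "hip": frac & (u_site < c_hip),
            "vertebral": frac & (u_site >= c_hip) & (u_site < c_vert),
            "other": frac & (u_site >= c_vert),
        }

        # bedridden draw (uniform 3)
        new_bed = ev["hip"] & (randoms.u[:, t, 3] < FR.p_bedridden_after_hip)
        bedridden = bedridden | new_bed

        # bookkeeping
        any_event = np.zeros(n, dtype=bool)
        for s in FRACTURE_SITES:
            events_by_cycle[s][t] = int(ev[s].sum())
            last_frac[s][ev[s]] = t
            ever[s] = ever[s] | ev[s]
            any_event |= ev[s]
        any_frac = any_frac | any_event

        # accrual for survivors
        cost = np.where(alive, C.annual_medical_cost, 0.0) if A.medical_cost_all_alive else (
            np.where(alive & (any_frac | any_event), C.annual_medical_cost, 0.0)
        )
        for s in FRACTURE_SITES:
            cost = cost + np.where(ev[s], C.fracture_cost(s), 0.0)
        cost = cost + np.where(alive & bedridden, C.annual_bedridden_cost, 0.0)
        if t == 0:
            cost = cost + np.where(alive, drug0, 0.0)

        util = np.full(n, U.baseline_utility(age))
        for s in FRACTURE_SITES:
            m = np.where(last_frac[s] == t, mult_y1[s], mult_later[s])
            util = util * np.where(ever[s], m, 1.0)
        util = np.where(bedridden, U.bedridden_utility, util)

        df_c = 1.0 / (1.0 + A.discount_rate_cost) ** (t + 1)
        df_q = 1.0 / (1.0 + A.discount_rate_qaly) ** (t + 1)
        cost_total += np.where(alive, cost, 0.0) * df_c
        qaly_total += np.where(alive, util, 0.0) * df_q
        years += alive

    prop = {s: float(ever[s].mean()) for s in FRACTURE_SITES}
    return StrategyResult(
        strategy=treatment.name if isinstance(strategy, TreatmentParams) else str(strategy),
        label=treatment.name,
        entry_age=int(entry_age),
        n=n,
        mean_cost=float(cost_total.mean()),
        mean_qalys=float(qaly_total.mean()),
        sd_cost=float(cost_total.std(ddof=1)) if n > 1 else 0.0,
        sd_qalys=float(qaly_total.std(ddof=1)) if n > 1 else 0.0,
        prop_fracture=prop,
        prop_any_fracture=float(any_frac.mean()),
        mean_years_survived=float(years.mean()),
        sd_years_survived=float(years.std(ddof=1)) if n > 1 else 0.0,
        events_by_cycle=events_by_cycle,
        at_risk_by_cycle=at_risk_by_cycle,
        costs=cost_total if keep_individual_totals else None,
        qalys=qaly_total if keep_individual_totals else None,
    )
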