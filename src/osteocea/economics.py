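"""Per-cycle cost and utility accrual with discounting.

Costs (2022 USD) accrue per annual cycle: a background annual medical cost
for every alive cycle (configurable to post-fracture-only), a one-off
site-specific treatment cost in a fracture-event cycle, annual bedridden
care while bedridden, and the drug acquisition cost in cycle 0 of an active
strategy (annual price x treatment time by default).

Utility for a cycle is the age-band baseline weight multiplied by the
disutility multipliers of every fracture site in the individual's history —
the first-year multiplier in the event cycle, the later-years multiplier
afterwards; multipliers for distinct sites stack multiplicatively.  The
bedridden state overrides everything with a flat weight, and the dead accrue
zero.

Discounting uses the end-of-cycle convention: cycle t is divided by
(1 + r)^(t + 1).
"""

from __future__ import annotations

from dataclasses import dataclass

from .parameters import (
    AnalysisSettings,
    CostParams,
    FRACTURE_SITES,
    TreatmentParams,
    UtilityParams,
)

__all__ = ["CyclePayoff", "cycle_cost", "cycle_utility", "discount", "drug_cost_cycle0"]


@dataclass(frozen=True)
class CyclePayoff:
    """Undiscounted payoffs of one cycle plus the factors applied to them."""

    cost: float
    utility: float
    discount_factor_cost: float
    discount_factor_qaly: float

    @property
    def discounted_cost(self) -> float:
        return self.cost * self.discount_factor_cost

    @property
    def discounted_qalys(self) -> float:
        return self.utility * self.discount_factor_qaly


def discount(value: float, rate: float, cycle_index: int) -> float:
    """End-of-cycle discounting: value / (1 + rate)^(cycle_index + 1)."""
    if rate < 0:
        raise ValueError("discount rate must be >= 0")
    return value / (1.0 + rate) ** (cycle_index + 1)


def drug_cost_cycle0(treatment: TreatmentParams, settings: AnalysisSettings) -> float:
    """Drug acquisition cost charged in cycle 0.

    Default: annual price pro-rated over the treatment course (6 months of
    the stated annual cost); ``settings.full_annual_drug_cost`` switches to
    the full annual price.
    """
    if settings.full_annual_drug_cost:
        return treatment.annual_drug_cost
    return treatment.annual_drug_cost * treatment.treatment_time


def cycle_cost(
    event: str | None,
    bedridden: bool,
    any_prior_fracture: bool,
    treatment: TreatmentParams,
    costs: CostParams,
    settings: AnalysisSettings,
    cycle_index: int,
) -> float:
    """Undiscounted cost of one alive cycle.

    ``event`` is a fracture site or ``None``; ``bedridden`` reflects the
    state during the cycle (a new bedridden transition counts).  The dead
    accrue nothing — callers do not invoke this for death cycles.
    """
    total = 0.0
    if settings.medical_cost_all_alive or any_prior_fracture or event is not None:
        total += costs.annual_medical_cost
    if event is not None:
        if event not in FRACTURE_SITES:
            raise ValueError(f"unknown fracture site {event!r}")
        total += costs.fracture_cost(event)
    if bedridden:
        total += costs.annual_bedridden_cost
    if cycle_index == 0:
        total += drug_cost_cycle0(treatment, settings)
    return total


def cycle_utility(
    age: float,
    bedridden: bool,
    site_fractured_this_cycle: dict[str, bool],
    site_ever_fractured: dict[str, bool],
    utilities: UtilityParams,
) -> float:
    """QALY weight of one alive cycle.

    Bedridden overrides with the flat bedridden utility.  Otherwise the
    age-band baseline is multiplied, per site with any history, by the
    first-year multiplier when that site's most recent fracture is this
    cycle and the later-years multiplier otherwise.
    """
    if bedridden:
        return utilities.bedridden_utility
    u = utilities.baseline_utility(age)
    for site in FRACTURE_SITES:
        if not site_ever_fractured.get(site, False):
            continue
        y1, later = utilities.multipliers(site)
        u *= y1 if site_fractured_this_cycle.get(site, False) else later
    return u
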