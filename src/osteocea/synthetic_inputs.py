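"""Synthetic stand-ins for model inputs that have no public machine-readable source.

Three inputs of the decision model come from external epidemiology rather
than from the printed parameter tables: the female life table, the excess
post-hip-fracture mortality ratio, and the age-specific fracture-incidence
curves used to calibrate the fracture model.  This module generates plausible
stand-ins with the structural properties the model relies on — mortality
monotone-increasing in age, fracture hazard increasing with age and
decreasing with BMD — so that every downstream stage is runnable and testable
without any download.  Users with real data supply it through the same CSV
formats these generators write.

The default generator settings define the package's synthetic baseline
scenario; they are documented, with rationale, in ``docs/methods.md``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .parameters import BmdAgeBand, ParameterError

__all__ = [
    "LifeTable",
    "IncidenceTargets",
    "make_life_table",
    "make_incidence_targets",
    "make_test_population",
    "default_life_table",
    "default_incidence_targets",
    "DEFAULT_EXCESS_HIP_MORTALITY_RR",
]

START_AGE = 55

#: Synthetic default for the mortality risk ratio in the year after a hip
#: fracture (applied lifelong while bedridden); order of magnitude of
#: published first-year post-hip-fracture relative mortality in older women.
DEFAULT_EXCESS_HIP_MORTALITY_RR = 2.5


@dataclass
class LifeTable:
    """Annual death probabilities q(age) for ages ``start..max_age``."""

    ages: np.ndarray
    annual_death_prob: np.ndarray

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=int)
        self.annual_death_prob = np.asarray(self.annual_death_prob, dtype=float)
        q = self.annual_death_prob
        if q.shape != self.ages.shape:
            raise ParameterError("ages and annual_death_prob must align")
        if np.any((q < 0) | (q > 1)):
            raise ParameterError("death probabilities must lie in [0, 1]")
        if np.any(np.diff(q) < 0):
            raise ParameterError("annual death probability must be non-decreasing in age")
        if q[-1] != 1.0:
            raise ParameterError("terminal age must have death probability 1")

    @property
    def max_age(self) -> int:
        return int(self.ages[-1])

    def q(self, age) -> np.ndarray | float:
        """Annual death probability; ages beyond the table return 1."""
        age = np.asarray(age)
        idx = np.clip(age - self.ages[0], 0, len(self.ages) - 1).astype(int)
        out = np.where(age > self.ages[-1], 1.0, self.annual_death_prob[idx])
        out = np.where(age < self.ages[0], self.annual_death_prob[0], out)
        return out if out.ndim else float(out)

    def life_expectancy(self, entry_age: int) -> float:
        """Closed-form expected number of whole years survived from entry.

        An individual who dies in her first cycle survives 0 years; the
        expectation is the sum of cumulative survival products.
        """
        q = np.array([self.q(a) for a in range(entry_age, self.max_age + 1)])
        surv = np.cumprod(1.0 - q)
        return float(surv.sum())

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"age": self.ages, "value": self.annual_death_prob}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "LifeTable":
        df = pd.read_csv(path)
        return cls(df["age"].to_numpy(), df["value"].to_numpy())


@dataclass
class IncidenceTargets:
    """Age-specific annual fracture incidence points for one site.

    The targets apply to an average woman with BMD equal to
    ``reference_bmd``; calibration spreads them over the band's BMD
    distribution.
    """

    site: str
    points: list[tuple[float, float]] = field(default_factory=list)
    reference_bmd: float = 0.73

    def __post_init__(self) -> None:
        for age, inc in self.points:
            if not 0.0 < inc < 1.0:
                raise ParameterError(f"incidence {inc} at age {age} outside (0, 1)")
        if self.site == "hip":
            incs = [inc for _, inc in sorted(self.points)]
            if any(b < a for a, b in zip(incs, incs[1:])):
                raise ParameterError("hip incidence targets must be non-decreasing in age")

    @property
    def ages(self) -> np.ndarray:
        return np.array([a for a, _ in self.points], dtype=float)

    @property
    def incidences(self) -> np.ndarray:
        return np.array([i for _, i in self.points], dtype=float)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"age": self.ages, "value": self.incidences}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, site: str, reference_bmd: float) -> "IncidenceTargets":
        df = pd.read_csv(path)
        return cls(site, list(zip(df["age"], df["value"])), reference_bmd)


def make_life_table(
    base_rate: float = 0.004,
    doubling_time: float = 8.0,
    max_age: int = 100,
    start_age: int = START_AGE,
) -> LifeTable:
    """Gompertz-form life table: q(a) = min(1, base_rate * 2^((a-start)/doubling)).

    The terminal entry is forced to 1 so the horizon is finite.
    """
    if not 0.0 < base_rate < 1.0:
        raise ParameterError("base_rate must lie in (0, 1)")
    if doubling_time <= 0:
        raise ParameterError("doubling_time must be > 0")
    ages = np.arange(start_age, max_age + 1)
    q = np.minimum(1.0, base_rate * 2.0 ** ((ages - start_age) / doubling_time))
    q[-1] = 1.0
    return LifeTable(ages, q)


def make_incidence_targets(
    site: str,
    anchor_incidence: float,
    log_slope: float,
    ages: list[int] | np.ndarray,
    reference_bmd: float = 0.73,
) -> IncidenceTargets:
    """Exponential-in-age incidence targets anchored at age 55.

    ``incidence(a) = anchor * exp(log_slope * (a - 55))``, capped below 1.
    """
    if not 0.0 < anchor_incidence < 1.0:
        raise ParameterError("anchor_incidence must lie in (0, 1)")
    pts = []
    for a in ages:
        inc = anchor_incidence * math.exp(log_slope * (a - START_AGE))
        pts.append((float(a), min(inc, 1.0 - 1e-12)))
    return IncidenceTargets(site, pts, reference_bmd)


# Synthetic baseline incidence scenario at the 55-59 band reference BMD:
# hip fracture risk doubling every 9 years from 5/10,000 at 55, vertebral
# from 4.5/1,000 doubling every 25 years, other fractures from 3/1,000
# doubling every 20 years.  Levels are set so a no-treatment cohort entering
# at 55 accumulates lifetime fracture probabilities of the magnitude the
# published base case reports (~7% hip, ~21% vertebral).
_DEFAULT_INCIDENCE = {
    "hip": (5e-4, math.log(2) / 9.0),
    "vertebral": (4.5e-3, math.log(2) / 25.0),
    "other": (3e-3, math.log(2) / 20.0),
}


def default_incidence_targets(
    reference_bmd: float = 0.73, ages: list[int] | None = None
) -> dict[str, IncidenceTargets]:
    """The synthetic baseline incidence targets for all three sites."""
    if ages is None:
        ages = list(range(55, 86, 5))
    return {
        site: make_incidence_targets(site, anchor, slope, ages, reference_bmd)
        for site, (anchor, slope) in _DEFAULT_INCIDENCE.items()
    }


def default_life_table(max_age: int = 100) -> LifeTable:
    return make_life_table(max_age=max_age)


def make_test_population(n: int, band: BmdAgeBand, rng: np.random.Generator):
    """n fracture-free individuals at the band's lower age.

    BMD is drawn from Normal(mean, sd) truncated below at zero, via the
    inverse CDF so each individual consumes exactly one uniform.
    Returns a list of :class:`osteocea.microsim.Individual`.
    """
    from .microsim import Individual  # deferred: avoids a module cycle

    if n < 1:
        raise ParameterError("n must be >= 1")
    bmd = sample_bmd(band, rng.uniform(size=n))
    return [
        Individual(current_age=float(band.age_low), bmd=float(b), entry_age=float(band.age_low))
        for b in bmd
    ]


def sample_bmd(band: BmdAgeBand, u: np.ndarray) -> np.ndarray:
    """Inverse-CDF truncated-normal (at zero) BMD draws from uniforms."""
    if band.sd_bmd == 0:
        return np.full_like(np.asarray(u, dtype=float), band.mean_bmd)
    a = (0.0 - band.mean_bmd) / band.sd_bmd
    return stats.truncnorm.ppf(u, a, np.inf, loc=band.mean_bmd, scale=band.sd_bmd)
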