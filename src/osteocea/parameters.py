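"""Model inputs: base values, sensitivity ranges and uncertainty distributions.

Every input of the decision model lives here, typed and validated: femoral-neck
BMD distributions by starting-age band, fracture relative risks, treatment
effects and drug costs, health-state costs, utilities, and analysis settings
(discount rates, willingness-to-pay threshold, cohort sizes).  Each uncertain
scalar carries two distinct pieces of sensitivity metadata:

* a deterministic sensitivity range ``(dsa_low, dsa_high)`` used by one-way
  sweeps, and
* a :class:`DistributionSpec` used by probabilistic sensitivity analysis.

The two are carried separately because they do not always coincide: the
bedridden-after-hip-fracture probability, for example, has a published range
but is held fixed in probabilistic analysis.

The shipped defaults (2022 USD) are read from ``data/default_parameters.yaml``
and can be overridden through :func:`load_parameters`.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, fields as dc_fields
from importlib import resources
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import yaml

__all__ = [
    "DistributionSpec",
    "BmdAgeBand",
    "FractureRiskParams",
    "TreatmentParams",
    "CostParams",
    "UtilityParams",
    "AnalysisSettings",
    "ParameterSet",
    "ParameterDef",
    "PARAMETER_MANIFEST",
    "default_parameters",
    "load_parameters",
    "write_parameters",
    "sample_parameter",
    "sample_psa_parameter_set",
    "get_value",
    "set_value",
]

_Z975 = 1.959963984540054  # standard normal 97.5% quantile

FRACTURE_SITES = ("hip", "vertebral", "other")


class ParameterError(ValueError):
    """Raised when a parameter value or configuration violates an invariant."""


# ---------------------------------------------------------------------------
# Distribution machinery
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DistributionSpec:
    """Uncertainty distribution of one scalar parameter.

    Parameters
    ----------
    family
        One of ``fixed``, ``log_normal``, ``beta``, ``triangular``.
    base_value
        Point estimate (median for log-normal, mode for triangular, mean for
        beta).
    low, high
        For ``triangular``: the support endpoints.  For ``log_normal`` and
        ``beta``: interpreted as a central 95% interval around the point
        estimate.  For ``fixed``: both equal ``base_value``.
    support
        Bounded support for the beta family; quantities already in [0, 1]
        use the default, others (BMD increments) are rescaled.
    """

    family: str
    base_value: float
    low: float
    high: float
    support: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        if self.family not in ("fixed", "log_normal", "beta", "triangular"):
            raise ParameterError(f"unknown distribution family {self.family!r}")
        if self.family == "fixed":
            if not (self.low == self.high == self.base_value):
                raise ParameterError(
                    "fixed distribution requires low == high == base_value, "
                    f"got ({self.low}, {self.base_value}, {self.high})"
                )
        else:
            if not (self.low <= self.base_value <= self.high):
                raise ParameterError(
                    f"{self.family}: need low <= base <= high, got "
                    f"({self.low}, {self.base_value}, {self.high})"
                )
        if self.family == "beta":
            lo, hi = self.support
            if not (lo <= self.low and self.high <= hi):
                raise ParameterError(
                    f"beta range ({self.low}, {self.high}) outside support {self.support}"
                )
        if self.family == "log_normal" and self.low <= 0:
            raise ParameterError("log_normal requires a strictly positive lower bound")

    # -- fitted shape ------------------------------------------------------

    def lognormal_mu_sigma(self) -> tuple[float, float]:
        """(mu, sigma) on the log scale: median = base, (low, high) = 95% CI."""
        mu = math.log(self.base_value)
        sigma = (math.log(self.high) - math.log(self.low)) / (2.0 * _Z975)
        return mu, sigma

    def beta_shapes(self) -> tuple[float, float]:
        """Method-of-moments (a, b) on the rescaled support.

        The mean is the base value and the standard deviation is derived from
        (low, high) treated as a central 95% interval.
        """
        lo, hi = self.support
        span = hi - lo
        m = (self.base_value - lo) / span
        sd = (self.high - self.low) / (2.0 * _Z975) / span
        v = sd * sd
        if v <= 0:
            raise ParameterError("beta fit needs a positive-width range")
        if v >= m * (1.0 - m):
            raise ParameterError(
                "beta fit infeasible: variance too large for the mean; "
                "shrink the (low, high) range or widen the support"
            )
        nu = m * (1.0 - m) / v - 1.0
        return m * nu, (1.0 - m) * nu


def sample_parameter(spec: DistributionSpec, rng: np.random.Generator) -> float:
    """Draw one value from *spec* using *rng*.

    ``fixed`` returns the base value without consuming randomness; degenerate
    triangulars (low == high) likewise collapse to the base value.
    """
    if spec.family == "fixed":
        return spec.base_value
    if spec.family == "triangular":
        if spec.low == spec.high:
            return spec.base_value
        x = rng.triangular(spec.low, spec.base_value, spec.high)
    elif spec.family == "log_normal":
        mu, sigma = spec.lognormal_mu_sigma()
        x = rng.lognormal(mu, sigma)
    elif spec.family == "beta":
        a, b = spec.beta_shapes()
        lo, hi = spec.support
        x = lo + (hi - lo) * rng.beta(a, b)
    else:  # pragma: no cover - guarded in __post_init__
        raise ParameterError(spec.family)
    if not math.isfinite(x):
        raise ParameterError(f"non-finite draw from {spec}")
    return float(x)


# ---------------------------------------------------------------------------
# Typed parameter groups
# ---------------------------------------------------------------------------


@dataclass
class BmdAgeBand:
    """Femoral-neck BMD distribution for one starting-age band (g/cm^2)."""

    age_low: int
    age_high: int
    mean_bmd: float
    sd_bmd: float
    n: int = 0  # survey sample size, documentation only

    def validate(self) -> None:
        if self.mean_bmd <= 0:
            raise ParameterError(f"band {self.age_low}-{self.age_high}: mean_bmd must be > 0")
        if self.sd_bmd <= 0:
            raise ParameterError(f"band {self.age_low}-{self.age_high}: sd_bmd must be > 0")
        if self.age_high < self.age_low:
            raise ParameterError("age_high < age_low")


@dataclass
class FractureRiskParams:
    rr_prior_fracture_hip: float = 1.97
    rr_prior_fracture_vertebral: float = 1.91
    rr_prior_fracture_other: float = 1.91
    p_bedridden_after_hip: float = 0.136

    def rr_for_site(self, site: str) -> float:
        try:
            return getattr(self, f"rr_prior_fracture_{site}")
        except AttributeError:
            raise ParameterError(f"unknown fracture site {site!r}") from None

    def validate(self) -> None:
        for site in FRACTURE_SITES:
            if self.rr_for_site(site) < 1.0:
                raise ParameterError(f"rr_prior_fracture_{site} must be >= 1")
        if not 0.0 <= self.p_bedridden_after_hip <= 1.0:
            raise ParameterError(
                f"p_bedridden_after_hip={self.p_bedridden_after_hip} outside [0, 1]"
            )


@dataclass
class TreatmentParams:
    name: str
    bmd_increment: float
    treatment_time: float
    annual_drug_cost: float

    def validate(self) -> None:
        if self.bmd_increment < 0:
            raise ParameterError(f"{self.name}: bmd_increment must be >= 0")
        if self.treatment_time <= 0:
            raise ParameterError(f"{self.name}: treatment_time must be > 0")
        if self.annual_drug_cost < 0:
            raise ParameterError(f"{self.name}: annual_drug_cost must be >= 0")


@dataclass
class CostParams:
    annual_medical_cost: float = 439.78
    cost_hip_fracture: float = 7379.82
    cost_vertebral_fracture: float = 1361.12
    cost_other_fracture: float = 1758.30
    annual_bedridden_cost: float = 4948.90

    def fracture_cost(self, site: str) -> float:
        try:
            return getattr(self, f"cost_{site}_fracture")
        except AttributeError:
            raise ParameterError(f"unknown fracture site {site!r}") from None

    def validate(self) -> None:
        for f in dc_fields(self):
            if getattr(self, f.name) < 0:
                raise ParameterError(f"{f.name} must be >= 0")


@dataclass
class UtilityParams:
    """Age-band baseline utilities and post-fracture disutility multipliers.

    Multipliers < 1 scale the baseline utility in years affected by a
    fracture; the first-year multiplier applies in the event cycle, the
    later-years multiplier in every subsequent cycle after that site's most
    recent fracture.  The bedridden state carries a flat utility.
    """

    baseline_utility_by_age: dict[str, float] = field(
        default_factory=lambda: {
            "55-59": 0.88,
            "60-65": 0.869,
            "66-70": 0.827,
            "71-74": 0.808,
        }
    )
    hip_multiplier_year1: float = 0.776
    hip_multiplier_later: float = 0.855
    vertebral_multiplier_year1: float = 0.724
    vertebral_multiplier_later: float = 0.868
    other_multiplier_year1: float = 0.910
    other_multiplier_later: float = 1.0
    bedridden_utility: float = 0.192

    def baseline_utility(self, age: float) -> float:
        """Band lookup; ages past the last band keep its utility."""
        if age < 60:
            return self.baseline_utility_by_age["55-59"]
        if age < 66:
            return self.baseline_utility_by_age["60-65"]
        if age < 71:
            return self.baseline_utility_by_age["66-70"]
        return self.baseline_utility_by_age["71-74"]

    def multipliers(self, site: str) -> tuple[float, float]:
        """(first-year, later-years) multiplier for a fracture site."""
        try:
            return (
                getattr(self, f"{site}_multiplier_year1"),
                getattr(self, f"{site}_multiplier_later"),
            )
        except AttributeError:
            raise ParameterError(f"unknown fracture site {site!r}") from None

    def validate(self) -> None:
        vals = dict(self.baseline_utility_by_age)
        vals.update(
            {
                f.name: getattr(self, f.name)
                for f in dc_fields(self)
                if f.name != "baseline_utility_by_age"
            }
        )
        for name, v in vals.items():
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"utility {name}={v} outside [0, 1]")
        for site in FRACTURE_SITES:
            y1, later = self.multipliers(site)
            if y1 > later:
                raise ParameterError(
                    f"{site}: first-year multiplier {y1} exceeds later-years {later}"
                )


@dataclass
class AnalysisSettings:
    discount_rate_cost: float = 0.03
    discount_rate_qaly: float = 0.03
    wtp_threshold: float = 38_223.0
    n_individuals: int = 100_000
    n_psa_iterations: int = 1_000
    max_age: int = 100
    rng_seed: int = 0
    # configurable modelling assumptions (defaults documented in the methods
    # note): untreated annual BMD decline; whether the annual medical cost
    # applies to every alive cycle or only post-fracture; whether the drug
    # cost is the full annual price or pro-rated over the treatment course.
    annual_bmd_decline: float = 0.0
    medical_cost_all_alive: bool = True
    full_annual_drug_cost: bool = False

    def validate(self) -> None:
        for name in ("discount_rate_cost", "discount_rate_qaly"):
            r = getattr(self, name)
            if not 0.0 <= r <= 0.05:
                raise ParameterError(f"{name}={r} outside [0, 0.05]")
        if self.wtp_threshold <= 0:
            raise ParameterError("wtp_threshold must be > 0")
        if self.n_individuals < 1:
            raise ParameterError("n_individuals must be >= 1")
        if self.max_age <= 55:
            raise ParameterError("max_age must exceed the entry ages")
        if self.annual_bmd_decline < 0:
            raise ParameterError("annual_bmd_decline must be >= 0")


# ---------------------------------------------------------------------------
# The full parameter set
# ---------------------------------------------------------------------------


@dataclass
class ParameterSet:
    bmd_bands: list[BmdAgeBand]
    fracture_risk: FractureRiskParams
    treatments: dict[str, TreatmentParams]
    costs: CostParams
    utilities: UtilityParams
    analysis: AnalysisSettings
    metadata: dict = field(default_factory=dict)

    def validate(self) -> None:
        if not self.bmd_bands:
            raise ParameterError("at least one BMD age band is required")
        bands = sorted(self.bmd_bands, key=lambda b: b.age_low)
        for b in bands:
            b.validate()
        for prev, nxt in zip(bands, bands[1:]):
            if nxt.age_low != prev.age_high + 1:
                raise ParameterError(
                    f"BMD bands must be contiguous and non-overlapping; "
                    f"{prev.age_low}-{prev.age_high} followed by {nxt.age_low}-{nxt.age_high}"
                )
        self.fracture_risk.validate()
        for t in self.treatments.values():
            t.validate()
        self.costs.validate()
        self.utilities.validate()
        self.analysis.validate()

    def band_for_age(self, age: float) -> BmdAgeBand:
        for b in self.bmd_bands:
            if b.age_low <= age <= b.age_high:
                return b
        raise ParameterError(f"no BMD band covers age {age}")

    def copy(self) -> "ParameterSet":
        return copy.deepcopy(self)

    def distributions(self) -> Iterator[tuple[str, DistributionSpec]]:
        """(path, DistributionSpec) for every manifest parameter."""
        for d in PARAMETER_MANIFEST:
            yield d.path, d.spec_for(self)


# -- dotted-path access (dict segments index mappings) ----------------------


def _walk(ps: ParameterSet, path: str):
    parts = path.split(".")
    obj = ps
    for part in parts[:-1]:
        obj = obj[part] if isinstance(obj, Mapping) else getattr(obj, part)
    return obj, parts[-1]


def get_value(ps: ParameterSet, path: str) -> float:
    obj, leaf = _walk(ps, path)
    return obj[leaf] if isinstance(obj, Mapping) else getattr(obj, leaf)


def set_value(ps: ParameterSet, path: str, value: float) -> None:
    obj, leaf = _walk(ps, path)
    if isinstance(obj, Mapping):
        obj[leaf] = value  # type: ignore[index]
    else:
        setattr(obj, leaf, value)


# ---------------------------------------------------------------------------
# Manifest: one entry per printed scalar input
# ---------------------------------------------------------------------------

_BMD_SUPPORT = (0.0, 0.3)  # g/cm^2 support for the beta fit of BMD increments


@dataclass(frozen=True)
class ParameterDef:
    """Sensitivity metadata for one scalar parameter.

    ``dsa_low``/``dsa_high`` bound the one-way deterministic sweep (``None``
    means not swept); ``family`` names the probabilistic distribution, with
    (psa_low, psa_high) defaulting to the DSA range when not given.
    """

    path: str
    label: str
    base: float
    dsa_low: float | None = None
    dsa_high: float | None = None
    family: str = "fixed"
    support: tuple[float, float] = (0.0, 1.0)
    psa_low: float | None = None
    psa_high: float | None = None

    @property
    def swept(self) -> bool:
        # zero-width ranges are legal sweeps (they reproduce the base ICER)
        return self.dsa_low is not None and self.dsa_high is not None

    def spec_for(self, ps: ParameterSet) -> DistributionSpec:
        base = get_value(ps, self.path)
        if self.family == "fixed":
            return DistributionSpec("fixed", base, base, base)
        low = self.psa_low if self.psa_low is not None else self.dsa_low
        high = self.psa_high if self.psa_high is not None else self.dsa_high
        if low is None or high is None:  # pragma: no cover
            raise ParameterError(f"{self.path}: non-fixed family needs a range")
        # Ranges stated as +/-20% scale with the current base value.
        if self.label.endswith("(+/-20%)"):
            low, high = 0.8 * base, 1.2 * base
        return DistributionSpec(self.family, base, low, high, self.support)


def _pm20(path: str, label: str, base: float, family: str = "triangular") -> ParameterDef:
    return ParameterDef(
        path, label + " (+/-20%)", base, round(0.8 * base, 6), round(1.2 * base, 6), family
    )


PARAMETER_MANIFEST: tuple[ParameterDef, ...] = (
    ParameterDef(
        "fracture_risk.rr_prior_fracture_hip",
        "RR hip fracture, prior fracture history",
        1.97, 1.12, 3.48, "log_normal",
    ),
    ParameterDef(
        "fracture_risk.rr_prior_fracture_vertebral",
        "RR vertebral fracture, prior fracture history",
        1.91, 1.50, 2.43, "log_normal",
    ),
    ParameterDef(
        "fracture_risk.rr_prior_fracture_other",
        "RR other fracture, prior fracture history",
        1.91, 1.50, 2.43, "log_normal",
    ),
    # DSA range printed, but held fixed in probabilistic analysis.
    ParameterDef(
        "fracture_risk.p_bedridden_after_hip",
        "Probability of bedridden after hip fracture",
        0.136, 0.095, 0.177, "fixed",
    ),
    ParameterDef(
        "treatments.xianling_gubao.bmd_increment",
        "Xianling Gubao BMD increase (g/cm^2)",
        0.05, 0.01, 0.08, "beta", _BMD_SUPPORT,
    ),
    ParameterDef("treatments.xianling_gubao.treatment_time", "Xianling Gubao treatment time (y)", 0.5),
    ParameterDef(
        "treatments.jintiange.bmd_increment",
        "Jintiange BMD increase (g/cm^2)",
        0.11, 0.03, 0.19, "beta", _BMD_SUPPORT,
    ),
    ParameterDef("treatments.jintiange.treatment_time", "Jintiange treatment time (y)", 0.5),
    _pm20("treatments.xianling_gubao.annual_drug_cost", "Xianling Gubao annual drug cost", 93.24),
    _pm20("treatments.jintiange.annual_drug_cost", "Jintiange annual drug cost", 574.82),
    _pm20("costs.annual_medical_cost", "Annual medical expenses", 439.78),
    _pm20("costs.cost_hip_fracture", "Hip fracture treatment cost", 7379.82),
    _pm20("costs.cost_vertebral_fracture", "Vertebral fracture treatment cost", 1361.12),
    _pm20("costs.cost_other_fracture", "Other fracture treatment cost", 1758.30),
    _pm20("costs.annual_bedridden_cost", "Annual bedridden care expenses", 4948.90),
    ParameterDef(
        "utilities.baseline_utility_by_age.55-59", "Baseline utility 55-59",
        0.88, 0.862, 0.897, "beta",
    ),
    ParameterDef(
        "utilities.baseline_utility_by_age.60-65", "Baseline utility 60-65",
        0.869, 0.852, 0.885, "beta",
    ),
    ParameterDef(
        "utilities.baseline_utility_by_age.66-70", "Baseline utility 66-70",
        0.827, 0.802, 0.851, "beta",
    ),
    ParameterDef(
        "utilities.baseline_utility_by_age.71-74", "Baseline utility 71-74",
        0.808, 0.770, 0.846, "beta",
    ),
    ParameterDef("utilities.hip_multiplier_year1", "Hip disutility multiplier, first year", 0.776, 0.720, 0.844, "beta"),
    ParameterDef("utilities.hip_multiplier_later", "Hip disutility multiplier, later years", 0.855, 0.800, 0.909, "beta"),
    ParameterDef("utilities.vertebral_multiplier_year1", "Vertebral disutility multiplier, first year", 0.724, 0.667, 0.779, "beta"),
    ParameterDef("utilities.vertebral_multiplier_later", "Vertebral disutility multiplier, later years", 0.868, 0.827, 0.922, "beta"),
    ParameterDef("utilities.other_multiplier_year1", "Other-fracture disutility multiplier, first year", 0.910, 0.880, 0.940, "beta"),
    ParameterDef("utilities.other_multiplier_later", "Other-fracture disutility multiplier, later years", 1.0),
    ParameterDef("utilities.bedridden_utility", "Utility of bedridden state", 0.192),
    ParameterDef("analysis.discount_rate_cost", "Discount rate, costs", 0.03, 0.0, 0.05, "fixed"),
    ParameterDef("analysis.discount_rate_qaly", "Discount rate, QALYs", 0.03, 0.0, 0.05, "fixed"),
)


def manifest_entry(path: str) -> ParameterDef:
    for d in PARAMETER_MANIFEST:
        if d.path == path:
            return d
    raise KeyError(path)


def sample_psa_parameter_set(params: ParameterSet, rng: np.random.Generator) -> ParameterSet:
    """One second-order draw: every non-fixed parameter replaced independently.

    Iterates the manifest in its fixed order so that a seeded generator gives
    reproducible draws; fixed parameters pass through unchanged.
    """
    out = params.copy()
    for d in PARAMETER_MANIFEST:
        spec = d.spec_for(params)
        if spec.family == "fixed":
            continue
        set_value(out, d.path, sample_parameter(spec, rng))
    out.validate()
    return out


# ---------------------------------------------------------------------------
# Config I/O
# ---------------------------------------------------------------------------

_TREATMENT_KEYS = {"name", "bmd_increment", "treatment_time", "annual_drug_cost"}


def _default_yaml_text() -> str:
    return resources.files("osteocea.data").joinpath("default_parameters.yaml").read_text()


def _from_mapping(doc: Mapping) -> ParameterSet:
    known = {"bmd_bands", "fracture_risk", "treatments", "costs", "utilities", "analysis", "metadata"}
    unknown = set(doc) - known
    if unknown:
        raise ParameterError(f"unknown top-level config keys: {sorted(unknown)}")

    def build(cls, section: Mapping, where: str):
        allowed = {f.name for f in dc_fields(cls)}
        bad = set(section) - allowed
        if bad:
            raise ParameterError(f"unknown keys in {where}: {sorted(bad)}")
        return cls(**section)

    bands = [build(BmdAgeBand, b, "bmd_bands") for b in doc["bmd_bands"]]
    treatments = {}
    for key, t in doc["treatments"].items():
        bad = set(t) - _TREATMENT_KEYS
        if bad:
            raise ParameterError(f"unknown keys in treatments.{key}: {sorted(bad)}")
        treatments[key] = TreatmentParams(name=t.get("name", key), **{k: v for k, v in t.items() if k != "name"})
    ps = ParameterSet(
        bmd_bands=bands,
        fracture_risk=build(FractureRiskParams, doc["fracture_risk"], "fracture_risk"),
        treatments=treatments,
        costs=build(CostParams, doc["costs"], "costs"),
        utilities=build(UtilityParams, doc["utilities"], "utilities"),
        analysis=build(AnalysisSettings, doc["analysis"], "analysis"),
        metadata=dict(doc.get("metadata", {})),
    )
    ps.validate()
    return ps


def default_parameters() -> ParameterSet:
    """The shipped Table-of-defaults parameter set (2022 USD)."""
    return _from_mapping(yaml.safe_load(_default_yaml_text()))


def _deep_update(base: dict, override: Mapping, where: str = "") -> dict:
    for key, val in override.items():
        loc = f"{where}.{key}" if where else str(key)
        if key not in base:
            raise ParameterError(f"unknown config key: {loc}")
        if isinstance(val, Mapping) and isinstance(base[key], dict):
            _deep_update(base[key], val, loc)
        else:
            base[key] = val
    return base


def load_parameters(config_source: str | Path | Mapping | None = None) -> ParameterSet:
    """Load a parameter set, falling back to the shipped defaults.

    ``config_source`` may be ``None`` (pure defaults), a mapping, or a path to
    a YAML file.  Overrides are merged key-by-key onto the defaults; unknown
    keys raise :class:`ParameterError` naming the offending key.
    """
    base = yaml.safe_load(_default_yaml_text())
    if config_source is None:
        doc = base
    else:
        if isinstance(config_source, Mapping):
            override = dict(config_source)
        else:
            path = Path(config_source)
            if not path.exists():
                raise FileNotFoundError(path)
            try:
                override = yaml.safe_load(path.read_text())
            except yaml.YAMLError as exc:
                raise ParameterError(f"malformed config file {path}: {exc}") from exc
            if override is None:
                override = {}
            if not isinstance(override, Mapping):
                raise ParameterError(f"config root must be a mapping, got {type(override).__name__}")
        # 'metadata' and whole-list 'bmd_bands' replace rather than merge
        if "bmd_bands" in override:
            base["bmd_bands"] = override.pop("bmd_bands")
        if "metadata" in override:
            base["metadata"].update(override.pop("metadata"))
        _deep_update(base, override)
        doc = base
    return _from_mapping(doc)


def _to_mapping(ps: ParameterSet) -> dict:
    def plain(obj):
        return {f.name: getattr(obj, f.name) for f in dc_fields(obj)}

    return {
        "bmd_bands": [plain(b) for b in ps.bmd_bands],
        "fracture_risk": plain(ps.fracture_risk),
        "treatments": {k: plain(t) for k, t in ps.treatments.items()},
        "costs": plain(ps.costs),
        "utilities": {
            **{
                f.name: getattr(ps.utilities, f.name)
                for f in dc_fields(ps.utilities)
                if f.name != "baseline_utility_by_age"
            },
            "baseline_utility_by_age": dict(ps.utilities.baseline_utility_by_age),
        },
        "analysis": plain(ps.analysis),
        "metadata": dict(ps.metadata),
    }


def write_parameters(ps: ParameterSet, path: str | Path) -> None:
    """Serialize a parameter set to YAML (round-trips through load_parameters)."""
    Path(path).write_text(yaml.safe_dump(_to_mapping(ps), sort_keys=False))
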