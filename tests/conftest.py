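"""Shared fixtures: default parameters, calibrated baseline models, and
simplified model builders used by the oracle tests."""

from __future__ import annotations

import numpy as np
import pytest

from osteocea.microsim import SimulationModels
from osteocea.model import OsteoporosisCEA
from osteocea.natural_history import IncidenceModel, MortalityModel
from osteocea.parameters import default_parameters
from osteocea.synthetic_inputs import default_life_table


@pytest.fixture()
def params():
    """Fresh default parameter set (mutable per-test)."""
    return default_parameters()


@pytest.fixture(scope="session")
def baseline_model():
    """Calibrated synthetic-baseline model at entry age 55 (do not mutate)."""
    return OsteoporosisCEA.with_synthetic_inputs(entry_age=55)


def constant_incidence_models(
    rates: dict[str, float], reference_bmd: float = 0.73, bmd_sd: float = 0.13
) -> dict[str, IncidenceModel]:
    """Age- and BMD-independent incidence models; a zero rate disables a site."""
    out = {}
    for site in ("hip", "vertebral", "other"):
        rate = rates.get(site, 0.0)
        out[site] = IncidenceModel(
            site=site,
            log_rate_at_anchor=np.log(rate) if rate > 0 else -np.inf,
            age_slope=0.0,
            rr_per_sd=1.0,
            reference_bmd=reference_bmd,
            bmd_sd=bmd_sd,
        )
    return out


def simple_models(
    rates: dict[str, float] | None = None,
    excess_hip_rr: float = 1.0,
    max_age: int = 100,
) -> SimulationModels:
    """SimulationModels with constant fracture rates and the synthetic
    Gompertz life table; fracture-free when ``rates`` is None."""
    return SimulationModels(
        incidence=constant_incidence_models(rates or {}),
        mortality=MortalityModel(default_life_table(max_age), excess_hip_rr=excess_hip_rr),
    )


@pytest.fixture()
def fracture_free_models():
    return simple_models()
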