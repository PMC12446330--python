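"""Microsimulation engine: treatment effect, state machine, the two-engine
equivalence and cohort-level properties."""

from __future__ import annotations

import math

import numpy as np
import pytest

from osteocea.microsim import (
    CohortRandoms,
    Individual,
    apply_treatment_effect,
    run_cohort,
    simulate_individual,
    step_cycle,
)
from osteocea.parameters import ParameterError, default_parameters
from osteocea.synthetic_inputs import LifeTable
from osteocea.natural_history import MortalityModel
from osteocea.microsim import SimulationModels

from conftest import constant_incidence_models, simple_models

SITES = ("hip", "vertebral", "other")


class TestTreatmentEffect:
    def test_no_treatment_leaves_bmd(self, params):
        ind = Individual(current_age=55, bmd=0.73)
        apply_treatment_effect(ind, params.treatments["no_treatment"], 0)
        assert ind.bmd == 0.73

    def test_jintiange_increment_cycle0(self, params):
        ind = Individual(current_age=55, bmd=0.73)
        apply_treatment_effect(ind, params.treatments["jintiange"], 0)
        assert ind.bmd == pytest.approx(0.84)

    def test_no_effect_after_cycle0(self, params):
        ind = Individual(current_age=56, bmd=0.84)
        apply_treatment_effect(ind, params.treatments["jintiange"], 1)
        assert ind.bmd == pytest.approx(0.84)

    def test_negative_cycle_rejected(self, params):
        with pytest.raises(ParameterError):
            apply_treatment_effect(Individual(55, 0.73), params.treatments["jintiange"], -1)

    def test_cost_without_effect_leaves_qalys_unchanged(self, params):
        """A zero-increment 'treatment' with a drug cost changes only costs
        under common random numbers."""
        params.treatments["placebo_priced"] = type(params.treatments["jintiange"])(
            name="Priced placebo", bmd_increment=0.0, treatment_time=0.5,
            annual_drug_cost=574.82,
        )
        models = simple_models({"hip": 0.02, "vertebral": 0.02})
        randoms = CohortRandoms.draw(9, 1000, 46)
        a = run_cohort(1000, 55, "no_treatment", params, models, randoms=randoms)
        b = run_cohort(1000, 55, "placebo_priced", params, models, randoms=randoms)
        np.testing.assert_allclose(a.qalys, b.qalys)
        # every survivor of cycle 0 pays exactly the discounted course price;
        # cycle-0 decedents accrue nothing
        diff = b.costs - a.costs
        expected = 574.82 * 0.5 / 1.03
        assert set(np.round(np.unique(diff), 9)) <= {0.0, round(expected, 9)}
        assert np.mean(np.isclose(diff, expected)) > 0.98


class TestStepCycle:
    def test_dead_individual_rejected(self, params, fracture_free_models):
        ind = Individual(current_age=60, bmd=0.7, alive=False, state="dead")
        with pytest.raises(ParameterError):
            step_cycle(ind, "no_treatment", params, fracture_free_models,
                       np.array([0.5] * 4), 1)

    def test_zero_hazards_accrues_baseline_utility(self, params):
        """With all hazards off, a 55-year-old accrues 0.88 discounted by the
        cycle factor."""
        models = simple_models()
        ind = Individual(current_age=55.0, bmd=0.73)
        ind, event = step_cycle(ind, "no_treatment", params, models,
                                np.array([0.99, 0.99, 0.5, 0.5]), 0)
        assert event is None
        assert ind.alive
        assert ind.discounted_qalys == pytest.approx(0.88 / 1.03)

    def test_forced_hip_with_bedridden_draw(self, params):
        models = simple_models({"hip": 5.0})
        ind = Individual(current_age=55.0, bmd=0.73)
        # u_death high (survive), u_frac 0 (event), u_site 0 (hip), u_bed 0
        ind, event = step_cycle(ind, "no_treatment", params, models,
                                np.array([0.999, 0.0, 0.0, 0.0]), 0)
        assert event == "hip"
        assert ind.bedridden and ind.state == "bedridden"

    def test_second_fracture_sets_complex_flag(self, params):
        models = simple_models({"vertebral": 5.0})
        ind = Individual(current_age=55.0, bmd=0.73)
        for t in range(2):
            ind, event = step_cycle(ind, "no_treatment", params, models,
                                    np.array([0.999, 0.0, 0.0, 0.9]), t)
            assert event == "vertebral"
        assert ind.complex_fracture_flag
        assert ind.fracture_counts["vertebral"] == 2


class TestSimulateIndividual:
    def test_certain_immediate_death_one_record(self, params):
        lt = LifeTable(np.arange(55, 57), np.array([1.0, 1.0]))
        models = SimulationModels(constant_incidence_models({}), MortalityModel(lt))
        params.analysis.max_age = 56
        traj = simulate_individual(55, "no_treatment", params, models,
                                   rng=np.random.default_rng(0))
        assert traj.years_survived == 0
        assert len(traj.records) == 1
        assert traj.records[0].state == "dead"
        assert traj.discounted_cost == 0.0

    def test_undiscounted_unit_utility_equals_years(self, params, fracture_free_models):
        """Discount 0 and utility 1 everywhere: QALYs == years survived."""
        params.analysis.discount_rate_cost = 0.0
        params.analysis.discount_rate_qaly = 0.0
        for k in params.utilities.baseline_utility_by_age:
            params.utilities.baseline_utility_by_age[k] = 1.0
        traj = simulate_individual(55, "no_treatment", params, fracture_free_models,
                                   rng=np.random.default_rng(4))
        assert traj.discounted_qalys == pytest.approx(traj.years_survived)

    def test_seeded_run_reproducible(self, params, fracture_free_models):
        t1 = simulate_individual(55, "no_treatment", params, fracture_free_models,
                                 rng=np.random.default_rng(11))
        t2 = simulate_individual(55, "no_treatment", params, fracture_free_models,
                                 rng=np.random.default_rng(11))
        assert t1 == t2

    def test_record_count_matches_survival(self, params):
        models = simple_models({"hip": 0.1, "vertebral": 0.1})
        traj = simulate_individual(55, "no_treatment", params, models,
                                   rng=np.random.default_rng(21))
        assert len(traj.records) == traj.years_survived + 1


class TestEngineEquivalence:
    def test_vectorized_equals_reference_engine(self, params):
        """Both engines consume the same uniform block and must agree
        individual-by-individual to numerical precision."""
        models = simple_models({"hip": 0.03, "vertebral": 0.05, "other": 0.02},
                               excess_hip_rr=2.0)
        n, T = 300, 46
        randoms = CohortRandoms.draw(17, n, T)
        res = run_cohort(n, 55, "jintiange", params, models, randoms=randoms)
        for i in range(n):
            traj = simulate_individual(55, "jintiange", params, models,
                                       randoms=randoms, index=i)
            assert traj.discounted_cost == pytest.approx(res.costs[i], rel=1e-9)
            assert traj.discounted_qalys == pytest.approx(res.qalys[i], rel=1e-9)

    def test_cohort_of_one_equals_individual(self, params):
        models = simple_models({"hip": 0.05})
        randoms = CohortRandoms.draw(3, 1, 46)
        res = run_cohort(1, 55, "no_treatment", params, models, randoms=randoms)
        traj = simulate_individual(55, "no_treatment", params, models,
                                   randoms=randoms, index=0)
        assert res.mean_cost == pytest.approx(traj.discounted_cost)
        assert res.mean_qalys == pytest.approx(traj.discounted_qalys)


class TestCohort:
    def test_zero_increment_zero_cost_equals_no_treatment(self, params):
        params.treatments["sham"] = type(params.treatments["jintiange"])(
            name="Sham", bmd_increment=0.0, treatment_time=0.5, annual_drug_cost=0.0
        )
        models = simple_models({"hip": 0.02, "vertebral": 0.03})
        randoms = CohortRandoms.draw(23, 2000, 46)
        a = run_cohort(2000, 55, "no_treatment", params, models, randoms=randoms)
        b = run_cohort(2000, 55, "sham", params, models, randoms=randoms)
        assert a.mean_cost == b.mean_cost
        assert a.mean_qalys == b.mean_qalys

    def test_seeded_cohort_deterministic(self, params):
        models = simple_models({"hip": 0.02})
        a = run_cohort(500, 55, "no_treatment", params, models, seed=31)
        b = run_cohort(500, 55, "no_treatment", params, models, seed=31)
        assert a.mean_cost == b.mean_cost and a.mean_qalys == b.mean_qalys

    def test_qalys_bounded_by_years_survived(self, params):
        models = simple_models({"hip": 0.05, "vertebral": 0.05})
        res = run_cohort(2000, 55, "no_treatment", params, models, seed=5)
        assert res.mean_qalys <= res.mean_years_survived

    def test_qaly_monotone_in_bmd_increment(self, params, baseline_model):
        """Larger BMD gains never reduce cohort QALYs under common random
        numbers."""
        models = baseline_model.models
        randoms = CohortRandoms.draw(41, 5000, 46)
        means = []
        for inc in (0.0, 0.05, 0.11, 0.20):
            params.treatments["probe"] = type(params.treatments["jintiange"])(
                name="probe", bmd_increment=inc, treatment_time=0.5, annual_drug_cost=0.0
            )
            res = run_cohort(5000, 55, "probe", params, models, randoms=randoms)
            means.append(res.mean_qalys)
        assert all(b >= a for a, b in zip(means, means[1:]))


class TestStateMachineSafety:
    def test_fuzz_no_forbidden_transitions(self, params):
        """Extreme hazards, 2,000 trajectories: dead is absorbing (the
        trajectory ends), bedridden never reverts, fracture history never
        clears, and the complex flag tracks the event count."""
        params.fracture_risk.p_bedridden_after_hip = 0.8
        models = simple_models(
            {"hip": 0.3, "vertebral": 0.3, "other": 0.3}, excess_hip_rr=5.0
        )
        rng = np.random.default_rng(99)
        for _ in range(2000):
            traj = simulate_individual(55, "no_treatment", params, models, rng=rng)
            states = [r.state for r in traj.records]
            assert states[-1] == "dead"
            assert "dead" not in states[:-1]
            seen_bedridden = False
            seen_fracture = False
            for s in states[:-1]:
                if seen_bedridden:
                    assert s == "bedridden"
                if s == "bedridden":
                    seen_bedridden = True
                if s != "no_fracture":
                    seen_fracture = True
                elif seen_fracture:
                    pytest.fail("returned to no_fracture after a fracture")

    def test_complex_flag_definition(self, params):
        models = simple_models({"hip": 0.5, "vertebral": 0.5})
        rng = np.random.default_rng(7)
        for _ in range(200):
            ind = Individual(current_age=55.0, bmd=0.73)
            t = 0
            while ind.alive and t < 45:
                step_cycle(ind, "no_treatment", params, models, rng.uniform(size=4), t)
                assert ind.complex_fracture_flag == (ind.total_fractures >= 2)
                t += 1


def test_cohort_survival_matches_life_table_expectancy(params, fracture_free_models):
    """Fracture-free cohort mean survival equals the closed-form life-table
    expectancy within 3 standard errors."""
    lt = fracture_free_models.mortality.life_table
    expected = lt.life_expectancy(55)
    res = run_cohort(50_000, 55, "no_treatment", params, fracture_free_models, seed=13)
    se = res.se_years_survived
    assert abs(res.mean_years_survived - expected) < 3 * se
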