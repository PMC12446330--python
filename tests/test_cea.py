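"""ICER tables, relative reductions, tornado sweep, PSA and CEAC mechanics."""

from __future__ import annotations

import math

import numpy as np
import pytest

import osteocea.cea as cea_mod
import osteocea.parameters as params_mod
from osteocea.cea import (
    PSAOutput,
    ceac,
    compute_icers,
    frontier_icers,
    one_way_dsa,
    relative_reduction,
    run_psa,
    validate_incidence,
)
from osteocea.microsim import StrategyResult, run_cohort
from osteocea.parameters import ParameterDef, ParameterError, default_parameters

from conftest import simple_models


def summary(strategy, cost, qalys):
    return StrategyResult.from_summary(strategy, cost, qalys)


class TestComputeIcers:
    def test_published_table_arithmetic(self):
        """The 55-59 published cohort summaries reproduce the printed ICER."""
        table = compute_icers(
            [
                summary("no_treatment", 7174.94, 13.0513),
                summary("jintiange", 8131.32, 13.1313),
            ],
            reference="no_treatment",
        )
        icer = table.icer("jintiange")
        assert round(icer) == 11955
        row = table.frame.set_index("strategy").loc["jintiange"]
        assert row["incremental_cost"] == pytest.approx(956.38)
        assert row["incremental_qalys"] == pytest.approx(0.08)

    def test_reference_row_blank(self):
        table = compute_icers(
            [summary("a", 100.0, 1.0), summary("b", 200.0, 2.0)], reference="a"
        )
        ref = table.frame.set_index("strategy").loc["a"]
        assert math.isnan(ref["icer"]) and ref["note"] == "Ref"

    def test_equal_strategies_flagged_undefined(self):
        table = compute_icers(
            [summary("a", 100.0, 1.0), summary("b", 100.0, 1.0)], reference="a"
        )
        assert math.isnan(table.icer("b"))

    def test_dominated_flag(self):
        table = compute_icers(
            [summary("a", 100.0, 2.0), summary("b", 150.0, 1.5)], reference="a"
        )
        row = table.frame.set_index("strategy").loc["b"]
        assert row["dominance"] == "dominated"

    def test_extended_dominance(self):
        # b's ICER vs a exceeds c's ICER vs b -> b extended-dominated
        table = compute_icers(
            [
                summary("a", 0.0, 0.0),
                summary("b", 1000.0, 0.1),
                summary("c", 1100.0, 1.0),
            ],
            reference="a",
        )
        assert (
            table.frame.set_index("strategy").loc["b", "dominance"]
            == "extended-dominated"
        )

    def test_sorted_by_cost_ascending(self):
        table = compute_icers(
            [summary("x", 300.0, 3.0), summary("y", 100.0, 1.0), summary("z", 200.0, 2.0)],
            reference="y",
        )
        assert list(table.frame["cost"]) == [100.0, 200.0, 300.0]

    def test_missing_reference_errors(self):
        with pytest.raises(ParameterError):
            compute_icers([summary("a", 1.0, 1.0), summary("b", 2.0, 2.0)], "zzz")

    def test_frontier_view(self):
        df = frontier_icers(
            [summary("a", 0.0, 0.0), summary("b", 100.0, 1.0), summary("c", 300.0, 2.0)]
        )
        assert list(df["comparator"]) == ["", "a", "b"]
        assert df["icer"].iloc[2] == pytest.approx(200.0)


class TestRelativeReduction:
    @pytest.mark.parametrize(
        "control, treated, expected",
        [
            (6.71, 6.16, 8.20),    # hip, lower-increment strategy
            (21.03, 18.50, 12.03),  # vertebral, lower-increment strategy
            (6.71, 5.48, 18.33),   # hip, higher-increment strategy
            (21.03, 15.47, 26.44),  # vertebral, higher-increment strategy
        ],
    )
    def test_published_fracture_reductions(self, control, treated, expected):
        assert round(relative_reduction(control, treated), 2) == expected

    def test_equal_inputs_zero(self):
        assert relative_reduction(0.3, 0.3) == 0.0

    def test_zero_control_undefined(self):
        assert math.isnan(relative_reduction(0.0, 0.1))


class TestOneWayDsa:
    @pytest.fixture()
    def setup(self, params, baseline_model):
        # calibrated models: treatment moves QALYs, so ICERs are finite
        return params, baseline_model.models

    def test_zero_width_range_reproduces_base(self, setup, monkeypatch):
        params, models = setup
        degenerate = ParameterDef(
            "costs.cost_hip_fracture", "hip cost (degenerate)", 7379.82,
            7379.82, 7379.82, "triangular",
        )
        monkeypatch.setattr(cea_mod, "PARAMETER_MANIFEST", (degenerate,))
        entries = one_way_dsa(params, models, 55, "jintiange", n=500, seed=1)
        e = entries[0]
        assert e.icer_low == e.icer_high == e.icer_base
        assert e.width == 0.0

    def test_discount_rate_sweep_monotone(self, setup):
        params, models = setup
        entries = one_way_dsa(
            params, models, 55, "jintiange", n=2000, seed=2,
            param_paths=["analysis.discount_rate_qaly"],
        )
        e = entries[0]
        # lower QALY discounting inflates the denominator -> lower ICER
        assert e.icer_low < e.icer_base < e.icer_high

    def test_unknown_path_rejected(self, setup):
        params, models = setup
        with pytest.raises(ParameterError):
            one_way_dsa(params, models, 55, "jintiange", n=100, seed=0,
                        param_paths=["treatments.jintiange.treatment_time"])

    def test_entries_sorted_by_width(self, setup):
        params, models = setup
        entries = one_way_dsa(
            params, models, 55, "jintiange", n=1000, seed=3,
            param_paths=[
                "treatments.jintiange.annual_drug_cost",
                "costs.cost_vertebral_fracture",
                "utilities.hip_multiplier_later",
            ],
        )
        widths = [e.width for e in entries]
        assert widths == sorted(widths, reverse=True)


class TestPsa:
    def test_all_fixed_iterations_identical(self, params, monkeypatch):
        fixed_only = tuple(d for d in params_mod.PARAMETER_MANIFEST if d.family == "fixed")
        monkeypatch.setattr(params_mod, "PARAMETER_MANIFEST", fixed_only)
        models = simple_models({"hip": 0.03})
        out = run_psa(params, models, 55, ["no_treatment", "jintiange"],
                      n_iterations=5, inner_n=300, seed=4)
        assert np.all(out.costs == out.costs[0])
        assert np.all(out.qalys == out.qalys[0])

    def test_seeded_reproducibility(self, params):
        models = simple_models({"hip": 0.03})
        kw = dict(n_iterations=8, inner_n=300, seed=5)
        a = run_psa(params, models, 55, ["no_treatment"], **kw)
        b = run_psa(params, models, 55, ["no_treatment"], **kw)
        np.testing.assert_array_equal(a.costs, b.costs)

    def test_iteration_mean_near_base_case(self, params):
        """Symmetric parameter uncertainty: the PSA iteration-mean cost of
        no treatment sits within 3 SE of the base-case cost under the same
        first-order noise."""
        models = simple_models({"hip": 0.02, "vertebral": 0.03})
        out = run_psa(params, models, 55, ["no_treatment"],
                      n_iterations=60, inner_n=2000, seed=6)
        psa_costs = out.costs[:, 0]
        # base case on the identical inner uniform block
        ss = np.random.SeedSequence(6)
        inner_seed = int(ss.spawn(61)[-1].generate_state(1, dtype=np.uint32)[0] % 2**31)
        from osteocea.microsim import CohortRandoms

        randoms = CohortRandoms.draw(inner_seed, 2000, 46)
        base = run_cohort(2000, 55, "no_treatment", params, models, randoms=randoms)
        se = psa_costs.std(ddof=1) / math.sqrt(len(psa_costs))
        assert abs(psa_costs.mean() - base.mean_cost) < 3 * se


class TestCeac:
    @pytest.fixture()
    def psa_output(self):
        # two strategies: A cheap/ineffective, B costly/effective
        costs = np.array([[100.0, 200.0]] * 4)
        qalys = np.array([[1.0, 1.5], [1.0, 1.4], [1.0, 1.6], [1.0, 1.5]])
        return PSAOutput(["A", "B"], costs, qalys, inner_n=1)

    def test_zero_wtp_prefers_cheapest(self, psa_output):
        curves = ceac(psa_output, [0.0])
        assert curves.loc[0, "A"] == 1.0

    def test_large_wtp_prefers_most_effective(self, psa_output):
        curves = ceac(psa_output, [1e9])
        assert curves.loc[0, "B"] == 1.0

    def test_probabilities_partition(self, psa_output):
        curves = ceac(psa_output, np.linspace(0, 1000, 21))
        sums = curves.drop(columns="wtp").sum(axis=1)
        assert np.allclose(sums, 1.0)

    def test_ties_split_equally(self):
        out = PSAOutput(["A", "B"], np.zeros((3, 2)), np.ones((3, 2)), inner_n=1)
        curves = ceac(out, [500.0])
        assert curves.loc[0, "A"] == 0.5 and curves.loc[0, "B"] == 0.5

    def test_empty_grid_rejected(self, psa_output):
        with pytest.raises(ParameterError):
            ceac(psa_output, [])


class TestValidateIncidence:
    def test_self_consistency_against_calibrated_model(self, baseline_model):
        """With history effects off, simulated no-treatment incidence brackets
        every calibration target."""
        params = baseline_model.params.copy()
        params.fracture_risk.rr_prior_fracture_hip = 1.0
        params.fracture_risk.rr_prior_fracture_vertebral = 1.0
        params.fracture_risk.rr_prior_fracture_other = 1.0
        params.fracture_risk.p_bedridden_after_hip = 0.0
        res = run_cohort(50_000, 55, "no_treatment", params, baseline_model.models,
                         seed=77)
        report = validate_incidence(res, baseline_model.targets["hip"])
        assert len(report) >= 7
        assert not report["outside_band"].any()

    def test_misfit_detected_when_hazards_doubled(self, baseline_model):
        """Doubling every hazard must flag (nearly) every age."""
        import copy

        models = copy.deepcopy(baseline_model.models)
        for m in models.incidence.values():
            m.log_rate_at_anchor += math.log(2.0)
        params = baseline_model.params.copy()
        params.fracture_risk.rr_prior_fracture_hip = 1.0
        params.fracture_risk.rr_prior_fracture_vertebral = 1.0
        params.fracture_risk.rr_prior_fracture_other = 1.0
        res = run_cohort(50_000, 55, "no_treatment", params, models, seed=78)
        report = validate_incidence(res, baseline_model.targets["hip"])
        assert report["outside_band"].all()

    def test_empty_cohort_rejected(self, baseline_model):
        empty = StrategyResult.from_summary("no_treatment", 0.0, 0.0)
        with pytest.raises(ParameterError):
            validate_incidence(empty, baseline_model.targets["hip"])
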