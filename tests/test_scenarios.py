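import dataclasses

import numpy as np
import pytest

from hivbia import (ScenarioSpec, ValidationError, apply_prevalence_delta,
                    generate_synthetic_params, pct_increase, run_model,
                    run_all_scenarios, run_scenario_comparison,
                    run_sensitivity_swap)


def _null_scenario(bundle):
    return ScenarioSpec(name="null", source="expert",
                        deltas={(c, l): 0.0 for c in ("renal",)
                                for l in bundle.cohort_labels})


class TestPrevalenceDelta:
    def test_published_cardiovascular_shift(self, paper_bundle):
        spec = paper_bundle.scenarios["cardiovascular_darunavir"]
        shifted = apply_prevalence_delta(paper_bundle, spec)
        recent = paper_bundle.cohort("recent")
        count = shifted[("cardiovascular", "recent")] * recent.size_2024
        assert count == pytest.approx(3273.7, abs=0.5)
        # published counterfactual 2024 count, 0.5% band
        assert count == pytest.approx(3271, rel=5e-3)

    def test_zero_delta_identity(self, paper_bundle):
        shifted = apply_prevalence_delta(paper_bundle,
                                         _null_scenario(paper_bundle))
        for (com, cohort), p in shifted.items():
            assert p == paper_bundle.epi[(com, cohort)].baseline_prevalence

    def test_capped_at_unity(self, paper_bundle):
        epi = {k: (dataclasses.replace(v, baseline_prevalence=0.99)
                   if k == ("renal", "recent") else v)
               for k, v in paper_bundle.epi.items()}
        bundle = dataclasses.replace(paper_bundle, epi=epi)
        spec = ScenarioSpec(name="big", source="expert",
                            deltas={("renal", "recent"): 5.0})
        assert apply_prevalence_delta(bundle, spec)[
            ("renal", "recent")] == 1.0

    def test_negative_delta_rejected(self):
        with pytest.raises(ValidationError):
            ScenarioSpec(name="bad", source="expert",
                         deltas={("renal", "recent"): -1.0})


class TestScenarioComparison:
    def test_null_scenario_is_identity(self, paper_bundle):
        comp = run_scenario_comparison(paper_bundle,
                                       _null_scenario(paper_bundle))
        row = comp.rows["renal"]
        assert row.scenario_py == row.current_py
        assert row.incremental_cost == 0.0
        assert row.py_increase_pct == 0.0

    def test_positive_deltas_increase_py_and_cost(self, paper_bundle):
        comps = run_all_scenarios(paper_bundle)
        assert len(comps) == 7
        for comp in comps.values():
            for row in comp.rows.values():
                assert row.scenario_py > row.current_py
                assert row.incremental_cost > 0

    def test_larger_deltas_dominate(self, paper_bundle):
        small = ScenarioSpec(name="small", source="expert",
                             deltas={("bone", "recent"): 1.0,
                                     ("bone", "longstanding"): 1.0})
        large = ScenarioSpec(name="large", source="expert",
                             deltas={("bone", "recent"): 2.0,
                                     ("bone", "longstanding"): 3.0})
        c_small = run_scenario_comparison(paper_bundle, small).rows["bone"]
        c_large = run_scenario_comparison(paper_bundle, large).rows["bone"]
        assert c_large.scenario_py >= c_small.scenario_py
        assert c_large.scenario_cost >= c_small.scenario_cost

    def test_zero_discount_aligns_py_and_cost_percentages(self,
                                                          paper_bundle):
        econ = dataclasses.replace(paper_bundle.econ, discount_rate=0.0)
        bundle = dataclasses.replace(paper_bundle, econ=econ)
        spec = bundle.scenarios["renal_tenofovir_disoproxil"]
        row = run_scenario_comparison(bundle, spec).rows["renal"]
        assert row.cost_increase_pct == pytest.approx(row.py_increase_pct,
                                                      abs=1e-9)

    def test_difference_decay_matches_loop_oracle(self, paper_bundle,
                                                  loop_oracle):
        """Scenario-minus-current prevalent difference shrinks by
        (1 - i(t))(1 - m) per cycle under the at-risk rule; check against
        the independent loop."""
        spec = paper_bundle.scenarios["cardiovascular_darunavir"]
        comp = run_scenario_comparison(paper_bundle, spec)
        cohort = paper_bundle.cohort("recent")
        epi = paper_bundle.epi[("cardiovascular", "recent")]
        m = paper_bundle.population.annual_mortality
        cur = comp.current.counts[("cardiovascular", "recent")].prevalent
        scen = comp.scenario.counts[("cardiovascular", "recent")].prevalent
        diff = scen - cur
        for k in range(len(diff) - 1):
            i_k = epi.incidence_young * (1 - 0.01) ** k
            assert diff[k + 1] == pytest.approx(
                diff[k] * (1 - i_k) * (1 - m), rel=1e-9)
        # and both trajectories agree with the independent loop
        for base, got in ((cur[0], cur), (scen[0], scen)):
            want = loop_oracle(cohort.size_2024, cohort.mean_age_2024, m,
                               base, epi.incidence_young, epi.incidence_old,
                               50.0, 0.01, len(got))
            np.testing.assert_allclose(got, want, rtol=1e-9)

    def test_unknown_scenario_name(self, paper_bundle):
        with pytest.raises(KeyError, match="available"):
            run_all_scenarios(paper_bundle, ["no_such_scenario"])

    def test_percentages_consistent_with_ratios(self, paper_bundle):
        comp = run_scenario_comparison(
            paper_bundle, paper_bundle.scenarios["bone_tenofovir_disoproxil"])
        row = comp.rows["bone"]
        assert row.py_increase_pct == pytest.approx(
            (row.scenario_py / row.current_py - 1) * 100, rel=1e-6)
        assert row.cost_increase_pct == pytest.approx(
            (row.scenario_cost / row.current_cost - 1) * 100, rel=1e-6)


class TestSensitivitySwap:
    def test_identity_swap_changes_nothing(self, paper_bundle):
        repl = {(com, "recent"): paper_bundle.epi[
            (com, "recent")].baseline_prevalence
            for com in ("cardiovascular", "renal", "neuropsychiatric")}
        comp = run_sensitivity_swap(paper_bundle, repl, {"recent"})
        assert comp.skipped == ("bone",)
        for row in comp.rows.values():
            assert row.incremental_cost == 0.0

    def test_halved_prevalence_matches_two_run_subtraction(self):
        sb = generate_synthetic_params(42)
        bundle = sb.bundle
        half = bundle.epi[("cardiovascular",
                           "recent")].baseline_prevalence / 2
        comp = run_sensitivity_swap(bundle,
                                    {("cardiovascular", "recent"): half},
                                    {"recent"})
        # independent pair of full model runs
        base = run_model(bundle)
        alt = run_model(bundle, baseline_prevalence_override={
            ("cardiovascular", "recent"): half})
        expected = (alt.cumulative_cost("cardiovascular")
                    - base.cumulative_cost("cardiovascular"))
        assert comp.rows["cardiovascular"].incremental_cost == \
            pytest.approx(expected)
        assert expected < 0

    def test_swap_ignores_unselected_cohort(self, paper_bundle):
        repl = {("renal", "recent"): 0.2, ("renal", "longstanding"): 0.2}
        comp = run_sensitivity_swap(paper_bundle, repl, {"recent"})
        long_cur = comp.current.counts[("renal", "longstanding")].prevalent
        long_alt = comp.scenario.counts[("renal", "longstanding")].prevalent
        np.testing.assert_array_equal(long_cur, long_alt)

    def test_out_of_range_replacement_rejected(self, paper_bundle):
        with pytest.raises(ValidationError):
            run_sensitivity_swap(paper_bundle,
                                 {("renal", "recent"): 1.2}, {"recent"})

    def test_unknown_cohort_rejected(self, paper_bundle):
        with pytest.raises(ValidationError):
            run_sensitivity_swap(paper_bundle, {}, {"middling"})


class TestPercentageHelper:
    def test_published_person_year_ratios(self):
        assert round(pct_increase(130_479, 203_252), 2) == 55.77
        assert round(pct_increase(287_002, 306_399), 2) == 6.76

    def test_degenerate_cases(self):
        assert pct_increase(0, 0) == 0.0
        assert pct_increase(100, 100) == 0.0
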