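"""Counterfactual scenarios and sensitivity analyses.

A scenario adds absolute percentage-point increments to the 2024 baseline
prevalence of one or more comorbidities — a full-exposure counterfactual
for a single ART regimen's toxicity profile.  Incidence, mortality and
costs are identical between the paired runs, so every difference in
person-years and cost is attributable to the shifted baseline stock.

Sensitivity analyses instead *replace* baseline prevalences for selected
cohorts with values from an alternative source cohort study.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .model import ModelResult, run_model
from .params import ParameterBundle, ScenarioSpec, ValidationError

DISPLAY_PRECISION = 2  # decimals on reported percentage increases


def pct_increase(current: float, scenario: float) -> float:
    """Percentage increase of ``scenario`` over ``current`` (0 if both 0)."""
    if current == 0:
        return 0.0 if scenario == 0 else float("inf")
    return (scenario / current - 1.0) * 100.0


def apply_prevalence_delta(bundle: ParameterBundle,
                           scenario: ScenarioSpec) -> dict:
    """Shifted 2024 baseline prevalences under a scenario.

    Returns ``{(comorbidity, cohort): new_prevalence}`` for every pair the
    scenario perturbs: ``min(1, baseline + pp/100)``.  Pairs without a
    delta keep their baseline and are not included.
    """
    shifted = {}
    for (com, cohort), pp in scenario.deltas.items():
        if pp < 0:
            raise ValidationError(
                f"scenario {scenario.name!r}: negative delta for "
                f"({com}, {cohort})")
        base = bundle.epi[(com, cohort)].baseline_prevalence
        shifted[(com, cohort)] = min(1.0, base + pp / 100.0)
    return shifted


@dataclass(frozen=True)
class ComparisonRow:
    """Paired-run outcome for one comorbidity.

    Person-year increases are computed on undiscounted person-years;
    cost increases on discounted cumulative costs — the two coincide only
    under zero discounting, so both are reported explicitly.
    """

    comorbidity: str
    current_py: float
    scenario_py: float
    current_cost: float        # cumulative discounted €
    scenario_cost: float

    @property
    def py_increase_pct(self) -> float:
        return pct_increase(self.current_py, self.scenario_py)

    @property
    def incremental_cost(self) -> float:
        return self.scenario_cost - self.current_cost

    @property
    def cost_increase_pct(self) -> float:
        return pct_increase(self.current_cost, self.scenario_cost)


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of a paired current-vs-counterfactual execution."""

    name: str
    rows: Mapping[str, ComparisonRow]   # comorbidity -> row
    skipped: tuple = ()                 # comorbidities not evaluated
    current: ModelResult | None = None
    scenario: ModelResult | None = None

    def frame(self) -> pd.DataFrame:
        records = []
        for com, r in self.rows.items():
            records.append({
                "scenario": self.name, "comorbidity": com,
                "current_py": r.current_py, "scenario_py": r.scenario_py,
                "py_increase_pct": round(r.py_increase_pct,
                                         DISPLAY_PRECISION),
                "current_cost_eur": r.current_cost,
                "scenario_cost_eur": r.scenario_cost,
                "incremental_cost_eur": r.incremental_cost,
                "cost_increase_pct": round(r.cost_increase_pct,
                                           DISPLAY_PRECISION)})
        for com in self.skipped:
            records.append({"scenario": self.name, "comorbidity": com,
                            "current_py": float("nan")})
        return pd.DataFrame(records)


def _compare(name, current: ModelResult, alternative: ModelResult,
             comorbidities, skipped=()) -> ComparisonResult:
    rows = {}
    for com in comorbidities:
        rows[com] = ComparisonRow(
            comorbidity=com,
            current_py=current.person_years(com),
            scenario_py=alternative.person_years(com),
            current_cost=current.cumulative_cost(com),
            scenario_cost=alternative.cumulative_cost(com))
    return ComparisonResult(name=name, rows=rows, skipped=tuple(skipped),
                            current=current, scenario=alternative)


def run_scenario_comparison(bundle: ParameterBundle,
                            scenario: ScenarioSpec) -> ComparisonResult:
    """Run the model twice — current and counterfactual — and compare.

    Only the 2024 baseline prevalences named by the scenario differ between
    the runs; results cover the comorbidities the scenario perturbs.
    """
    current = run_model(bundle)
    shifted = apply_prevalence_delta(bundle, scenario)
    alternative = run_model(bundle, baseline_prevalence_override=shifted)
    return _compare(scenario.name, current, alternative,
                    scenario.comorbidities)


def run_sensitivity_swap(bundle: ParameterBundle,
                         replacements: Mapping[tuple, float],
                         cohorts) -> ComparisonResult:
    """One-way sensitivity analysis: swap baseline prevalences of selected
    cohorts for values from an alternative source, re-run, and compare.

    ``replacements`` maps ``(comorbidity, cohort)`` to a replacement
    prevalence (a proportion, not a delta).  Only pairs whose cohort is in
    ``cohorts`` are applied.  Comorbidities with no replacement value for
    any selected cohort are skipped and flagged, mirroring source studies
    that do not cover every comorbidity.
    """
    cohorts = set(cohorts)
    unknown = cohorts - set(bundle.cohort_labels)
    if unknown:
        raise ValidationError(f"unknown cohort labels {sorted(unknown)}")
    override = {}
    for (com, cohort), prev in replacements.items():
        if not (0.0 <= prev <= 1.0):
            raise ValidationError(
                f"replacement prevalence for ({com}, {cohort}) out of "
                f"range: {prev}")
        if cohort in cohorts:
            override[(com, cohort)] = float(prev)

    from .params import COMORBIDITIES
    evaluated = [c for c in COMORBIDITIES
                 if any(k[0] == c for k in override)]
    skipped = [c for c in COMORBIDITIES if c not in evaluated]

    current = run_model(bundle)
    swapped = run_model(bundle, baseline_prevalence_override=override)
    return _compare("sensitivity_swap", current, swapped, evaluated,
                    skipped=skipped)


def run_all_scenarios(bundle: ParameterBundle,
                      names=None) -> dict:
    """Run every (or each named) configured scenario; returns name->result."""
    if names is None:
        names = list(bundle.scenarios)
    missing = [n for n in names if n not in bundle.scenarios]
    if missing:
        raise KeyError(
            f"unknown scenario(s) {missing}; available: "
            f"{sorted(bundle.scenarios)}")
    return {n: run_scenario_comparison(bundle, bundle.scenarios[n])
            for n in names}
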