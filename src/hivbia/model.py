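"""End-to-end model execution: project every cohort and comorbidity from a
parameter bundle and cost the resulting person-years."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .costing import CostTrajectory, annual_cost_per_patient, cost_trajectory
from .params import COMORBIDITIES, ParameterBundle
from .projection import (CountTrajectory, PopulationTrajectory, person_years,
                         project_cohort_population,
                         project_comorbidity_counts)


@dataclass(frozen=True)
class ModelResult:
    """All trajectories of one model run, with aggregation helpers."""

    bundle: ParameterBundle
    population: Mapping[str, PopulationTrajectory]        # cohort -> traj
    counts: Mapping[tuple, CountTrajectory]               # (com, cohort)
    costs: Mapping[tuple, CostTrajectory]                 # (com, cohort)
    per_patient_cost: Mapping[str, float] = field(default_factory=dict)

    def person_years(self, comorbidity: str, cohort: str | None = None):
        """Prevalent person-years, per cohort or summed over cohorts."""
        if cohort is not None:
            return person_years(self.counts[(comorbidity, cohort)])
        return sum(person_years(self.counts[(comorbidity, c)])
                   for c in self.bundle.cohort_labels)

    def cumulative_cost(self, comorbidity: str, cohort: str | None = None,
                        discounted: bool = True) -> float:
        keys = ([(comorbidity, cohort)] if cohort is not None else
                [(comorbidity, c) for c in self.bundle.cohort_labels])
        attr = "cumulative_discounted" if discounted \
            else "cumulative_undiscounted"
        return sum(getattr(self.costs[k], attr) for k in keys)

    def total_person_years(self) -> float:
        """Alive person-years across all cohorts (denominator bookkeeping)."""
        return sum(person_years(t) for t in self.population.values())

    def prevalent(self, comorbidity: str, year: int,
                  cohort: str | None = None) -> float:
        total = 0.0
        for c in ([cohort] if cohort else self.bundle.cohort_labels):
            traj = self.counts[(comorbidity, c)]
            idx = int(year - traj.years[0])
            total += float(traj.prevalent[idx])
        return total

    def trajectories_frame(self) -> pd.DataFrame:
        """Tidy (year, cohort, comorbidity, alive, prevalent) table."""
        rows = []
        for (com, cohort), traj in self.counts.items():
            alive = self.population[cohort].alive
            for k, year in enumerate(traj.years):
                rows.append({"year": int(year), "cohort": cohort,
                             "comorbidity": com,
                             "alive": float(alive[k]),
                             "prevalent": float(traj.prevalent[k])})
        return pd.DataFrame(rows)

    def costs_frame(self) -> pd.DataFrame:
        """Tidy (year, cohort, comorbidity, undiscounted, discounted)."""
        rows = []
        for (com, cohort), ct in self.costs.items():
            for k, year in enumerate(ct.years):
                rows.append({"year": int(year), "cohort": cohort,
                             "comorbidity": com,
                             "undiscounted_eur": float(ct.undiscounted[k]),
                             "discounted_eur": float(ct.discounted[k])})
        return pd.DataFrame(rows)


def run_model(bundle: ParameterBundle,
              baseline_prevalence_override: Mapping[tuple, float]
              | None = None) -> ModelResult:
    """Run projection and costing for every cohort and comorbidity.

    ``baseline_prevalence_override`` replaces the 2024 baseline prevalence
    for selected (comorbidity, cohort) pairs — the hook used by scenario
    and sensitivity analyses, which never touch incidence or mortality.
    """
    override = dict(baseline_prevalence_override or {})
    horizon = bundle.econ.horizon

    population = {c.label: project_cohort_population(c, bundle.population,
                                                     horizon)
                  for c in bundle.cohorts}
    counts, costs, per_patient = {}, {}, {}
    for com in COMORBIDITIES:
        per_patient[com] = annual_cost_per_patient(bundle.resources[com],
                                                   bundle.econ)
        for cohort in bundle.cohorts:
            epi = bundle.epi[(com, cohort.label)]
            prevalence = override.get((com, cohort.label),
                                      epi.baseline_prevalence)
            baseline = min(1.0, prevalence) * cohort.size_2024
            traj = project_comorbidity_counts(
                population[cohort.label], epi, baseline,
                bundle.population.annual_mortality, rule=bundle.update_rule)
            counts[(com, cohort.label)] = traj
            costs[(com, cohort.label)] = cost_trajectory(
                traj, per_patient[com], bundle.econ)
    return ModelResult(bundle=bundle, population=population, counts=counts,
                       costs=costs, per_patient_cost=per_patient)
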