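"""Synthetic parameter-bundle generator for property testing.

Draws a complete, schema-valid parameter bundle from documented ranges, so
every stage of the pipeline (projection, costing, scenarios, calibration)
can be exercised without external data.  The generating truth (the drawn
rates) is recorded so calibration-recovery tests can compare against it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import (COHORT_LABELS, COMORBIDITIES, RESOURCE_CATEGORIES,
                     CohortSpec, ComorbidityEpi, EconSettings,
                     ParameterBundle, PopulationParams, ResourceProfile,
                     ScenarioSpec, UnitCost, ValidationError)

#: Documented sampling ranges (uniform unless noted).  Cohort sizes span
#: three orders of magnitude; epidemiological rates stay in the plausible
#: chronic-comorbidity regime; unit costs match the magnitude of Spanish
#: per-event healthcare tariffs.
DEFAULT_RANGES = {
    "cohort_size": (1e3, 1e5),
    "mean_age": (30.0, 55.0),
    "prevalence": (0.0, 0.3),
    "incidence": (0.0, 0.05),
    "mortality": (0.0, 0.05),
    "incidence_reduction": (0.0, 0.02),
    "quantity": (0.0, 10.0),
    "unit_cost": (20.0, 5000.0),
    "delta_pp": (0.0, 8.0),
    "discount_rate": (0.0, 0.05),
}


@dataclass(frozen=True)
class SyntheticBundle:
    """A generated bundle plus its seed and generating truth."""

    bundle: ParameterBundle
    seed: int
    truth: dict   # raw drawn values, keyed by parameter name


def generate_synthetic_params(seed: int,
                              ranges: dict | None = None) -> SyntheticBundle:
    """Draw a full schema-valid bundle, deterministically from ``seed``."""
    ranges = {**DEFAULT_RANGES, **(ranges or {})}
    for name, bounds in ranges.items():
        if name not in DEFAULT_RANGES:
            raise ValidationError(f"unknown range name {name!r}")
        lo, hi = bounds
        if not (lo <= hi):
            raise ValidationError(f"malformed range {name}: {bounds}")
    rng = np.random.default_rng(seed)

    def u(name):
        lo, hi = ranges[name]
        return float(rng.uniform(lo, hi))

    mortality = u("mortality")
    population = PopulationParams(
        national_population=1e7, hiv_prevalence=0.003,
        diagnosed_fraction=0.9, recent_fraction=0.4,
        annual_mortality=mortality)

    cohorts, truth = [], {"annual_mortality": mortality}
    for label in COHORT_LABELS:
        size = u("cohort_size")
        age = u("mean_age")
        truth[f"size_{label}"] = size
        cohorts.append(CohortSpec(label=label, size_2024=size,
                                  mean_age_2024=age))

    decay = u("incidence_reduction")
    truth["annual_incidence_reduction"] = decay
    epi = {}
    for com in COMORBIDITIES:
        for cohort in cohorts:
            prev = u("prevalence")
            inc = u("incidence")
            # old band tied to the young band so calibration recovery is
            # exact when the assumed ratio matches the generating one
            ratio = float(rng.uniform(1.0, 2.0))
            e = ComorbidityEpi(
                comorbidity=com, cohort=cohort.label,
                baseline_prevalence=prev, incidence_young=inc,
                incidence_old=min(1.0, inc * ratio),
                annual_incidence_reduction=decay)
            epi[(com, cohort.label)] = e
            truth[f"prevalence_{com}_{cohort.label}"] = prev
            truth[f"incidence_{com}_{cohort.label}"] = inc
            truth[f"old_young_ratio_{com}_{cohort.label}"] = ratio

    resources = {com: ResourceProfile(
        comorbidity=com,
        quantities={cat: u("quantity") for cat in RESOURCE_CATEGORIES})
        for com in COMORBIDITIES}

    base_year = 2024
    econ = EconSettings(
        unit_costs={cat: UnitCost(cost=u("unit_cost"),
                                  origin_year=base_year)
                    for cat in RESOURCE_CATEGORIES},
        cpi_index={base_year: 100.0},
        discount_rate=u("discount_rate"),
        base_year=base_year, horizon=(base_year, base_year + 10))

    scenario = ScenarioSpec(
        name="synthetic_shift", source="expert",
        deltas={(com, c.label): u("delta_pp")
                for com in COMORBIDITIES for c in cohorts})

    bundle = ParameterBundle(population=population, cohorts=tuple(cohorts),
                             epi=epi, resources=resources, econ=econ,
                             scenarios={scenario.name: scenario})
    return SyntheticBundle(bundle=bundle, seed=int(seed), truth=truth)
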