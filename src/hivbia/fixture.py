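"""Reference parameter set for the Spanish 2024–2034 analysis.

Assembles the published inputs — national epidemiology, per-comorbidity
resource use and unit costs, and regimen counterfactual prevalence
increments — into a full parameter bundle.  Two pieces of the original
model were not published and are reconstructed here:

* baseline prevalences, derived as published 2024 prevalent counts divided
  by the cohort sizes;
* annual incidence schedules, calibrated by bisection so the forward run
  reproduces the published 2034 prevalent counts exactly (endpoint
  matching; see :mod:`hivbia.calibration`).

Everything is deterministic, so rebuilding the fixture always yields
identical calibrated rates.
"""

from __future__ import annotations

from importlib import resources as importlib_resources

from .calibration import calibrate_incidence
from .params import (COHORT_LABELS, COMORBIDITIES, CohortSpec,
                     ComorbidityEpi, EconSettings, ParameterBundle,
                     PopulationParams, ResourceProfile, ScenarioSpec,
                     UnitCost, derive_baseline_prevalence,
                     derive_population_2024, load_model_config)

BASE_YEAR = 2024
HORIZON = (2024, 2034)

# National epidemiology: Spain 2024.  The national population is
# back-solved so that population x prevalence x diagnosed fraction gives
# the published total of 139 390 diagnosed PLWH.
POPULATION = PopulationParams(
    national_population=48_610_288,
    hiv_prevalence=0.0031,
    diagnosed_fraction=0.925,
    recent_fraction=0.396,
    annual_mortality=0.0207,
)

COHORT_MEAN_AGES = {"recent": 34.0, "longstanding": 48.0}

#: Published 2024 and 2034 prevalent counts per comorbidity and cohort.
PREVALENT_COUNTS = {
    # (comorbidity, cohort): (2024 count, 2034 count)
    ("cardiovascular", "recent"): (2650, 5166),
    ("cardiovascular", "longstanding"): (14397, 28389),
    ("renal", "recent"): (1270, 2583),
    ("renal", "longstanding"): (6483, 12808),
    ("bone", "recent"): (3809, 8241),
    ("bone", "longstanding"): (13892, 25709),
    ("neuropsychiatric", "recent"): (2484, 5606),
    ("neuropsychiatric", "longstanding"): (13723, 21782),
}

#: Unit costs (2024 €) and annual resource-use quantities per prevalent
#: patient (events/year).
UNIT_COSTS = {
    "hospital_admissions": 4669.00,
    "diagnostic_tests": 157.23,
    "ed_visits": 225.93,
    "outpatient_visits": 158.21,
    "hiv_visits": 158.21,
    "blood_tests": 30.96,
}

RESOURCE_QUANTITIES = {
    "cardiovascular": {
        "hospital_admissions": 0.63, "diagnostic_tests": 3.88,
        "ed_visits": 1.31, "outpatient_visits": 1.62,
        "hiv_visits": 3.21, "blood_tests": 9.20},
    "renal": {
        "hospital_admissions": 0.84, "diagnostic_tests": 4.60,
        "ed_visits": 1.98, "outpatient_visits": 1.72,
        "hiv_visits": 3.06, "blood_tests": 8.64},
    "bone": {
        "hospital_admissions": 0.32, "diagnostic_tests": 3.23,
        "ed_visits": 0.80, "outpatient_visits": 1.30,
        "hiv_visits": 2.90, "blood_tests": 7.85},
    "neuropsychiatric": {
        "hospital_admissions": 0.83, "diagnostic_tests": 4.24,
        "ed_visits": 1.95, "outpatient_visits": 1.67,
        "hiv_visits": 3.02, "blood_tests": 8.43},
}

#: Regimen counterfactuals: absolute percentage-point additions to the
#: 2024 baseline prevalence, per cohort.  Literature-sourced
#: neuropsychiatric increments apply one published value to both cohorts.
SCENARIO_DELTAS = [
    ("cardiovascular_darunavir", "expert",
     {("cardiovascular", "recent"): 1.13,
      ("cardiovascular", "longstanding"): 1.88}),
    ("renal_tenofovir_disoproxil", "expert",
     {("renal", "recent"): 2.93, ("renal", "longstanding"): 7.23}),
    ("bone_tenofovir_disoproxil", "expert",
     {("bone", "recent"): 2.38, ("bone", "longstanding"): 4.66}),
    ("neuropsychiatric_dolutegravir_expert", "expert",
     {("neuropsychiatric", "recent"): 1.88,
      ("neuropsychiatric", "longstanding"): 2.05}),
    ("neuropsychiatric_bictegravir_expert", "expert",
     {("neuropsychiatric", "recent"): 1.25,
      ("neuropsychiatric", "longstanding"): 2.00}),
    ("neuropsychiatric_dolutegravir_literature", "literature",
     {("neuropsychiatric", "recent"): 2.58,
      ("neuropsychiatric", "longstanding"): 2.58}),
    ("neuropsychiatric_bictegravir_literature", "literature",
     {("neuropsychiatric", "recent"): 0.70,
      ("neuropsychiatric", "longstanding"): 0.70}),
]

ANNUAL_INCIDENCE_REDUCTION = 0.01
AGE_THRESHOLD = 50.0

#: Old:young incidence ratio assumed per cohort when calibrating.  The
#: recent cohort never reaches the age threshold within the horizon, so
#: its ratio is irrelevant and left at 1.  For the longstanding cohort two
#: endpoints cannot identify two band rates; 1.5 encodes a moderate age
#: effect and reproduces the qualitative uptick when the cohort's mean age
#: crosses 50 in 2026.
OLD_YOUNG_RATIO = {"recent": 1.0, "longstanding": 1.5}


def fixture_cohorts() -> tuple:
    """Cohort specs with sizes derived from the national parameters."""
    _, recent, longstanding = derive_population_2024(POPULATION)
    sizes = {"recent": recent, "longstanding": longstanding}
    return tuple(CohortSpec(label=label, size_2024=sizes[label],
                            mean_age_2024=COHORT_MEAN_AGES[label])
                 for label in COHORT_LABELS)


def paper_fixture(update_rule: str = "at-risk") -> ParameterBundle:
    """Build the full reference bundle, calibrating incidence on the fly."""
    cohorts = fixture_cohorts()
    epi = {}
    for cohort in cohorts:
        ratio = OLD_YOUNG_RATIO[cohort.label]
        for com in COMORBIDITIES:
            count_2024, count_2034 = PREVALENT_COUNTS[(com, cohort.label)]
            prevalence = derive_baseline_prevalence(count_2024,
                                                    cohort.size_2024)
            cal = calibrate_incidence(
                target_2034=count_2034, baseline_2024=float(count_2024),
                cohort=cohort, pop=POPULATION, comorbidity=com,
                decay=ANNUAL_INCIDENCE_REDUCTION, old_young_ratio=ratio,
                horizon=HORIZON, rule=update_rule)
            epi[(com, cohort.label)] = ComorbidityEpi(
                comorbidity=com, cohort=cohort.label,
                baseline_prevalence=prevalence,
                incidence_young=cal.base_incidence,
                incidence_old=cal.old_incidence,
                age_threshold=AGE_THRESHOLD,
                annual_incidence_reduction=ANNUAL_INCIDENCE_REDUCTION)

    resources = {com: ResourceProfile(comorbidity=com,
                                      quantities=dict(q))
                 for com, q in RESOURCE_QUANTITIES.items()}
    econ = EconSettings(
        unit_costs={cat: UnitCost(cost=c, origin_year=BASE_YEAR)
                    for cat, c in UNIT_COSTS.items()},
        cpi_index={BASE_YEAR: 100.0},
        discount_rate=0.03, base_year=BASE_YEAR, horizon=HORIZON)
    scenarios = {}
    for name, source, deltas in SCENARIO_DELTAS:
        scenarios[name] = ScenarioSpec(name=name, source=source,
                                       deltas=dict(deltas))
    return ParameterBundle(population=POPULATION, cohorts=cohorts, epi=epi,
                           resources=resources, econ=econ,
                           scenarios=scenarios, update_rule=update_rule)


def packaged_fixture_path():
    """Path to the pre-generated YAML copy of the fixture config."""
    return importlib_resources.files("hivbia.data") / "paper_fixture.yaml"


def load_packaged_fixture() -> ParameterBundle:
    """Load the packaged YAML fixture through the normal config loader."""
    return load_model_config(packaged_fixture_path())
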