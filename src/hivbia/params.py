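"""Model parameter types, validation, config I/O and simple derivations.

The model is driven entirely by a structured configuration (YAML or JSON)
describing the national epidemiology of diagnosed HIV, two since-diagnosis
cohorts, per-comorbidity prevalence/incidence schedules, healthcare
resource-use profiles with unit costs, economic settings and named
counterfactual scenarios.  Every numeric input is validated against explicit
bounds; unknown keys are rejected so a mis-typed field can never silently
default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import yaml

SCHEMA_VERSION = 1

#: The four comorbidity groups the model tracks.
COMORBIDITIES = ("cardiovascular", "renal", "bone", "neuropsychiatric")

#: Cohort labels: diagnosed <10 years ago vs >=10 years ago.
COHORT_LABELS = ("recent", "longstanding")

#: Closed enumeration of healthcare resource categories (one per cost row).
RESOURCE_CATEGORIES = (
    "hospital_admissions",
    "diagnostic_tests",
    "ed_visits",
    "outpatient_visits",
    "hiv_visits",
    "blood_tests",
)

UPDATE_RULES = ("at-risk", "whole-cohort")
SCENARIO_SOURCES = ("expert", "literature")


class ConfigError(ValueError):
    """Base class for configuration problems."""


class SchemaError(ConfigError):
    """A required field is missing or an unknown key is present."""


class ValidationError(ConfigError):
    """A field value violates its documented bounds."""


def _require(mapping: Mapping, key: str, context: str):
    if key not in mapping:
        raise SchemaError(f"{context}: missing required field '{key}'")
    return mapping[key]


def _reject_unknown(mapping: Mapping, allowed: tuple, context: str) -> None:
    unknown = set(mapping) - set(allowed)
    if unknown:
        raise SchemaError(f"{context}: unknown keys {sorted(unknown)}")


def _check_proportion(value: float, name: str, context: str,
                      upper_open: bool = False) -> float:
    v = float(value)
    if not (0.0 <= v <= 1.0) or (upper_open and v == 1.0):
        hi = "1)" if upper_open else "1]"
        raise ValidationError(f"{context}: {name}={value!r} outside [0, {hi}")
    return v


def _check_nonneg(value: float, name: str, context: str) -> float:
    v = float(value)
    if v < 0:
        raise ValidationError(f"{context}: {name}={value!r} must be >= 0")
    return v


def _check_positive(value: float, name: str, context: str) -> float:
    v = float(value)
    if v <= 0:
        raise ValidationError(f"{context}: {name}={value!r} must be > 0")
    return v


@dataclass(frozen=True)
class PopulationParams:
    """National-level epidemiology of diagnosed HIV.

    ``national_population`` is a config input (no live statistics lookup);
    diagnosed people living with HIV are
    ``national_population * hiv_prevalence * diagnosed_fraction``, split
    into the recent (<10 years since diagnosis) and longstanding cohorts by
    ``recent_fraction``.  ``annual_mortality`` is a per-person-year death
    probability applied uniformly.
    """

    national_population: float
    hiv_prevalence: float
    diagnosed_fraction: float
    recent_fraction: float
    annual_mortality: float

    def __post_init__(self):
        ctx = "PopulationParams"
        _check_positive(self.national_population, "national_population", ctx)
        _check_proportion(self.hiv_prevalence, "hiv_prevalence", ctx)
        _check_proportion(self.diagnosed_fraction, "diagnosed_fraction", ctx)
        _check_proportion(self.recent_fraction, "recent_fraction", ctx)
        _check_proportion(self.annual_mortality, "annual_mortality", ctx,
                          upper_open=True)


@dataclass(frozen=True)
class CohortSpec:
    """A closed since-diagnosis cohort: 2024 size and 2024 mean age."""

    label: str
    size_2024: float
    mean_age_2024: float

    def __post_init__(self):
        ctx = f"CohortSpec[{self.label}]"
        if self.label not in COHORT_LABELS:
            raise ValidationError(
                f"{ctx}: label must be one of {COHORT_LABELS}")
        _check_nonneg(self.size_2024, "size_2024", ctx)
        _check_positive(self.mean_age_2024, "mean_age_2024", ctx)


@dataclass(frozen=True)
class ComorbidityEpi:
    """Prevalence/incidence schedule for one (comorbidity, cohort) pair.

    ``incidence_young`` applies while the cohort mean age is below
    ``age_threshold``; ``incidence_old`` applies at or above it.  Both decay
    by ``annual_incidence_reduction`` per model year (a conservative
    treatment-improvement assumption).
    """

    comorbidity: str
    cohort: str
    baseline_prevalence: float
    incidence_young: float
    incidence_old: float
    age_threshold: float = 50.0
    annual_incidence_reduction: float = 0.01

    def __post_init__(self):
        ctx = f"ComorbidityEpi[{self.comorbidity}/{self.cohort}]"
        if self.comorbidity not in COMORBIDITIES:
            raise ValidationError(
                f"{ctx}: unknown comorbidity {self.comorbidity!r}")
        if self.cohort not in COHORT_LABELS:
            raise ValidationError(f"{ctx}: unknown cohort {self.cohort!r}")
        _check_proportion(self.baseline_prevalence, "baseline_prevalence", ctx)
        _check_proportion(self.incidence_young, "incidence_young", ctx)
        _check_proportion(self.incidence_old, "incidence_old", ctx)
        _check_positive(self.age_threshold, "age_threshold", ctx)
        _check_proportion(self.annual_incidence_reduction,
                          "annual_incidence_reduction", ctx, upper_open=True)


@dataclass(frozen=True)
class ResourceProfile:
    """Annual healthcare resource use per prevalent patient (events/PY)."""

    comorbidity: str
    quantities: Mapping[str, float]

    def __post_init__(self):
        ctx = f"ResourceProfile[{self.comorbidity}]"
        if self.comorbidity not in COMORBIDITIES:
            raise ValidationError(
                f"{ctx}: unknown comorbidity {self.comorbidity!r}")
        _reject_unknown(self.quantities, RESOURCE_CATEGORIES, ctx)
        for cat in RESOURCE_CATEGORIES:
            q = _require(self.quantities, cat, ctx)
            _check_nonneg(q, cat, ctx)
        object.__setattr__(
            self, "quantities",
            {c: float(self.quantities[c]) for c in RESOURCE_CATEGORIES})


@dataclass(frozen=True)
class UnitCost:
    """A unit cost in euros together with its price-year."""

    cost: float
    origin_year: int

    def __post_init__(self):
        _check_nonneg(self.cost, "cost", "UnitCost")


@dataclass(frozen=True)
class EconSettings:
    """Unit costs, CPI series, discounting and the projection horizon."""

    unit_costs: Mapping[str, UnitCost]
    cpi_index: Mapping[int, float]
    discount_rate: float = 0.03
    base_year: int = 2024
    horizon: tuple = (2024, 2034)

    def __post_init__(self):
        ctx = "EconSettings"
        _reject_unknown(self.unit_costs, RESOURCE_CATEGORIES, ctx)
        for cat in RESOURCE_CATEGORIES:
            uc = _require(self.unit_costs, cat, ctx)
            if not isinstance(uc, UnitCost):
                uc = UnitCost(**uc)
            object.__setattr__(self, "unit_costs",
                               {**self.unit_costs, cat: uc})
        for year, idx in self.cpi_index.items():
            _check_positive(idx, f"cpi_index[{year}]", ctx)
        _check_nonneg(self.discount_rate, "discount_rate", ctx)
        start, end = self.horizon
        object.__setattr__(self, "horizon", (int(start), int(end)))
        if self.horizon[0] != self.base_year:
            raise ValidationError(
                f"{ctx}: horizon start {self.horizon[0]} must equal "
                f"base_year {self.base_year}")
        if self.horizon[1] < self.horizon[0]:
            raise ValidationError(f"{ctx}: empty horizon {self.horizon}")

    @property
    def years(self) -> range:
        return range(self.horizon[0], self.horizon[1] + 1)


@dataclass(frozen=True)
class ScenarioSpec:
    """A named counterfactual: absolute prevalence increases (percentage
    points) added to the 2024 baseline prevalence, per comorbidity/cohort.

    Scenarios are full-exposure counterfactuals — the whole cohort carries
    the regimen's risk increment; incidence schedules are never touched.
    """

    name: str
    source: str
    deltas: Mapping[tuple, float]  # (comorbidity, cohort) -> percentage points

    def __post_init__(self):
        ctx = f"ScenarioSpec[{self.name}]"
        if self.source not in SCENARIO_SOURCES:
            raise ValidationError(
                f"{ctx}: source must be one of {SCENARIO_SOURCES}")
        clean = {}
        for key, pp in self.deltas.items():
            com, cohort = key
            if com not in COMORBIDITIES:
                raise ValidationError(f"{ctx}: unknown comorbidity {com!r}")
            if cohort not in COHORT_LABELS:
                raise ValidationError(f"{ctx}: unknown cohort {cohort!r}")
            if float(pp) < 0:
                raise ValidationError(
                    f"{ctx}: delta for ({com}, {cohort}) is negative: {pp}")
            clean[(com, cohort)] = float(pp)
        object.__setattr__(self, "deltas", clean)

    @property
    def comorbidities(self) -> tuple:
        """Comorbidities this scenario perturbs, in canonical order."""
        present = {c for c, _ in self.deltas}
        return tuple(c for c in COMORBIDITIES if c in present)


@dataclass(frozen=True)
class ParameterBundle:
    """The full validated parameter set for one model run."""

    population: PopulationParams
    cohorts: tuple  # of CohortSpec
    epi: Mapping[tuple, ComorbidityEpi]      # (comorbidity, cohort) -> epi
    resources: Mapping[str, ResourceProfile]  # comorbidity -> profile
    econ: EconSettings
    scenarios: Mapping[str, ScenarioSpec] = field(default_factory=dict)
    update_rule: str = "at-risk"

    def __post_init__(self):
        ctx = "ParameterBundle"
        labels = [c.label for c in self.cohorts]
        if len(set(labels)) != len(labels):
            raise ValidationError(f"{ctx}: duplicate cohort labels {labels}")
        if self.update_rule not in UPDATE_RULES:
            raise ValidationError(
                f"{ctx}: update_rule must be one of {UPDATE_RULES}")
        for com in COMORBIDITIES:
            if com not in self.resources:
                raise SchemaError(f"{ctx}: missing resource profile for {com}")
            for label in labels:
                if (com, label) not in self.epi:
                    raise SchemaError(
                        f"{ctx}: missing epidemiology for ({com}, {label})")

    def cohort(self, label: str) -> CohortSpec:
        for c in self.cohorts:
            if c.label == label:
                return c
        raise KeyError(label)

    @property
    def cohort_labels(self) -> tuple:
        return tuple(c.label for c in self.cohorts)


# ---------------------------------------------------------------------------
# Derivations

def derive_population_2024(pop: PopulationParams) -> tuple:
    """Split the national population into (total diagnosed, recent,
    longstanding) counts of people living with diagnosed HIV in 2024.

    Fractional persons are retained; rounding is a display concern only.
    """
    total = (pop.national_population * pop.hiv_prevalence
             * pop.diagnosed_fraction)
    recent = total * pop.recent_fraction
    return total, recent, total - recent


def derive_baseline_prevalence(count_2024: float,
                               cohort_size_2024: float) -> float:
    """Baseline prevalence as prevalent count / cohort size."""
    if cohort_size_2024 <= 0:
        raise ValidationError(
            f"cohort_size_2024={cohort_size_2024!r} must be > 0")
    if not (0 <= count_2024 <= cohort_size_2024):
        raise ValidationError(
            f"count_2024={count_2024!r} outside [0, {cohort_size_2024}]")
    return count_2024 / cohort_size_2024


# ---------------------------------------------------------------------------
# Config parsing

_TOP_KEYS = ("schema_version", "population", "cohorts", "comorbidity_epi",
             "resources", "econ", "scenarios", "update_rule")


def _parse_bundle(doc: Mapping, context: str = "config") -> ParameterBundle:
    if not isinstance(doc, Mapping):
        raise SchemaError(f"{context}: top level must be a mapping")
    _reject_unknown(doc, _TOP_KEYS, context)
    version = _require(doc, "schema_version", context)
    if int(version) != SCHEMA_VERSION:
        raise SchemaError(
            f"{context}: schema_version {version} != {SCHEMA_VERSION}")

    pop_doc = _require(doc, "population", context)
    _reject_unknown(pop_doc, ("national_population", "hiv_prevalence",
                              "diagnosed_fraction", "recent_fraction",
                              "annual_mortality"), f"{context}.population")
    population = PopulationParams(
        national_population=_require(pop_doc, "national_population",
                                     f"{context}.population"),
        hiv_prevalence=_require(pop_doc, "hiv_prevalence",
                                f"{context}.population"),
        diagnosed_fraction=_require(pop_doc, "diagnosed_fraction",
                                    f"{context}.population"),
        recent_fraction=_require(pop_doc, "recent_fraction",
                                 f"{context}.population"),
        annual_mortality=_require(pop_doc, "annual_mortality",
                                  f"{context}.population"),
    )

    cohorts = []
    for i, cdoc in enumerate(_require(doc, "cohorts", context)):
        cctx = f"{context}.cohorts[{i}]"
        _reject_unknown(cdoc, ("label", "size_2024", "mean_age_2024"), cctx)
        cohorts.append(CohortSpec(
            label=_require(cdoc, "label", cctx),
            size_2024=_require(cdoc, "size_2024", cctx),
            mean_age_2024=_require(cdoc, "mean_age_2024", cctx)))

    epi = {}
    for i, edoc in enumerate(_require(doc, "comorbidity_epi", context)):
        ectx = f"{context}.comorbidity_epi[{i}]"
        _reject_unknown(edoc, ("comorbidity", "cohort", "baseline_prevalence",
                               "incidence_young", "incidence_old",
                               "age_threshold", "annual_incidence_reduction"),
                        ectx)
        e = ComorbidityEpi(
            comorbidity=_require(edoc, "comorbidity", ectx),
            cohort=_require(edoc, "cohort", ectx),
            baseline_prevalence=_require(edoc, "baseline_prevalence", ectx),
            incidence_young=_require(edoc, "incidence_young", ectx),
            incidence_old=_require(edoc, "incidence_old", ectx),
            age_threshold=edoc.get("age_threshold", 50.0),
            annual_incidence_reduction=edoc.get("annual_incidence_reduction",
                                                0.01))
        epi[(e.comorbidity, e.cohort)] = e

    resources = {}
    res_doc = _require(doc, "resources", context)
    _reject_unknown(res_doc, COMORBIDITIES, f"{context}.resources")
    for com, quantities in res_doc.items():
        resources[com] = ResourceProfile(comorbidity=com,
                                         quantities=dict(quantities))

    econ_doc = _require(doc, "econ", context)
    ectx = f"{context}.econ"
    _reject_unknown(econ_doc, ("unit_costs", "cpi_index", "discount_rate",
                               "base_year", "horizon"), ectx)
    unit_costs = {}
    for cat, uc in _require(econ_doc, "unit_costs", ectx).items():
        _reject_unknown(uc, ("cost", "origin_year"),
                        f"{ectx}.unit_costs[{cat}]")
        unit_costs[cat] = UnitCost(cost=_require(uc, "cost", ectx),
                                   origin_year=int(_require(uc, "origin_year",
                                                            ectx)))
    econ = EconSettings(
        unit_costs=unit_costs,
        cpi_index={int(y): float(v)
                   for y, v in _require(econ_doc, "cpi_index", ectx).items()},
        discount_rate=econ_doc.get("discount_rate", 0.03),
        base_year=int(econ_doc.get("base_year", 2024)),
        horizon=tuple(_require(econ_doc, "horizon", ectx)))

    scenarios = {}
    for i, sdoc in enumerate(doc.get("scenarios", [])):
        sctx = f"{context}.scenarios[{i}]"
        _reject_unknown(sdoc, ("name", "source", "deltas"), sctx)
        deltas = {}
        for j, ddoc in enumerate(_require(sdoc, "deltas", sctx)):
            dctx = f"{sctx}.deltas[{j}]"
            _reject_unknown(ddoc, ("comorbidity", "cohort", "pp"), dctx)
            deltas[(_require(ddoc, "comorbidity", dctx),
                    _require(ddoc, "cohort", dctx))] = \
                _require(ddoc, "pp", dctx)
        spec = ScenarioSpec(name=_require(sdoc, "name", sctx),
                            source=_require(sdoc, "source", sctx),
                            deltas=deltas)
        scenarios[spec.name] = spec

    return ParameterBundle(population=population, cohorts=tuple(cohorts),
                           epi=epi, resources=resources, econ=econ,
                           scenarios=scenarios,
                           update_rule=doc.get("update_rule", "at-risk"))


def load_model_config(path) -> ParameterBundle:
    """Load and fully validate a model configuration (YAML or JSON)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    text = path.read_text()
    if path.suffix == ".json":
        doc = json.loads(text)
    else:
        doc = yaml.safe_load(text)
    return _parse_bundle(doc, context=str(path.name))


def bundle_to_doc(bundle: ParameterBundle) -> dict:
    """Serialize a bundle to the plain-dict config schema (inverse of
    :func:`load_model_config` up to float representation)."""
    return {
        "schema_version": SCHEMA_VERSION,
        "population": asdict(bundle.population),
        "cohorts": [asdict(c) for c in bundle.cohorts],
        "comorbidity_epi": [asdict(e) for e in bundle.epi.values()],
        "resources": {com: dict(p.quantities)
                      for com, p in bundle.resources.items()},
        "econ": {
            "unit_costs": {cat: {"cost": uc.cost,
                                 "origin_year": uc.origin_year}
                           for cat, uc in bundle.econ.unit_costs.items()},
            "cpi_index": dict(bundle.econ.cpi_index),
            "discount_rate": bundle.econ.discount_rate,
            "base_year": bundle.econ.base_year,
            "horizon": list(bundle.econ.horizon),
        },
        "scenarios": [
            {"name": s.name, "source": s.source,
             "deltas": [{"comorbidity": com, "cohort": cohort, "pp": pp}
                        for (com, cohort), pp in sorted(s.deltas.items())]}
            for s in bundle.scenarios.values()],
        "update_rule": bundle.update_rule,
    }


def dump_model_config(bundle: ParameterBundle, path) -> None:
    """Write a bundle back out as YAML (or JSON if the suffix is .json)."""
    path = Path(path)
    doc = bundle_to_doc(bundle)
    if path.suffix == ".json":
        path.write_text(json.dumps(doc, indent=2))
    else:
        path.write_text(yaml.safe_dump(doc, sort_keys=False))


def export_params_csv(bundle: ParameterBundle, out_dir) -> list:
    """Dump each parameter table to a CSV for audit; returns written paths."""
    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []

    def _write(name, frame):
        p = out_dir / f"params_{name}.csv"
        frame.to_csv(p, index=False)
        written.append(p)

    _write("population", pd.DataFrame([asdict(bundle.population)]))
    _write("cohorts", pd.DataFrame([asdict(c) for c in bundle.cohorts]))
    _write("comorbidity_epi",
           pd.DataFrame([asdict(e) for e in bundle.epi.values()]))
    _write("resources", pd.DataFrame([
        {"comorbidity": com, **p.quantities}
        for com, p in bundle.resources.items()]))
    _write("unit_costs", pd.DataFrame([
        {"resource": cat, "cost": uc.cost, "origin_year": uc.origin_year}
        for cat, uc in bundle.econ.unit_costs.items()]))
    _write("scenarios", pd.DataFrame([
        {"scenario": s.name, "source": s.source, "comorbidity": com,
         "cohort": cohort, "pp": pp}
        for s in bundle.scenarios.values()
        for (com, cohort), pp in sorted(s.deltas.items())]))
    return written
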