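"""Costing of prevalent person-years: resource dot-products, CPI inflation
and annual discounting.

Every prevalent person accrues one year of the comorbidity's resource
profile per cycle.  Unit costs are inflated from their origin price-year to
the base year with a consumer-price-index ratio, and future annual costs
are discounted back to the base year at a constant annual rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import EconSettings, ResourceProfile, ValidationError
from .projection import CountTrajectory


class CostingError(ValueError):
    """A resource category cannot be priced or a CPI year is missing."""


def inflate_cost(amount: float, origin_year: int, target_year: int,
                 cpi_index) -> float:
    """Re-express ``amount`` from origin-year prices in target-year prices
    using the CPI ratio ``cpi(target) / cpi(origin)``."""
    for year in (origin_year, target_year):
        if year not in cpi_index:
            raise CostingError(f"CPI index has no entry for year {year}")
    return amount * cpi_index[target_year] / cpi_index[origin_year]


def annual_cost_per_patient(profile: ResourceProfile,
                            econ: EconSettings) -> float:
    """Annual direct healthcare cost of one prevalent patient (€/PY).

    Dot product of the resource-use quantities with unit costs, each unit
    cost inflated from its origin year to the base year first.
    """
    total = 0.0
    for category, quantity in profile.quantities.items():
        if category not in econ.unit_costs:
            raise CostingError(
                f"no unit cost for resource category {category!r}")
        uc = econ.unit_costs[category]
        price = inflate_cost(uc.cost, uc.origin_year, econ.base_year,
                             econ.cpi_index)
        total += quantity * price
    return total


def discount_factor(year: int, econ: EconSettings) -> float:
    """Present-value factor ``(1 + r)^-(year - base_year)``; 1 at base."""
    if year < econ.base_year:
        raise ValidationError(
            f"year {year} precedes base year {econ.base_year}")
    return (1.0 + econ.discount_rate) ** -(year - econ.base_year)


@dataclass(frozen=True)
class CostTrajectory:
    """Annual and cumulative discounted costs for one cohort/comorbidity."""

    cohort: str
    comorbidity: str
    years: np.ndarray
    undiscounted: np.ndarray   # € per year
    discounted: np.ndarray     # € per year, present value at base year

    @property
    def cumulative_discounted(self) -> float:
        return float(np.sum(self.discounted))

    @property
    def cumulative_undiscounted(self) -> float:
        return float(np.sum(self.undiscounted))


def cost_trajectory(counts: CountTrajectory, per_patient: float,
                    econ: EconSettings) -> CostTrajectory:
    """Annual costs = prevalent stock × per-patient cost, then discounted."""
    if per_patient < 0:
        raise ValidationError(f"per_patient={per_patient} must be >= 0")
    undiscounted = counts.prevalent * per_patient
    factors = np.array([discount_factor(int(y), econ) for y in counts.years])
    return CostTrajectory(cohort=counts.cohort,
                          comorbidity=counts.comorbidity,
                          years=counts.years.copy(),
                          undiscounted=undiscounted,
                          discounted=undiscounted * factors)
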