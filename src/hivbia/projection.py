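"""Closed-cohort projection of population and prevalent comorbidity counts.

The engine advances two closed since-diagnosis cohorts through annual
cycles.  Attrition is a single uniform mortality probability; nobody enters
and nobody migrates between cohorts.  Prevalent counts per comorbidity start
from a baseline stock and grow by age-banded, annually decaying incidence.
Comorbidity is absorbing (no remission), and comorbidities are modelled
independently of each other.

Two update rules are available for the incident flow:

* ``at-risk`` (default): incidence applies to the comorbidity-free pool,
  ``P(t+1) = [P(t) + i(t) * (N(t) - P(t))] * (1 - m)``.
* ``whole-cohort``: incidence applies to everyone alive,
  ``P(t+1) = [P(t) + i(t) * N(t)] * (1 - m)``, clipped at the cohort size
  so the prevalent pool can never exceed the living cohort.

Counts are cycle-start stocks; mortality acts at cycle end; no half-cycle
correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import (CohortSpec, ComorbidityEpi, PopulationParams,
                     ValidationError, UPDATE_RULES)


@dataclass(frozen=True)
class PopulationTrajectory:
    """Alive persons and mean age of one cohort at each cycle start."""

    cohort: str
    years: np.ndarray        # calendar years, consecutive
    alive: np.ndarray        # persons alive at cycle start (fractional)
    mean_age: np.ndarray     # mean cohort age, +1 per cycle

    def __len__(self) -> int:
        return len(self.years)


@dataclass(frozen=True)
class CountTrajectory:
    """Prevalent persons with one comorbidity in one cohort, per year."""

    cohort: str
    comorbidity: str
    years: np.ndarray
    prevalent: np.ndarray

    def __len__(self) -> int:
        return len(self.years)


def project_cohort_population(cohort: CohortSpec, pop: PopulationParams,
                              horizon: tuple) -> PopulationTrajectory:
    """Geometric survival decay of a closed cohort over the horizon.

    ``N(t) = size_2024 * (1 - m)^(t - start)``; mean age advances one year
    per cycle.
    """
    start, end = int(horizon[0]), int(horizon[1])
    if end < start:
        raise ValidationError(f"empty horizon ({start}, {end})")
    offsets = np.arange(end - start + 1)
    alive = cohort.size_2024 * (1.0 - pop.annual_mortality) ** offsets
    return PopulationTrajectory(
        cohort=cohort.label,
        years=start + offsets,
        alive=alive,
        mean_age=cohort.mean_age_2024 + offsets.astype(float))


def incidence_at(epi: ComorbidityEpi, cohort_mean_age: float,
                 years_since_base: int) -> float:
    """Annual incidence probability for a cohort of the given mean age,
    ``years_since_base`` cycles after model entry.

    The age band switches to the old-age rate the year the mean age reaches
    the threshold (``>=``), and the selected rate decays geometrically by
    the annual incidence reduction.
    """
    if years_since_base < 0:
        raise ValidationError(
            f"years_since_base={years_since_base} must be >= 0")
    band = (epi.incidence_old if cohort_mean_age >= epi.age_threshold
            else epi.incidence_young)
    return band * (1.0 - epi.annual_incidence_reduction) ** years_since_base


def project_comorbidity_counts(traj: PopulationTrajectory,
                               epi: ComorbidityEpi,
                               baseline_count: float,
                               annual_mortality: float,
                               rule: str = "at-risk") -> CountTrajectory:
    """Advance the prevalent stock of one comorbidity along a cohort
    trajectory.

    The baseline stock enters in the first year; each cycle adds incident
    cases from the selected pool (at-risk or whole cohort) and removes the
    mortality share.
    """
    if rule not in UPDATE_RULES:
        raise ValidationError(f"unknown update rule {rule!r}")
    if baseline_count < 0 or baseline_count > traj.alive[0]:
        raise ValidationError(
            f"baseline_count={baseline_count} outside [0, {traj.alive[0]}] "
            f"for cohort {traj.cohort!r}")

    n = len(traj)
    prevalent = np.empty(n)
    prevalent[0] = baseline_count
    surv = 1.0 - annual_mortality
    for k in range(n - 1):
        i_k = incidence_at(epi, traj.mean_age[k], k)
        pool = (traj.alive[k] - prevalent[k]) if rule == "at-risk" \
            else traj.alive[k]
        nxt = (prevalent[k] + i_k * pool) * surv
        # whole-cohort flow can overshoot the living cohort at extreme rates
        prevalent[k + 1] = min(nxt, traj.alive[k + 1])
    return CountTrajectory(cohort=traj.cohort, comorbidity=epi.comorbidity,
                           years=traj.years.copy(), prevalent=prevalent)


def person_years(traj) -> float:
    """Person-years of a trajectory: the sum of its annual stocks.

    Each person present at a cycle start contributes one person-year for
    that cycle; an 11-year horizon therefore has 11 contributing cycles.
    Accepts a :class:`CountTrajectory`, a :class:`PopulationTrajectory`, or
    any array of per-cycle counts.
    """
    if isinstance(traj, CountTrajectory):
        values = traj.prevalent
    elif isinstance(traj, PopulationTrajectory):
        values = traj.alive
    else:
        values = np.asarray(traj, dtype=float)
    return float(np.sum(values))
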