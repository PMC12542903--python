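"""Incidence calibration: recover annual incidence rates from printed
endpoint counts by bisection.

Published model outputs give the 2024 and 2034 prevalent counts per
comorbidity and cohort, but not the annual incidence schedule that links
them.  Because the projected 2034 count is strictly increasing in the base
incidence (monotone update rule), a single scalar per (comorbidity, cohort)
can be recovered by bisection on [0, 1].  Two band rates cannot both be
identified from two endpoints, so the old-age band is tied to the young
band by a configurable ``old_young_ratio``.
"""

from __future__ import annotations

from dataclasses import dataclass

from .params import CohortSpec, ComorbidityEpi, PopulationParams
from .projection import project_cohort_population, project_comorbidity_counts

#: |achieved - target| below this counts as converged (persons).
RESIDUAL_TOL = 0.5
#: Bisection tolerance on the incidence probability itself.
INCIDENCE_TOL = 1e-10
MAX_ITERATIONS = 200


class CalibrationError(RuntimeError):
    """Target infeasible or bisection failed to converge."""


@dataclass(frozen=True)
class CalibrationResult:
    comorbidity: str
    cohort: str
    base_incidence: float      # fitted young-band annual probability
    old_incidence: float       # base_incidence * old_young_ratio (capped 1)
    achieved_2034: float
    target_2034: float
    iterations: int
    converged: bool

    @property
    def residual(self) -> float:
        return self.achieved_2034 - self.target_2034


def _endpoint(base: float, *, comorbidity: str, cohort: CohortSpec,
              pop: PopulationParams, baseline: float, decay: float,
              ratio: float, horizon: tuple, rule: str) -> float:
    epi = ComorbidityEpi(comorbidity=comorbidity, cohort=cohort.label,
                         baseline_prevalence=baseline / cohort.size_2024,
                         incidence_young=base,
                         incidence_old=min(1.0, base * ratio),
                         annual_incidence_reduction=decay)
    traj = project_cohort_population(cohort, pop, horizon)
    counts = project_comorbidity_counts(traj, epi, baseline,
                                        pop.annual_mortality, rule=rule)
    return float(counts.prevalent[-1])


def calibrate_incidence(target_2034: float, baseline_2024: float,
                        cohort: CohortSpec, pop: PopulationParams,
                        comorbidity: str = "cardiovascular",
                        decay: float = 0.01, old_young_ratio: float = 1.0,
                        horizon: tuple = (2024, 2034),
                        rule: str = "at-risk") -> CalibrationResult:
    """Find the base (young-band) incidence whose forward projection hits
    the target endpoint count, by bisection on [0, 1].

    Raises :class:`CalibrationError` if the target lies below the
    zero-incidence survival projection or above the incidence-1 bound.
    """
    if not (0 <= baseline_2024 <= cohort.size_2024):
        raise CalibrationError(
            f"baseline {baseline_2024} outside [0, {cohort.size_2024}]")

    kw = dict(comorbidity=comorbidity, cohort=cohort, pop=pop,
              baseline=baseline_2024, decay=decay, ratio=old_young_ratio,
              horizon=horizon, rule=rule)
    lo, hi = 0.0, 1.0
    f_lo, f_hi = _endpoint(lo, **kw), _endpoint(hi, **kw)
    if target_2034 < f_lo - RESIDUAL_TOL:
        raise CalibrationError(
            f"infeasible target {target_2034}: below the zero-incidence "
            f"projection {f_lo:.2f}")
    if target_2034 > f_hi + RESIDUAL_TOL:
        raise CalibrationError(
            f"infeasible target {target_2034}: above the maximum "
            f"achievable count {f_hi:.2f}")

    base, achieved, iterations = lo, f_lo, 0
    for iterations in range(1, MAX_ITERATIONS + 1):
        base = 0.5 * (lo + hi)
        achieved = _endpoint(base, **kw)
        if achieved < target_2034:
            lo = base
        else:
            hi = base
        if hi - lo < INCIDENCE_TOL:
            break
    converged = abs(achieved - target_2034) < RESIDUAL_TOL
    if not converged:
        raise CalibrationError(
            f"bisection did not converge for ({comorbidity}, "
            f"{cohort.label}): bracket [{lo}, {hi}], achieved {achieved:.3f} "
            f"vs target {target_2034}")
    return CalibrationResult(comorbidity=comorbidity, cohort=cohort.label,
                             base_incidence=base,
                             old_incidence=min(1.0, base * old_young_ratio),
                             achieved_2034=achieved,
                             target_2034=float(target_2034),
                             iterations=iterations, converged=converged)


def calibration_report(results) -> "pandas.DataFrame":
    """Tabulate calibration results for CSV export."""
    import pandas as pd

    return pd.DataFrame([
        {"comorbidity": r.comorbidity, "cohort": r.cohort,
         "base_incidence": r.base_incidence,
         "old_incidence": r.old_incidence,
         "achieved_2034": r.achieved_2034, "target_2034": r.target_2034,
         "residual": r.residual, "iterations": r.iterations,
         "converged": r.converged}
        for r in results])
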