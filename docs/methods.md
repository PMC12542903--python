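# Methods

## Model structure and assumptions

The model is a deterministic, static-cohort projection with 1-year cycles
over an inclusive 11-year horizon (2024–2034 in the reference
configuration). Two closed cohorts — diagnosed <10 years ago ("recent",
mean age 34 in 2024) and ≥10 years ago ("longstanding", mean age 48) — are
subject only to attrition: a single annual mortality probability applied
uniformly, with no new diagnoses, no migration between cohorts, and no
differential mortality for people with comorbidities. Cohort mean age
advances exactly one year per cycle and drives the incidence age band.

Four comorbidity groups (cardiovascular, renal, bone, neuropsychiatric)
are modelled independently: a person may appear in several prevalent
pools, and no multimorbidity adjustment is made. Comorbidity is an
absorbing state (no remission). Counts are cycle-start stocks; mortality
acts at cycle end; no half-cycle correction is applied — with these
conventions the alive person-years equal the plain geometric sum
N₀·Σ(1−m)^t, which matches the published bookkeeping to 0.02%.

Two update rules are implemented for the incident flow:

- **at-risk** (default): incidence applies to the comorbidity-free pool,
  P(t+1) = [P(t) + i(t)(N(t) − P(t))](1 − m). This is the default because
  the published scenario-vs-current differences shrink over the horizon
  faster than survival alone would explain, which is the signature of
  pool-saturation dynamics.
- **whole-cohort**: P(t+1) = [P(t) + i(t)N(t)](1 − m), kept selectable
  because the semantics of the source incidence schedule are not
  published. This rule can mathematically overshoot the living cohort at
  extreme rates, so the stock is clipped at N(t+1) each cycle; the clip is
  inactive in every realistic regime.

The age-band switch uses "mean age ≥ threshold" (default 50): a cohort
entering at 48 switches in its third model year, which reproduces the
qualitative cost uptick in 2026. Incidence decays by 1%/year
(i(t) = band·0.99^t), a conservative treatment-improvement assumption.

## Key parameters (reference configuration)

| parameter | value | units |
|---|---|---|
| national population | 48 610 288 | persons (back-solved; see below) |
| HIV prevalence | 0.31% | proportion |
| diagnosed fraction | 92.5% | of PLWH |
| recent-diagnosis fraction | 39.6% | of diagnosed |
| annual mortality | 0.0207 | probability/person-year |
| age threshold | 50 | years |
| annual incidence reduction | 1% | per year |
| discount rate | 3% | per year, base 2024 |
| horizon | 2024–2034 | inclusive, 11 cycles |

The national population is not an external lookup: it is back-solved so
that population × prevalence × diagnosed fraction equals the published
total of 139 390 diagnosed PLWH, splitting into 55 198.4 / 84 191.6 per
cohort. Fractional persons are retained through every computation;
half-up rounding to integers happens only in presentation layouts, and
recomputing from full-precision tidy exports reproduces in-memory results
exactly.

## Costing

Each prevalent person-year accrues the comorbidity's annual resource
profile: six closed categories (hospital admissions, diagnostic tests,
emergency visits, non-HIV outpatient visits, HIV visits, blood tests)
priced at national unit costs. Unit costs carry an origin price-year and
are inflated to the base year by a CPI ratio; in the reference
configuration they are already expressed in 2024 euros, so the CPI path is
an identity kept for configurations with older cost sources. Future annual
costs are discounted by (1 + r)^−(t − base); the base year is undiscounted.
Drug-acquisition, indirect and societal costs and utility weighting are
out of scope.

## Scenarios and sensitivity analyses

A scenario adds absolute percentage-point increments to the 2024 baseline
prevalence of one comorbidity, per cohort, capped at 100% — a
full-exposure counterfactual for one regimen at a time, never
market-share-weighted or combined. Incidence, mortality and costs are
identical between the paired runs. Percentage increases are reported on
two explicitly labelled bases: undiscounted person-years and discounted
cumulative cost. The two differ slightly (the extra stock enters at model
start where discounting weighs least), and neither is asserted to be "the"
published basis, which is not internally consistent across comorbidities.

Sensitivity analyses replace (rather than shift) baseline prevalences for
a selected cohort with values from an alternative source study;
comorbidities without a replacement value are skipped and flagged, since
the source cohort studies do not all cover all four groups. The original
study's sensitivity prevalence inputs are unpublished, so the test suite
exercises this operation with synthetic replacement values only.

## Calibration of unpublished incidence

Baseline prevalences are derived as published 2024 prevalent counts ÷
cohort sizes. The annual incidence schedules are unpublished and are
recovered by endpoint matching: the projected 2034 count is strictly
increasing in the base incidence, so bisection on [0, 1] (tolerance 1e−10
on the rate, ≤200 iterations, convergence declared at |residual| < 0.5
persons) recovers one scalar per (comorbidity, cohort). Infeasible targets
— below the zero-incidence survival projection or above the incidence-1
bound — raise an error with the bracket state.

Two printed endpoints cannot identify two age-band rates, so the old band
is tied to the young band by a configurable old:young ratio. The recent
cohort never reaches age 50 in-horizon, so its ratio is irrelevant and
fixed at 1. For the longstanding cohort the ratio is genuinely
underdetermined; the default of 1.5 encodes a moderate age effect and
reproduces the qualitative 2026 inflection, but any ratio > 1 would. The
calibration is deterministic, so rebuilding the reference bundle always
yields bit-identical rates. Calibration matches endpoints only: interior
years (and therefore person-year totals) depend on the unpublished
schedule's shape, and the reference run lands within 0.2–1.2% of the
published person-year totals.

## Synthetic data generator

`generate_synthetic_params(seed)` draws a complete schema-valid bundle
from documented uniform ranges: cohort sizes 10³–10⁵, mean ages 30–55,
baseline prevalences 0–0.3, incidences 0–0.05, mortality 0–0.05, incidence
decay 0–2%/yr, resource quantities 0–10 events/PY, unit costs €20–€5000,
scenario deltas 0–8 pp, discount 0–5% — the order of magnitude of the
reference inputs. It records the generating truth so calibration-recovery
tests can invert it. The generator emulates the *structure* of real
inputs, not their correlations: quantities and rates are drawn
independently, mortality is uniform, and cohorts are exactly closed, so
passing property tests demonstrates arithmetic correctness of the engine,
not epidemiological realism of any particular configuration.

## Numerical choices

- Bisection rather than a derivative-based root finder: the objective is
  monotone and cheap, bracketing is guaranteed, and the tolerance (1e−10)
  is far below person-level resolution.
- The engine's population path is the vectorized closed form
  N₀(1−m)^t; prevalent stocks are advanced by an explicit per-cycle
  recurrence. Tests compare both against an independently written scalar
  loop at rtol 1e−9 (sequential products and powers differ only at
  accumulated machine epsilon).
- Degenerate inputs: empty horizons are rejected; baseline counts above
  the cohort size are validation errors; prevalence deltas are capped at
  unity; zero cohort sizes, zero prevalences and zero rates propagate
  exactly.
- Percentage increases use the plain ratio (scenario/current − 1)·100 and
  are rounded only for display (2 decimals).

## Known limitations

- No incident-HIV inflow, cohort re-assignment, cause-specific or
  comorbidity-differential mortality, probabilistic sensitivity analysis,
  or treatment-switching dynamics.
- Cohort aging is tracked by mean age only; the age-band switch is a step
  function of the mean, not an integral over an age distribution.
- Interior-year incidence shape is identified only up to the endpoint
  constraint and the assumed band ratio.
- Published input tables are rounded to 2 decimals; recomputed first-year
  costs therefore differ from published values by up to ~0.35%, within
  the 1% band the input precision supports.
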