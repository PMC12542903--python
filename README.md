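# hivbia

A deterministic static-cohort budget-impact model of cardiovascular, renal,
bone and neuropsychiatric comorbidities in people living with HIV (PLWH),
parametrized for the Spanish National Health System over 2024–2034, with
counterfactual scenarios for the toxicity profiles of common antiretroviral
regimens (darunavir, dolutegravir, bictegravir, tenofovir disoproxil).

It is written for health economists and HIV epidemiologists who want a
tested, configurable, scriptable version of this class of Excel budget
model: closed cohorts, annual cycles, prevalence–incidence dynamics,
resource-based costing, discounting, scenario and sensitivity analyses —
plus a calibration routine that recovers unpublished incidence schedules
from published endpoint counts.

## The model

Two closed cohorts (diagnosed <10 years, diagnosed ≥10 years) are projected
over annual cycles *t* = 2024 … 2034:

- population: *N(t+1) = N(t)·(1 − m)*, with a uniform annual mortality
  probability *m* = 0.0207; cohort mean age advances one year per cycle;
- prevalent comorbidity stock (default at-risk rule, absorbing state):

  *P(t+1) = [P(t) + i(t)·(N(t) − P(t))]·(1 − m)*

  where *i(t) = i_band(age(t))·(1 − d)^t*, with age-banded incidence
  (band switch at mean age ≥ 50) and annual incidence decay *d* = 0.01.
  A whole-cohort variant *P(t+1) = [P(t) + i(t)·N(t)]·(1 − m)* is
  selectable by config flag;
- costs: each prevalent person-year is priced with a per-comorbidity
  resource dot-product (admissions, diagnostic tests, ED visits,
  outpatient, HIV visits, blood tests × unit costs, CPI-inflated to 2024)
  and discounted at 3%/year: *(1 + r)^−(t − 2024)*;
- scenarios: absolute percentage-point additions to the 2024 baseline
  prevalence (full-exposure counterfactuals, incidence untouched), run as
  paired executions and reported as person-year and cost increases;
- calibration: the 2034 endpoint count is strictly increasing in the base
  incidence, so bisection on [0, 1] recovers one incidence scalar per
  (comorbidity, cohort) from the published 2024/2034 counts.

Fractional persons are carried everywhere; rounding is display-only.

## Worked example

```sh
python examples/current_scenario.py
```

prints (abridged):

```
Diagnosed PLWH: 139,390 in 2024 -> 113,081 in 2034 (2.07%/yr mortality, closed cohorts)
Alive person-years over the horizon: 1,384,053

comorbidity          2024    2034  person-years  cost 2024 (M EUR)  cum. disc. (M EUR)
cardiovascular     17,047  33,555       286,484              83.47                1192
renal               7,753  15,391       129,575              47.42                 673
bone               17,701  33,950       291,935              54.70                 767
neuropsychiatric   16,207  27,388       244,404              97.01                1248
```

Reading: 17 047 people have a cardiovascular comorbidity at model entry and
33 555 at the end of the horizon; they accumulate 286 484 prevalent
person-years, cost €83.47 million in the first year, and €1 192 million
cumulatively at a 3% discount rate. Counts nearly double even though the
cohort shrinks, because incidence outpaces mortality.

Other examples: `art_toxicity_scenarios.py` (the seven regimen
counterfactuals; e.g. the tenofovir-disoproxil renal increment adds ~56%
person-years), `calibrate_from_endpoints.py` (incidence recovery from two
published counts), `synthetic_pipeline.py` (end-to-end run on a seeded
synthetic parameter bundle).

The same pipeline is available from a shell:

```sh
hivbia run --config src/hivbia/data/paper_fixture.yaml --scenario all --out out/
```

which writes trajectory, cost and comparison CSVs plus a run manifest.

## Configuration

All parameters live in one YAML/JSON schema (see
`src/hivbia/data/paper_fixture.yaml` for the full Spanish reference set):
national epidemiology, cohort specs, per-(comorbidity, cohort)
prevalence/incidence, resource quantities, unit costs with origin year and
a CPI series, discount rate, horizon, and named scenario blocks. Validation
is strict — unknown keys and out-of-range values are rejected with errors
naming the offending field.

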