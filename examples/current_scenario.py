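"""Project the current scenario: comorbidity burden and costs 2024-2034.

Builds the Spanish reference parameter set (two since-diagnosis cohorts,
four comorbidities), runs the deterministic annual-cycle projection, and
prints prevalent counts, person-years and cumulative discounted costs.
"""

from hivbia import paper_fixture, run_model
from hivbia.params import COMORBIDITIES

bundle = paper_fixture()
result = run_model(bundle)

total_2024 = sum(c.size_2024 for c in bundle.cohorts)
total_2034 = sum(t.alive[-1] for t in result.population.values())
print(f"Diagnosed PLWH: {total_2024:,.0f} in 2024 -> {total_2034:,.0f} "
      f"in 2034 (2.07%/yr mortality, closed cohorts)")
print(f"Alive person-years over the horizon: "
      f"{result.total_person_years():,.0f}\n")

print(f"{'comorbidity':<17}{'2024':>8}{'2034':>8}{'person-years':>14}"
      f"{'cost 2024 (M EUR)':>19}{'cum. disc. (M EUR)':>20}")
for com in COMORBIDITIES:
    n24 = result.prevalent(com, 2024)
    n34 = result.prevalent(com, 2034)
    py = result.person_years(com)
    cost24 = n24 * result.per_patient_cost[com] / 1e6
    cum = result.cumulative_cost(com) / 1e6
    print(f"{com:<17}{n24:>8,.0f}{n34:>8,.0f}{py:>14,.0f}"
          f"{cost24:>19.2f}{cum:>20.0f}")

print("\nEach row: prevalent patients at model entry and at the end of the"
      "\nhorizon, prevalent person-years accumulated over the 11 annual"
      "\ncycles, the first-year annual cost, and the 3%-discounted"
      "\ncumulative cost. Counts nearly double while the cohort shrinks:"
      "\nincidence outpaces mortality.")
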