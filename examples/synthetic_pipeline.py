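"""Exercise the whole pipeline on a synthetic parameter bundle.

Draws a schema-valid bundle from documented ranges (seeded, reproducible),
runs projection + costing + a scenario comparison, and demonstrates that
endpoint calibration recovers the generating incidence.
"""

from hivbia import (calibrate_incidence, generate_synthetic_params,
                    run_model, run_scenario_comparison)
from hivbia.calibration import _endpoint

sb = generate_synthetic_params(seed=2024)
bundle = sb.bundle
result = run_model(bundle)

print(f"synthetic bundle (seed {sb.seed}): cohort sizes "
      + ", ".join(f"{c.label}={c.size_2024:,.0f}" for c in bundle.cohorts))
print(f"alive person-years: {result.total_person_years():,.0f}")

comp = run_scenario_comparison(bundle, bundle.scenarios["synthetic_shift"])
for com, row in comp.rows.items():
    print(f"  {com:<17} PY +{row.py_increase_pct:6.2f}%   "
          f"cost +{row.cost_increase_pct:6.2f}%")

# parameter recovery: hide the renal/recent incidence, recover it from the
# endpoint its own forward run produces
cohort = bundle.cohort("recent")
epi = bundle.epi[("renal", "recent")]
truth = sb.truth["incidence_renal_recent"]
ratio = sb.truth["old_young_ratio_renal_recent"]
baseline = epi.baseline_prevalence * cohort.size_2024
target = _endpoint(truth, comorbidity="renal", cohort=cohort,
                   pop=bundle.population, baseline=baseline,
                   decay=epi.annual_incidence_reduction, ratio=ratio,
                   horizon=bundle.econ.horizon, rule="at-risk")
cal = calibrate_incidence(target, baseline, cohort, bundle.population,
                          comorbidity="renal",
                          decay=epi.annual_incidence_reduction,
                          old_young_ratio=ratio,
                          horizon=bundle.econ.horizon)
print(f"\nincidence recovery: truth={truth:.8f}  "
      f"recovered={cal.base_incidence:.8f}  "
      f"|error|={abs(cal.base_incidence - truth):.2e}")
print("\nScenario percentages respond to the drawn percentage-point"
      "\nshifts, and bisection recovers the generating incidence to"
      "\nbetter than 1e-6 — the identifiability property the reference"
      "\nparameter set relies on.")
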