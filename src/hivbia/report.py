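"""Presentation layouts, CSV export and run manifests.

Tidy exports carry full precision; presentation layouts (the published
table shapes) round to whole persons, half up.  Display rounding never
feeds back into any computation.
"""

from __future__ import annotations

import hashlib
import json
import math
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from .model import ModelResult
from .params import COMORBIDITIES
from .projection import person_years

LAYOUTS = ("table3", "table4", "figure1_series", "figure2_series", "tidy")


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def counts_wide(result: ModelResult) -> pd.DataFrame:
    """Published count-table layout: per comorbidity, the first-year and
    last-year prevalent counts and total person-years, per cohort and
    overall.  Counts rounded half-up for display."""
    first = result.bundle.econ.horizon[0]
    last = result.bundle.econ.horizon[1]
    rows = []
    for com in COMORBIDITIES:
        row = {"comorbidity": com}
        total_py = 0.0
        for cohort in result.bundle.cohort_labels:
            traj = result.counts[(com, cohort)]
            py = person_years(traj)
            total_py += py
            row[f"{cohort}_{first}"] = round_half_up(traj.prevalent[0])
            row[f"{cohort}_{last}"] = round_half_up(traj.prevalent[-1])
            row[f"{cohort}_py"] = round_half_up(py)
        row["total_py"] = round_half_up(total_py)
        rows.append(row)
    return pd.DataFrame(rows)


def scenario_counts_wide(comparisons: dict) -> pd.DataFrame:
    """Counterfactual count layout: one row per (scenario, comorbidity)."""
    rows = []
    for name, comp in comparisons.items():
        res = comp.scenario
        first = res.bundle.econ.horizon[0]
        last = res.bundle.econ.horizon[1]
        for com in comp.rows:
            row = {"scenario": name, "comorbidity": com}
            total_py = 0.0
            for cohort in res.bundle.cohort_labels:
                traj = res.counts[(com, cohort)]
                py = person_years(traj)
                total_py += py
                row[f"{cohort}_{first}"] = round_half_up(traj.prevalent[0])
                row[f"{cohort}_{last}"] = round_half_up(traj.prevalent[-1])
                row[f"{cohort}_py"] = round_half_up(py)
            row["total_py"] = round_half_up(total_py)
            rows.append(row)
    return pd.DataFrame(rows)


def cumulative_cost_series(result: ModelResult) -> pd.DataFrame:
    """Cumulative discounted cost per comorbidity per year (full
    precision), one point per horizon year."""
    rows = []
    for com in COMORBIDITIES:
        years = result.bundle.econ.years
        running = 0.0
        per_year = {y: 0.0 for y in years}
        for cohort in result.bundle.cohort_labels:
            ct = result.costs[(com, cohort)]
            for k, y in enumerate(ct.years):
                per_year[int(y)] += float(ct.discounted[k])
        for y in years:
            running += per_year[y]
            rows.append({"comorbidity": com, "year": y,
                         "cumulative_discounted_eur": running})
    return pd.DataFrame(rows)


def incremental_cost_series(comparisons: dict) -> pd.DataFrame:
    """Scenario-vs-current cumulative discounted cost per year, with the
    incremental difference — the published cost-figure series."""
    rows = []
    for name, comp in comparisons.items():
        cur = cumulative_cost_series(comp.current)
        scen = cumulative_cost_series(comp.scenario)
        for com in comp.rows:
            c = cur[cur.comorbidity == com].set_index("year")
            s = scen[scen.comorbidity == com].set_index("year")
            for y in c.index:
                cv = float(c.loc[y, "cumulative_discounted_eur"])
                sv = float(s.loc[y, "cumulative_discounted_eur"])
                rows.append({"scenario": name, "comorbidity": com,
                             "year": int(y),
                             "current_cumulative_eur": cv,
                             "scenario_cumulative_eur": sv,
                             "incremental_eur": sv - cv})
    return pd.DataFrame(rows)


def export_tables(result: ModelResult, layout: str, out_dir,
                  comparisons: dict | None = None) -> list:
    """Write the requested layout under ``out_dir``; returns paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []

    def _w(name, frame):
        p = out_dir / name
        frame.to_csv(p, index=False)
        written.append(p)

    if layout == "table3":
        _w("counts_wide.csv", counts_wide(result))
    elif layout == "table4":
        if not comparisons:
            raise ValueError("table4 layout needs scenario comparisons")
        _w("scenario_counts_wide.csv", scenario_counts_wide(comparisons))
    elif layout == "figure1_series":
        _w("cumulative_costs.csv", cumulative_cost_series(result))
    elif layout == "figure2_series":
        if not comparisons:
            raise ValueError("figure2_series layout needs comparisons")
        _w("incremental_costs.csv", incremental_cost_series(comparisons))
    elif layout == "tidy":
        _w("trajectories.csv", result.trajectories_frame())
        _w("costs.csv", result.costs_frame())
    else:
        raise ValueError(f"unknown layout {layout!r}; choose from {LAYOUTS}")
    return written


def config_digest(path) -> str:
    """SHA-256 of the raw config bytes (deterministic for equal content)."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(out_dir, *, config_path, scenarios, update_rule,
                   outputs) -> Path:
    from . import __version__

    manifest = {
        "config_digest": config_digest(config_path),
        "package_version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "scenarios": sorted(scenarios),
        "update_rule": update_rule,
        "outputs": sorted(str(Path(p).name) for p in outputs),
    }
    path = Path(out_dir) / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path
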