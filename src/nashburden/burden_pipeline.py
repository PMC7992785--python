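"""End-to-end burden estimation: prevalence -> cohort runs -> cost report.

For each reporting band the prevalent significant-NASH cohort is placed in
the model at the band's configured fibrosis-stage split and representative
entry age, iterated to the lifetime horizon, costed and rolled up into
first-year, fifth-year and lifetime totals.  Band cells are rounded (cases
to persons, costs to whole dollars, half-up) and the totals row is the sum
of the rounded band cells, so the report is internally consistent to the
person and the dollar; unrounded values are retained alongside.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .param_store import (
    INITIAL_STATES,
    N_STATES,
    REPORTING_BANDS,
    STATE_INDEX,
    AgeBand,
    ParameterSet,
    round_half_up,
    _format_band,
)
from .prevalence_stage import (
    CohortEstimate,
    PopulationTable,
    aggregate_prevalence,
    estimate_cohorts,
)
from .markov_engine import LifeTable, run_cohort
from .cost_engine import cost_stream, per_case, rollup


class BurdenStageError(RuntimeError):
    """A pipeline stage failed; the message carries the band context."""


@dataclass(frozen=True)
class BandBurden:
    age_band: AgeBand
    cases: float
    first_year_cost: float
    fifth_year_cost: float
    lifetime_cost: float

    @property
    def lifetime_cost_per_case(self) -> int:
        return per_case(self.lifetime_cost, self.cases) if self.cases > 0 else 0


@dataclass(frozen=True)
class BurdenReport:
    """Band rows, a totals row and the GDP share of the lifetime total."""

    bands: tuple[BandBurden, ...]
    estimates: tuple[CohortEstimate, ...]
    gdp_share_pct: Optional[float]

    # -- rounded presentation (cases to persons, costs to whole USD) --------

    def rounded_rows(self) -> list[dict]:
        rows = []
        for b in self.bands:
            rows.append({
                "age_group": _format_band(b.age_band),
                "cases": round_half_up(b.cases),
                "first_year_cost": round_half_up(b.first_year_cost),
                "fifth_year_cost": round_half_up(b.fifth_year_cost),
                "lifetime_cost": round_half_up(b.lifetime_cost),
                "lifetime_cost_per_case": b.lifetime_cost_per_case,
            })
        total = {
            "age_group": "Total",
            "cases": sum(r["cases"] for r in rows),
            "first_year_cost": sum(r["first_year_cost"] for r in rows),
            "fifth_year_cost": sum(r["fifth_year_cost"] for r in rows),
            "lifetime_cost": sum(r["lifetime_cost"] for r in rows),
            "lifetime_cost_per_case": (per_case(
                sum(b.lifetime_cost for b in self.bands), self.total_cases)
                if self.total_cases > 0 else 0),
        }
        rows.append(total)
        return rows

    @property
    def total_cases(self) -> float:
        return sum(b.cases for b in self.bands)

    @property
    def total_lifetime_cost(self) -> float:
        return sum(b.lifetime_cost for b in self.bands)

    @property
    def total_first_year_cost(self) -> float:
        return sum(b.first_year_cost for b in self.bands)

    @property
    def total_fifth_year_cost(self) -> float:
        return sum(b.fifth_year_cost for b in self.bands)


def initial_vector(cases: float, ps: ParameterSet, band: AgeBand) -> np.ndarray:
    """Occupancy vector: prevalent cases spread over the band's stage split."""
    v = np.zeros(N_STATES)
    for state in INITIAL_STATES:
        v[STATE_INDEX[state]] = cases * ps.initial_distribution[band].get(state, 0.0)
    return v


def run_band(estimate: CohortEstimate, ps: ParameterSet,
             life_table: LifeTable) -> BandBurden:
    """Run one reporting band's prevalent cohort to the lifetime horizon."""
    band = estimate.age_band
    entry_age = ps.entry_ages[band]
    horizon = max(5, int(math.ceil(ps.econ.horizon_age - entry_age)))
    v0 = initial_vector(estimate.nash_cohort, ps, band)
    trace = run_cohort(entry_age, v0, ps, life_table, horizon)
    stream = cost_stream(trace, ps)
    if len(stream) < 5:  # extinct before year five: pad with zero cost
        pad = 5 - len(stream)
        stream = type(stream)(
            undiscounted=np.concatenate([stream.undiscounted, np.zeros(pad)]),
            discounted=np.concatenate([stream.discounted, np.zeros(pad)]))
    r = rollup(stream)
    return BandBurden(age_band=band, cases=estimate.nash_cohort,
                      first_year_cost=r.first_year, fifth_year_cost=r.fifth_year,
                      lifetime_cost=r.lifetime)


def run_burden(pop: PopulationTable, ps: ParameterSet, life_table: LifeTable,
               gdp: Optional[float] = None) -> BurdenReport:
    """The full prevalence -> Markov -> cost pipeline over all bands."""
    estimates = estimate_cohorts(pop, ps)
    bands = []
    for est in estimates:
        try:
            bands.append(run_band(est, ps, life_table))
        except Exception as exc:
            raise BurdenStageError(
                f"band {_format_band(est.age_band)}: {exc}") from exc
    gdp = gdp if gdp is not None else ps.econ.gdp_usd
    total_lifetime = sum(b.lifetime_cost for b in bands)
    share = gdp_share(total_lifetime, gdp) if gdp else None
    return BurdenReport(bands=tuple(bands), estimates=tuple(estimates),
                        gdp_share_pct=share)


def gdp_share(lifetime_total: float, gdp: float) -> float:
    """Lifetime burden as a percentage of a reference GDP."""
    if gdp <= 0:
        raise ValueError(f"gdp must be > 0, got {gdp}")
    return 100.0 * lifetime_total / gdp


def write_burden_report(report: BurdenReport, csv_path: Union[str, Path],
                        json_path: Optional[Union[str, Path]] = None) -> None:
    """Cost-table-shaped CSV (and optional JSON with the GDP share)."""
    rows = report.rounded_rows()
    fields = ["age_group", "cases", "first_year_cost", "fifth_year_cost",
              "lifetime_cost", "lifetime_cost_per_case"]
    with open(csv_path, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=fields)
        w.writeheader()
        w.writerows(rows)
    if json_path is not None:
        doc = {"bands": rows,
               "gdp_share_pct": report.gdp_share_pct,
               "prevalence": {
                   "nafld_pct": round_half_up(
                       aggregate_prevalence(report.estimates).nafld_pct, 2),
                   "nash_pct": round_half_up(
                       aggregate_prevalence(report.estimates).nash_pct, 2),
               }}
        with open(json_path, "w") as fh:
            json.dump(doc, fh, indent=2)
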