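"""Discounted direct-medical-cost accrual over cohort traces.

Costs attach to the state occupied at cycle start (no half-cycle correction;
no one-off transition costs).  The pre-cirrhotic states F0–F3 share the
annual NASH outpatient cost; NORMAL and DEATH cost nothing.  Year zero is
undiscounted; cycle t is discounted by 1/(1+r)^t.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .param_store import (
    NASH_COST_STATES,
    N_STATES,
    STATE_INDEX,
    HealthState,
    ParameterSet,
    round_half_up,
)
from .markov_engine import CohortTrace

#: cost-group membership of each costed health state
STATE_TO_COST_GROUP: dict[HealthState, str] = {
    **{s: "NASH" for s in NASH_COST_STATES},
    HealthState.F4_CC: "CC",
    HealthState.DC: "DC",
    HealthState.HCC: "HCC",
    HealthState.LT: "LT",
    HealthState.POST_LT: "POST_LT",
}


@dataclass(frozen=True)
class CostStream:
    """Per-cycle cost accrual in 2019 USD."""

    undiscounted: np.ndarray
    discounted: np.ndarray

    def __len__(self) -> int:
        return len(self.undiscounted)


class Rollup(NamedTuple):
    first_year: float
    fifth_year: float
    lifetime: float


def discount_factor(t: int, r: float) -> float:
    """Present-value factor 1/(1+r)^t; year zero is undiscounted."""
    if t < 0:
        raise ValueError(f"cycle index must be >= 0, got {t}")
    if r < 0:
        raise ValueError(f"discount rate must be >= 0, got {r}")
    return (1.0 + r) ** (-t)


def state_cost_map(ps: ParameterSet) -> np.ndarray:
    """Annual cost vector over the 11 states (NORMAL and DEATH cost 0)."""
    costs = np.zeros(N_STATES)
    for state, group in STATE_TO_COST_GROUP.items():
        costs[STATE_INDEX[state]] = ps.cost(group).annual_cost
    return costs


def cost_stream(trace: CohortTrace, ps: ParameterSet) -> CostStream:
    """Accrue annual state costs over a trace, discounted at the model rate.

    Cycle t's cost is the cycle-start occupancy times the annual state
    costs; the trace's terminal row (the state reached after the final
    transition, start of a year that is never lived) accrues nothing.
    """
    costs = state_cost_map(ps)
    undiscounted = trace.occupancy[:-1] @ costs
    t = np.arange(len(undiscounted))
    factors = (1.0 + ps.econ.discount_rate) ** (-t.astype(float))
    return CostStream(undiscounted=undiscounted,
                      discounted=undiscounted * factors)


def rollup(stream: CostStream) -> Rollup:
    """(first-year, fifth-year, lifetime) discounted costs.

    First year is cycle 0, fifth year is cycle 4 (cost incurred during the
    fifth model year, not cumulative), lifetime is the sum over all cycles.
    """
    if len(stream) < 5:
        raise ValueError(
            f"stream has {len(stream)} cycles; >= 5 required for the "
            f"fifth-year outcome")
    return Rollup(first_year=float(stream.discounted[0]),
                  fifth_year=float(stream.discounted[4]),
                  lifetime=float(stream.discounted.sum()))


def per_case(total_cost: float, cases: float) -> int:
    """Cost per case in whole 2019 USD (half-up at presentation)."""
    if cases <= 0:
        raise ValueError(f"cases must be > 0, got {cases}")
    return int(round_half_up(total_cost / cases))


def adjust_currency(amount_thb: float, cpi_multiplier: float,
                    thb_per_usd: float) -> float:
    """CPI-adjust a Thai-baht amount and convert to 2019 USD."""
    if thb_per_usd <= 0:
        raise ValueError(f"exchange rate must be > 0, got {thb_per_usd}")
    return amount_thb * cpi_multiplier / thb_per_usd
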