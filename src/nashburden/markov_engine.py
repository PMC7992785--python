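"""Age-dependent transition matrices and deterministic cohort iteration.

Each model cycle is one year.  For every live state the annual death
probability is applied first: background age-specific mortality (ASMR),
multiplied by a disease relative risk in the fibrosis and cirrhosis states,
or a state-specific total death probability for HCC, the transplant year and
post-transplant.  Printed exit probabilities are treated as conditional on
surviving the cycle, so each exit edge carries printed x (1 - p_death) and
the self-loop receives the residual — rows are valid by construction and are
never renormalised after the fact.  The one exception is the transplant row,
whose printed exit is the published complement of the transplant death
probability and therefore absorbs the full survival mass.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np

from .param_store import (
    N_STATES,
    STATE_INDEX,
    STATES,
    HealthState,
    MortalityModifiers,
    ParameterSet,
)

MIN_ADULT_AGE = 18
#: cohort is considered extinct below this living fraction
EXTINCTION_FRACTION = 1e-9


class InfeasibleParametersError(ValueError):
    """Exit probabilities for a state sum above 1 before death adjustment."""


@dataclass(frozen=True)
class LifeTable:
    """Annual all-cause mortality probability by integer age.

    Lookups below the first tabulated age raise; lookups beyond the last use
    the terminal value (flat extrapolation).
    """

    ages: np.ndarray
    q: np.ndarray

    def __post_init__(self):
        if len(self.ages) == 0:
            raise ValueError("life table is empty")
        if not np.all(np.diff(self.ages) == 1):
            raise ValueError("life table ages must be consecutive integers")
        if np.any((self.q < 0) | (self.q > 1)):
            raise ValueError("mortality probabilities must lie in [0, 1]")

    def lookup(self, age: float) -> float:
        a = int(math.floor(age))
        lo = int(self.ages[0])
        if a < lo:
            raise ValueError(f"age {age} below life-table start {lo}")
        idx = min(a - lo, len(self.ages) - 1)
        return float(self.q[idx])

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "LifeTable":
        ages, q = [], []
        with open(path, newline="") as fh:
            for rec in csv.DictReader(fh):
                ages.append(int(rec["age"]))
                q.append(float(rec["annual_mortality_probability"]))
        order = np.argsort(ages)
        return cls(ages=np.asarray(ages)[order], q=np.asarray(q, float)[order])

    def to_csv(self, path: Union[str, Path]) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["age", "annual_mortality_probability"])
            for a, qa in zip(self.ages, self.q):
                w.writerow([int(a), repr(float(qa))])


@dataclass(frozen=True)
class CohortTrace:
    """State occupancy per cycle for one entry-age cohort.

    ``occupancy[t, s]`` holds persons (or proportions) in state ``s`` at the
    start of cycle ``t``; row 0 is the initial vector.
    """

    entry_age: float
    occupancy: np.ndarray  # shape (T+1, 11)

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    def age_at(self, t: int) -> float:
        return self.entry_age + t

    @property
    def cohort_size(self) -> float:
        return float(self.occupancy[0].sum())


def background_mortality(state: HealthState, age: float, life_table: LifeTable,
                         mods: MortalityModifiers) -> float:
    """Annual death probability for one state at one age."""
    if age < MIN_ADULT_AGE:
        raise ValueError(f"model covers adults only; age {age} < {MIN_ADULT_AGE}")
    if state is HealthState.DEATH:
        return 1.0
    if state is HealthState.HCC:
        return mods.p_death_hcc
    if state is HealthState.LT:
        return mods.p_death_lt
    if state is HealthState.POST_LT:
        return mods.p_death_post_lt
    asmr = life_table.lookup(age)
    if state is HealthState.NORMAL:
        return asmr
    if state in (HealthState.F4_CC, HealthState.DC):
        return min(1.0, asmr * mods.rr_cirrhosis)
    # F0..F3
    return min(1.0, asmr * mods.rr_nafld)


def build_matrix(age: float, ps: ParameterSet, life_table: LifeTable) -> np.ndarray:
    """Annual transition matrix over the 11 states for one age.

    Death first; conditional exits scaled by survival; self-loop residual.
    """
    M = np.zeros((N_STATES, N_STATES))
    a = math.floor(age)  # ages advance in integer years within a cycle
    exits: dict[HealthState, list] = {s: [] for s in STATES}
    for e in ps.edges:
        if e.target is HealthState.DEATH:
            continue  # death comes from background_mortality
        if e.age_band is not None:
            lo, hi = e.age_band
            if not (lo <= a <= hi):
                # flat extrapolation beyond the tabulated bands
                bands = [x.age_band for x in ps.edges if x.family == e.family]
                top = max(b[1] for b in bands)
                if not (a > top and e.age_band[1] == top):
                    continue
        exits[e.source].append(e)
    for s in STATES:
        i = STATE_INDEX[s]
        if s is HealthState.DEATH:
            M[i, i] = 1.0
            continue
        d = background_mortality(s, age, life_table, ps.mortality)
        M[i, STATE_INDEX[HealthState.DEATH]] = d
        survival = 1.0 - d
        cond_total = sum(e.probability for e in exits[s]
                         if not e.complement_of_death)
        if cond_total > 1.0 + 1e-12:
            raise InfeasibleParametersError(
                f"exit probabilities from {s.value} sum to {cond_total} > 1")
        for e in exits[s]:
            j = STATE_INDEX[e.target]
            if e.complement_of_death:
                M[i, j] += survival  # printed value is 1 - p_death
            else:
                M[i, j] += e.probability * survival
        exit_mass = M[i].sum() - d  # non-death mass placed so far
        M[i, i] = max(0.0, survival - exit_mass)
    return M


def run_cohort(entry_age: float, initial, ps: ParameterSet,
               life_table: LifeTable, horizon: int) -> CohortTrace:
    """Iterate a cohort for up to ``horizon`` one-year cycles.

    ``initial`` is an occupancy vector over the 11 states (person counts or
    proportions).  Iteration stops early once the living fraction falls below
    ``EXTINCTION_FRACTION`` of the cohort.
    """
    if horizon < 1:
        raise ValueError(f"horizon must be >= 1 cycle, got {horizon}")
    v = np.asarray(initial, dtype=float)
    if v.shape != (N_STATES,):
        raise ValueError(f"initial vector must have length {N_STATES}")
    if np.any(v < 0):
        raise ValueError("initial occupancy must be non-negative")
    size = v.sum()
    rows = [v.copy()]
    dead_ix = STATE_INDEX[HealthState.DEATH]
    for t in range(horizon):
        M = build_matrix(entry_age + t, ps, life_table)
        v = v @ M
        rows.append(v.copy())
        living = size - v[dead_ix]
        if size > 0 and living < EXTINCTION_FRACTION * size:
            break
    return CohortTrace(entry_age=entry_age, occupancy=np.vstack(rows))


def write_trace(trace: CohortTrace, path: Union[str, Path]) -> None:
    """Tidy CSV: one row per (cycle, state) with age and occupancy."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["cycle", "age", "state", "occupancy"])
        for t in range(trace.occupancy.shape[0]):
            for s in STATES:
                w.writerow([t, trace.age_at(t), s.value,
                            repr(float(trace.occupancy[t, STATE_INDEX[s]]))])


def write_matrix(M: np.ndarray, path: Union[str, Path]) -> None:
    """Debug dump of one transition matrix with state labels."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["state"] + [s.value for s in STATES])
        for s in STATES:
            w.writerow([s.value] + [repr(float(x)) for x in M[STATE_INDEX[s]]])
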