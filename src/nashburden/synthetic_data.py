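"""Synthetic generators for the inputs the source tables do not print.

Two inputs of the analysis exist only in unpublished appendices: the
background life table and the single-year population pyramid.  This module
generates statistically realistic stand-ins — a Gompertz–Makeham mortality
schedule and a population pyramid whose reporting-band sums are pinned
exactly to the published head counts — plus a complete, validation-passing
fixture bundle combining them with the packaged base-case parameters.
Everything produced here is synthetic and labelled as such; no attempt is
made to reconstruct the real Thai life table or registry stage distribution.
"""

from __future__ import annotations

import math
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np

from .param_store import (
    AgeBand,
    OPEN_END,
    ParameterSet,
    base_case_path,
    load_parameters,
)
from .prevalence_stage import PopulationTable
from .markov_engine import LifeTable

#: published reporting-band head counts (2019)
DEFAULT_BAND_TOTALS: dict[AgeBand, int] = {
    (18, 39): 20_533_776,
    (40, 59): 19_919_412,
    (60, OPEN_END): 11_136_059,
}

#: synthetic relative weights of the fine bands inside each reporting band,
#: shaped like an ageing middle-income pyramid
DEFAULT_SUB_BAND_SHAPE: dict[AgeBand, float] = {
    (18, 29): 0.48, (30, 39): 0.52,
    (40, 49): 0.52, (50, 59): 0.48,
    (60, 69): 0.55, (70, 79): 0.30, (80, OPEN_END): 0.15,
}


class SpecError(ValueError):
    """A generator spec violates its own invariants."""


@dataclass(frozen=True)
class LifeTableSpec:
    """Gompertz–Makeham annual mortality: q(a) = 1 - exp(-(c + b e^{g a})).

    Defaults give an adult life expectancy near 75 years (synthetic,
    plausible for the study population; not the real national schedule).
    """

    makeham_c: float = 7.5e-4
    gompertz_b: float = 7.0e-5
    gompertz_g: float = 0.086
    age_min: int = 18
    age_max: int = 110
    #: terminal cap keeping q strictly below 1
    q_cap: float = 0.999

    def hazard(self, age: float) -> float:
        return self.makeham_c + self.gompertz_b * math.exp(self.gompertz_g * age)


@dataclass(frozen=True)
class PyramidSpec:
    """Population pyramid pinned to reporting-band totals.

    Fine-band counts are proportional to ``sub_band_shape`` (optionally
    jittered, deterministically per seed) and integerised by largest
    remainder so each reporting band's sum hits its target exactly.
    """

    band_totals: dict[AgeBand, int] = field(
        default_factory=lambda: dict(DEFAULT_BAND_TOTALS))
    sub_band_shape: dict[AgeBand, float] = field(
        default_factory=lambda: dict(DEFAULT_SUB_BAND_SHAPE))
    jitter_seed: int | None = None
    jitter_sd: float = 0.03  # lognormal sd of the weight jitter


def make_life_table(spec: LifeTableSpec) -> LifeTable:
    """Tabulate the spec's annual mortality schedule over integer ages."""
    if spec.makeham_c < 0 or spec.gompertz_b < 0 or spec.gompertz_g <= 0:
        raise SpecError(
            "life-table spec requires makeham_c >= 0, gompertz_b >= 0, "
            "gompertz_g > 0")
    ages = np.arange(spec.age_min, spec.age_max + 1)
    q = 1.0 - np.exp(-(spec.makeham_c
                       + spec.gompertz_b * np.exp(spec.gompertz_g * ages)))
    q = np.minimum(q, spec.q_cap)
    uncapped = q < spec.q_cap
    # b == 0 is the degenerate Makeham-only limit: a flat schedule is allowed
    if spec.gompertz_b > 0 and np.any(np.diff(q[uncapped]) <= 0):
        raise SpecError("implied mortality schedule is not strictly increasing")
    if np.any((q <= 0) | (q >= 1)):
        raise SpecError("implied mortality probabilities leave (0, 1)")
    return LifeTable(ages=ages, q=q)


def largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Apportion ``total`` integer units proportionally to ``weights``."""
    weights = np.asarray(weights, dtype=float)
    if np.any(weights < 0) or weights.sum() <= 0:
        raise SpecError("weights must be non-negative with positive sum")
    quotas = weights / weights.sum() * total
    counts = np.floor(quotas).astype(np.int64)
    shortfall = int(total - counts.sum())
    if shortfall:
        order = np.argsort(-(quotas - counts), kind="stable")
        counts[order[:shortfall]] += 1
    return counts


def make_population(spec: PyramidSpec) -> PopulationTable:
    """Fine-band population table whose band sums equal the pinned totals."""
    rng = (np.random.default_rng(spec.jitter_seed)
           if spec.jitter_seed is not None else None)
    rows = []
    for band, total in spec.band_totals.items():
        lo, hi = band
        fine = [b for b in spec.sub_band_shape if b[0] >= lo and b[1] <= hi]
        fine.sort()
        if not fine:
            raise SpecError(f"no sub-bands cover reporting band {band}")
        w = np.array([spec.sub_band_shape[b] for b in fine], dtype=float)
        if rng is not None:
            w = w * rng.lognormal(0.0, spec.jitter_sd, size=len(w))
        counts = largest_remainder(w, int(total))
        rows.extend((b, int(c)) for b, c in zip(fine, counts))
    return PopulationTable(rows=tuple(rows))


@dataclass(frozen=True)
class FixtureBundle:
    parameters: Path
    population: Path
    life_table: Path


def make_fixture_bundle(seed: int, out_dir: Union[str, Path]) -> FixtureBundle:
    """Write a complete, self-consistent input set to ``out_dir``.

    Parameters are the packaged base case verbatim; the population pyramid is
    pinned to the published band totals (fine structure jittered
    deterministically per seed); the life table is the default synthetic
    schedule.  The bundle is byte-identical for a given seed and passes full
    validation.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params_path = out / "parameters.yaml"
    shutil.copyfile(base_case_path(), params_path)
    pop = make_population(PyramidSpec(jitter_seed=seed))
    pop_path = out / "population.csv"
    pop.to_csv(pop_path)
    lt = make_life_table(LifeTableSpec())
    lt_path = out / "life_table.csv"
    lt.to_csv(lt_path)
    return FixtureBundle(parameters=params_path, population=pop_path,
                         life_table=lt_path)


# -- packaged-default convenience loaders -----------------------------------

def default_life_table() -> LifeTable:
    """The default synthetic mortality schedule."""
    return make_life_table(LifeTableSpec())


def default_population() -> PopulationTable:
    """Fine-band pyramid pinned to the published totals (no jitter)."""
    return make_population(PyramidSpec())


def base_parameter_set() -> ParameterSet:
    """The packaged base-case parameter set."""
    return load_parameters(base_case_path())
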