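"""Population counts x layered prevalence -> cohort sizes (the prevalence table).

Two prevalence layers are combined: NAFLD in the general population (three
reporting bands) and significant NASH within NAFLD (seven finer bands).  The
finer layer is collapsed onto the reporting bands with population weights
taken from the finest available population table.  Published reporting-band
prevalences may be pinned via ``ParameterSet.band_overrides``; otherwise the
default population-weighted collapse is used.

All arithmetic is kept at full floating precision; counts are rounded
half-up to whole persons and percentages to 2 dp only by the report writer.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

from .param_store import (
    NASH_LAYER_BANDS,
    REPORTING_BANDS,
    AgeBand,
    ParameterSet,
    round_half_up,
    _format_band,
)


class CoverageError(ValueError):
    """A population band cannot be resolved onto the prevalence bands."""


class EmptyInputError(ValueError):
    pass


@dataclass(frozen=True)
class PopulationTable:
    """Head counts by age band (closed intervals; 200 encodes an open end)."""

    rows: tuple[tuple[AgeBand, float], ...]

    def __post_init__(self):
        bands = sorted(b for b, _ in self.rows)
        for (lo, hi), c in self.rows:
            if c < 0:
                raise ValueError(f"population count for {lo}-{hi} is negative")
            if hi < lo:
                raise ValueError(f"band {lo}-{hi} is empty")
        for (_, hi), (lo2, _) in zip(bands, bands[1:]):
            if lo2 <= hi:
                raise ValueError(f"overlapping population bands at age {lo2}")

    @property
    def total(self) -> float:
        return sum(c for _, c in self.rows)

    def in_band(self, band: AgeBand) -> tuple[tuple[AgeBand, float], ...]:
        """Rows fully contained in ``band``; error if a row straddles it."""
        lo, hi = band
        out = []
        for (blo, bhi), count in self.rows:
            if blo >= lo and bhi <= hi:
                out.append(((blo, bhi), count))
            elif blo <= hi and bhi >= lo:  # partial overlap
                raise CoverageError(
                    f"population band {blo}-{bhi} straddles prevalence band "
                    f"{lo}-{hi}; provide sub-band counts")
        return tuple(out)

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "PopulationTable":
        rows = []
        with open(path, newline="") as fh:
            for rec in csv.DictReader(fh):
                rows.append(((int(rec["age_band_start"]), int(rec["age_band_end"])),
                             float(rec["count"])))
        return cls(rows=tuple(rows))

    def to_csv(self, path: Union[str, Path]) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["age_band_start", "age_band_end", "count"])
            for (lo, hi), count in self.rows:
                w.writerow([lo, hi, int(count) if count == int(count) else count])


@dataclass(frozen=True)
class CohortEstimate:
    age_band: AgeBand
    population: float
    nafld_prevalence: float
    nafld_cohort: float
    nash_prevalence: float  # in the general population
    nash_cohort: float


@dataclass(frozen=True)
class PrevalenceSummary:
    total_population: float
    total_nafld: float
    total_nash: float
    nafld_pct: float
    nash_pct: float
    nash_share_of_nafld_pct: float


def weighted_band_prevalence(pop: PopulationTable, ps: ParameterSet,
                             band: AgeBand) -> tuple[float, float]:
    """Default collapse: (NAFLD prevalence, NASH prevalence) for one band.

    NAFLD comes from the matching coarse layer entry; the NASH-within-NAFLD
    share is the population-weighted mean of the finer layer over the
    sub-bands contained in ``band``.  Returns prevalences in the general
    population.
    """
    nafld_entry = next((p for p in ps.prevalence_layer("NAFLD_IN_POPULATION")
                        if p.age_band == band), None)
    if nafld_entry is None:
        raise CoverageError(f"no NAFLD prevalence entry for band "
                            f"{_format_band(band)}")
    sub = [b for b in NASH_LAYER_BANDS if b[0] >= band[0] and b[1] <= band[1]]
    nash_values = {p.age_band: p.value
                   for p in ps.prevalence_layer("NASH_IN_NAFLD")}
    if len(sub) == 1:
        share = nash_values[sub[0]]
    else:
        weights = []
        for b in sub:
            rows = pop.in_band(b)
            if not rows:
                raise CoverageError(
                    f"population table has no counts inside NASH layer band "
                    f"{_format_band(b)}, needed to weight band "
                    f"{_format_band(band)}")
            weights.append(sum(c for _, c in rows))
        total_w = sum(weights)
        if total_w == 0:
            share = sum(nash_values[b] for b in sub) / len(sub)
        else:
            share = sum(w * nash_values[b]
                        for w, b in zip(weights, sub)) / total_w
    return nafld_entry.value, nafld_entry.value * share


def estimate_cohorts(pop: PopulationTable, ps: ParameterSet, *,
                     use_overrides: bool = True) -> list[CohortEstimate]:
    """Per reporting band: population, NAFLD and significant-NASH cohorts.

    nafld_cohort = population x NAFLD prevalence;
    nash_cohort = population x NASH prevalence (in the general population).
    Prevalences come from ``ps.band_overrides`` when present (and
    ``use_overrides``), else from the weighted collapse of the layers.
    """
    out = []
    for band in REPORTING_BANDS:
        rows = pop.in_band(band)
        population = sum(c for _, c in rows)
        override = ps.band_overrides.get(band) if use_overrides else None
        if override is not None:
            nafld_p, nash_p = override.nafld_prevalence, override.nash_prevalence
        else:
            nafld_p, nash_p = weighted_band_prevalence(pop, ps, band)
        out.append(CohortEstimate(
            age_band=band, population=population,
            nafld_prevalence=nafld_p, nafld_cohort=population * nafld_p,
            nash_prevalence=nash_p, nash_cohort=population * nash_p,
        ))
    covered = {b for band in REPORTING_BANDS for b, _ in pop.in_band(band)}
    stray = [b for b, _ in pop.rows if b not in covered]
    if stray:
        raise CoverageError(
            f"population bands outside the reporting bands: "
            f"{[_format_band(b) for b in stray]}")
    return out


def aggregate_prevalence(estimates: Sequence[CohortEstimate]) -> PrevalenceSummary:
    """Totals and percentage rates over the reporting bands."""
    if not estimates:
        raise EmptyInputError("no cohort estimates to aggregate")
    total_pop = sum(e.population for e in estimates)
    total_nafld = sum(e.nafld_cohort for e in estimates)
    total_nash = sum(e.nash_cohort for e in estimates)
    return PrevalenceSummary(
        total_population=total_pop,
        total_nafld=total_nafld,
        total_nash=total_nash,
        nafld_pct=100.0 * total_nafld / total_pop if total_pop else 0.0,
        nash_pct=100.0 * total_nash / total_pop if total_pop else 0.0,
        nash_share_of_nafld_pct=(100.0 * total_nash / total_nafld
                                 if total_nafld else 0.0),
    )


def calibrate_overrides(sampled: ParameterSet, base: ParameterSet,
                        pop: PopulationTable) -> ParameterSet:
    """Rescale pinned band prevalences by the sampled/base layer movement.

    The pinned overrides are published model outputs; when the layered inputs
    are perturbed (e.g. in a probabilistic sensitivity analysis) each
    override is multiplied by the ratio of the default-weighted band
    prevalence under the sampled layers to that under the base layers, so the
    layer standard errors propagate while the base case stays pinned.
    """
    if not base.band_overrides:
        return sampled
    new = {}
    for band, o in base.band_overrides.items():
        nafld_b, nash_b = weighted_band_prevalence(pop, base, band)
        nafld_s, nash_s = weighted_band_prevalence(pop, sampled, band)
        nafld_p = min(1.0, o.nafld_prevalence * (nafld_s / nafld_b if nafld_b else 1.0))
        nash_p = min(nafld_p, o.nash_prevalence * (nash_s / nash_b if nash_b else 1.0))
        new[band] = type(o)(age_band=band, nafld_prevalence=nafld_p,
                            nash_prevalence=nash_p)
    return sampled.replace(band_overrides=new)


def write_prevalence_report(estimates: Sequence[CohortEstimate],
                            path: Union[str, Path],
                            summary: Optional[PrevalenceSummary] = None) -> None:
    """Prevalence-table-shaped CSV: band rows plus a total row, rounded."""
    if summary is None:
        summary = aggregate_prevalence(estimates)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["age_group", "population", "nafld_prevalence_pct",
                    "nafld_cohort", "nash_prevalence_pct", "nash_cohort"])
        for e in estimates:
            w.writerow([
                _format_band(e.age_band),
                round_half_up(e.population),
                round_half_up(100.0 * e.nafld_prevalence, 2),
                round_half_up(e.nafld_cohort),
                round_half_up(100.0 * e.nash_prevalence, 2),
                round_half_up(e.nash_cohort),
            ])
        w.writerow([
            "Total",
            round_half_up(summary.total_population),
            round_half_up(summary.nafld_pct, 2),
            round_half_up(summary.total_nafld),
            round_half_up(summary.nash_pct, 2),
            round_half_up(summary.total_nash),
        ])
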