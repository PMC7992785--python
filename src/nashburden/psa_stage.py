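"""Probabilistic sensitivity analysis over the full burden pipeline.

Every uncertain input carries a standard error; the PSA draws each from a
method-of-moments distribution on its natural support — Beta for
probabilities and prevalences, Gamma for costs — runs the whole pipeline per
draw, and summarises the outcome distribution.  Parameters are sampled
independently (no published correlation structure).  Structural constants
(the age-specific incidence rates, the zero regression to NORMAL, the
transplant-row complement) are never varied; the transplant exit is
recomputed as 1 - sampled transplant death probability.  Sampled sets that
fail validation or matrix feasibility are rejected and redrawn whole, so the
marginal means stay unbiased; redraws are counted.

Reproducibility: per-iteration generators derive from
``SeedSequence([seed, iteration])``, so iteration i is identical no matter
how many iterations run or in what order.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .param_store import (
    REPORTING_BANDS,
    HealthState,
    ParameterSet,
    TransitionEdge,
    _format_band,
)
from .prevalence_stage import PopulationTable, calibrate_overrides
from .markov_engine import LifeTable, build_matrix
from .burden_pipeline import run_burden

MAX_REDRAWS = 1000
#: ages at which sampled matrices are checked for feasibility
_FEASIBILITY_AGES = (18, 45, 70, 95)

_SUMMARY_QUANTILES = (0.025, 0.25, 0.50, 0.75, 0.975)


class InfeasibleMomentsError(ValueError):
    """Mean/SE pair admits no distribution in the requested family."""


class SamplingFailureError(RuntimeError):
    """Too many consecutive infeasible redraws for one parameter set."""


@dataclass(frozen=True)
class PSAConfig:
    n_iterations: int = 1000
    seed: int = 20190301
    vary_probabilities: bool = True
    vary_prevalences: bool = True
    vary_costs: bool = True

    def __post_init__(self):
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


@dataclass(frozen=True)
class PSAResult:
    """Per-iteration outcome table plus recomputable percentile summaries."""

    iterations: pd.DataFrame
    summary: pd.DataFrame
    config: PSAConfig
    n_failed: int = 0
    redraws: int = 0

    def write(self, out_dir: Union[str, Path]) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.iterations.to_csv(out / "psa_iterations.csv", index=False)
        self.summary.to_csv(out / "psa_summary.csv")
        with open(out / "psa_summary.json", "w") as fh:
            json.dump({
                "config": dataclasses.asdict(self.config),
                "n_failed": self.n_failed,
                "redraws": self.redraws,
                "summary": {col: self.summary[col].to_dict()
                            for col in self.summary.columns},
            }, fh, indent=2)
        # box-plot-ready quantile table per band outcome
        q = self.iterations.drop(columns=["iteration"]).quantile(
            [0.025, 0.25, 0.50, 0.75, 0.975])
        q.to_csv(out / "psa_quantiles.csv")


# ---------------------------------------------------------------------------
# method-of-moments distribution fitting
# ---------------------------------------------------------------------------

def fit_distribution(mean: float, se: float, family: str):
    """Method-of-moments parameters for Beta or Gamma.

    Returns ("point", mean) when se == 0, ("beta", alpha, beta) or
    ("gamma", shape, scale) otherwise.
    """
    if se < 0:
        raise InfeasibleMomentsError(f"se {se} < 0")
    if se == 0:
        return ("point", float(mean))
    if family == "beta":
        if not 0.0 < mean < 1.0:
            raise InfeasibleMomentsError(
                f"beta requires 0 < mean < 1, got {mean}")
        var = se * se
        if var >= mean * (1.0 - mean):
            raise InfeasibleMomentsError(
                f"beta requires se^2 < mean(1-mean); got mean={mean}, se={se}")
        nu = mean * (1.0 - mean) / var - 1.0
        return ("beta", mean * nu, (1.0 - mean) * nu)
    if family == "gamma":
        if mean <= 0:
            raise InfeasibleMomentsError(f"gamma requires mean > 0, got {mean}")
        return ("gamma", (mean / se) ** 2, se * se / mean)
    raise ValueError(f"unknown family {family!r}")


def _draw(dist, rng: np.random.Generator) -> float:
    kind = dist[0]
    if kind == "point":
        return dist[1]
    if kind == "beta":
        return float(rng.beta(dist[1], dist[2]))
    return float(rng.gamma(dist[1], dist[2]))


# ---------------------------------------------------------------------------
# parameter-set sampling
# ---------------------------------------------------------------------------

def _sample_once(ps: ParameterSet, cfg: PSAConfig,
                 rng: np.random.Generator) -> ParameterSet:
    m = ps.mortality
    if cfg.vary_probabilities:
        p_hcc = _draw(fit_distribution(m.p_death_hcc, m.se_death_hcc, "beta"), rng)
        p_lt = _draw(fit_distribution(m.p_death_lt, m.se_death_lt, "beta"), rng)
        p_plt = _draw(fit_distribution(m.p_death_post_lt, m.se_death_post_lt,
                                       "beta"), rng)
        mortality = dataclasses.replace(m, p_death_hcc=p_hcc, p_death_lt=p_lt,
                                        p_death_post_lt=p_plt)
    else:
        mortality = m

    edges = []
    for e in ps.edges:
        if e.complement_of_death:
            # recomputed below from the sampled death probability
            edges.append(dataclasses.replace(
                e, probability=1.0 - mortality.p_death_lt))
        elif (cfg.vary_probabilities and e.se is not None and e.se > 0
              and 0.0 < e.probability < 1.0):
            if e.source is HealthState.LT and e.target is HealthState.DEATH:
                p = mortality.p_death_lt
            elif e.source is HealthState.HCC and e.target is HealthState.DEATH:
                p = mortality.p_death_hcc
            elif e.source is HealthState.POST_LT and e.target is HealthState.DEATH:
                p = mortality.p_death_post_lt
            else:
                p = _draw(fit_distribution(e.probability, e.se, "beta"), rng)
            edges.append(dataclasses.replace(e, probability=p))
        else:
            edges.append(e)  # structural constant (se absent or boundary)

    if cfg.vary_costs:
        costs = tuple(
            dataclasses.replace(
                c, annual_cost=_draw(
                    fit_distribution(c.annual_cost, c.se, "gamma"), rng))
            if c.se > 0 else c
            for c in ps.costs)
    else:
        costs = ps.costs

    if cfg.vary_prevalences:
        prevalence = tuple(
            dataclasses.replace(
                p, value=_draw(fit_distribution(p.value, p.se, "beta"), rng))
            if p.se > 0 and 0.0 < p.value < 1.0 else p
            for p in ps.prevalence)
    else:
        prevalence = ps.prevalence

    return ps.replace(edges=tuple(edges), costs=costs, prevalence=prevalence,
                      mortality=mortality)


def _feasible(ps: ParameterSet, life_table: Optional[LifeTable]) -> bool:
    from .param_store import validate_parameter_set
    if validate_parameter_set(ps):
        return False
    if life_table is not None:
        try:
            for age in _FEASIBILITY_AGES:
                build_matrix(age, ps, life_table)
        except Exception:
            return False
    return True


def sample_parameter_set(ps: ParameterSet, cfg: PSAConfig, iteration: int,
                         life_table: Optional[LifeTable] = None,
                         ) -> tuple[ParameterSet, int]:
    """One reproducible parameter-set draw for a given iteration index.

    Returns (sampled set, number of rejected redraws).  Draws violating
    validation or matrix feasibility are redrawn whole (rejection sampling).
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, iteration]))
    for redraw in range(MAX_REDRAWS + 1):
        cand = _sample_once(ps, cfg, rng)
        if _feasible(cand, life_table):
            return cand, redraw
    raise SamplingFailureError(
        f"iteration {iteration}: {MAX_REDRAWS} consecutive infeasible draws")


# ---------------------------------------------------------------------------
# the PSA loop
# ---------------------------------------------------------------------------

def _band_col(band, name: str) -> str:
    return f"{name}_{_format_band(band).replace('-', '_').replace('+', 'plus')}"


def run_psa(pop: PopulationTable, ps: ParameterSet, life_table: LifeTable,
            cfg: PSAConfig, gdp: Optional[float] = None) -> PSAResult:
    """Monte-Carlo propagation of all parameter uncertainty.

    Runs the full burden pipeline once per sampled parameter set and
    collects total cases, lifetime cost and lifetime cost per case, overall
    and per reporting band.
    """
    records, failures, redraw_total = [], [], 0
    for it in range(cfg.n_iterations):
        try:
            sampled, redraws = sample_parameter_set(ps, cfg, it, life_table)
            redraw_total += redraws
            sampled = calibrate_overrides(sampled, ps, pop)
            report = run_burden(pop, sampled, life_table, gdp=gdp)
            rec = {
                "iteration": it,
                "total_cases": report.total_cases,
                "lifetime_cost": report.total_lifetime_cost,
                "lifetime_cost_per_case": (report.total_lifetime_cost
                                           / report.total_cases),
            }
            for b in report.bands:
                rec[_band_col(b.age_band, "cases")] = b.cases
                rec[_band_col(b.age_band, "lifetime_cost")] = b.lifetime_cost
                rec[_band_col(b.age_band, "cost_per_case")] = (
                    b.lifetime_cost / b.cases if b.cases else float("nan"))
            records.append(rec)
        except Exception as exc:  # logged, not fatal, unless too frequent
            failures.append((it, repr(exc)))
            if len(failures) > 0.05 * cfg.n_iterations:
                raise RuntimeError(
                    f"PSA aborted: {len(failures)} failed iterations "
                    f"(> 5% of {cfg.n_iterations}); first failures: "
                    f"{failures[:3]}") from exc
    iterations = pd.DataFrame.from_records(records)
    summary = summarize(iterations)
    return PSAResult(iterations=iterations, summary=summary, config=cfg,
                     n_failed=len(failures), redraws=redraw_total)


def summarize(iterations: pd.DataFrame) -> pd.DataFrame:
    """Mean/min/max and percentile summaries, recomputable from the draws."""
    outcomes = iterations.drop(columns=["iteration"])
    rows = {"mean": outcomes.mean(), "min": outcomes.min(),
            "max": outcomes.max()}
    for q in _SUMMARY_QUANTILES:
        rows[f"q{q*100:g}"] = outcomes.quantile(q)
    return pd.DataFrame(rows).T
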