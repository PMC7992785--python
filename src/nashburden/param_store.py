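"""Typed containers, file I/O and validation for every model input.

The parameter file is a single YAML document (schema version 1) that mirrors
the published input table one-to-one: layered prevalence estimates, annual
transition probabilities with standard errors, annual state costs, mortality
modifiers and economic settings.  A packaged base-case fixture carries the
published values; everything the source tables do not print (mortality
relative risks, the initial fibrosis-stage split) is a documented, editable
synthetic default.
"""

from __future__ import annotations

import decimal
import importlib.resources
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Union

import yaml

SCHEMA_VERSION = 1

AgeBand = tuple[int, int]

#: Open-ended bands are encoded with this upper bound (e.g. "60+" -> (60, 200)).
OPEN_END = 200


class HealthState(str, Enum):
    """The eleven health states of the natural-history model.

    Disease runs NORMAL -> F0..F3 (fibrosis stages) -> F4_CC (compensated
    cirrhosis) -> DC (decompensated cirrhosis) / HCC (hepatocellular
    carcinoma) -> LT (liver-transplant year) -> POST_LT, with DEATH absorbing.
    """

    NORMAL = "NORMAL"
    F0 = "F0"
    F1 = "F1"
    F2 = "F2"
    F3 = "F3"
    F4_CC = "F4_CC"
    DC = "DC"
    HCC = "HCC"
    LT = "LT"
    POST_LT = "POST_LT"
    DEATH = "DEATH"


#: Canonical state ordering used for every matrix / vector in the package.
STATES: tuple[HealthState, ...] = tuple(HealthState)
STATE_INDEX: dict[HealthState, int] = {s: i for i, s in enumerate(STATES)}
N_STATES = len(STATES)

#: The 19 permitted non-death transition edge families (NORMAL->F0 is one
#: family with four age bands).  Everything else in a row is self-loop or death.
EDGE_FAMILIES: tuple[tuple[HealthState, HealthState], ...] = (
    # progression
    (HealthState.NORMAL, HealthState.F0),
    (HealthState.F0, HealthState.F1),
    (HealthState.F1, HealthState.F2),
    (HealthState.F2, HealthState.F3),
    (HealthState.F3, HealthState.F4_CC),
    (HealthState.F4_CC, HealthState.DC),
    (HealthState.F4_CC, HealthState.HCC),
    (HealthState.DC, HealthState.HCC),
    (HealthState.DC, HealthState.LT),
    (HealthState.HCC, HealthState.LT),
    (HealthState.HCC, HealthState.DEATH),
    (HealthState.LT, HealthState.POST_LT),
    (HealthState.LT, HealthState.DEATH),
    (HealthState.POST_LT, HealthState.DEATH),
    # regression
    (HealthState.F0, HealthState.NORMAL),
    (HealthState.F1, HealthState.F0),
    (HealthState.F2, HealthState.F1),
    (HealthState.F3, HealthState.F2),
    (HealthState.F4_CC, HealthState.F3),
)

AGE_SPECIFIC_FAMILIES = frozenset({(HealthState.NORMAL, HealthState.F0)})

#: States that share the pre-cirrhotic NASH outpatient cost.
NASH_COST_STATES = (HealthState.F0, HealthState.F1, HealthState.F2, HealthState.F3)

COST_GROUPS = ("NASH", "CC", "DC", "HCC", "LT", "POST_LT")

NAFLD_LAYER_BANDS: tuple[AgeBand, ...] = ((18, 39), (40, 59), (60, OPEN_END))
NASH_LAYER_BANDS: tuple[AgeBand, ...] = (
    (18, 29), (30, 39), (40, 49), (50, 59), (60, 69), (70, 79), (80, OPEN_END),
)
REPORTING_BANDS: tuple[AgeBand, ...] = NAFLD_LAYER_BANDS

#: Initial-severity support: prevalent significant-NASH cases start in F2+.
INITIAL_STATES = (
    HealthState.F2, HealthState.F3, HealthState.F4_CC, HealthState.DC, HealthState.HCC,
)


class ParameterError(ValueError):
    """Base class for parameter-file problems."""


class SchemaError(ParameterError):
    """The file does not match the documented schema."""


class RangeError(ParameterError):
    """A numeric field is outside its admissible range."""


class ParameterValidationError(ParameterError):
    """A loaded parameter set violates one or more model invariants."""

    def __init__(self, violations: list["Violation"]):
        self.violations = violations
        super().__init__(
            "parameter set failed validation:\n"
            + "\n".join(f"  - {v}" for v in violations)
        )


@dataclass(frozen=True)
class Violation:
    """One validation failure: the offending type, field and broken rule."""

    type: str
    field: str
    rule: str

    def __str__(self) -> str:  # pragma: no cover - trivial
        return f"{self.type}.{self.field}: {self.rule}"


@dataclass(frozen=True)
class TransitionEdge:
    source: HealthState
    target: HealthState
    probability: float
    se: Optional[float] = None
    age_band: Optional[AgeBand] = None
    #: printed value is 1 - p(death) for the source state; it absorbs the full
    #: survival mass and is never independently sampled or death-scaled.
    complement_of_death: bool = False

    @property
    def family(self) -> tuple[HealthState, HealthState]:
        return (self.source, self.target)


@dataclass(frozen=True)
class StateCost:
    state_group: str
    annual_cost: float  # 2019 USD per person-year
    se: float


@dataclass(frozen=True)
class PrevalenceEntry:
    age_band: AgeBand
    layer: str  # NAFLD_IN_POPULATION | NASH_IN_NAFLD
    value: float
    se: float


@dataclass(frozen=True)
class MortalityModifiers:
    """Excess-mortality inputs.

    ``rr_nafld`` multiplies the background age-specific mortality rate in
    NORMAL..F3; ``rr_cirrhosis`` in F4_CC and DC.  HCC, LT and POST_LT carry
    their own total annual death probabilities.
    """

    rr_nafld: float
    rr_cirrhosis: float
    p_death_hcc: float
    se_death_hcc: float
    p_death_lt: float
    se_death_lt: float
    p_death_post_lt: float
    se_death_post_lt: float


@dataclass(frozen=True)
class EconomicSettings:
    discount_rate: float = 0.03
    currency_year: int = 2019
    thb_per_usd: float = 32.3
    horizon_age: float = 100.0  # run cohorts until this age (lifetime horizon)
    cycle_length_years: int = 1
    gdp_usd: Optional[float] = None  # reference GDP for the burden share


@dataclass(frozen=True)
class BandOverride:
    """Reporting-band prevalences pinned from published outputs.

    When present these supersede the default population-weighted collapse of
    the layered inputs for that band (both are prevalence in the general
    population, not within NAFLD for ``nash_prevalence``).
    """

    age_band: AgeBand
    nafld_prevalence: float
    nash_prevalence: float


@dataclass(frozen=True)
class ParameterSet:
    edges: tuple[TransitionEdge, ...]
    costs: tuple[StateCost, ...]
    prevalence: tuple[PrevalenceEntry, ...]
    mortality: MortalityModifiers
    econ: EconomicSettings
    #: per reporting band: proportions over INITIAL_STATES summing to 1
    initial_distribution: dict[AgeBand, dict[HealthState, float]]
    #: per reporting band: representative cohort entry age
    entry_ages: dict[AgeBand, float]
    band_overrides: dict[AgeBand, BandOverride] = field(default_factory=dict)
    schema_version: int = SCHEMA_VERSION

    # -- convenience lookups -------------------------------------------------

    def edge(self, source: HealthState, target: HealthState,
             age: Optional[float] = None) -> TransitionEdge:
        """Return the unique edge for (source, target), resolving age bands."""
        hits = [e for e in self.edges if e.family == (source, target)]
        if not hits:
            raise KeyError(f"no edge {source.value}->{target.value}")
        if hits[0].age_band is None:
            return hits[0]
        if age is None:
            raise KeyError(
                f"edge {source.value}->{target.value} is age-specific; pass age")
        for e in hits:
            lo, hi = e.age_band
            if lo <= age <= hi:
                return e
        # flat extrapolation onto the nearest band
        return max(hits, key=lambda e: e.age_band[0]) if age > hits[-1].age_band[1] \
            else min(hits, key=lambda e: e.age_band[0])

    def cost(self, state_group: str) -> StateCost:
        for c in self.costs:
            if c.state_group == state_group:
                return c
        raise KeyError(f"no cost for state group {state_group}")

    def prevalence_layer(self, layer: str) -> tuple[PrevalenceEntry, ...]:
        return tuple(p for p in self.prevalence if p.layer == layer)

    def replace(self, **kwargs) -> "ParameterSet":
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# rounding helper shared by the report writers
# ---------------------------------------------------------------------------

def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (the convention of the source tables)."""
    q = decimal.Decimal(1).scaleb(-ndigits)
    d = decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP)
    return int(d) if ndigits <= 0 else float(d)


# ---------------------------------------------------------------------------
# (de)serialisation
# ---------------------------------------------------------------------------

def _parse_band(raw) -> AgeBand:
    if isinstance(raw, str):
        raw = raw.replace(" ", "")
        if raw.endswith("+"):
            return (int(raw[:-1]), OPEN_END)
        lo, hi = raw.split("-")
        return (int(lo), int(hi))
    if isinstance(raw, (list, tuple)) and len(raw) == 2:
        return (int(raw[0]), int(raw[1]))
    raise SchemaError(f"age_band: cannot parse {raw!r}")


def _format_band(band: AgeBand) -> str:
    lo, hi = band
    return f"{lo}+" if hi >= OPEN_END else f"{lo}-{hi}"


def _req(mapping: dict, key: str, context: str):
    if key not in mapping:
        raise SchemaError(f"{context}: missing required field '{key}'")
    return mapping[key]


def _state(name: str, context: str) -> HealthState:
    try:
        return HealthState[str(name)]
    except KeyError:
        raise SchemaError(f"{context}: unknown health state {name!r}") from None


def load_parameters(path: Union[str, Path]) -> ParameterSet:
    """Load and validate a parameter file.

    Raises
    ------
    SchemaError
        if the document does not follow the documented schema.
    RangeError
        if a probability or rate is outside its admissible range.
    ParameterValidationError
        if structural invariants (edge completeness, distribution sums, the
        transplant-row complement) are violated.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return parameters_from_dict(doc)


def parameters_from_dict(doc: dict) -> ParameterSet:
    if not isinstance(doc, dict):
        raise SchemaError("top level: expected a mapping")
    version = doc.get("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise SchemaError(f"schema_version: unsupported version {version}")

    econ_raw = dict(doc.get("economics", {}))
    econ = EconomicSettings(
        discount_rate=float(econ_raw.get("discount_rate", 0.03)),
        currency_year=int(econ_raw.get("currency_year", 2019)),
        thb_per_usd=float(econ_raw.get("thb_per_usd", 32.3)),
        horizon_age=float(econ_raw.get("horizon_age", 100.0)),
        cycle_length_years=int(econ_raw.get("cycle_length_years", 1)),
        gdp_usd=(float(econ_raw["gdp_usd"]) if econ_raw.get("gdp_usd") is not None
                 else None),
    )
    if econ.discount_rate < 0:
        raise RangeError("economics.discount_rate: must be >= 0")
    if econ.thb_per_usd <= 0:
        raise RangeError("economics.thb_per_usd: must be > 0")
    if econ.cycle_length_years != 1:
        raise SchemaError("economics.cycle_length_years: fixed at 1 year")

    mort_raw = _req(doc, "mortality", "document")

    def _pse(key):
        entry = _req(mort_raw, key, "mortality")
        return float(_req(entry, "value", f"mortality.{key}")), \
            float(entry.get("se", 0.0))

    p_hcc, se_hcc = _pse("p_death_hcc")
    p_lt, se_lt = _pse("p_death_lt")
    p_plt, se_plt = _pse("p_death_post_lt")
    mortality = MortalityModifiers(
        rr_nafld=float(_req(mort_raw, "rr_nafld", "mortality")),
        rr_cirrhosis=float(_req(mort_raw, "rr_cirrhosis", "mortality")),
        p_death_hcc=p_hcc, se_death_hcc=se_hcc,
        p_death_lt=p_lt, se_death_lt=se_lt,
        p_death_post_lt=p_plt, se_death_post_lt=se_plt,
    )
    for nm, p in (("p_death_hcc", p_hcc), ("p_death_lt", p_lt),
                  ("p_death_post_lt", p_plt)):
        if not 0.0 <= p <= 1.0:
            raise RangeError(f"mortality.{nm}: probability {p} outside [0, 1]")

    edges = []
    for i, raw in enumerate(_req(doc, "transitions", "document")):
        ctx = f"transitions[{i}]"
        prob = float(_req(raw, "probability", ctx))
        if not 0.0 <= prob <= 1.0:
            raise RangeError(f"{ctx}: probability {prob} outside [0, 1]")
        se = raw.get("se")
        if se is not None and float(se) < 0:
            raise RangeError(f"{ctx}: se {se} < 0")
        edges.append(TransitionEdge(
            source=_state(_req(raw, "source", ctx), ctx),
            target=_state(_req(raw, "target", ctx), ctx),
            probability=prob,
            se=None if se is None else float(se),
            age_band=_parse_band(raw["age_band"]) if raw.get("age_band") else None,
            complement_of_death=bool(raw.get("complement_of_death", False)),
        ))

    costs = []
    for group, raw in _req(doc, "costs", "document").items():
        if group not in COST_GROUPS:
            raise SchemaError(f"costs.{group}: unknown state group")
        value = float(_req(raw, "value", f"costs.{group}"))
        se = float(raw.get("se", 0.0))
        if value < 0 or se < 0:
            raise RangeError(f"costs.{group}: cost and se must be >= 0")
        costs.append(StateCost(state_group=group, annual_cost=value, se=se))

    prevalence = []
    prev_raw = _req(doc, "prevalence", "document")
    for layer_key, layer_name in (("nafld_in_population", "NAFLD_IN_POPULATION"),
                                  ("nash_in_nafld", "NASH_IN_NAFLD")):
        for i, raw in enumerate(_req(prev_raw, layer_key, "prevalence")):
            ctx = f"prevalence.{layer_key}[{i}]"
            value = float(_req(raw, "value", ctx))
            if not 0.0 <= value <= 1.0:
                raise RangeError(f"{ctx}: value {value} outside [0, 1]")
            prevalence.append(PrevalenceEntry(
                age_band=_parse_band(_req(raw, "age_band", ctx)),
                layer=layer_name, value=value, se=float(raw.get("se", 0.0)),
            ))

    initial = {}
    for raw in _req(doc, "initial_distribution", "document"):
        band = _parse_band(_req(raw, "age_band", "initial_distribution"))
        initial[band] = {
            _state(k, "initial_distribution"): float(v)
            for k, v in raw.items() if k != "age_band"
        }

    entry_ages = {}
    for raw in _req(doc, "entry_ages", "document"):
        band = _parse_band(_req(raw, "age_band", "entry_ages"))
        entry_ages[band] = float(_req(raw, "age", "entry_ages"))

    overrides = {}
    for raw in doc.get("reporting_band_overrides", []) or []:
        band = _parse_band(_req(raw, "age_band", "reporting_band_overrides"))
        overrides[band] = BandOverride(
            age_band=band,
            nafld_prevalence=float(_req(raw, "nafld_prevalence",
                                        "reporting_band_overrides")),
            nash_prevalence=float(_req(raw, "nash_prevalence",
                                       "reporting_band_overrides")),
        )

    ps = ParameterSet(
        edges=tuple(edges), costs=tuple(costs), prevalence=tuple(prevalence),
        mortality=mortality, econ=econ, initial_distribution=initial,
        entry_ages=entry_ages, band_overrides=overrides, schema_version=version,
    )
    violations = validate_parameter_set(ps)
    if violations:
        raise ParameterValidationError(violations)
    return ps


def parameters_to_dict(ps: ParameterSet) -> dict:
    doc: dict = {"schema_version": ps.schema_version}
    doc["economics"] = {
        "discount_rate": ps.econ.discount_rate,
        "currency_year": ps.econ.currency_year,
        "thb_per_usd": ps.econ.thb_per_usd,
        "horizon_age": ps.econ.horizon_age,
        "cycle_length_years": ps.econ.cycle_length_years,
    }
    if ps.econ.gdp_usd is not None:
        doc["economics"]["gdp_usd"] = ps.econ.gdp_usd
    m = ps.mortality
    doc["mortality"] = {
        "rr_nafld": m.rr_nafld,
        "rr_cirrhosis": m.rr_cirrhosis,
        "p_death_hcc": {"value": m.p_death_hcc, "se": m.se_death_hcc},
        "p_death_lt": {"value": m.p_death_lt, "se": m.se_death_lt},
        "p_death_post_lt": {"value": m.p_death_post_lt, "se": m.se_death_post_lt},
    }
    doc["transitions"] = []
    for e in ps.edges:
        raw = {"source": e.source.value, "target": e.target.value,
               "probability": e.probability}
        if e.se is not None:
            raw["se"] = e.se
        if e.age_band is not None:
            raw["age_band"] = _format_band(e.age_band)
        if e.complement_of_death:
            raw["complement_of_death"] = True
        doc["transitions"].append(raw)
    doc["costs"] = {c.state_group: {"value": c.annual_cost, "se": c.se}
                    for c in ps.costs}
    doc["prevalence"] = {
        "nafld_in_population": [
            {"age_band": _format_band(p.age_band), "value": p.value, "se": p.se}
            for p in ps.prevalence_layer("NAFLD_IN_POPULATION")],
        "nash_in_nafld": [
            {"age_band": _format_band(p.age_band), "value": p.value, "se": p.se}
            for p in ps.prevalence_layer("NASH_IN_NAFLD")],
    }
    doc["initial_distribution"] = [
        {"age_band": _format_band(band),
         **{s.value: frac for s, frac in dist.items()}}
        for band, dist in ps.initial_distribution.items()
    ]
    doc["entry_ages"] = [
        {"age_band": _format_band(band), "age": age}
        for band, age in ps.entry_ages.items()
    ]
    if ps.band_overrides:
        doc["reporting_band_overrides"] = [
            {"age_band": _format_band(band),
             "nafld_prevalence": o.nafld_prevalence,
             "nash_prevalence": o.nash_prevalence}
            for band, o in ps.band_overrides.items()
        ]
    return doc


def write_parameters(ps: ParameterSet, path: Union[str, Path]) -> None:
    """Write a parameter set back to YAML; numeric round-trip is exact."""
    with open(path, "w") as fh:
        yaml.safe_dump(parameters_to_dict(ps), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_parameter_set(ps: ParameterSet) -> list[Violation]:
    """Check every structural invariant; returns (not raises) the violations."""
    out: list[Violation] = []

    def bad(type_: str, field_: str, rule: str):
        out.append(Violation(type_, field_, rule))

    # --- edges: membership, ranges, completeness
    seen: dict[tuple, int] = {}
    for e in ps.edges:
        label = f"{e.source.value}->{e.target.value}"
        if e.family not in EDGE_FAMILIES:
            bad("TransitionEdge", label, "not a permitted model edge")
            continue
        if not 0.0 <= e.probability <= 1.0:
            bad("TransitionEdge", f"{label}.probability",
                f"value {e.probability} outside [0, 1]")
        if e.se is not None and e.se < 0:
            bad("TransitionEdge", f"{label}.se", f"value {e.se} < 0")
        if (e.family in AGE_SPECIFIC_FAMILIES) != (e.age_band is not None):
            bad("TransitionEdge", label,
                "age_band must be present exactly for age-specific families")
        key = (e.family, e.age_band)
        seen[key] = seen.get(key, 0) + 1
    for key, n in seen.items():
        if n > 1:
            (src, tgt), band = key
            bad("TransitionEdge", f"{src.value}->{tgt.value}",
                f"duplicated {n} times for band {band}")
    for fam in EDGE_FAMILIES:
        present = [k for k in seen if k[0] == fam]
        if not present:
            bad("ParameterSet", f"edges.{fam[0].value}->{fam[1].value}",
                "required edge missing")
    age_bands = sorted(b for (fam, b) in seen if fam in AGE_SPECIFIC_FAMILIES
                       and b is not None)
    if age_bands:
        for (lo, hi), (lo2, _hi2) in zip(age_bands, age_bands[1:]):
            if lo2 != hi + 1:
                bad("TransitionEdge", "NORMAL->F0",
                    f"age bands not contiguous at {hi}/{lo2}")

    # --- regression F0->NORMAL fixed at zero by assumption
    try:
        e = ps.edge(HealthState.F0, HealthState.NORMAL)
        if e.probability != 0.0:
            bad("TransitionEdge", "F0->NORMAL.probability",
                "fixed at 0.000 by assumption")
    except KeyError:
        pass  # already reported as missing

    # --- LT row: printed complement of the transplant death probability
    try:
        e = ps.edge(HealthState.LT, HealthState.POST_LT)
        if abs(e.probability - (1.0 - ps.mortality.p_death_lt)) > 1e-4:
            bad("TransitionEdge", "LT->POST_LT.probability",
                f"must equal 1 - p_death_lt within 1e-4 "
                f"(got {e.probability}, expected {1.0 - ps.mortality.p_death_lt})")
        lt_death = ps.edge(HealthState.LT, HealthState.DEATH)
        if abs(lt_death.probability - ps.mortality.p_death_lt) > 1e-9:
            bad("TransitionEdge", "LT->DEATH.probability",
                "must equal mortality.p_death_lt")
    except KeyError:
        pass

    # --- costs
    groups = {c.state_group for c in ps.costs}
    for g in COST_GROUPS:
        if g not in groups:
            bad("StateCost", g, "required cost group missing")
    for c in ps.costs:
        if c.annual_cost < 0:
            bad("StateCost", f"{c.state_group}.annual_cost",
                f"value {c.annual_cost} < 0")
        if c.se < 0:
            bad("StateCost", f"{c.state_group}.se", f"value {c.se} < 0")

    # --- prevalence layers
    for layer, expected in (("NAFLD_IN_POPULATION", NAFLD_LAYER_BANDS),
                            ("NASH_IN_NAFLD", NASH_LAYER_BANDS)):
        bands = tuple(p.age_band for p in ps.prevalence_layer(layer))
        if tuple(sorted(bands)) != tuple(sorted(expected)):
            bad("PrevalenceEntry", layer,
                f"bands {sorted(bands)} != required {sorted(expected)}")
    for p in ps.prevalence:
        if not 0.0 <= p.value <= 1.0:
            bad("PrevalenceEntry", f"{p.layer}[{_format_band(p.age_band)}].value",
                f"value {p.value} outside [0, 1]")
        if p.se < 0:
            bad("PrevalenceEntry", f"{p.layer}[{_format_band(p.age_band)}].se",
                f"value {p.se} < 0")

    # --- mortality modifiers
    m = ps.mortality
    if m.rr_nafld < 1.0:
        bad("MortalityModifiers", "rr_nafld", f"relative risk {m.rr_nafld} < 1")
    if m.rr_cirrhosis < 1.0:
        bad("MortalityModifiers", "rr_cirrhosis",
            f"relative risk {m.rr_cirrhosis} < 1")
    for nm, p in (("p_death_hcc", m.p_death_hcc), ("p_death_lt", m.p_death_lt),
                  ("p_death_post_lt", m.p_death_post_lt)):
        if not 0.0 <= p <= 1.0:
            bad("MortalityModifiers", nm, f"probability {p} outside [0, 1]")

    # --- economics
    if ps.econ.discount_rate < 0:
        bad("EconomicSettings", "discount_rate",
            f"value {ps.econ.discount_rate} < 0")
    if ps.econ.thb_per_usd <= 0:
        bad("EconomicSettings", "thb_per_usd", "must be > 0")
    if ps.econ.cycle_length_years != 1:
        bad("EconomicSettings", "cycle_length_years", "fixed at 1 year")

    # --- initial distributions
    for band in REPORTING_BANDS:
        if band not in ps.initial_distribution:
            bad("ParameterSet", f"initial_distribution[{_format_band(band)}]",
                "missing reporting band")
            continue
        dist = ps.initial_distribution[band]
        extra = set(dist) - set(INITIAL_STATES)
        if extra:
            bad("ParameterSet", f"initial_distribution[{_format_band(band)}]",
                f"states outside the prevalent-case support: "
                f"{sorted(s.value for s in extra)}")
        if any(v < 0 for v in dist.values()):
            bad("ParameterSet", f"initial_distribution[{_format_band(band)}]",
                "negative proportion")
        total = sum(dist.values())
        if abs(total - 1.0) > 1e-9:
            bad("ParameterSet", f"initial_distribution[{_format_band(band)}]",
                f"proportions sum to {total}, not 1 +/- 1e-9")
    for band in REPORTING_BANDS:
        if band not in ps.entry_ages:
            bad("ParameterSet", f"entry_ages[{_format_band(band)}]",
                "missing reporting band")

    # --- overrides
    for band, o in ps.band_overrides.items():
        if not 0.0 <= o.nash_prevalence <= o.nafld_prevalence <= 1.0:
            bad("BandOverride", _format_band(band),
                "requires 0 <= nash_prevalence <= nafld_prevalence <= 1")

    return out


# ---------------------------------------------------------------------------
# packaged base-case fixture
# ---------------------------------------------------------------------------

def base_case_path() -> Path:
    """Path of the packaged base-case parameter file."""
    return Path(importlib.resources.files("nashburden").joinpath(
        "data/base_case.yaml"))


def load_base_parameters() -> ParameterSet:
    """The packaged base-case parameter set (published inputs + defaults)."""
    return load_parameters(base_case_path())
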