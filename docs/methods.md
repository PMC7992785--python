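# Methods

## Model structure

The package implements a deterministic Markov cohort model over eleven
health states — NORMAL, fibrosis stages F0–F3, compensated cirrhosis
(F4/CC), decompensated cirrhosis (DC), hepatocellular carcinoma (HCC),
liver transplantation (LT), post-transplantation (post-LT) and DEATH — with
one-year cycles and a lifetime horizon. Progression follows the natural
history of NAFLD; regression is allowed one stage at a time down to F0, and
F0 → NORMAL is fixed at zero by assumption. DEATH is absorbing.

### Mortality

Each live state's annual death probability is assembled as:

| state        | annual death probability                       |
|--------------|------------------------------------------------|
| NORMAL       | q(a) — background age-specific mortality       |
| F0–F3        | min(1, q(a) · RR_NAFLD)                        |
| F4/CC, DC    | min(1, q(a) · RR_cirrhosis)                    |
| HCC          | 0.4490 (total; background not added)           |
| LT           | 0.2007 (the transplant-year probability)       |
| post-LT      | 0.0653                                         |

The HCC/LT/post-LT values are treated as *total* annual death
probabilities, not ASMR-additive: they are quoted as single transitions and
dominate background mortality at every adult age. Ages advance in integer
years; the life table is looked up at the floor of the cohort's current age
and extrapolated flat beyond its terminal row.

### Row construction (competing risks)

Death is applied first each cycle. Printed exit probabilities are read as
conditional on surviving the cycle, so each exit edge receives
`p_exit · (1 − p_death)` and the self-loop the residual — rows are valid by
construction and never renormalised. One exception: the printed LT →
post-LT value (0.7993) equals 1 − 0.2007 and is therefore the unconditional
complement of transplant-year death; it is flagged as such, receives the
full survival mass, and is recomputed from the sampled death probability in
the PSA. Exit bundles whose conditional probabilities sum above 1 raise an
infeasibility error naming the state.

No half-cycle correction is applied: state membership and costs are
evaluated at cycle start, matching the spreadsheet-style cohort models this
package emulates. A trace's terminal occupancy row (the state reached after
the final transition) is never costed, so a T-cycle run accrues exactly T
years of cost.

### Horizon

Cohorts run until age 100 (configurable `horizon_age`) or until the living
fraction falls below 1e-9 of the cohort, whichever comes first.

## Prevalence staging

Prevalence is layered: NAFLD in the general population over three reporting
bands (18–39 / 40–59 / 60+), and NASH-with-significant-fibrosis within
NAFLD over seven finer bands. The default collapse onto reporting bands is
a population-weighted mean of the finer layer using the finest available
population table; a population band that straddles a prevalence band is a
coverage error.

The published reporting-band prevalences are model outputs whose weighting
lives in an unpublished appendix, so the packaged fixture *pins* each
reporting band to the exact ratio printed-cohort / printed-population
(e.g. 339,981 / 11,136,059 → 3.05 % at 2 dp). This reproduces the published
case counts to the person. In the PSA these pinned values are rescaled by
the ratio (sampled / base) of the default-weighted band prevalence, so the
layer standard errors still propagate while the base case stays pinned.

All arithmetic keeps full floating precision; counts are rounded half-up to
whole persons and percentages to 2 dp only in reports. Report totals are
the sums of the *rounded* band cells, which keeps every emitted table
internally consistent to the person and the dollar (the published tables
have exactly this property).

## Costs

Annual direct-medical costs (2019 USD): pre-cirrhotic NASH (applied to
F0–F3) $89, CC $2,121, DC $3,916, HCC $4,787, LT $18,703, post-LT $2,908;
NORMAL and DEATH cost zero. There are no one-off transition costs. Costs
are discounted at 3 %/year with year zero undiscounted; outcomes are the
first-year (cycle 0), fifth-year (cycle 4, the cost incurred *during* the
fifth year — not cumulative) and lifetime (sum over all cycles) costs. A
THB→USD helper applies a scalar CPI multiplier and the fixed 32.3 THB/USD
rate; no CPI time series is modelled.

## Probabilistic sensitivity analysis

Every parameter with a standard error is drawn from a method-of-moments
distribution on its natural support: Beta for probabilities and prevalences
(α = m(m(1−m)/s² − 1), β = (1−m)(···)), Gamma for costs (shape = (m/s)²,
scale = s²/m). Parameters are sampled independently; se-absent values (the
age-specific NORMAL → F0 incidence, the zero regression, the LT → post-LT
complement) stay fixed or are recomputed. Draws producing an invalid
parameter set are rejected and redrawn whole (rejection keeps marginal
means unbiased; redraws are counted, with a hard cap of 1000 per set).
Iteration i uses a generator seeded from SeedSequence([seed, i]), making
every iteration reproducible independently of execution order. Outcome
summaries (mean, min/max, 2.5/25/50/75/97.5 percentiles) are recomputable
from the persisted per-iteration table.

## Synthetic inputs and their limits

Three inputs exist only in unpublished appendices and are generated
synthetically:

- **Life table** — Gompertz–Makeham, q(a) = 1 − exp(−(c + b·e^{g·a})),
  defaults c = 7.5e-4, b = 7e-5, g = 0.086 over ages 18–110, giving an
  adult life expectancy ≈ 75 years (plausible for a middle-income
  population). b = 0 is allowed as the flat Makeham-only limit; otherwise
  the schedule must be strictly increasing.
- **Population pyramid** — fine-band counts proportional to a plausible
  ageing-pyramid shape (optionally jittered, deterministically per seed),
  integerised by largest remainder so the three reporting-band totals hit
  the published head counts exactly (20,533,776 / 19,919,412 / 11,136,059).
- **Initial stage split** — the fibrosis-stage distribution of prevalent
  cases at entry is unpublished; the default gives older bands more F3/F4+
  mass (18–39: 70/25/4/0.7/0.3 % over F2/F3/F4CC/DC/HCC; 40–59:
  55/30/11/2.5/1.5; 60+: 35/33/22/6/4). Entry ages default to band
  midpoints (28.5, 49.5, 70).
- **Mortality relative risks** — RR_NAFLD = 1.57 and RR_cirrhosis = 5.0 are
  editable defaults in the fixture; the source study cites but does not
  print them.

Consequences: the **case counts and prevalence rates are exact** (pinned to
printed cells), but the **cost cells are not reproducible** — they depend on
all four synthetic inputs. At these defaults the model yields a lifetime
total of ≈ $20.1 billion and a *higher* per-case cost for the youngest band
(longevity dominates the severity gradient), whereas the study it emulates
reports $15.2 billion with the oldest band costing most per case. The
defaults are deliberately not tuned to reverse this: a contrast test in the
suite verifies the structural point that, with flat severity and flat
costs, an older cohort can never cost more per case — the published pattern
*requires* age-weighted initial severity (and/or progression) information
that is not public. A green test suite therefore establishes arithmetic
consistency with the printed tables and the engine's structural invariants,
not the published cost figures.

## Numerical conventions

- Rounding: half-up (ties away from zero), applied only at report time.
- Conservation: every trace cycle sums to the cohort size within 1e-6
  relative; six-cycle traces match the explicit ordered matrix product to
  1e-12.
- Validation returns a violation list (type, field, rule) rather than
  raising; loading raises with all violations attached.
- YAML round-trips are numerically exact (floats serialised via repr).
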