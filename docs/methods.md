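# Methods

## Model

`visioncea` implements a cohort state-transition (Markov) model for
comparing two intravitreal treatments of naïve diabetic macular edema
(DME): an anti-VEGF agent (aflibercept) and a delayed-release dexamethasone
implant.  Health states are five visual-acuity (VA) bands of the
better-seeing eye on the Snellen scale — >20/40, ≤20/40–>20/80,
≤20/80–>20/200, ≤20/200–>20/400, ≤20/400 — plus an absorbing death state.
The cycle length is 3 months; allowed per-cycle VA transitions are one band
of improvement and one or two bands of worsening (the band structure of the
published per-arm matrices, which the validator enforces).

Each cycle, for each arm:

1. The age-specific annual death probability `q_x` is looked up at
   floor(current age) and converted to a cycle probability with the
   constant-rate identity `q_c = 1 − (1 − q_x)^t` (t in years).  Composing
   `q_c` over `1/t` cycles reproduces `q_x` exactly; this identity is
   property-tested to 1e-12.
2. Mortality is embedded first: the 5×5 VA row is scaled by `1 − q_c` and
   `q_c` is placed in the death column.  The order of competing risks is
   not identifiable from published inputs; mortality-first is the standard
   cohort convention and preserves row-stochasticity.
3. The occupancy vector advances, QALYs accrue as `Σ s_k[state]·u(state)·t`
   and costs as (alive occupancy) × (annual cost) × t.  The death state
   accrues nothing.
4. Both streams are discounted at cycle start times with annual-equivalent
   compounding `(1+d)^{−k t}`; d = 3.5 %/year by default.  Continuous
   discounting is deliberately not implemented; the 0 %/5 % scenario runs
   bound the sensitivity to this choice.

Half-cycle correction (averaging adjacent occupancies) is available as a
flag and exercised in tests, but is off by default.  A lifetime horizon
runs until cohort absorption; the life table forces q = 1 at its terminal
age (100 by default), so absorption always occurs.  A validated
closed-form check: with constant mortality and frozen VA dynamics, the
engine's discounted life-years agree with the annuity
`∫ e^{−(μ+δ)s} ds` within 1 % at 3-month cycles over 40 years.

Incremental results are reported as ΔC, ΔQ and ICER = ΔC/ΔQ (€/QALY) when
both increments share a sign; otherwise a dominance label is reported and
no ratio is formed.

## Inputs and their provenance

Transition matrices (per arm), utilities by VA state under time trade-off
(TTO) and standard gamble (SG) elicitation, unit costs (2020 €), annual
resource use with PSA ranges, adverse-event rates and annual
comorbidity/non-medical/rehabilitation/equipment costs are transcribed in
`src/visioncea/data/reference_parameters.yaml` with explicit units in every
field name, so each number can be audited against its source table.  A
completeness test asserts that every transcribed figure appears in the
fixture.

Two required inputs have no published values and are generated
synthetically (and clearly labelled as such):

* **Life table** — a Gompertz–Makeham schedule
  `q_x = 1 − exp(−[c + (a/b)(e^{b(x+1)} − e^{bx})])` with defaults
  a = 2.4e-5, b = 0.095, c = 0, chosen once to give a remaining life
  expectancy of ≈ 17 years at age 68 (the cohort's mean age), the right
  order of magnitude for a Western European population.  Users supply a
  real national table as a two-column CSV (age, qx) via
  `LifeTable.from_csv` / `--life-table`.
* **Starting VA distribution** — a preset occupancy vector
  (0.10, 0.25, 0.30, 0.20, 0.15) over the five bands
  (`synthetic_moderate`), or any user-supplied 5-vector, or Dirichlet
  draws for testing.

Because both stand-ins differ from the (unpublished) originals, the
deterministic totals this package prints are not expected to equal any
externally reported totals; the engine's correctness is instead
established by closed forms, invariants and the microsimulation oracle.

The sentence sourcing the comorbidity (€771/yr) and non-medical
(€1,577/yr) figures is ambiguous about whether they are per cost category
or per arm; the default (`other_cost_interpretation="category"`) applies
their sum to every alive patient in both arms, and the per-arm reading is
available in config.  The choice is logged at load time.

## A note on the transcribed cost inputs

With the inputs exactly as transcribed — 9.8 aflibercept injections/year
at €588.8/vial versus 3.1 dexamethasone injections/year at €750.92/vial,
and identical age-only background mortality — the dexamethasone arm has
both the lower annual cost (≈ €4,140 vs ≈ €8,372 in treatment costs) and
the more favourable transition matrix, so it strictly **dominates** and no
positive ICER exists.  The source tables these inputs were transcribed
from nevertheless report dexamethasone as roughly 1.8× the dearer arm
with an ICER near €29,000/QALY.  Those per-arm totals are arithmetically
reproducible (to within ~8 %) under exactly one single-field change:
exchanging the annual injection counts between the arms.  The package
keeps the transcription faithful by default and ships the exchange as an
explicit, named scenario (`exchanged_injection_scenario` /
`cost_ordering_reconciliation`), never applying it silently.  ICER-based
sensitivity analyses (tornado, scenario orderings) are reported under that
reconciliation, since ICER orderings are undefined under dominance.

## Extrapolation beyond the one-year trial window

* **continuous** (reference case): year-1 matrices and full treatment
  costs persist over the whole horizon.
* **one_time_benefit**: both treatments stop after year 1.  Thereafter
  both cohorts decline under a common natural-decline matrix and only
  background (comorbidity, non-medical, rehabilitation, equipment) costs
  accrue.  The common matrix is not published; the default takes the
  reference arm's worsening probabilities with improvement entries zeroed
  (mass returned to the diagonal) and is overridable.  Every run logs the
  choice.
* **rebound**: as one_time_benefit, but the treated cohort's worsening
  probabilities are multiplied by a catch-up factor (default 2.0) until
  its alive-state VA distribution meets the reference cohort's.  Catch-up
  detection uses a total-variation tolerance (default 0.01) with a
  one-step lookahead: the accelerated matrix is applied only while it
  still closes the distance, so a coarse cycle grid cannot overshoot past
  the reference trajectory and decline at the accelerated rate forever.
  No functional form for the rebound is published; a single multiplier is
  the simplest parameterization and both knobs are config fields.

Cycle lengths other than 3 months re-aggregate the transition matrices by
matrix power (the exact aggregation of the embedded chain), projected back
onto the allowed band; entry-wise scalar conversion of probabilities would
not yield a stochastic matrix.  The one-year-cycle scenario reproduces the
3-month totals within 5 % on the bundled model (timing granularity only).

## Probabilistic sensitivity analysis

Sampled per draw, following standard practice for each parameter type:

* transition probabilities: independent beta distributions on the nonzero
  off-diagonal entries (method-of-moments from the printed mean and a 20 %
  variation coefficient), diagonal set to the complement; rows whose
  off-diagonal draws exceed 1 are renormalised and the frequency logged,
* utilities of the configured elicitation method: beta per state with SD
  derived from the printed range as (high − low)/4 (ranges resemble ±2 SD
  intervals; configurable), draws clipped at 1 — the printed SG upper
  bound of 1.11 is stored as published but a utility above perfect health
  is not meaningful in QALY arithmetic,
* unit costs (drug vials, procedures, adverse events) and the
  comorbidity/non-medical annual costs: gamma at the printed SDs (20 % CV),
* annual resource use: uniform over the printed ranges.

Adverse-event rates and injection counts stay fixed (they are scenario
levers, not PSA parameters).  Each draw is evaluated deterministically for
both arms; summaries are the CE-plane quadrant fractions, per-arm absolute
scatters and the CEAC over λ ∈ [0, 100,000] €/QALY in €500 steps (fraction
of draws with net monetary benefit λ·ΔQ − ΔC > 0, ties to the reference
arm).  One master seed spawns one child seed sequence per draw, so results
are bit-identical for a given (seed, N).

## Microsimulation oracle

An individual-level simulator drives n patients through exactly the same
per-cycle matrices (shared schedule and mortality-embedding code path) and
accrues discounted cost/QALYs per path.  It validates the cohort trace
arithmetic — accumulation, discounting, absorption — against the law of
large numbers (agreement within 3 SE at n = 100,000), while the matrices
themselves are validated separately against the transcribed tables.  The
simulator draws from a single seeded generator with vectorized per-cycle
draws across individuals; results are reproducible from the seed.

## Problem sizes and numerical choices

The bundled lifetime run spans ≈ 132 cycles (age 68.1 to 101).  The
default PSA uses 10,000 repetitions; the acceptance script runs at that
size, while unit tests use 10–150 draws.  Row-stochasticity is enforced to
1e-9; occupancy conservation holds to 1e-9 over the whole horizon;
round-trips of parameter files are exact (full-precision float
serialisation).  ICERs are reported at full precision with a
nearest-euro convenience property.

## Limitations

* The synthetic life table and starting distribution are order-of-magnitude
  stand-ins, not national statistics; absolute totals shift with both.
* No tunnel states, no within-year treatment-effect waning, single-eye
  (better-seeing-eye) perspective, adverse events priced as expected
  annual costs rather than modelled as transitions.
* Utilities are sampled independently across states; no cost–utility
  correlation structure.
* The PSA propagates parameter uncertainty through the full model; a
  scatter generated instead by perturbing the incremental results directly
  would show more dispersion across quadrants than parameter propagation
  does.
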