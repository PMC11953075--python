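# Methods

## Model structure and assumptions

`dcisim` follows single-birth-cohort life histories through a discrete-time
(annual) Markov state-transition model of DCIS natural history. States are
healthy, DCIS by grade (1–3), and four absorbing exits — death from other
causes, invasive breast cancer (IBC), screen-detected DCIS, clinically
detected DCIS. Key structural assumptions:

- **One lesion at a time.** A woman carries at most one DCIS lesion; its
  grade is fixed at onset (no grade transitions). After regression she is
  again at the full age-specific onset risk, so multiple episodes per woman
  are possible.
- **IBC is an exit, not a disease course.** Progression ends the episode and
  removes the woman; invasive-cancer natural history, treatment and
  breast-cancer-specific mortality are out of scope. Direct
  healthy-to-IBC transitions are likewise excluded.
- **Death is disease-independent.** The all-cause death probability in the
  DCIS state equals the healthy-state probability; death *of* DCIS is
  treated as negligible.
- **Screening is memoryless.** Attendance is drawn independently per round
  at a constant participation rate; no persistent attender/non-attender
  subpopulations, and no detection outside scheduled rounds other than the
  constant clinical-detection hazard.

### Event order within a model year

The within-year order is screening → death → disease transition (onset or
one competing-risk draw among regression, progression, clinical detection,
remain). Screening first means a lesion present at a round cannot be
pre-empted by a same-year transition, and a lesion arising in the same year
becomes detectable only at the next round. The order is defined once, in
`kernel.py`, and consumed by both the stochastic engine and the expectation
oracle, so the two cannot drift apart. Annual probabilities are used as
printed — the competing draw is a single multinomial with residual "remain"
mass (rejected at load if the hazards sum above 1), never converted to
continuous rates.

## Input parameters

All probabilities are per year and stored as plain fractions; source-table
units (mortality ×10⁻², onset ×10⁻³) are applied once at load time.

| Parameter | Meaning | Dutch base value |
|---|---|---|
| P1(a) | all-cause death, per age | life table, 0.00324 at birth → 1.0 at 100 |
| P2(a, g) | DCIS onset | banded, peaks at ages 49–54 (e.g. 0.325×10⁻³ for grade 3) |
| P3(g) | regression to healthy | 0.0488, all grades |
| P4(a, g) | progression to IBC | 0.087–0.159 (ages 20–54), 0.073–0.134 (55+) |
| P5 | mammographic sensitivity for DCIS | 0.86 |
| P6 | clinical detection of a present DCIS | 0.05 |
| — | screening schedule | biennial, ages 50–74 |
| — | participation per round | 0.76 |

The mortality table is printed as per-band endpoint ranges; per-age values
are obtained by pinning the endpoints to the band's first and last age and
interpolating log-linearly in between (mortality grows approximately
exponentially with age). An explicit per-age table can be supplied instead
(`life_table: {ages: file.csv}`) when exact registry values are available.
Age bands are closed integer intervals; open-ended printed bands ("95 +",
"55 +") run to `max_age` (default 100, where death is certain). The onset
band printed as 80–95 adjoining a zero "95 +" band is encoded as 80–94 so
bands partition the age axis; the choice is numerically irrelevant because
the neighbouring band is zero.

The shipped scenarios define the study conditions: `nl_base.yaml` (Dutch
programme, 10 iterations × 100,000 women, seed 1) and `uk_base.yaml`
(triennial rounds at ages 50–71 with UK-magnitude mortality; participation
and sensitivity inherited from the Dutch base, as no UK-specific values are
published for this setting). The UK life table shipped here is a **synthetic
stand-in** with plausible national-life-table magnitudes
(`uk_mortality_bands_synthetic.csv`); replace it with an official per-age
table for real analyses. Mortality at screening ages is a second-order
influence on detection rates, so conclusions that depend on the screening
schedule are insensitive to this stand-in.

## Outputs and conventions

- **Detection rates** are screen-detected DCIS per 1,000 screening
  examinations (one examination per attended round of an in-model woman),
  attributed to 5-year age groups by age at the round — matching how
  registries report. Grade strata share the all-examinations denominator,
  so grade rates sum exactly to the total.
- **Fate fractions** are per episode (onsets, not women), over six
  exhaustive fates: regressed, progressed to IBC, screen-detected,
  clinically detected, died of other causes, censored at the horizon
  (structurally empty when death is certain at `max_age`).
- **Intervals** are 2.5/97.5 percentile bounds across cohort iterations.
  Note that such percentile intervals do *not* narrow as iterations are
  added (they converge to the sampling distribution's quantiles); the
  standard error of the reported mean does shrink, and that is the quantity
  the test suite checks.

## Expectation oracle

Because every yearly update is linear in the state probability masses, the
exact expectation of any aggregate can be computed by propagating masses
through the same ordered update (`expectation.propagate`). The oracle
checks mass conservation at every age to 10⁻¹², reproduces an independent
memoized path enumeration exactly on short-horizon configurations, and
bounds the Monte Carlo engine: tests require engine aggregates to match the
oracle within three across-iteration standard errors. It is also the
noise-free route for direction-and-magnitude sensitivity checks.

## Sensitivity analyses

Univariate analysis re-runs the scenario at each parameter's interval
bounds with common random numbers (the base master seed), so bound runs
differ from base only through the varied parameter; results are ordered by
largest absolute effect on the screen-detection rate (tornado order).
Table-valued inputs (onset, progression, mortality) vary through one
table-wide multiplier, preserving their age/grade shape. The probabilistic
analysis samples all parameters jointly and uniformly within their
intervals (default 100 scenarios; the sampler is pluggable) with a fully
seed-determined design. No authoritative 95% CIs are published for the base
inputs, so interval files are user-supplied; the shipped
`intervals_example.yaml` uses illustrative ±10% bounds.

## Numerical and design choices

- Reproducibility: each cohort iteration uses a child seed spawned
  deterministically from the master seed (`numpy.random.SeedSequence`);
  identical configuration and seed give bit-identical output.
- The engine is vectorized over women (one numpy pass per model year);
  a full Dutch base run (10 × 100,000 women, 101 years) takes a few seconds
  on one CPU. `simulate_woman` and `simulate_year` run the same vectorized
  step at n = 1.
- Degenerate inputs: zero-residual competing draws (hazards summing to
  exactly 1) are allowed; hazard sums above 1, age-band gaps or overlaps,
  and probabilities outside [0, 1] are rejected at load with the offending
  entry named. Strata with zero examinations are omitted from rate tables
  rather than reported as 0/0.
- Whether clinical detection may occur in a screening year was left open by
  the source material; here it can (the competing draw always includes P6),
  which keeps the yearly update uniform across ages.

## Known limitations

- **First-round prevalence.** Registry data show a U-shaped age profile
  with a pronounced peak in the 50–54 group, driven by the prevalent pool
  at a woman's first screen. Under the published annual hazards the pool
  that can accumulate before age 50 is smaller than that peak implies, so
  the model's profile is flatter: the 50–54 rate is underpredicted
  (≈1.4 vs 1.7 per 1,000) while the total, the remaining age groups, grade
  strata, fates, and the grade distribution reproduce well. The same effect
  slightly depresses the UK triennial total (≈1.57 vs 1.7 per 1,000).
- The model describes the general population; high-risk subgroups,
  screening outside the organized programme beyond the constant clinical
  hazard, and programme roll-out dynamics are not represented.
- Onset probabilities derive from observed incidence and therefore cannot
  include DCIS that never surfaces by any route.
- Overdiagnosis is not computed here, though the fate machinery (episode
  fates under scenarios with and without screening) is the intended basis
  for such estimates.
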