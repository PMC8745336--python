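# Methods

## Measures

**Catastrophic health expenditure.** For household *i*, let *T_i* be annual
out-of-pocket (OOP) health spending and *X_i* the resource denominator —
annual total consumption expenditure, or non-food consumption
(total − food, "capacity to pay").  With threshold share *Z* ∈ (0, 1):

    E_i = 1{ T_i / X_i > Z }
    H   = (1/N) Σ E_i
    O_i = E_i ( T_i/X_i − Z ),   O = (1/N) Σ O_i

The indicator uses the **strict** inequality, following the defining
equation; prose summaries of such studies often say "10% or more", so a
`weak` variant (≥) is exposed on `CheThreshold` and in the run config
(`che_inequality`).  Ties are measure-zero in continuous data, so the choice
is immaterial in practice but is pinned down for reproducibility.
Households with a non-positive denominator (e.g. food share of 1 under the
non-food rule) are excluded from N with a logged count — they are neither
assumed catastrophic nor safe, and the effective N is always reported.
`O(z)` is by construction the mean of `max(ratio − z, 0)`: non-increasing,
convex, piecewise linear with right-derivative −H(z); the test suite checks
these shape properties against brute-force enumeration.

**Impoverishment.** Per-person consumption is `X / size**theta`; the
household-composition exponent θ defaults to 1 (plain per-capita) because no
specific equivalence scale is standard for this setting; θ is configurable
(`equivalence_exponent`).  A household is *pre-payment poor* if its gross
per-person consumption is below the annualised line, and *impoverished* if
it is not pre-payment poor but falls below the line after OOP is deducted;
post-payment poor = pre-poor + impoverished by construction.  Net
consumption is floored at zero before the per-person division: OOP can
exceed annual consumption (financed by savings, gifts, asset sales or debt),
and a negative consumption level is meaningless.  The flooring is flagged in
CLI output metadata.  The poverty line is `per_day_ppp × 365 × ppp_factor`;
the PPP factor (local currency per international dollar) has **no silent
default for real data** — it must be supplied — while synthetic data are
denominated in international dollars, where 1 applies.

**Pen's parade.** Households sorted ascending by gross per-person
consumption (ties broken by household id), each carrying its net value; the
vertical drips from gross to net against the poverty line visualise who is
pushed under.  A convenience matplotlib renderer is included; the CSV series
is the analysis artifact.

**Wealth quintiles.** Ranking is by annual per-capita total consumption.
Cuts are made on ranks, not values: with N = 5q + r, the first r quintiles
get q + 1 members, so sizes differ by at most one even under ties, and the
id tie-break makes the assignment deterministic.  The equity table computes
CHE headcount/overshoot per threshold, mean expenditure and mean OOP within
each quintile, and appends an all-households row computed on the pooled data
(never by averaging quintile rows); the size-weighted average of quintile
headcounts equals the pooled headcount exactly, which the tests assert at
1e-12.

**Determinants and comparisons.** The CHE outcome (default: 10% of total)
is regressed on hospitalisation (any inpatient admission), wealth quintile
(indicators Q1–Q4, richest quintile as reference), residence outside the
capital, and any private-facility care, by maximum-likelihood logistic
regression (statsmodels).  Adjusted odds ratios are exponentiated
coefficients with Wald 95% CIs.  Non-convergence — perfect separation or a
single-class outcome — is reported as an explicit status with no
coefficients, never hidden.  The OOP comparison between government and
private care is a standard one-way ANOVA (scipy) on total OOP with the
binary grouping public vs any-private.  The design sample-size formula uses
normal quantiles computed from `scipy.stats.norm.ppf`; `rounded_z=True`
rounds them to two decimals (1.96, 0.84 at α = 0.05, power 0.80),
reproducing the textbook arithmetic (raw 90.16 → 91 per group).  A
recruitment helper inflates per-group n across strata by an anticipated
non-response rate but asserts nothing about any particular survey's total.

## Costing

Total OOP is the exact seven-term sum: direct medical (procedure, drug,
bed, laboratory/imaging) plus direct non-medical (transport, attendant,
other).  "Other expenses" sits in the non-medical block, matching its
placement in the published cost table.  ETB amounts are converted to 2018
USD at 28.574 ETB/USD at read time; all internal arithmetic is USD and
unrounded.  Monthly-collected expenditures are annualised by ×12.
Projection from visit counts multiplies a per-event mean cost by the number
of outpatient visits and inpatient admissions; the per-event means come from
the household's own observed events where available, with the sample mean
per event (`per_event_means`) as the imputation source otherwise — the
published description of the projection does not specify the source, and the
household-first rule preserves observed totals.

## Synthetic-data generator

The generator emulates the published marginals of the 452-household survey:

| Quantity | Distribution | Default | Source of default |
|---|---|---|---|
| household size | rounded normal, truncated at 1 | mean 4.5, SD 2.1 | published table |
| annual expenditure | log-normal | mean $2,520, median $2,050 | published table |
| food share | Beta | mean 0.46, concentration 20 | published share; concentration chosen for a realistic spread (SD ≈ 0.11) |
| residence outside capital | Bernoulli | 268/452 | published table |
| sex (male) | Bernoulli | 318/452 | published table |
| facility type | categorical | 391/34/27 of 452 | published table |
| visit pattern | categorical | 67 outpatient-only / 217 inpatient-only / 168 mixed | running text (the table's two labels are swapped) |
| extra visits | Poisson on top of the guaranteed first event | 1.5 outpatient, 0.3 inpatient | chosen as typical follow-up intensity |
| per-episode cost | log-normal, σ = 1 | scale $60 per public outpatient visit | set from the published public outpatient median |
| cost multipliers (log scale) | inpatient ln(250/60), private ln 6, outside ln(992/881) | — | published medians/means and ratios |
| category split | Dirichlet, concentration 4 | expectations ∝ published category means | published table |

The log-normal is pinned by the (mean, median) pair: μ = ln(median),
σ = √(2 ln(mean/median)) ≈ 0.643.  Multipliers act on the log scale, so the
default private shift of ln 6 makes private episode costs six times public
ones in expectation; mixed-facility households flip a fair coin per episode.

Household size and log-expenditure share a Gaussian copula with correlation
0.5 (configurable): consumption scales with household size in real surveys,
both marginals remain exactly as configured, and the joint dependence is not
identifiable from printed tables.  This is the main respect in which the
generator is weaker than real data: the published per-person poverty rate
(36% pre-payment poor) reflects a joint size–expenditure distribution the
tables do not pin down, and the synthetic rate is substantially higher.
Passing tests therefore demonstrate that the *measures* are computed
correctly and that planted quantities are recovered — not that the synthetic
population reproduces every published joint statistic.  Exact replication of
the quintile-table cells is explicitly not a target for the same reason; the
qualitative gradient (CHE falling from the poorest to the richest quintile)
is reproduced and tested.

**Planted truths.** `generate_with_known_truth` supports two modes.
(1) *Calibrated CHE rate*: with common random draws, the expected headcount
as a function of a multiplicative cost scale is the empirical survival
function of the baseline OOP ratios, so the calibrating scale is the
threshold divided by the (1 − rate)-quantile of ratios on a 20,000-household
calibration sample — the exact root of the Monte-Carlo rate equation, well
inside the 1e-3 tolerance.  (2) *Planted logistic model*: the CHE outcome is
drawn from the stated logistic model on the generated covariates and the
household's OOP is placed on the matching side of the threshold, so the
pipeline's indicator reproduces the planted outcome exactly and confidence-
interval coverage can be assessed honestly.  Requested rates outside (0, 1)
are rejected.

## Numerical and design choices

- Row screening at read time excludes, with per-rule counts: missing ids or
  values, unparseable numbers, negative money or counts, food > total,
  size < 1, invalid categories, visit-type/count inconsistencies, duplicate
  ids.  Nothing is dropped silently; `passed` means zero exclusions.
- Quantile interpolation (numpy default linear) is used in the calibration;
  at the 20,000-household calibration size the achieved expected rate is
  within 5e-5 of the target.
- Determinism: one `numpy.random.Generator` per generation, fixed draw
  order (economics → visit structure → costs); derived seeds come from
  `SeedSequence.spawn` and stay below 2^31.
- Problem sizes in the test and acceptance runs: moment recovery at
  n = 100,000; CHE-rate calibration at n = 20,000; coverage of the planted
  private-facility log-odds over 200 replicates at the survey's own
  n = 452; brute-force oracle equivalence over 1,000 random datasets of
  size ≤ 20 at tolerance 1e-12.

## Known limitations

- Indirect costs (productivity loss of patients and caregivers) are out of
  scope; only direct medical and non-medical OOP is modelled.
- The non-food denominator deducts food only; a fuller "basic necessities"
  subsistence deduction would need data the survey instrument did not
  collect.
- No survey weights: the analysis treats the sample as self-weighting, as
  the source survey did.
- Wald CIs for the logistic model are first-order; at small strata (tens of
  private-facility patients) their coverage is near-nominal but not exact.
- Concentration indices and poverty-gap measures are not implemented (out
  of scope).
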