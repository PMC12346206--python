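# Methods

## Scope and model

`handcost` implements a one-year cost-of-illness analysis of surgically
treated diabetic hand infections from the healthcare-payer perspective,
with indirect productivity losses added through the human-capital approach.
The underlying study population is a 75-patient surgical case series
(2015–2020, single centre, Türkiye); its per-patient data are unpublished,
so the package works with synthetic cohorts whose *marginal* structure
matches the published summaries, plus a Monte Carlo scenario model for
prospective cost uncertainty.

## Synthetic cohort generator

The stochastic generator draws all fields from one seeded
`numpy.random.Generator` in a fixed, documented order, making cohorts
bit-reproducible from `(config, seed)`.

* **Categorical fields** are Bernoulli/categorical draws at the study
  prevalences: sex 11/75 female; diabetes type 62/75 type-2; eight
  surgical-intervention groups with probabilities 24/4/5/18/7/10/6/1 out
  of 75; admission signs purulent discharge 52%, erythema 68%, swelling
  74%, gangrene 29%, limited joint motion 35%; right-handedness 59/75 and
  dominant-hand infection 58/75.
* **Admission labs and age** are normals matched to the published
  mean ± SD and clipped to the published min–max (e.g. CRP 49.83 ± 15.72,
  range 25–102 mg/L). Clipping (not resampling) is used deliberately so
  the support equals the observed range; it leaves small atoms at the
  bounds and slightly shrinks the variance, which is acceptable for a
  generator whose claims are calibration of prevalences and ranges, not
  of higher moments.
* **Cost components** are log-normals matched to the published mean/SD and
  clipped to the published range — costs are nonnegative and right-skewed
  (median < mean in every published component). ICU and ward-stay costs
  are zeroed when the corresponding stay is zero days.
* **Outpatient visits** are a negative binomial matched to mean 22.29 and
  SD 11.01, shifted to the hard floor of 7 visits and capped at the
  observed maximum 59 — an over-dispersed count with roughly 15/75 of mass
  at ≥ 30 visits, matching the heavy-user subgroup.
* **ICU days and incapacity days** (median 0, long right tails) are
  over-dispersed negative binomials matched to the published mean/SD.
* **Currency structure.** Component values are drawn on the USD-2022Q4
  scale (the scale of the published summaries) and back-converted to
  nominal TRY for a uniformly drawn year in the 2015–2020 study window, so
  downstream aggregation exercises the full FX + CPI pipeline. Incapacity
  items are priced at a daily wage of 8.54 USD (2020) — chosen so the
  longest observed spell (102 days) prices out near the published maximum
  (~1002 USD target-period) — and are a config input, not a wage-series
  estimate.

### Reference fixture

`build_reference_fixture()` is RNG-free. Marginal counts (75; 11/64;
62 type-2; 24/4/5/18/7/10/6/1; 15 at ≥ 30 visits; handedness joint counts
48/11/6/10) are exact by construction and asserted as equalities.
Continuous fields are deterministic spreads pinned to each published
median, minimum and maximum (the overall visit median is exactly 20),
distributed across patients by fixed coprime-stride permutations so fields
are not artificially co-monotone. Per-patient joint structure beyond these
marginals is *not* claimed: the published rank tests (H = 10.728 and
21.162) depend on the unpublished per-patient values and are therefore not
reproduction targets.

### What the generator does not emulate

Correlations between components (e.g. ward days vs ward cost beyond the
zero-stay link, visit counts vs outpatient cost in stochastic mode),
microbiology, infection location, and ICD-10 coding are not modelled.
Passing tests therefore demonstrate calibration of marginals and correct
pipeline arithmetic, not clinical realism of joint distributions.

## Cost model

Bottom-up aggregation: each cost item is converted to target-period USD
and summed by category; `total` is the exact sum of the package's own
components and `subtotal_without_surgical = total − surgical`. (The
published component means do not sum exactly to the published total; the
package enforces the self-consistent definition instead of reproducing the
residual.) SDs use the n−1 denominator; an n=1 group reports SD 0 with a
degenerate flag in summaries and a suppressed SD in comparison tables.
Monetary arithmetic is unrounded internally; rounding is half-even to two
decimals at presentation and in CSV cost cells.

## Currency conversion

Three fixed steps: multiply by 1/fx[year] (annual-average local units per
USD), then by cpi[2022Q4]/cpi[year]. Source-year amounts use that year's
annual-average CPI; only the target uses the quarterly index — the quoted
procedure names a quarterly target only. The CPI-U series is assumed. The
packaged FX/CPI CSVs are example tables for tests and worked examples;
real analyses should supply the official ECB/BLS series in the same
two-column schemas, which are validated strictly on load.

## Monte Carlo engine

The five inputs and their distributions are fixed by the scenario
definition (see README). Because no composition formula is stated by the
source analysis, the engine uses the simplest linear composition
consistent with the named cost categories, with three explicit unit-cost
coefficients defaulting to documented placeholders (antibiotics 150
TRY/day, re-infection episode 9,000 TRY, wage 400 TRY/day, all nominal
2022). Design choices:

* **Two-stage re-infection**: the beta draw is an uncertain *rate*; a
  Bernoulli event per iteration propagates that uncertainty into the cost
  tail. Supplying a `bernoulli` spec instead collapses this to a
  single-stage (possibly degenerate) event, which also provides the exact
  deterministic limit used in tests.
* **Event rule**: `uniform(0,1) < p`, which is exact. The classical
  two-digit random-number-table rule ("00–66 of 00–99") fires on 67/100
  integers at a nominal 66% and is kept only as a documented
  compatibility mode.
* **Triangular sampling** is by inverse-CDF; a degenerate triangular
  (min=mode=max) is a point mass.
* **Iterations** default to 10,000 (5,000 is an equally citable
  alternative; both are configurable).
* **CI**: percentile (2.5th/97.5th) by default since no interval method is
  prescribed; a normal-approximation CI is available.
* **PSA**: Spearman rank correlation of each input draw sequence with the
  total sequence; constant sequences get ρ = 0 by convention. Tornado
  ranking follows from |ρ|.
* Totals are composed in nominal TRY of a single scenario year and
  converted to USD-2022Q4 afterwards; mixing input years within one
  scenario is deliberately not supported.

## Kruskal–Wallis

H is computed on average ranks with the standard tie correction
(divide by 1 − Σ(t³−t)/(N³−N)); when all pooled values are identical the
statistic is defined as 0 with p = 1. P-values: chi-square with k−1 df
(default at cohort sizes), exact enumeration of all labelled group
assignments (pooled n ≤ 12, or on request), or a Monte Carlo permutation
null. The permutation path exploits that pooled ranks are invariant under
relabelling, so each resample is a permutation of one fixed rank vector —
vectorised across resamples. Groups of n=1 stay in the statistic (their
rank is well defined); their SD is suppressed in output. Which tie
convention and software produced the originally published p-values is
unknown, so those H/p values are not asserted anywhere.

## Problem sizes and numerical choices

Calibration checks run at n = 10,000 draws against closed-form moments
with 3-standard-error bands; the type-I-error check uses 2,000 null
datasets of three groups of 10 with 199-permutation p-values (α·(B+1)
integral, so the Monte Carlo test is exact at α = 0.05); convergence
diagnostics compare CI half-widths at n = 100/1,000/10,000 against 1/√n
scaling. Ties in H are compared with a 1e-12 slack; truncation-at-zero
resampling aborts after 1,000 rounds to catch near-empty supports.

## Known limitations

Synthetic cohorts cannot reproduce the study's per-patient statistics
(including the published rank tests and the published total
24,602 ± 5,257 USD, whose components were measured, not drawn from the
summary-matched distributions used here). The MCS absolute level is only
as meaningful as its placeholder coefficients. The FX/CPI example tables
approximate the official annual series and should be replaced for any
citable analysis.
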