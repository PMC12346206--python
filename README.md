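# handcost

Cost-of-illness modelling for surgically treated **diabetic hand
infections** — a neglected, expensive complication of diabetes mellitus.
The package is aimed at health-economics and biostatistics researchers who
want a tested, reproducible implementation of a one-year bottom-up cost
analysis: synthetic patient cohorts with the statistical structure of a
75-patient surgical case series, direct/indirect cost aggregation in
inflation-adjusted US dollars, a Monte Carlo cost simulator with
probabilistic sensitivity analysis (PSA), and rank-based comparisons of
outcomes across surgical-intervention groups.

## What it computes

**Cohorts.** `generate_cohort` draws synthetic patients (demographics,
admission labs, clinical signs, eight surgical-intervention groups,
over-dispersed outpatient-visit counts, itemised cost lines in nominal
Turkish lira). `build_reference_fixture()` returns a deterministic
75-patient cohort reproducing every published marginal count exactly
(11 female / 64 male, 62 type-2 diabetics, intervention groups
24/4/5/18/7/10/6/1, 15 patients with ≥ 30 outpatient visits).

**Costing.** Direct costs are summed bottom-up by category (drugs, ward
stay, ICU stay, outpatient follow-up, surgery); indirect costs use the
human-capital approach, `incapacity_days × daily_wage`. Every item is
converted to Q4-2022 USD in two steps — annual-average FX rate, then the
US CPI ratio:

    usd_2022Q4 = amount_local × (1 / fx[year]) × cpi[2022Q4] / cpi[year]

**Monte Carlo simulation.** Per iteration the engine samples five inputs —
hospitalization cost ~ Triangular(8000, 12000, 18000) TRY, surgical cost ~
Normal(6500, 1200) TRY truncated at zero, antibiotic days ~ Uniform(10, 21),
re-infection probability ~ Beta(3, 20) (two-stage: a Bernoulli event is
drawn from the sampled rate), lost workdays ~ Triangular(7, 14, 28) — and
composes them linearly with three user-configurable unit-cost coefficients:

    total = hosp + surg + abx_days·c_abx + I(reinfect)·c_episode + lost_days·wage

Results: mean total with a percentile 95% CI over 10,000 iterations, plus
a PSA table of Spearman rank correlations between each input and the total
(a tornado ranking by |ρ|), and a convergence report.

**Group comparisons.** Tie-corrected Kruskal–Wallis H across intervention
groups, with chi-square, exact-enumeration, or permutation p-values.

## Worked example

```python
>>> import handcost as hc
>>> fix = hc.build_reference_fixture()
>>> len(fix), sum(r.sex == "female" for r in fix)
(75, 11)
>>> tables = hc.packaged_tables()           # example TRY/USD FX + CPI-U tables
>>> result = hc.run_simulation(hc.ScenarioModel(seed=1), tables)
>>> round(result.mean_total, 2), [round(x, 2) for x in result.ci95]
(1796.42, [1382.15, 2436.93])
>>> {k: round(v, 2) for k, v in result.sensitivity.items()}
{'hospitalization_cost': 0.54, 'surgical_cost': 0.31, 'antibiotic_days': 0.13,
 'reinfection_rate': 0.1, 'lost_workdays': 0.46}
```

The simulated mean annual cost is ≈ 1,796 USD-2022Q4 with 95% of
iterations between ≈ 1,382 and 2,437 USD; hospitalization cost is the
dominant driver of total-cost variability (largest |ρ|), consistent with
the clinical picture that inpatient care dominates the economic burden.
The absolute level depends on the placeholder unit-cost coefficients —
set them from local tariffs for a substantive analysis.

The same pipeline runs from the shell:

```bash
handcost all --source fixture --seed 1 -o run/
handcost compare --cohort run/cohort.csv --field outpatient_visits
```

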