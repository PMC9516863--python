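# multimort — multiverse analysis of excess mortality

Excess-death estimates are notoriously sensitive to two analytic choices:
which past years define the *reference baseline* (the mortality level a
country "should" have had) and how many years make up the *projected
window* whose excess is being assessed. Different reasonable choices
produce markedly different numbers for the same country and year, which is
a recurring source of controversy in pandemic mortality comparisons.

`multimort` removes the arbitrary choice by computing the estimate under
**every** admissible specification. For a baseline period of *n*
consecutive calendar years it enumerates all *n(n+1)/2* consecutive-year
reference windows (66 for an 11-year period such as 2009–2019), crosses
them with every projected window of width 1–4 years, and summarises the
resulting grid: per-country spread, cross-country rank stability, per-year
time patterns, and the attenuation of single-year mortality peaks under
wider projected windows.

## The statistic

For age bands *b* ∈ {0–14, 15–64, 65–74, 75–84, 85+}, a reference window
*R* and a projected window *P*:

- baseline band rates: m̂_b = mean over years *y* ∈ *R* of D_{b,y} / N_{b,y}
  (unweighted mean of annual band death rates),
- expected deaths: E = Σ_{y ∈ P} Σ_b m̂_b · N_{b,y}
  (baseline rates applied to each projected year's own band populations),
- observed deaths: D = Σ_{y ∈ P} Σ_b D_{b,y},
- relative excess: **p% = 100 · (D − E) / E**.

Multi-year windows pool D and E before taking the ratio, so the pooled p%
is the E-weighted mean of the single-year values. A mortality peak caused
by deaths of people with short remaining life expectancy shrinks rapidly
as the window widens; a peak among people with long life expectancy does
not — the attenuation table makes this diagnostic explicit.

## Who it is for

Epidemiologists and demographers comparing all-cause mortality across
countries from weekly STMF-dialect surveillance files or annual
1-year-age archive files (both dialects are read and merged, newer data
overwriting older), and anyone wanting a specification-curve view of an
excess-death claim instead of a single arbitrary baseline.

## Worked example

The package ships a synthetic five-country cohort (2009–2021, Poisson
death counts, mortality shocks of 0/5/10/15/20 % injected in 2020–2021,
declining secular trend):

```python
import multimort as mm

dataset, truth = mm.default_cohort(seed=1)
res = mm.ExcessMortalityMultiverse(dataset).fit()
print(res.summary())
```

```
Excess-death multiverse analysis
  countries: 5   baselines: 66 (2009-2019)   widths: (1, 2, 3, 4)
  projected window: 2020-2021

Relative excess deaths p% across baselines (percent):
country  average  sd  minimum  maximum  range
    SYA     -3.7 1.1     -6.3     -1.3    4.9
    SYB      2.2 1.2     -0.3      4.7    5.0
    SYC      6.3 1.3      3.7      8.9    5.2
    SYD     11.2 1.4      7.9     13.9    5.9
    SYE     15.9 1.3     13.2     18.6    5.4

Cross-country mean 6.36%  SD 7.64%
```

Each row is the spread of the 2020–2021 pooled p% across all 66 baselines.
The countries' injected shocks (0–20 %) are recovered in the correct
order; every estimate sits a few points below its injected shock because
the cohort's mortality declines ~0.5 %/year, so baselines that include
older, higher-mortality years inflate the expected deaths — exactly the
baseline sensitivity the multiverse is designed to expose. The spread
(range ≈ 5 points) quantifies it, and `res.rank_table()` shows the country
*ranking* is nevertheless identical under all 66 baselines.
`res.attenuation()` reports how each country's single-year peak shrinks
when pooled over 2–4-year windows, and `res.year_patterns(country)` gives
the per-year average and min–max envelope.

The same pipeline runs from the shell:

```bash
multimort simulate --seed 1 --out sim/
multimort report --data sim/dataset.csv --out tables/
```

writing `grid.csv`, `table1_summary.csv`, `table2_ranks.csv`,
`table3_attenuation.csv`, `fig1_patterns.csv`, `worst_periods.csv` and
`moments.csv`. Real data enter through `multimort ingest` (STMF weekly CSV
and/or annual archive CSVs).

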