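# Methods

## The model

`multimort` implements a descriptive, model-free estimator of excess
mortality. No time trend is prespecified and no stochastic mortality model
is fitted; instead the estimate is computed under every admissible
specification of the two free choices — reference baseline window and
projected window — and the variation across specifications is itself the
uncertainty statement.

For a country with annual deaths D_{b,y} and mid-year populations N_{b,y}
in the five age bands b (0–14, 15–64, 65–74, 75–84, 85+):

1. **Baseline rates.** For a reference window R of consecutive years, the
   baseline rate of band b is the *unweighted* arithmetic mean of the
   annual band rates over R, not pooled deaths over pooled person-time.
   The two coincide when populations are stable; the unweighted mean
   treats each calendar year as one draw of the mortality regime, which
   matches the window-enumeration logic (each year is one admissible
   baseline on its own).
2. **Expected deaths.** E for a target year multiplies each baseline band
   rate by that year's *own* band population and sums over bands. Using
   current populations (rather than baseline populations) separates
   demographic change from mortality change: a growing or aging
   population raises E, not p%.
3. **Pooling.** For a k-year projected window, D and E are summed over
   the years and the ratio is taken once. Algebraically the pooled p% is
   the E-weighted mean of the single-year p% values; pooling matches the
   additivity of death counts, whereas averaging yearly percentages would
   weight low-mortality years too heavily.
4. **The multiverse.** All consecutive-year sub-spans of the baseline
   period (n(n+1)/2 of them; 66 for 11 years) are crossed with all
   projected windows of widths 1–4 inside the study span. Reference and
   projected windows may overlap — the enumeration requires it, and the
   degenerate case (baseline {y} scoring year y) yields p% = 0 exactly,
   which the tests assert as an identity.

### Assumptions

- Age structure within the five bands is ignored; band rates are treated
  as homogeneous. Finer bands would add multiverse dimensions, not change
  the machinery.
- Annual resolution throughout. Weekly input data are summed to ISO
  years; no sub-annual excess estimation is attempted.
- Countries with any missing year in the configured study span are
  excluded, never imputed.

## Summary products

- **Spread table** (per country, fixed projected window): mean, sample
  (n−1) SD, min, max, range of p% across baselines. The extrema are
  attained by actual baselines, so argmin/argmax are recoverable.
- **Rank distribution**: for each baseline, countries are ranked by p%
  descending (rank 1 = highest excess, ties broken alphabetically by
  country code); counts of each rank are tallied per country. Each row
  and each column sums to the number of baselines.
- **Attenuation table**: for final year Y, the five windows {Y−1}, {Y},
  {Y−1,Y}, {Y−2..Y}, {Y−3..Y}; each entry is the baseline-averaged pooled
  p%, and drop_k = max(p_{Y−1}, p_Y) − p_{k-year}, computed on unrounded
  values. For a single noiseless shock of size s in year Y the pooled
  k-year value is s·E_Y/Σ_k E — monotone decreasing in k — which the
  tests verify in closed form.
- **Year patterns / worst periods**: per projected window of a fixed
  width, the baseline-averaged p% with its min–max envelope; windows
  ordered by average descending (ties to the earlier start year).
- **Cross-country moments and correlations**: mean and sample SD of the
  per-country averages; Pearson correlations of average with max, min, SD
  and range (NaN with a warning when a vector is degenerate).

## Data ingestion

The STMF weekly dialect carries band death counts and band death *rates*
per week. Band exposure is recovered as summed weekly person-time,
Σ_w d_w/r_w, equivalently annual deaths divided by the death-weighted
annual rate. This is exact when weekly rates are uniform (as in files
produced by the package's own annual→52-equal-weeks conversion) and
robust when they vary; weeks with zero deaths contribute no recoverable
person-time, and a band with no deaths all year is rejected rather than
guessed. Only "both sexes" rows are used. Annual archive files with
1-year ages are collapsed onto the five bands (85 and older into 85+);
the collapse conserves total deaths. When both sources are given, the
weekly-file data overwrite the archive wherever they overlap, and the
merged dataset is revalidated for gap-free country spans.

## Synthetic data generator

Each synthetic country has per-band initial rates and populations,
geometric rate trend and population growth, and a map of shock years to
multiplicative rate shocks; deaths are exact expectations (noiseless) or
seeded Poisson draws. The generator emulates the *data shapes* and the
arithmetic of age-standardised expectations: there is no migration, no
cohort aging between bands, no seasonality, and no week-level structure
beyond the 52-equal-weeks convention. Passing recovery tests therefore
demonstrates correctness of the estimator's arithmetic and its documented
baseline sensitivity, not robustness to real-world demographic artifacts
(census revision noise, band reclassification, late registration).

Defaults: five countries spanning 2009–2021 with band rates around
(0.0005, 0.002, 0.015, 0.045, 0.13) deaths/person-year and ~19M
population scaled per country — roughly 180k deaths/year, a realistic
national scale at which Poisson noise on p% is a few tenths of a point;
rate trend 0.995/year (mild secular decline), population growth
1.003/year, shocks of 0/5/10/15/20 % applied in 2020 and 2021, seed
20090923. Poisson was chosen as the minimal count-data noise model; it
gives the recovery tests a standard-error scale (mean over 200 replicates
within 3 SE of truth).

## Numerical choices

- All arithmetic in double precision; identities (self-reference zero,
  scale invariance, pooling, weekly round trip) are asserted at 1e-9
  absolute/relative tolerance, and the vectorised grid is checked against
  a plain-Python nested-loop reference at 1e-9.
- Reported tables round to 1 decimal (2 for correlations) only at the
  reporting layer; ranks, drops and comparisons use unrounded values.
- Rank ties break alphabetically by country code; worst-period ties break
  to the earlier start (stable sorts throughout, so equal averages keep
  enumeration order).
- The canonical CSV writes floats with 17 significant digits and reads
  them with round-trip parsing, so write→read is the identity.
- Expected deaths ≤ 0 (possible only with all-zero baseline rates) raise
  an error rather than returning an infinite percentage.

## Design choices where the design was open

- **Model/Results surface.** The analysis is exposed statsmodels-style:
  `ExcessMortalityMultiverse(dataset, …).fit()` returns a results object
  holding the grid and derived tables, with plain functions underneath
  for each operation. The grid is computed once and reused by every
  summary.
- **Attenuation entries** are means over all enumerated baselines (the
  same rule as the spread table) rather than any single preferred
  baseline; using one baseline would reintroduce the arbitrary choice the
  multiverse exists to remove.
- **Config** is a flat dataclass validated by an explicit function that
  collects *all* violations before failing; the surface is small enough
  that a schema library would add a dependency without adding safety.
- **Exposure recovery** from rate columns (above) is the one place the
  weekly dialect underdetermines the data; the person-time derivation was
  chosen for exactness under uniform weeks and is isolated in one
  function should a different convention be needed.

## Problem sizes

The packaged cohort is 5 countries × 13 years; its full grid is
5 × 66 × 46 = 15,180 estimates and fits in milliseconds, so the default
test and acceptance runs complete in seconds. The Poisson recovery study
uses 200 replicate countries. A full 33-country, 13-year analysis is the
same code path (33 × 66 × 46 ≈ 10^5 grid rows) and runs in seconds on one
CPU once data are local.

## Known limitations

- Five fixed age bands; no finer standardisation or life-expectancy
  weighting.
- No uncertainty beyond the multiverse spread — no Poisson intervals on
  individual estimates, no inference on summaries.
- Annual populations are taken as given; census interpolation error is
  not modelled.
- Weekly inputs are only a carrier format; week-53 deaths are kept in
  their labelled ISO year and the 52-equal-weeks conversion ignores
  leap-week calendars.
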