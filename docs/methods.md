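# Methods

## The model

`frontiergap` treats sex inequality in remaining life expectancy as a
benchmarking problem rather than a raw comparison. Let L_{f,a,i} and
L_{m,a,i} be female and male remaining life expectancy at exact age
a ∈ {0, 5, 15, 35, 50, 70} in location i for a given calendar year, taken
from period life tables (the package consumes the values as given; it does
not construct life tables).

1. **Raw ratio.** R_{a,i} = L_{f,a,i} / L_{m,a,i}.
2. **Frontier.** For each sex independently, the frontier value L*_{s,a} is
   the (1 − p) empirical quantile of the cross-location distribution of
   L_{s,a,i}, default p = 0.05. The frontier sex ratio is
   R*_a = L*_{f,a} / L*_{m,a}. Frontier *members* are all locations with
   L_{s,a,i} ≥ L*_{s,a}; the two sex-specific member sets need not
   coincide, and the membership count is derived, never fixed.
3. **Adjustment.** N_{a,i} = R_{a,i} / R*_a. The premise is that the sex gap
   observed at the frontier is, under current conditions, not attributable
   to avoidable inequality; dividing it out leaves the country-specific
   excess. N > 1 reads as male disadvantage, N < 1 as female disadvantage.
4. **Buffer.** An interval (L, U) around N = 1 inside which no disadvantage
   is declared, because small N-deviations can correspond to negligible
   absolute differences. The default construction perturbs the frontier by
   half a year: U = (L*_f + 0.5)/L*_f and L = L*_m/(L*_m + 0.5). Boundary
   values classify as *none* (closed buffer): boundary cases are maximally
   ambiguous and the buffer exists precisely to avoid over-interpretation.

Difference-space analogs are computed alongside: the adjusted difference
(L_f − L_m) − (L*_f − L*_m) in years, classified against a ±0.5-year buffer
(the natural analog of the half-year rule; the half-width is a parameter).
Ratio- and difference-space classifications need not agree for any given
country and are reported separately, never mixed.

### Assumptions

- Each sex's frontier is attainable by that sex everywhere; the frontier
  gap is treated as the currently-unavoidable component. It is an
  *empirical* benchmark, not a biological norm — frontier composition
  reflects whatever drives longevity in the best-performing locations.
- Cross-sections are independent: frontiers are estimated per (year, age)
  with no smoothing across years or ages.
- Observations are country-level point estimates without uncertainty
  intervals; no sampling error is modelled (the buffer is the only guard
  against over-reading small deviations).

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `percentile` | 0.05 | fraction | upper-tail size defining the frontier; sensitivity grid uses {0.01, 0.05, 0.10, 0.15} |
| `buffer_method` | `half_year_increase` | — | alternatives: `one_year_decrease` (U = L*_m/(L*_m−1), L = (L*_f−1)/L*_f), `fixed_0.99_1.01`, `central_30pct` |
| `min_population` | off | persons | when set (sensitivity value 5,000,000), locations below it are excluded from *setting* the frontier only; every location is still classified |
| `difference_halfwidth` | 0.5 | years | buffer half-width in difference space |

Numerical choices:

- **Quantile definition.** Linear interpolation between order statistics
  (numpy's default, the "type 7" convention). The tail fraction only reaches
  the data through this quantile, so the convention affects roughly the
  third decimal of R*; the sensitivity module exposes the percentile so the
  choice is auditable.
- **Half-year buffer direction.** The female-side increase sets the upper
  bound and the male-side increase the lower bound; this is the only
  assignment that yields L < 1 < U, and both bounds tend to 1 as frontier
  life expectancy grows. Because 0.5 years is a larger share of the shorter
  remaining life expectancies at older ages, this buffer widens with age;
  the fixed 0.99–1.01 buffer, by contrast, implies *more* confidence at
  older ages.
- **`central_30pct` construction.** Rank locations by |N − 1|, keep the
  smallest 30% (count rounded to nearest integer, minimum 1), set (L, U) to
  that subset's min/max adjusted ratio. "The central share of the data" is
  ambiguous between rank-symmetric and value-symmetric readings; the
  rank-symmetric one is used and isolated behind the method enum. On
  degenerate inputs where the central subset does not straddle 1 (e.g., a
  panel whose adjusted ratios are all identical), the buffer invariant
  L < 1 < U fails and a ValueError is raised rather than a silent fix-up.
- **Ties at the frontier.** Membership uses ≥, so ties are included; the
  member count is whatever the rule yields.
- **Population unknown.** Locations with no population value are excluded
  from population-filtered frontiers and population-weighted summaries,
  with a warning — never silently imputed.
- **Reporting precision.** Ratios print at 2 decimals, life expectancies at
  1, percentages as integers; classification always uses unrounded values,
  so printing cannot flip a label.

## Synthetic panel generator

`SyntheticConfig`/`generate` emulate the *structure* of a WPP-style abridged
panel so every operation is testable offline: ~200 locations; female life
expectancy at birth spread evenly over 55–87 years; remaining life
expectancy decaying with age by a fixed schedule (fractions 1.0, 0.946,
0.830, 0.599, 0.430, 0.220 of e0 — anchored to the observed 2019 frontier
schedule); a female−male gap of 4.3 years at birth scaled per age
(multipliers 1.0, 1.023, 1.023, 0.953, 0.930, 0.698) so the *relative* gap
widens with age and the frontier ratio lands near 1.05 at birth and 1.19 at
age 70, i.e., the same regime the method is designed for; one Gaussian
level shift per (location, sex) with SD 0.5 years applied at every age, so
age schedules stay perfectly correlated within a location; log-uniform
populations; and injectable per-location deficits subtracted from one sex's
life expectancy at all ages. Everything is driven by a single seed and
panels are bit-identical per seed.

Two gap regimes are provided. `gap_mode="absolute"` (default) gives every
location the same gap in years — realistic, and it reproduces the
mechanical fact that lower-longevity countries carry higher raw ratios.
`gap_mode="proportional"` scales the gap with each location's life
expectancy so that *every* location shares the frontier ratio exactly: a
panel with no avoidable inequality by construction, used to verify that the
pipeline classifies no-disadvantage everywhere in the absence of noise and
injected effects.

What the generator does **not** emulate: real-world correlation between
longevity level and gap size (Eastern-European-style male excess mortality
arises only by injection), time trends (years are independent draws),
heaped or missing data, and any within-country heterogeneity. Passing tests
on synthetic panels therefore demonstrate the estimator's correctness and
the classifier's ability to recover known injected disadvantage — not that
real-world classifications are substantively right, which depends on the
quality of the input life tables.

## Problem sizes in the test and acceptance runs

Unit and property tests run on panels of 2–60 locations; recovery and
invariance checks use the default 200-location single-year panel; the
quantile oracle check uses 100 random panels of ≤ 30 locations. These sizes
make every distributional claim exact or tightly bounded while keeping the
full suite in seconds. The acceptance script's benchmark quantities are
deterministic arithmetic on published inputs and are independent of seed.

## Integration with real data

The published 237-country results (per-age classification counts,
individual country ratios, 2000-vs-2019 comparisons) require the WPP2024
extract, which is not bundled. Reshape it to the long CSV layout
(`location, iso_code, year, sex, age, ex, population`) and run:

```bash
frontiergap adjust --panel wpp.csv --year 2019 --buffer half_year --out results.csv
frontiergap report --results results.csv --regions cih_regions.yaml --out-dir reports/
```

`reports/summary.csv` then holds the raw and adjusted classification counts
per age, and `results.csv` the per-country adjusted ratios. Which WPP
variant (medium estimates assumed) and the authors' exact quantile/rounding
pipeline are not published, so third-decimal differences in R* are
expected.

## Known limitations

- The frontier percentile and buffer are empirical conventions; the
  sensitivity grid quantifies, but cannot remove, their influence — at older
  ages classification is genuinely buffer-dependent.
- Quantiles on ~237 observations are noisy at the 1% tail; the percentile
  curve exposes this rather than correcting it.
- Binary sex only, country-level only, life expectancy only; no causal
  attribution of the classified disadvantage.
- Ratio- and difference-space conclusions can disagree; neither is
  privileged by the package.
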