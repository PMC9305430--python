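# Methods

This note documents the models, defaults and numerical conventions behind
nutribasket, and what its synthetic data do and do not establish.

## Product scoring (FSA-NPS)

Scoring follows the 2005 UK FSA nutrient-profiling point system per 100 g:
four negative components (energy kJ, sugars g, saturated fat g, sodium mg)
at 0–10 points and three positive components (fruit/vegetable/legume/nut %,
fiber g, protein g) at 0–5 points. The band table ships as
`data/fsa_bands_2005.yaml`; alternative tables (e.g. beverage-specific
bands, or the NSP fiber variant 0.7/1.4/2.1/2.8/3.5 g instead of the AOAC
0.9/1.9/2.8/3.7/4.7 g shipped) can be loaded at run time. Band membership
is lower-exclusive / upper-inclusive: a value exactly on a boundary stays in
the lower band. Points are integers; inputs are real-valued and validated
(non-negative, finite, fvln in [0, 100]).

The protein cap — protein points are not counted when negative points ≥ 11
unless fvln points = 5 — is on by default and switchable, since component
points are also reported separately as outcomes. Sodium is taken in mg; a
salt-to-sodium helper (×393.4 mg/g) converts label values declared as salt.
Letter grades (A–E) and per-portion scoring are out of scope.

## Basket dietary index

The DI of a set of purchased items is the weighted mean of per-product
scores over solid foods. The weighting mode is configurable:
**energy** (purchased kJ, the default, matching the energy-intake-weighted
DI construction) or **mass** (purchased grams). Sources describing
receipt-based DIs rarely state the weight exactly; both modes are provided
and neither is claimed to match any specific deployment. With uniform
energy density the two modes coincide (tested). A selection with zero total
energy (e.g. water only) falls back to mass weights rather than dividing by
zero.

Beverages are scored into a separate `beverage_di` and excluded from all
headline solid-food outputs. Items without resolvable products raise a
listing error; items with zero mass are skipped and counted.

Two aggregation granularities exist deliberately:

* **rolling_component_means** — equal-weight mean of per-basket component
  means over the last *n* baskets (windows are counted in baskets, not
  days); feeds the avatar (n = 12).
* **period_di** — item-level pooled weighted mean over a half-open date
  window `[start, end)`; feeds trial periods (4-week windows) and differs
  from a mean of basket DIs whenever baskets are unequal (tested).

## Avatar engine

Drivers follow the intervention's system rules: fitness = mean steps/day of
the 7 calendar days ending at the evaluation date (inclusive); heart health
= ½ sodium + ½ saturated-fat points; mental well-being = ½ fvln + ½ fiber
points; bone health = protein points; blood sugar = sugar points — all from
the 12-basket rolling component means, in points (not raw nutrient
amounts), per the rule table's units.

The five-state cut-offs of the deployed app are not public, so defaults are
declared here, not inferred: steps `<2500/<5000/<7500/<10000/≥10000` →
states 1–5 (anchored on the ≥7500 steps/day activity target); negative
point drivers `≥8/≥6/≥4/≥2/<2` → 1–5; positive point drivers
`<1/<2/<3/<4/≥4` → 1–5. Boundaries are lower-inclusive; all tables are
overridable via `StateThresholds`. A feature without data in its window is
an explicit "no data" condition (state `None`) and never collapses to
state 1. Feedback messages are templated per (feature, state), interpolate
the driver value, and stay encouraging at every state; rendering (facial
expressions, aging imagery) is out of scope.

## Recommender

Contributions pool items across the last 7 baskets (rather than averaging
within-basket shares — the pooled reading of "weight-averaged"), weight by
purchased mass within each of the four negative dimensions (sugar, sodium,
saturated fat, energy density) and average the four dimensions equally.
This makes per-dimension contributions sum exactly (1e−9 in tests) to the
pooled mass-weighted mean points. Ranking is by combined contribution,
ties broken by larger mass share then smaller category id; zero-contribution
categories never rank, and at most 4 categories are returned without
padding.

Substitutes are same-category products with a score strictly below the
mass-weighted mean score of the user's purchases in that category,
ascending by score. Because the benchmark is the purchase *mean*, a swap is
guaranteed to improve the basket only when it replaces an item at or above
that mean; the improvement property is therefore stated (and tested) for
replacing the worst purchased item. Tips rotate per category across calls
so repeat weekly visits cycle through all mapped tips before repeating.
Allergy or price awareness is out of scope.

## Synthetic cohorts

The generator emulates the study conditions of a 12-week two-arm
receipt-tracking trial: 95 participants allocated 42/53, 6 baseline step
days, 4 baseline food weeks, an attrition funnel of 78/42/30 participants
with data in T1/T2/T3, and 28 participants whose loyalty card never
connects (no food data at all). Dropout is missing-completely-at-random by
default, matching the trial's own sensitivity conclusion; an optional
`age_dropout_beta` links dropout to older age (the one demographic
difference that trial reported).

**Steps** are lognormal: participant effect σ = 0.6 on the log scale,
weekly AR(1) level (σ = 0.25, ρ = 0.5), daily noise σ = 0.35, anchored so
the median of participant mean steps/day is 4624 (the log-median is shifted
by −σ_day²/2 because a mean of lognormal days exceeds its median). These
dispersions produce participant-level IQRs of the same order as the
baseline median, as published summaries show; they are calibration
defaults, not fitted values.

**Baskets** arrive weekly on a random weekday (~15 items plus an optional
beverage). Item choice combines participant category preferences
(Dirichlet, concentration 0.3 over 125 categories) with an exponential
tilt `exp(−λ·score)` on product scores; λ is solved by bisection so the
energy-weighted expected DI equals the participant's target (baseline
target ~N(6.13, 2.5²), clipped to the catalog-attainable range). Because
the tilt is solved against the same energy weighting the scorer uses,
injected DI drifts are recovered without bias (tested: −0.5/period
recovered to ±0.03 over 500 replicates).

**Group effects** are additive per-period drifts (period = ⌈week/4⌉)
applied to the intervention arm only, in steps/day or DI points; zero
effects give a null cohort with no systematic T0→T3 slope (tested).
Logins are Poisson with period rates 4.5/1.5/1.5 × a lognormal person
effect, reproducing the early-engagement-then-decay pattern; surveys are
means of discretized Likert items per construct at T0 and (completers
only) T3.

What the generator does **not** model: seasonality and pandemic-period
shocks, shopping at non-participating retailers, household sharing and
food waste, product prices and names, and any dependence of dropout on
outcomes. Passing recovery tests therefore show the pipeline is unbiased
under its own assumptions, not that real receipt data meet them.

## Statistics

* **Wilcoxon signed-rank**: complete-case pairs; zero differences use the
  Pratt method by default (zeros keep their ranks in the |d| ranking, then
  leave the statistic; "wilcox" dropping is available). Exact two-sided
  p-values — conditional on the observed tie/zero pattern — come from a
  generating-function convolution over sign flips of the (doubled,
  midrank-tied) ranks for up to 25 nonzero differences; larger samples use
  the normal approximation with zero and tie variance corrections, no
  continuity correction. All-zero data return p = 1.
* **Mann-Whitney U**: U counts pairs where the first group exceeds the
  second (ties ½). Exact p by enumerating all C(n+m, n) label assignments
  when that count is ≤ 20,000 (exact under ties); otherwise tie-corrected
  normal approximation with continuity correction.
* **Chi-square**: Pearson statistic without Yates correction
  (scipy.stats.chi2_contingency); expected counts < 5 raise a flag, zero
  marginals an error.
* **Median/IQR**: type-7 (linear-interpolation) quantiles, pinned and
  documented rather than claimed to match any particular statistics
  package's default.
* **Sample size**: per-group `⌈2·sd²·(z_{1−α/2}+z_{power})²/δ²⌉`, doubled,
  then inflated by 1/(1−dropout). At δ = 1566, sd = 2620 this gives
  44/group → 88 total → 110 after 20% dropout inflation (by this formula;
  other published roundings of the same inputs exist). Simulation at that
  design point under the generator's lognormal step model yields
  Mann-Whitney power ≈ 0.9 — above the nominal 0.80 because the rank test
  outperforms the normal-theory calculation on right-skewed data.
* **Multiple testing**: none, matching a fixed α = .05 analysis plan.
  Missing data are never imputed; every test result carries the
  complete-case n it used.

## Problem sizes

Statistical test fixtures use n ≤ 10 where enumeration is the oracle.
Monte-Carlo checks run 500 replicate participants for drift recovery,
1000 replicates for null rejection rates and power closure, against a
desk-scale catalog of 625 products across the full 125 categories (the
default catalog is 2000 products, emulating a 55,000-product retail
database at workstation scale). These sizes keep every simulated check at
seconds while leaving Monte-Carlo standard errors well inside the asserted
tolerances (±3.5 SE bands).

## Known limitations

* Band thresholds and avatar cut-offs are package defaults; deployments
  with different tables must supply their own configs.
* The sugars band scores whatever sugars value the catalog provides; no
  fructose/lactose adjustment is attempted.
* `solid_di` weighting ("energy" vs "mass") changes numeric results;
  cross-study comparisons must pin the mode.
* The exact Wilcoxon p-value conditions on the zero pattern (standard for
  Pratt); p-values for heavily zero-inflated data are approximate in the
  unconditional sense.
* The trial report reproduces table *shapes* and test machinery; real
  participant-level data from any specific deployment are not included.
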