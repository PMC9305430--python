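# nutribasket

Computational engine for digital-receipt diet interventions: score grocery
products and shopping baskets under the British Food Standards Agency
Nutrient Profiling System (FSA-NPS, the basis of Nutri-Score), drive a
future-self avatar's five health-feature states from step counts and basket
history, rank the food categories that hurt a user's basket quality most and
propose healthier in-category substitutes, simulate two-arm trial cohorts
with realistic attrition, and run the nonparametric statistics such trials
report.

It is written for researchers building or evaluating mHealth nutrition
interventions that track food purchases through loyalty-card receipts
instead of manual food diaries.

## The model

**Product score.** Per 100 g, a product earns 0–10 "negative" points each
for energy density, sugars, saturated fat and sodium, and 0–5 "positive"
points each for the fruit/vegetable/legume/nut fraction, fiber and protein,
via the 2005 UK FSA band table (shipped as package data). The total is

```
score = (energy + sugar + satfat + sodium points)
        − (fvln + fiber [+ protein]) ∈ [−15, +40]
```

with protein counted only when negative points < 11 or fvln points = 5
(the protein cap). −15 is healthiest, +40 least healthy.

**Basket dietary index (DI).** The DI of a receipt (or any pooled set of
items) is the intake-weighted mean of per-product scores over solid foods,
energy-weighted by default (purchased mass optional); beverages are scored
separately and kept out of headline numbers.

**Avatar.** Five features with five states each: fitness follows the 7-day
mean of steps/day; heart health = ½ sodium + ½ saturated-fat points, mental
well-being = ½ fruit/vegetable + ½ fiber points, bone health = protein
points, blood sugar = sugar points, all as 12-basket rolling component-point
means. Missing data is an explicit sixth condition, never the worst state.

**Recommender.** Over the last 7 baskets, category `c`'s contribution to
negative dimension `d` is `Σ_{items∈c} mass·points_d / Σ mass`, so
contributions sum exactly to the pooled mean points (conservation). Up to 4
top categories are flagged; substitutes are same-category products scoring
strictly below the user's purchases.

**Trial statistics.** 4-week period aggregation (T1–T3 plus
outcome-specific baselines), Wilcoxon signed-rank (exact null distribution
up to n = 25, Pratt zero handling), Mann-Whitney U (exact by enumeration
for small samples, valid under ties), Pearson chi-square, median/IQR
summaries, a dropouts-vs-completers sensitivity analysis, and the
two-sample sample-size formula
`n/group = ⌈2·sd²·(z_{1−α/2}+z_{power})²/δ²⌉`.

## Worked example

```python
from nutribasket import NutrientProfile, score_profile, total_fsa_score

yogurt = NutrientProfile(energy_kj=450, sugars_g=12.0, satfat_g=2.1,
                         sodium_mg=60, fvln_pct=10.0, fiber_g=0.2, protein_g=4.1)
pts = score_profile(yogurt)
print(pts.as_dict(), total_fsa_score(pts))
```

prints

```
{'energy_pts': 1, 'sugar_pts': 2, 'satfat_pts': 2, 'sodium_pts': 0,
 'fvln_pts': 0, 'fiber_pts': 0, 'protein_pts': 2} 3
```

5 negative points (energy band 1, sugar band 2, saturated-fat band 2),
2 positive protein points, total score +3 — a mildly unhealthy product on
the −15..+40 scale. The `examples/` directory has one short script per
capability (product scoring, receipt scoring, avatar states, substitution
recommendations, cohort simulation + analysis, power calculation); e.g.
`python examples/power_calculation.py` prints

```
per-group n: 44 | total: 88 | inflated for 20% dropout: 110
empirical Mann-Whitney power at n=88: 0.92
```

## Command line

A thin CLI wraps the library:

```bash
nutribasket score-product --energy-kj 4000 --sugars-g 60 --satfat-g 20 --sodium-mg 1500
nutribasket simulate-cohort --seed 2 --out sim/ --n-total 95
nutribasket analyze-trial --data sim/ --out report.json
nutribasket power --delta 1566 --sd 2620 --dropout 0.2
nutribasket validate --catalog products.csv --receipts receipts.jsonl
```

See `nutribasket --help` for the full list (score-basket, avatar-state,
recommend, …).

## Layout

```
src/nutribasket/
  nutrient_profiling.py   FSA-NPS product scoring + band table
  basket_scoring.py       receipts, catalogs, DI, rolling windows
  avatar_engine.py        feature drivers, states, feedback messages
  recommender.py          category contributions, substitutes, tips
  synthetic_data.py       catalogs, participants, cohorts (seeded)
  trial_analysis.py       periods, tests, sensitivity, sample size
  cli_io.py               file formats, validation, batch pipeline
  cli.py                  click commands
docs/methods.md           model assumptions, defaults, limitations
```
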