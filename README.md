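# smhat — School Menu Healthiness Assessment Tool

`smhat` is a configurable auditing engine for school food and drink
provision. It scores primary and secondary school menu cycles against
food-based healthiness criteria, checks the reproducibility of the coding
with intercoder-reliability statistics, and analyses whether free-school-meal
(FSM) allowances actually cover the priced offering in the canteen. It is
aimed at public-health nutritionists, dietitians and researchers who audit
school food against national standards and current dietary guidance without
nutrient-level analysis software.

## The instrument

The instrument is a **codebook**: an ordered list of items grouped into
categories (breakfast; break time; fruit and vegetables; meat, fish and
alternatives; starchy carbohydrates; dairy and alternatives; oils and
spreads; HFSS foods; prices; general observations). Each item carries a
scoring rule over a controlled food-tag vocabulary:

* **`A`** — the item is absent from the menu (not mentioned). This is
  distinct from a failed criterion and contributes 0 points.
* **binary** — 1 if the criterion is met in the week, 0 if the relevant
  foods appear but the criterion is not met.
* **per-day** — incremental credit for "at least one portion per day"
  criteria: *(days met)*/5 ∈ {0, 0.2, 0.4, 0.6, 0.8, 1.0} over the 5-day
  school week.
* **frequency-per-period** — cycle-scoped rules such as oily fish at least
  twice over a four-week period, pro-rated as ⌈threshold ×
  weeks/period⌉ for shorter cycles.
* **limit** — 1 when a food (red meat, processed meat, confectionery, free
  salt) stays within its weekly limit, 0 when it exceeds it.

Each week *w* of a rotational cycle is coded separately; the healthiness
score of a provision with *W* weeks is

```
S = (1/W) · Σ_w Σ_items rating(item, w)
```

rounded half-up to one decimal place only at the end. The shipped
instruments have fixed maxima of **22 points (primary)** and **28 points
(secondary)**; higher scores sit closer to the ideal healthiness standard.
Provisions for which only a price list exists are scored from the price list
alone, flagged as **anomalies**, and excluded from subgroup averages.

Coding reproducibility is quantified on binary-recoded ratings: per-item
sample SD across coders, mean pairwise agreement, and Cohen's
κ = (p_o − p_e)/(1 − p_e) for two coders, interpreted with McHugh's bands
for health research (0.60–0.79 moderate, 0.80–0.90 strong, >0.90 almost
perfect).

Affordability is integer-pence arithmetic: the disparity between the
cheapest bundled main-meal-and-drink ("meal deal") price and the FSM
allowance, the residual allowance when affordable, the items outpriced
entirely, and per-category price summaries (n, mean, sample SD, mode).

No real menu corpus is distributed, so the package includes a
truth-planting synthetic generator: it draws a target rating for every
codebook item and constructs offerings whose true rating equals that
target, which makes exact end-to-end recovery testable.

## Worked example

```bash
$ smhat synth menu --phase secondary --weeks 3 --seed 7 --out menu7.yaml
wrote 3-week secondary cycle to menu7.yaml

$ smhat score --menu menu7.yaml
week 1: 17.4
week 2: 19.0
week 3: 19.8
synthetic_7: healthiness score 18.7 / 28
```

Each week is coded separately (17.4, 19.0, 19.8 points of the 28-point
secondary maximum); their unrounded mean, 18.7, is the provision's
healthiness score — a fairly healthy offering that still loses points on
items such as wholegrain or oily-fish provision in individual weeks.

```bash
$ smhat afford --pricelist prices7.csv --allowance 252
allowance: £2.52
meal deal £2.70 NOT affordable; shortfall £0.18
outpriced items: meal deal (£2.70)

price summary per category (pence):
                  n  mean    sd  mode
category_tag
bread             3    42     6    36
condiment         3    12     4    10
...
```

Against a £2.52 allowance this canteen's £2.70 meal deal leaves an 18p
shortfall: an FSM-eligible pupil cannot buy the bundled main meal and drink
at all, and must assemble a cheaper lunch from individual items.

From Python, the same machinery is importable directly:

```python
from smhat import default_codebook, score_menu, cohens_kappa, mchugh_band

result = cohens_kappa([1, 1, 1, 1, 0, 0, 1, 0, 1, 1],
                      [1, 1, 0, 1, 0, 1, 1, 0, 1, 1])
print(result.kappa, result.band)   # 0.5238..., below_moderate
print(mchugh_band(0.85))           # strong
```

## Layout

- `src/smhat/codebook.py` — the instrument as data; shipped YAML codebooks
  in `src/smhat/data/`
- `src/smhat/menu_model.py` — menu/price-list schema, YAML/CSV I/O, the
  keyword→tag auto-tagger
- `src/smhat/scoring_engine.py` — rule semantics, week sheets, cycle
  scores, subgroup aggregation
- `src/smhat/reliability.py` — binary recoding, dispersion, agreement,
  Cohen's κ, McHugh bands
- `src/smhat/affordability.py` — FSM allowance checks and price summaries
- `src/smhat/synthetic_data.py` — truth-planting menu generator and coder
  noise model
- `docs/methods.md` — the model, parameter choices and known limitations
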