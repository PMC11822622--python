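# Methods

This note records how the auditing engine works, the choices made where the
instrument's published description leaves the design open, and what the
synthetic-data tests do and do not demonstrate about real menus.

## The instrument as data

The codebook is configuration, not code: a YAML file listing items, each
with a category, a scoring rule, the food tags the rule inspects, and a
maximum score. Two instruments ship with the package, a 22-point primary
and a 28-point secondary version; the secondary instrument embeds all
twenty-two primary points and adds six (break-time provision, drinks,
vegan alternatives).

The exact item-by-item composition of the original instrument is not
published in full. The shipped itemisation is therefore a **declared
reconstruction**, constrained to (a) sum exactly to the published 22/28
maxima, (b) contain every criterion the instrument is documented to
contain — daily fruit and vegetables, fruit variety, weekly fish, oily fish
twice per four weeks, red-meat and processed-meat limits, meat-cut variety,
non-meat proteins, daily non-potato starch, bread, weekly wholegrain, daily
milk with lower-fat specification, low-sugar yogurt, the HFSS prohibitions
(confectionery/crisps, sweet snacks, free salt), breakfast and break-time
items, drink sugar information, vegan alternatives — and (c) use one point
per item. Because the codebook is data, a corrected itemisation replaces
the YAML file without code changes.

One vocabulary compromise: the controlled tag set has no oils/spreads tag,
so the single oils-and-spreads point inspects the `condiment` tag (the
closest class); it rates 1 when spread/condiment provision is stated and
'A' otherwise.

## Rule semantics

Ratings are three-valued: `'A'` (absent/not mentioned), or points. The
operative distinction is **relevance**: every item has a relevance tag set
(defaulting to its required tags) that decides between 'A' (nothing relevant
mentioned) and 0 (relevant foods mentioned, criterion unmet). For example,
weekly wholegrain rates 0 when starches appear but none is wholegrain, and
'A' when the menu mentions no starch at all.

* **binary** — 1 when at least `min_distinct` distinct offering names carry
  a required tag in the week (fruit variety uses `min_distinct: 3`).
* **per_day** — (days met)/5; the school week is fixed at five days and
  menus listing fewer days are invalid input rather than silently padded.
* **frequency_per_period** — evidence is pooled over the whole cycle and a
  single rating is written into every week sheet, so week totals remain
  comparable. For a cycle of *W* weeks the required count is
  ⌈threshold × W / period⌉ (rotations are typically 3 weeks while the
  oily-fish rule is stated per 4 weeks). Occurrences are counted as
  distinct (week, day) serving occasions.
* **limit** — counts the days per week on which the tag appears; within
  the limit scores 1, above it 0. Two absence behaviours exist and are set
  per item: red-meat and processed-meat limits rate **'A'** when the meat is
  never mentioned (absence is uninformative, not a virtue of the menu text),
  whereas prohibitions (confectionery/crisps, non-compliant sweet snacks,
  free salt) carry `absence_credit` and rate **1** when the food never
  appears — a menu that sells no confectionery complies. A consequence
  worth knowing: an entirely empty week is not all-'A' under the default
  instruments; it scores exactly the three prohibition points.

Items scoped to the breakfast or break slot treat "mentioned" as *the slot
carries any offering at all*: a provision that publishes no breakfast
information rates 'A' on every breakfast item, while a breakfast of only
fried food rates 0 on the healthy-breakfast item.

## Score arithmetic

'A' contributes 0 to week totals, keeping the 22/28 maxima fixed
denominators so scores are comparable across provisions; completeness is
reported separately so 'A'-heavy provisions remain interpretable. Week
totals are exact rationals internally (per-day ratings are fifths);
the healthiness score is the unrounded mean of week totals, rounded once at
the end, half-up, to one decimal place. Money is integer pence throughout,
formatted only for display.

Price-list-only provisions are scored from a pseudo-week in which each
price-list entry appears once on a single day: availability-type binary
items can still earn credit, per-day items earn at most 0.2, and slot-scoped
items rate 'A'. Such scores are flagged anomalies and excluded from
subgroup means/SDs (they are counted and listed instead), since they measure
document completeness more than provision healthiness.

## Reliability statistics

Because 'A' is non-numerical, all agreement statistics operate on
binary-recoded ratings: 1 when a numeric rating reaches `cutpoint ×
item_max`, else 0, with 'A' → 0. The default cutpoint is full marks; it is
a parameter because any recode rule is a convention. Multi-coder agreement
is the mean over coder pairs of the match indicator; per-item dispersion is
the sample SD (n−1) of the recoded ratings across coders, averaged over
menus as a separate reduction, which ranks the items coders interpret
differently.

Cohen's κ is computed per menu over the pooled item × week units of two
coders' sheets (per-item κ is available by filtering the sheet). The
McHugh bands are printed at two-decimal precision, which leaves
0.79 < κ < 0.80 undefined; values in that gap are assigned by rounding κ
half-up to two decimals first. The band edges themselves are exact — in
particular κ = 0.901 is "almost perfect" (strictly above 0.90), not rounded
down to "strong". For binary data the degenerate case p_e = 1 with
p_o < 1 cannot arise (p_e = 1 forces both coders constant on the same
class); the error branch is defensive only, and identical constant coders
are defined as κ = 1.

## Affordability

The meal-deal check uses the *cheapest* entry tagged `meal_deal`;
disparity = price − allowance (positive = shortfall), and when affordable
the residual bounds the extras a pupil can add (often only condiment
money). Price summaries report mean to the penny (half-up), sample SD and
the mode, with ties broken toward the lower price — conservative for
affordability claims. Exact unrounded means are kept alongside so that
mean × n conserves the total.

## The synthetic generator

The generator defines the study conditions under which the engine is
tested. Defaults: 3-week cycles (the typical rotation), a per-item pass
probability of 0.7 (a generally compliant but imperfect provision), an
absence probability of 0.2 per food class (menus routinely omit whole
classes — breakfast information most of all), and price models centred on
plausible canteen magnitudes (toast ≈ 38p, whole fruit ≈ 49p, vegetables ≈
54p, HFSS sweet snack ≈ 92p, condiment ≈ 11p, meal deal ≈ £2.50). These
are plausibility defaults, not estimates of any real distribution.

The generator is truth-planting. For each food class it first draws the
target state, then constructs offerings from a small name bank wired to the
shipped lexicon so that the true rating equals the target; the planted
truth is returned for testing. Per-day targets are Binomial(5, p) — the
pass probability acts per day — which pins both endpoints: p = 1 plants the
criterion daily (a cycle scoring exactly the maximum) and p = 0 plants
nothing (ratings 'A' or 0 throughout, a zero score). Classes whose tags
interact are planted jointly and the recorded truth is the *implied* rating
derived from the planting logic, never from the scoring engine: a vegan
dish also satisfies the non-meat-protein item; fruit at break is itself a
non-HFSS break option; a week with no fruit forces both daily-fruit and
fruit-variety to 'A'; oily fish can only be rated 0 when white fish keeps
the class mentioned.

Coder simulation is a symmetric noise model: each coder independently flips
each true binary rating with probability ε ∈ [0, 0.5]. κ is 1 at ε = 0 and
decreases to chance level at ε = 0.5; the suite checks this monotonicity by
Monte-Carlo over seeds.

**What passing tests show — and don't.** Exact planted-rating recovery
shows the generator and engine agree on rule semantics, and boundedness/
monotonicity hold over the generated distribution. Synthetic menus are
tag-clean by construction: real menus have ambiguous free text ("Buddha
bowl"), inconsistent naming, and coder judgement calls — exactly the
discrepancies intercoder reliability testing exists to measure. The
auto-tagger is assistive, never authoritative: unmatched names yield an
empty tag set and a logged warning, and manual tags in the menu file
override nothing (they *are* the record).

## Numerical and interface choices

* Round-half-up everywhere a figure is reported (scores to 0.1, money to
  the penny); never banker's rounding.
* Week totals are averaged unrounded; rounding happens once per provision.
* Menu cycles are YAML; price lists, lexica and coder sheets are CSV; all
  I/O validates against the controlled vocabulary and names the offending
  field.
* Problem sizes in the test suite and acceptance script (hundreds to a
  thousand synthetic provisions, 1000-unit coder sheets) were chosen as the
  smallest sizes at which the Monte-Carlo checks are stable.

## Known limitations

* The itemisation is a reconstruction: per-item results are faithful to the
  documented criteria but not guaranteed to match the original instrument
  item-for-item; only the category structure, rule forms and maxima are
  pinned.
* The limit thresholds (red meat ≤ 2 days/week, processed meat ≤ 1
  day/week) are this package's defaults where the published text states no
  number; both are configuration.
* Whether credit should be given for a limit item when the food is wholly
  absent is genuinely open; the default ('A' for meat limits, credit for
  prohibitions) is documented above and configurable per item.
* Drink criteria are information-limited: without stated sugar/brand
  information a drink is unrateable ('A'), mirroring how sparse real drink
  menus are.
* No modelling of pupil purchasing behaviour, demand elasticity, or
  meal-deal composition rules; affordability is pure price arithmetic.
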