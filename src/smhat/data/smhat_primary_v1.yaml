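# Primary-phase school menu healthiness instrument, 22 points.
# This itemisation is a declared reconstruction: it houses every criterion the
# instrument is documented to contain and sums to the published 22-point
# maximum; replace this file to audit against a revised instrument.
phase: primary
version: smhat_primary_v1
declared_max: 22.0
items:
  # --- breakfast (2) -------------------------------------------------------
  - item_id: breakfast_healthy_daily
    category: breakfast
    slot: breakfast
    rule: {kind: per_day}
    max_score: 1.0
    required_tags: [fruit, wholegrain, bread, milk, lower_fat_milk, yogurt, low_sugar_yogurt, compliant_snack]
    description: >
      A healthy breakfast option (fruit, wholegrain cereal, bread, milk,
      yogurt or a compliant snack) is available each school day.
  - item_id: breakfast_no_hfss
    category: breakfast
    slot: breakfast
    rule: {kind: limit, limit_max: 0}
    max_score: 1.0
    required_tags: [hfss_confectionery, hfss_savoury, hfss_sweet_snack]
    description: No food high in fat, salt and sugar is offered at breakfast.
  # --- fruit and vegetables (4) -------------------------------------------
  - item_id: fruit_daily
    category: fruit_and_vegetables
    slot: lunch
    rule: {kind: per_day}
    max_score: 1.0
    required_tags: [fruit]
    description: At least one portion of fruit is available every day.
  - item_id: vegetable_daily
    category: fruit_and_vegetables
    slot: lunch
    rule: {kind: per_day}
    max_score: 1.0
    required_tags: [vegetable, salad]
    description: At least one portion of vegetables or salad is available every day.
  - item_id: fruit_variety_weekly
    category: fruit_and_vegetables
    slot: lunch
    rule: {kind: binary, min_distinct: 3}
    max_score: 1.0
    required_tags: [fruit]
    description: At least three distinct fruits are offered over the week.
  - item_id: salad_available
    category: fruit_and_vegetables
    slot: lunch
    rule: {kind: binary}
    max_score: 1.0
    required_tags: [salad]
    relevance_tags: [vegetable, salad]
    description: Salad is available during the week.
  # --- meat, fish and alternatives (6) ------------------------------------
  - item_id: fish_weekly
    category: meat_fish_alternatives
    slot: lunch
    rule: {kind: binary}
    max_score: 1.0
    required_tags: [fish, oily_fish]
    description: Fish is served at least once in the week.
  - item_id: oily_fish_frequency
    category: meat_fish_alternatives
    slot: lunch
    rule: {kind: frequency_per_period, threshold: 2, period_weeks: 4}
    max_score: 1.0
    required_tags: [oily_fish]
    relevance_tags: [fish, oily_fish]
    description: Oily fish is served at least twice over a four-week period.
  - item_id: red_meat_limit
    category: meat_fish_alternatives
    slot: lunch
    rule: {kind: limit, limit_max: 2}
    max_score: 1.0
    required_tags: [red_meat]
    description: >
      Red meat appears on no more than two days per week.  A menu that never
      mentions red meat rates 'A' (absence is uninformative, not credit).
  - item_id: processed_meat_limit
    category: meat_fish_alternatives
    slot: lunch
    rule: {kind: limit, limit_max: 1}
    max_score: 1.0
    required_tags: [processed_meat]
    description: >
      Processed meat (bacon, sausages, popcorn chicken, etc.) appears on at
      most one day per week; daily provision scores 0.
  - item_id: meat_cut_variety
    category: meat_fish_alternatives
    slot: lunch
    rule: {kind: binary}
    max_score: 1.0
    required_tags: [meat_cut]
    relevance_tags: [meat_cut, red_meat, poultry, processed_meat]
    description: Whole cuts of meat (e.g. roasts) feature among the meat dishes.
  - item_id: non_meat_protein_weekly
    category: meat_fish_alternatives
    slot: lunch
    rule: {kind: binary}
    max_score: 1.0
    required_tags: [non_meat_protein, vegan_alternative]
    description: A non-meat protein dish (beans, pulses, vegetarian or vegan) is offered weekly.
  # --- starchy carbohydrates (3) ------------------------------------------
  - item_id: non_potato_starch_daily
    category: starchy_carbohydrates
    slot: lunch
    rule: {kind: per_day}
    max_score: 1.0
    required_tags: [non_potato_starch, bread, wholegrain]
    relevance_tags: [non_potato_starch, bread, wholegrain, potato]
    description: A starchy carbohydrate other than potato is available every day.
  - item_id: bread_available
    category: starchy_carbohydrates
    slot: lunch
    rule: {kind: binary}
    max_score: 1.0
    required_tags: [bread]
    relevance_tags: [bread, non_potato_starch, wholegrain, potato]
    description: Bread is available during the week.
  - item_id: wholegrain_weekly
    category: starchy_carbohydrates
    slot: lunch
    rule: {kind: binary}
    max_score: 1.0
    required_tags: [wholegrain]
    relevance_tags: [wholegrain, bread, non_potato_starch, potato]
    description: At least one wholegrain carbohydrate is identified in the week.
  # --- dairy and alternatives (3) -----------------------------------------
  - item_id: milk_daily
    category: dairy_and_alternatives
    slot: lunch
    rule: {kind: per_day}
    max_score: 1.0
    required_tags: [milk, lower_fat_milk, non_dairy_milk]
    description: Milk (or a non-dairy alternative) is available every day.
  - item_id: lower_fat_milk_specified
    category: dairy_and_alternatives
    slot: lunch
    rule: {kind: binary}
    max_score: 1.0
    required_tags: [lower_fat_milk]
    relevance_tags: [milk, lower_fat_milk, non_dairy_milk]
    description: The milk on offer is specified as semi-skimmed or skimmed.
  - item_id: low_sugar_yogurt
    category: dairy_and_alternatives
    slot: lunch
    rule: {kind: binary}
    max_score: 1.0
    required_tags: [low_sugar_yogurt]
    relevance_tags: [yogurt, low_sugar_yogurt]
    description: Yogurts on offer are low in sugar.
  # --- HFSS (3) -------------------------------------------------------------
  - item_id: no_confectionery_or_crisps
    category: hfss
    slot: lunch
    rule: {kind: limit, limit_max: 0, absence_credit: true}
    max_score: 1.0
    required_tags: [hfss_confectionery, hfss_savoury]
    description: No confectionery or non-compliant savoury snacks (e.g. crisps) are sold.
  - item_id: sweet_snacks_compliant
    category: hfss
    slot: lunch
    rule: {kind: limit, limit_max: 0, absence_credit: true}
    max_score: 1.0
    required_tags: [hfss_sweet_snack]
    description: Sweet baked snacks on offer comply with the healthiness criteria.
  - item_id: no_free_salt
    category: hfss
    slot: lunch
    rule: {kind: limit, limit_max: 0, absence_credit: true}
    max_score: 1.0
    required_tags: [salt_sachet]
    description: Salt is not freely available to pupils.
  # --- oils and spreads (1) -------------------------------------------------
  - item_id: spreads_condiments_noted
    category: oils_and_spreads
    slot: lunch
    rule: {kind: binary}
    max_score: 1.0
    required_tags: [condiment]
    description: >
      Spread/condiment provision is stated on the menu, allowing the coder to
      verify lower-fat spreads are used.
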