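"""Controlled vocabularies shared across the package.

The food-tag lexicon is deliberately food-based rather than nutrient-based:
coders (or the assistive auto-tagger) attach tags from ``FOOD_TAGS`` to each
menu offering, and every scoring rule is expressed over those tags.
"""

from __future__ import annotations

#: Permitted food/drink tags for offerings and price-list entries.
FOOD_TAGS: frozenset[str] = frozenset(
    {
        "fruit",
        "vegetable",
        "salad",
        "fish",
        "oily_fish",
        "red_meat",
        "processed_meat",
        "meat_cut",
        "poultry",
        "non_meat_protein",
        "vegan_alternative",
        "potato",
        "non_potato_starch",
        "bread",
        "wholegrain",
        "milk",
        "lower_fat_milk",
        "yogurt",
        "low_sugar_yogurt",
        "non_dairy_milk",
        "hfss_confectionery",
        "hfss_savoury",
        "hfss_sweet_snack",
        "compliant_snack",
        "drink",
        "sugar_info_present",
        "salt_sachet",
        "condiment",
        "meal_of_day",
        "meal_deal",
    }
)

#: Meal slots across the school day.
SLOTS: tuple[str, ...] = ("breakfast", "break", "lunch")

#: Instrument categories.
CATEGORIES: tuple[str, ...] = (
    "breakfast",
    "break_time",
    "fruit_and_vegetables",
    "meat_fish_alternatives",
    "starchy_carbohydrates",
    "dairy_and_alternatives",
    "oils_and_spreads",
    "hfss",
    "prices",
    "general",
)

#: Provision subgroups: local-authority vs school-organised catering, by phase.
SUBGROUPS: tuple[str, ...] = (
    "LA_primary",
    "LA_secondary",
    "school_primary",
    "school_secondary",
)

#: School phases.
PHASES: tuple[str, ...] = ("primary", "secondary")

#: Length of the school week in days.
DAYS_PER_WEEK: int = 5
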