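"""Synthetic menu cycles, price lists and noisy coder ratings.

No real menu dataset is deposited anywhere, so every other module is
exercised against generated provisions.  The generator is truth-planting:
for each codebook item it first draws the *target* state (absent with
probability ``absence_prob``, otherwise pass with the item's
``criterion_pass_prob``), then constructs offerings — from a small name bank
wired to the shipped lexicon — whose true rating under the instrument's rule
semantics equals that target.  The planted truth is returned alongside the
cycle, which makes exact end-to-end recovery testable: scoring the generated
menu must reproduce the planted rating for every item in every week.

Food classes whose tags interact (fruit variety needs fruit days; a vegan
dish is also a non-meat protein) are planted jointly and the recorded truth
is the *implied* rating, derived from the planting logic itself, never from
the scoring engine.

Coder simulation is a simple symmetric noise model: each coder independently
flips each true binary rating with probability epsilon, which drives kappa
from 1 (epsilon 0) down to chance level (epsilon 0.5).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np

from .codebook import Codebook, default_codebook
from .errors import SmhatError
from .menu_model import (
    MenuCycle,
    MenuDay,
    MenuWeek,
    Offering,
    PriceEntry,
    PriceList,
    tag_offering,
)
from .vocabulary import DAYS_PER_WEEK

Truth = dict[str, list[object]]  # item_id -> per-week 'A' or float

#: Plausible price magnitudes (pence): mean and SD per category tag.
DEFAULT_PRICE_MODEL: dict[str, tuple[float, float]] = {
    "meal_deal": (250.0, 30.0),
    "bread": (38.0, 7.0),  # a slice of toast
    "fruit": (49.0, 11.0),
    "vegetable": (54.0, 13.0),
    "hfss_sweet_snack": (92.0, 17.0),
    "yogurt": (65.0, 10.0),
    "drink": (80.0, 15.0),
    "condiment": (11.0, 4.0),
}

_PRICE_ENTRY_NAMES: dict[str, str] = {
    "meal_deal": "meal deal",
    "bread": "slice of toast",
    "fruit": "whole fruit",
    "vegetable": "portion of vegetables",
    "hfss_sweet_snack": "flapjack",
    "yogurt": "strawberry yogurt",
    "drink": "bottled water",
    "condiment": "ketchup sachet",
}

_FRUITS = ("apple", "banana", "orange")
_VEGETABLES = ("carrots", "peas", "broccoli")


@lru_cache(maxsize=None)
def _bank_tags(name: str) -> frozenset[str]:
    """Auto-tag a name-bank offering (cached: the bank is small and fixed)."""
    return frozenset(tag_offering(name))


@dataclass
class MenuGenParams:
    """Study conditions for one synthetic provision."""

    seed: int
    phase: str = "primary"
    subgroup: Optional[str] = None  # default: LA catering for the phase
    n_weeks: int = 3  # menus generally run on a 3-week rotational cycle
    criterion_pass_prob: dict[str, float] = field(default_factory=dict)
    default_pass_prob: float = 0.7
    absence_prob: float = 0.2
    price_model: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PRICE_MODEL)
    )
    with_price_list: Optional[bool] = None  # default: secondary only
    provision_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.n_weeks < 1:
            raise ValueError("n_weeks must be >= 1")
        for item_id, p in self.criterion_pass_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"pass probability for {item_id!r} outside [0, 1]")
        if not 0.0 <= self.absence_prob <= 1.0:
            raise ValueError("absence_prob outside [0, 1]")
        if not 0.0 <= self.default_pass_prob <= 1.0:
            raise ValueError("default_pass_prob outside [0, 1]")
        for tag, (_, sd) in self.price_model.items():
            if sd < 0:
                raise ValueError(f"price SD for {tag!r} must be >= 0")


@dataclass
class CoderGenParams:
    """Noise model for simulated coders."""

    seed: int
    n_coders: int = 2
    flip_prob: float = 0.1

    def __post_init__(self) -> None:
        if self.n_coders < 2:
            raise ValueError("n_coders must be >= 2")
        if not 0.0 <= self.flip_prob <= 0.5:
            raise ValueError("flip_prob must lie in [0, 0.5]")


class _CycleBuilder:
    """Plants offerings week by week and records the implied true ratings."""

    def __init__(self, params: MenuGenParams, codebook: Codebook, rng: np.random.Generator):
        self.params = params
        self.codebook = codebook
        self.rng = rng
        self.n = params.n_weeks
        # plan[week][day] -> offerings; week 0-based here, day 1-based
        self.plan: list[dict[int, list[Offering]]] = [
            {d: [] for d in range(1, DAYS_PER_WEEK + 1)} for _ in range(self.n)
        ]
        self.truth: Truth = {it.item_id: ["A"] * self.n for it in codebook.items}

    # -- drawing helpers ----------------------------------------------------
    def _p(self, item_id: str) -> float:
        return self.params.criterion_pass_prob.get(item_id, self.params.default_pass_prob)

    def passes(self, item_id: str) -> bool:
        return bool(self.rng.random() < self._p(item_id))

    def absent(self) -> bool:
        return bool(self.rng.random() < self.params.absence_prob)

    def days_for(self, item_id: str) -> int:
        """Per-day target: the pass probability acts per day, Binomial(5, p).

        This pins both endpoints — p=1 plants the criterion daily, p=0 plants
        it never — while intermediate p produces the incremental 0.2-step
        ratings.
        """
        return int(self.rng.binomial(DAYS_PER_WEEK, self._p(item_id)))

    def add(self, week: int, day: int, name: str, slot: str = "lunch") -> None:
        self.plan[week][day].append(
            Offering(name=name, slot=slot, tags=set(_bank_tags(name)))
        )

    def set_truth(self, item_id: str, week: int, value: object) -> None:
        if item_id in self.truth:
            self.truth[item_id][week] = value

    # -- food-class groups --------------------------------------------------
    def plant_fruit(self) -> None:
        if self.absent():
            return  # fruit never mentioned: fruit_daily and variety stay 'A'
        for w in range(self.n):
            d = self.days_for("fruit_daily")
            if d == 0:
                continue  # no fruit this week: both items 'A'
            variety = self.passes("fruit_variety_weekly")
            if variety:
                for f in _FRUITS:
                    self.add(w, 1, f)
                for day in range(2, d + 1):
                    self.add(w, day, _FRUITS[0])
            else:
                for day in range(1, d + 1):
                    self.add(w, day, _FRUITS[0])
            self.set_truth("fruit_daily", w, d / DAYS_PER_WEEK)
            self.set_truth("fruit_variety_weekly", w, 1.0 if variety else 0.0)

    def plant_vegetables(self) -> None:
        if self.absent():
            return
        for w in range(self.n):
            d = self.days_for("vegetable_daily")
            if d == 0:
                continue  # vegetables not mentioned this week: both items 'A'
            for day in range(1, d + 1):
                self.add(w, day, _VEGETABLES[(day - 1) % len(_VEGETABLES)])
            salad = self.passes("salad_available")
            if salad:
                self.add(w, 1, "side salad")
            self.set_truth("vegetable_daily", w, d / DAYS_PER_WEEK)
            self.set_truth("salad_available", w, 1.0 if salad else 0.0)

    def plant_fish(self) -> None:
        """Cycle-scoped: weekly white fish plus the oily-fish frequency rule."""
        if self.absent():
            return  # no fish anywhere: fish_weekly 'A' each week, oily 'A'
        needed = max(1, math.ceil(2 * self.n / 4))  # twice per four-week period
        oily_pass = self.passes("oily_fish_frequency")
        fish_weeks: set[int] = set()
        if oily_pass:
            for i in range(needed):
                w = i % self.n
                self.add(w, 3, "grilled salmon")
                fish_weeks.add(w)
        for w in range(self.n):
            if self.passes("fish_weekly"):
                self.add(w, 2, "breaded cod")
                fish_weeks.add(w)
        if not fish_weeks:
            return  # every draw failed: the class is absent after all ('A')
        for w in range(self.n):
            self.set_truth("fish_weekly", w, 1.0 if w in fish_weeks else "A")
            self.set_truth("oily_fish_frequency", w, 1.0 if oily_pass else 0.0)

    def plant_meat(self) -> None:
        if self.absent():
            return  # meatless provision: all four meat items 'A'
        for w in range(self.n):
            cut = self.passes("meat_cut_variety")
            self.add(w, 1, "roast chicken" if cut else "chicken curry")
            self.set_truth("meat_cut_variety", w, 1.0 if cut else 0.0)
            if not self.absent():
                ok = self.passes("red_meat_limit")
                for day in (1, 2) if ok else (1, 2, 3):  # limit is 2 days/week
                    self.add(w, day, "beef casserole")
                self.set_truth("red_meat_limit", w, 1.0 if ok else 0.0)
            if not self.absent():
                ok = self.passes("processed_meat_limit")
                for day in (4,) if ok else (4, 5):  # limit is 1 day/week
                    self.add(w, day, "chicken popcorn")
                self.set_truth("processed_meat_limit", w, 1.0 if ok else 0.0)

    def plant_proteins(self) -> None:
        """Non-meat proteins and (secondary) vegan alternatives, jointly."""
        secondary = self.codebook.phase == "secondary"
        for w in range(self.n):
            vegan = secondary and self.passes("vegan_alternative_available")
            if vegan:
                self.add(w, 2, "vegan burger")
                self.set_truth("vegan_alternative_available", w, 1.0)
            direct = self.passes("non_meat_protein_weekly")
            if direct:
                self.add(w, 3, "bean chilli")
            if direct or vegan:  # a vegan dish is also a non-meat protein
                self.set_truth("non_meat_protein_weekly", w, 1.0)

    def plant_starch(self) -> None:
        if self.absent():
            return
        for w in range(self.n):
            d = self.days_for("non_potato_starch_daily")
            for day in range(1, d + 1):
                self.add(w, day, "penne pasta")
            for day in range(d + 1, DAYS_PER_WEEK + 1):
                self.add(w, day, "chips")  # potato keeps the class mentioned
            self.set_truth("non_potato_starch_daily", w, d / DAYS_PER_WEEK)
            if d == 0:
                bread = wholegrain = False  # potatoes only, nothing else to credit
            else:
                bread = self.passes("bread_available")
                wholegrain = self.passes("wholegrain_weekly")
                if bread:
                    self.add(w, 1, "crusty roll")
                if wholegrain:
                    self.add(w, 1, "wholemeal pasta")
            self.set_truth("bread_available", w, 1.0 if bread else 0.0)
            self.set_truth("wholegrain_weekly", w, 1.0 if wholegrain else 0.0)

    def plant_dairy(self) -> None:
        if not self.absent():
            for w in range(self.n):
                d = self.days_for("milk_daily")
                if d == 0:
                    continue  # no milk this week: both milk items 'A'
                lower = self.passes("lower_fat_milk_specified")
                self.add(w, 1, "semi-skimmed milk" if lower else "milk carton")
                for day in range(2, d + 1):
                    self.add(w, day, "milk carton")
                self.set_truth("milk_daily", w, d / DAYS_PER_WEEK)
                self.set_truth("lower_fat_milk_specified", w, 1.0 if lower else 0.0)
        if not self.absent():
            for w in range(self.n):
                low_sugar = self.passes("low_sugar_yogurt")
                self.add(
                    w, 2, "natural low-sugar yogurt" if low_sugar else "strawberry yogurt"
                )
                self.set_truth("low_sugar_yogurt", w, 1.0 if low_sugar else 0.0)

    def plant_hfss(self) -> None:
        # Prohibition items score 1 by default; a failed draw plants the
        # offending food.
        for w in range(self.n):
            for item_id, name in (
                ("no_confectionery_or_crisps", "chocolate bar"),
                ("sweet_snacks_compliant", "flapjack"),
                ("no_free_salt", "salt sachet"),
            ):
                ok = self.passes(item_id)
                if not ok:
                    self.add(w, 5, name)
                self.set_truth(item_id, w, 1.0 if ok else 0.0)
            self.add(w, 4, "oatcakes")  # a compliant snack; no item penalises it

    def plant_condiments(self) -> None:
        for w in range(self.n):
            if self.passes("spreads_condiments_noted"):
                self.add(w, 1, "tomato ketchup")
                self.set_truth("spreads_condiments_noted", w, 1.0)

    def plant_breakfast(self) -> None:
        if self.absent():
            return  # no breakfast information at all (common in practice)
        for w in range(self.n):
            d = self.days_for("breakfast_healthy_daily")
            for day in range(1, d + 1):
                self.add(w, day, "porridge" if day % 2 else "toast", slot="breakfast")
            for day in range(d + 1, DAYS_PER_WEEK + 1):
                self.add(w, day, "fried sausage", slot="breakfast")
            no_hfss = self.passes("breakfast_no_hfss")
            if not no_hfss:
                self.add(w, 1, "danish pastry", slot="breakfast")
            self.set_truth("breakfast_healthy_daily", w, d / DAYS_PER_WEEK)
            self.set_truth("breakfast_no_hfss", w, 1.0 if no_hfss else 0.0)

    def plant_break(self) -> None:
        if self.codebook.phase != "secondary" or self.absent():
            return
        for w in range(self.n):
            fruit = self.passes("break_fruit_available")
            if fruit:
                self.add(w, 1, "apple", slot="break")
            bacon_ok = self.passes("break_processed_meat_not_daily")
            bacon_days = (1,) if bacon_ok else tuple(range(1, DAYS_PER_WEEK + 1))
            for day in bacon_days:
                self.add(w, day, "grilled bacon", slot="break")
            if fruit:
                non_hfss = True  # fruit at break is itself a non-HFSS option
            else:
                non_hfss = self.passes("break_non_hfss_option")
                if non_hfss:
                    self.add(w, 2, "oatcakes", slot="break")
            self.set_truth("break_fruit_available", w, 1.0 if fruit else 0.0)
            self.set_truth("break_processed_meat_not_daily", w, 1.0 if bacon_ok else 0.0)
            self.set_truth("break_non_hfss_option", w, 1.0 if non_hfss else 0.0)

    def plant_drinks(self) -> None:
        if self.codebook.phase != "secondary" or self.absent():
            return  # no drinks menu: both drink items 'A'
        for w in range(self.n):
            stated = self.passes("drink_info_stated")
            if stated:
                self.add(w, 1, "diet cola")
                self.set_truth("drink_info_stated", w, 1.0)
                self.set_truth("drink_free_sugar_compliant", w, 1.0)
            else:
                self.add(w, 1, "juice drink")
                self.set_truth("drink_info_stated", w, 0.0)
                # without sugar information the compliance item is unrateable

    def build(self) -> tuple[MenuCycle, Truth]:
        for w in range(self.n):
            for day in range(1, DAYS_PER_WEEK + 1):
                self.add(w, day, "meal of the day")
        self.plant_fruit()
        self.plant_vegetables()
        self.plant_fish()
        self.plant_meat()
        self.plant_proteins()
        self.plant_starch()
        self.plant_dairy()
        self.plant_hfss()
        self.plant_condiments()
        self.plant_breakfast()
        self.plant_break()
        self.plant_drinks()

        weeks = [
            MenuWeek(
                week_index=w + 1,
                days=[
                    MenuDay(day_index=d, offerings=self.plan[w][d])
                    for d in range(1, DAYS_PER_WEEK + 1)
                ],
            )
            for w in range(self.n)
        ]
        params = self.params
        subgroup = params.subgroup or (
            "LA_primary" if params.phase == "primary" else "LA_secondary"
        )
        with_prices = (
            params.with_price_list
            if params.with_price_list is not None
            else params.phase == "secondary"
        )
        price_list = (
            generate_price_list(self.rng, params.price_model) if with_prices else None
        )
        cycle = MenuCycle(
            provision_id=params.provision_id or f"synthetic_{params.seed}",
            subgroup=subgroup,
            weeks=weeks,
            price_list=price_list,
            notes="synthetic provision",
        )
        return cycle, self.truth


def generate_price_list(
    rng: np.random.Generator,
    price_model: Optional[dict[str, tuple[float, float]]] = None,
    n_per_category: int = 3,
) -> PriceList:
    """Draw a price list from per-category normal price models.

    Prices are truncated at zero and rounded to the penny.  The meal-deal
    category gets a single bundled price; other categories get
    ``n_per_category`` entries.
    """
    price_model = dict(DEFAULT_PRICE_MODEL if price_model is None else price_model)
    entries = []
    for tag in sorted(price_model):
        mean, sd = price_model[tag]
        count = 1 if tag == "meal_deal" else n_per_category
        for i in range(count):
            price = int(np.round(max(0.0, rng.normal(mean, sd))))
            name = _PRICE_ENTRY_NAMES.get(tag, tag.replace("_", " "))
            entries.append(PriceEntry(name=name, category_tag=tag, price=price))
    return PriceList(entries=entries)


def generate_menu(
    params: MenuGenParams, return_truth: bool = False
) -> MenuCycle | tuple[MenuCycle, Truth]:
    """Generate one synthetic provision; reproducible given the seed.

    With ``return_truth`` the planted per-item, per-week true ratings are
    returned alongside the cycle for recovery testing.
    """
    codebook = default_codebook(params.phase)
    known = {it.item_id for it in codebook.items}
    unknown = set(params.criterion_pass_prob) - known
    if unknown:
        raise SmhatError(
            f"criterion_pass_prob references unknown item_ids: {sorted(unknown)}"
        )
    rng = np.random.default_rng(params.seed)
    cycle, truth = _CycleBuilder(params, codebook, rng).build()
    return (cycle, truth) if return_truth else cycle


def ideal_menu(phase: str, n_weeks: int = 3, seed: int = 0) -> MenuCycle:
    """A provision meeting every criterion: scores exactly the phase maximum."""
    params = MenuGenParams(
        seed=seed,
        phase=phase,
        n_weeks=n_weeks,
        default_pass_prob=1.0,
        absence_prob=0.0,
    )
    return generate_menu(params)


def generate_coders(
    truth: Sequence[int], params: CoderGenParams
) -> dict[str, list[int]]:
    """Simulate coders who flip each true binary rating with ``flip_prob``.

    Returns one rating sheet per coder, keyed ``coder_1`` .. ``coder_k``;
    reproducible given the seed.
    """
    for v in truth:
        if v not in (0, 1):
            raise SmhatError("truth ratings must be binary 0/1")
    rng = np.random.default_rng(params.seed)
    sheets = {}
    for i in range(1, params.n_coders + 1):
        flips = rng.random(len(truth)) < params.flip_prob
        sheets[f"coder_{i}"] = [int(t ^ f) for t, f in zip(truth, flips)]
    return sheets
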