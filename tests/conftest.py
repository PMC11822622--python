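"""Shared fixtures and hand-construction helpers for the test suite."""

from __future__ import annotations

import logging

import pytest

from smhat.codebook import Codebook, CodebookItem, ScoringRule, default_codebook
from smhat.menu_model import MenuCycle, MenuDay, MenuWeek, Offering
from smhat.vocabulary import DAYS_PER_WEEK

# auto-tagger warnings about unmatched names are expected noise in tests
logging.getLogger("smhat.menu_model").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def primary_codebook() -> Codebook:
    return default_codebook("primary")


@pytest.fixture(scope="session")
def secondary_codebook() -> Codebook:
    return default_codebook("secondary")


def make_week(
    offerings_by_day: dict[int, list[tuple]], week_index: int = 1
) -> MenuWeek:
    """Build a five-day week from {day: [(name, tags) or (name, tags, slot)]}."""
    days = []
    for day_index in range(1, DAYS_PER_WEEK + 1):
        offerings = []
        for spec in offerings_by_day.get(day_index, []):
            name, tags, *rest = spec
            slot = rest[0] if rest else "lunch"
            offerings.append(Offering(name=name, tags=set(tags), slot=slot))
        days.append(MenuDay(day_index=day_index, offerings=offerings))
    return MenuWeek(week_index=week_index, days=days)


def make_cycle(
    weeks: list[MenuWeek],
    subgroup: str = "LA_primary",
    provision_id: str = "test",
    price_list=None,
    notes: str = "",
) -> MenuCycle:
    return MenuCycle(
        provision_id=provision_id,
        subgroup=subgroup,
        weeks=weeks,
        price_list=price_list,
        notes=notes,
    )


def simple_item(
    item_id: str,
    kind: str = "binary",
    required=("fruit",),
    relevance=None,
    slot="lunch",
    **rule_kwargs,
) -> CodebookItem:
    return CodebookItem(
        item_id=item_id,
        category="general",
        rule=ScoringRule(kind=kind, **rule_kwargs),
        max_score=1.0,
        required_tags=list(required),
        relevance_tags=list(relevance) if relevance is not None else None,
        slot=slot,
    )
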