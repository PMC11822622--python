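"""Provision data model, menu/price-list file I/O, and offering auto-tagging.

A menu cycle is the unit under audit: a rotational set of 5-day weeks of
tagged food and drink offerings, optionally accompanied by a price list.
Cycles where only a price list could be obtained (``completeness ==
"prices_only"``) are still scorable but are flagged as anomalies downstream.

Files are YAML (menu cycles) and CSV (price lists, lexicon).  All prices are
integer pence; display formatting is the caller's concern.
"""

from __future__ import annotations

import csv
import logging
import re
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from .errors import SchemaError, VocabularyError
from .vocabulary import DAYS_PER_WEEK, FOOD_TAGS, SLOTS, SUBGROUPS

logger = logging.getLogger(__name__)

Completeness = Literal["full", "prices_only", "menu_only"]

Lexicon = dict[str, frozenset[str]]


class Offering(BaseModel):
    """One food or drink item listed on a menu."""

    name: str
    slot: Literal["breakfast", "break", "lunch"] = "lunch"
    tags: set[str] = Field(default_factory=set)
    price: Optional[int] = None  # pence

    @field_validator("tags")
    @classmethod
    def _known_tags(cls, v: set[str]) -> set[str]:
        unknown = sorted(v - FOOD_TAGS)
        if unknown:
            raise ValueError(
                f"unknown tags {unknown}; permitted vocabulary: {sorted(FOOD_TAGS)}"
            )
        return v

    @field_validator("price")
    @classmethod
    def _price_pence(cls, v: Optional[int]) -> Optional[int]:
        if v is not None and v < 0:
            raise ValueError("price must be >= 0 pence")
        return v


class MenuDay(BaseModel):
    """One school day of offerings (day_index 1..5, Monday..Friday)."""

    day_index: int
    offerings: list[Offering] = Field(default_factory=list)

    @field_validator("day_index")
    @classmethod
    def _in_week(cls, v: int) -> int:
        if not 1 <= v <= DAYS_PER_WEEK:
            raise ValueError(f"day_index must be in 1..{DAYS_PER_WEEK}")
        return v


class MenuWeek(BaseModel):
    """One week of the rotational cycle: exactly five school days."""

    week_index: int
    days: list[MenuDay]

    @model_validator(mode="after")
    def _five_days(self) -> "MenuWeek":
        if len(self.days) != DAYS_PER_WEEK:
            raise ValueError(
                f"week {self.week_index} has {len(self.days)} days; "
                f"exactly {DAYS_PER_WEEK} are required"
            )
        indices = sorted(d.day_index for d in self.days)
        if indices != list(range(1, DAYS_PER_WEEK + 1)):
            raise ValueError(
                f"week {self.week_index} day_index values must be 1..{DAYS_PER_WEEK} "
                f"each exactly once, got {indices}"
            )
        return self

    def day(self, day_index: int) -> MenuDay:
        for d in self.days:
            if d.day_index == day_index:
                return d
        raise KeyError(day_index)


class PriceEntry(BaseModel):
    """One priced line of a price list."""

    name: str
    category_tag: str
    price: int  # pence

    @field_validator("category_tag")
    @classmethod
    def _known_tag(cls, v: str) -> str:
        if v not in FOOD_TAGS:
            raise ValueError(
                f"unknown category_tag {v!r}; permitted vocabulary: {sorted(FOOD_TAGS)}"
            )
        return v

    @field_validator("price")
    @classmethod
    def _non_negative(cls, v: int) -> int:
        if v < 0:
            raise ValueError("price must be >= 0 pence")
        return v


class PriceList(BaseModel):
    entries: list[PriceEntry] = Field(default_factory=list)

    def by_tag(self, tag: str) -> list[PriceEntry]:
        return [e for e in self.entries if e.category_tag == tag]


class MenuCycle(BaseModel):
    """A school food provision: rotational menu weeks plus optional prices."""

    provision_id: str
    subgroup: Literal["LA_primary", "LA_secondary", "school_primary", "school_secondary"]
    weeks: list[MenuWeek] = Field(default_factory=list)
    price_list: Optional[PriceList] = None
    notes: str = ""

    @model_validator(mode="after")
    def _week_indices(self) -> "MenuCycle":
        indices = sorted(w.week_index for w in self.weeks)
        if indices != list(range(1, len(self.weeks) + 1)):
            raise ValueError(
                f"week_index values must be 1..{len(self.weeks)}, got {indices}"
            )
        return self

    @property
    def completeness(self) -> Completeness:
        """Inferred from what is present: menus, prices, or both."""
        if self.weeks and self.price_list is not None:
            return "full"
        if self.weeks:
            return "menu_only"
        if self.price_list is not None:
            return "prices_only"
        # degenerate empty provision; rejected at scoring time
        return "menu_only"

    @property
    def n_weeks(self) -> int:
        return len(self.weeks)

    @property
    def phase(self) -> str:
        return "primary" if self.subgroup.endswith("primary") else "secondary"


# ---------------------------------------------------------------------------
# Auto-tagging

_WORD_RE = re.compile(r"[a-z0-9]+")


def normalise_name(name: str) -> str:
    """Lower-case, strip punctuation/hyphens, collapse whitespace."""
    return " ".join(_WORD_RE.findall(name.lower()))


def load_lexicon(path: str | Path) -> Lexicon:
    """Read a keyword->tags lexicon from a two-column CSV (tags ';'-separated)."""
    lexicon: Lexicon = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or set(reader.fieldnames) < {"keyword", "tags"}:
            raise SchemaError(f"{path}: lexicon needs 'keyword' and 'tags' columns")
        for row in reader:
            tags = frozenset(t.strip() for t in row["tags"].split(";") if t.strip())
            unknown = sorted(tags - FOOD_TAGS)
            if unknown:
                raise VocabularyError(
                    f"{path}: keyword {row['keyword']!r} maps to unknown tags "
                    f"{unknown}; permitted vocabulary: {sorted(FOOD_TAGS)}"
                )
            lexicon[normalise_name(row["keyword"])] = tags
    if not lexicon:
        raise SchemaError(f"{path}: lexicon is empty")
    return lexicon


@lru_cache(maxsize=1)
def default_lexicon() -> Lexicon:
    """The lexicon shipped with the package."""
    path = resources.files("smhat.data").joinpath("lexicon.csv")
    return load_lexicon(str(path))


def _phrase_in(needle: tuple[str, ...], haystack: tuple[str, ...]) -> bool:
    n = len(needle)
    return any(haystack[i : i + n] == needle for i in range(len(haystack) - n + 1))


def tag_offering(name: str, lexicon: Optional[Lexicon] = None) -> set[str]:
    """Auto-tag an offering name against the keyword lexicon.

    Matching is case-insensitive on whole words; multi-word keywords match as
    contiguous phrases, and a matched keyword that is itself a sub-phrase of a
    longer matched keyword is suppressed (so "fruit salad" tags as fruit, not
    salad).  An empty result is valid — the offering must then be tagged
    manually — and is logged.
    """
    if lexicon is None:
        lexicon = default_lexicon()
    if not lexicon:
        raise SchemaError("lexicon must be non-empty")
    words = tuple(normalise_name(name).split())
    hits = [kw for kw in lexicon if _phrase_in(tuple(kw.split()), words)]
    kept = [
        kw
        for kw in hits
        if not any(
            other != kw and _phrase_in(tuple(kw.split()), tuple(other.split()))
            for other in hits
        )
    ]
    tags: set[str] = set()
    for kw in kept:
        tags |= lexicon[kw]
    if not tags:
        logger.warning("offering %r matched no lexicon keyword; tag it manually", name)
    return tags


# ---------------------------------------------------------------------------
# File I/O

def _offering_to_dict(o: Offering) -> dict:
    d: dict = {"name": o.name, "slot": o.slot, "tags": sorted(o.tags)}
    if o.price is not None:
        d["price_pence"] = o.price
    return d


def write_menu(cycle: MenuCycle, path: str | Path) -> None:
    """Serialise a menu cycle to YAML (round-trips through :func:`read_menu`)."""
    data: dict = {
        "provision_id": cycle.provision_id,
        "subgroup": cycle.subgroup,
        "completeness": cycle.completeness,
        "notes": cycle.notes,
        "weeks": [
            {
                "week_index": w.week_index,
                "days": [
                    {
                        "day_index": d.day_index,
                        "offerings": [_offering_to_dict(o) for o in d.offerings],
                    }
                    for d in w.days
                ],
            }
            for w in cycle.weeks
        ],
    }
    if cycle.price_list is not None:
        data["price_list"] = [
            {"name": e.name, "category_tag": e.category_tag, "price_pence": e.price}
            for e in cycle.price_list.entries
        ]
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False, allow_unicode=True))


def read_menu(path: str | Path) -> MenuCycle:
    """Load a menu cycle from YAML, validating the schema and vocabulary.

    Completeness is inferred from the presence of weeks and prices; a
    ``completeness`` field in the file is informational only.
    """
    path = Path(path)
    try:
        data = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise SchemaError(f"{path}: not valid YAML: {exc}") from exc
    if not isinstance(data, dict):
        raise SchemaError(f"{path}: menu file must be a mapping at top level")
    try:
        weeks = [
            MenuWeek(
                week_index=w["week_index"],
                days=[
                    MenuDay(
                        day_index=d["day_index"],
                        offerings=[
                            Offering(
                                name=o["name"],
                                slot=o.get("slot", "lunch"),
                                tags=set(o.get("tags", [])),
                                price=o.get("price_pence"),
                            )
                            for o in d.get("offerings", [])
                        ],
                    )
                    for d in w.get("days", [])
                ],
            )
            for w in data.get("weeks") or []
        ]
        price_list = None
        if data.get("price_list") is not None:
            price_list = PriceList(
                entries=[
                    PriceEntry(
                        name=e["name"],
                        category_tag=e["category_tag"],
                        price=e["price_pence"],
                    )
                    for e in data["price_list"]
                ]
            )
        return MenuCycle(
            provision_id=data["provision_id"],
            subgroup=data["subgroup"],
            weeks=weeks,
            price_list=price_list,
            notes=data.get("notes", "") or "",
        )
    except KeyError as exc:
        raise SchemaError(f"{path}: missing required field {exc}") from exc
    except ValueError as exc:
        raise SchemaError(f"{path}: {exc}") from exc


def read_price_list(path: str | Path) -> PriceList:
    """Read a price list CSV with columns name, category_tag, price_pence."""
    entries = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"name", "category_tag", "price_pence"}
        if reader.fieldnames is None or set(reader.fieldnames) < required:
            raise SchemaError(f"{path}: price list needs columns {sorted(required)}")
        for row in reader:
            try:
                entries.append(
                    PriceEntry(
                        name=row["name"],
                        category_tag=row["category_tag"],
                        price=int(row["price_pence"]),
                    )
                )
            except ValueError as exc:
                raise SchemaError(f"{path}: {exc}") from exc
    return PriceList(entries=entries)


def write_price_list(price_list: PriceList, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["name", "category_tag", "price_pence"])
        for e in price_list.entries:
            writer.writerow([e.name, e.category_tag, e.price])


def format_pence(pence: int) -> str:
    """Display integer pence as pounds, e.g. 252 -> '£2.52'."""
    sign = "-" if pence < 0 else ""
    pence = abs(pence)
    return f"{sign}£{pence // 100}.{pence % 100:02d}"
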