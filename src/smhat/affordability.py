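"""Free-school-meal allowance sufficiency against canteen price lists.

All arithmetic is in integer pence; rounding happens only when figures are
displayed.  The provision's bundled main-meal-and-drink price ("meal deal")
is compared against the local authority's FSM allowance: a positive
disparity is a shortfall (the meal deal cannot be bought), a non-positive
one leaves a residual allowance that bounds what else a pupil can buy.
"""

from __future__ import annotations

import csv
import statistics
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from ._rounding import round_half_up_int
from .errors import SchemaError
from .menu_model import PriceEntry, PriceList


@dataclass(frozen=True)
class FSMAllowance:
    """A local authority's free-school-meal allowance for one phase."""

    la_id: str
    phase: str  # primary | secondary
    amount: int  # pence

    def __post_init__(self) -> None:
        if self.amount <= 0:
            raise ValueError("FSM allowance must be positive pence")
        if self.phase not in ("primary", "secondary"):
            raise ValueError(f"unknown phase {self.phase!r}")


@dataclass
class AffordabilityReport:
    """Verdict on whether the allowance covers the priced offering."""

    provision_id: str
    allowance: int  # pence
    meal_deal_price: Optional[int]  # pence; absent when no meal deal is listed
    affordable: Optional[bool]
    disparity: Optional[int]  # price - allowance; positive = shortfall
    residual: Optional[int]  # allowance left after the meal deal, when affordable
    affordable_items: list[PriceEntry] = field(default_factory=list)
    outpriced_items: list[PriceEntry] = field(default_factory=list)


def outpriced_items(allowance: FSMAllowance, price_list: PriceList) -> list[PriceEntry]:
    """Entries a pupil on the allowance cannot buy at all, dearest first."""
    over = [e for e in price_list.entries if e.price > allowance.amount]
    return sorted(over, key=lambda e: (-e.price, e.name))


def meal_deal_check(
    allowance: FSMAllowance, price_list: PriceList, provision_id: str = ""
) -> AffordabilityReport:
    """Check the cheapest meal deal against the allowance.

    When affordable, ``affordable_items`` are the non-meal-deal entries still
    purchasable with the residual allowance (e.g. an inexpensive condiment
    sachet); when not affordable — or when no meal deal is listed — they are
    the entries purchasable with the full allowance.
    """
    deals = price_list.by_tag("meal_deal")
    others = [e for e in price_list.entries if e.category_tag != "meal_deal"]
    out = outpriced_items(allowance, price_list)
    if not deals:
        return AffordabilityReport(
            provision_id=provision_id,
            allowance=allowance.amount,
            meal_deal_price=None,
            affordable=None,
            disparity=None,
            residual=None,
            affordable_items=[e for e in others if e.price <= allowance.amount],
            outpriced_items=out,
        )
    price = min(e.price for e in deals)
    disparity = price - allowance.amount
    affordable = disparity <= 0
    residual = -disparity if affordable else None
    budget = residual if affordable else allowance.amount
    return AffordabilityReport(
        provision_id=provision_id,
        allowance=allowance.amount,
        meal_deal_price=price,
        affordable=affordable,
        disparity=disparity,
        residual=residual,
        affordable_items=[e for e in others if e.price <= budget],
        outpriced_items=out,
    )


def price_summary(price_list: PriceList) -> pd.DataFrame:
    """Per-category price statistics: n, mean, sample SD, mode.

    Mean and SD are reported to the penny (half-up); exact values are kept in
    the ``mean_exact``/``sd_exact`` columns.  The mode is the most frequent
    price, ties broken toward the lower price (conservative for
    affordability claims).  Categories with a single entry have no SD;
    empty categories are simply absent from the table.
    """
    rows = []
    categories = sorted({e.category_tag for e in price_list.entries})
    for tag in categories:
        prices = [e.price for e in price_list.by_tag(tag)]
        mean_exact = sum(prices) / len(prices)
        sd_exact = statistics.stdev(prices) if len(prices) >= 2 else float("nan")
        counts = Counter(prices)
        top = max(counts.values())
        mode = min(p for p, c in counts.items() if c == top)
        rows.append(
            {
                "category_tag": tag,
                "n": len(prices),
                "mean": round_half_up_int(mean_exact),
                "sd": round_half_up_int(sd_exact) if len(prices) >= 2 else pd.NA,
                "mode": mode,
                "mean_exact": mean_exact,
                "sd_exact": sd_exact,
            }
        )
    return pd.DataFrame(rows).set_index("category_tag")


def read_allowances(path: str | Path) -> list[FSMAllowance]:
    """Read an allowance table CSV with columns la_id, phase, amount_pence."""
    allowances = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"la_id", "phase", "amount_pence"}
        if reader.fieldnames is None or set(reader.fieldnames) < required:
            raise SchemaError(f"{path}: allowance table needs columns {sorted(required)}")
        for row in reader:
            try:
                allowances.append(
                    FSMAllowance(
                        la_id=row["la_id"],
                        phase=row["phase"],
                        amount=int(row["amount_pence"]),
                    )
                )
            except ValueError as exc:
                raise SchemaError(f"{path}: {exc}") from exc
    return allowances
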