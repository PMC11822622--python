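"""Apply a codebook to a menu cycle and aggregate healthiness scores.

Each week of the cycle is coded separately against every codebook item; the
week totals are averaged (unrounded) across the cycle and rounded once,
half-up, to one decimal place to give the provision's healthiness score.
'A' ratings (item absent / not mentioned) contribute zero to totals, so the
phase maxima (22 primary / 28 secondary) are fixed denominators and scores
are comparable across provisions.

Cycles consisting only of a price list are scored from a pseudo-week built
out of the price-list entries (each entry is treated as mentioned once), and
the resulting score is flagged as an anomaly: such scores are reported but
excluded from subgroup averages so they do not skew the results.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional, Sequence, Union

import pandas as pd

from ._rounding import round_half_up
from .codebook import Codebook, CodebookItem
from .errors import ConfigurationError, EmptyProvisionError
from .menu_model import MenuCycle, MenuWeek, Offering, normalise_name
from .vocabulary import DAYS_PER_WEEK, FOOD_TAGS

Rating = Union[str, float]  # 'A' or points

#: Evidence triple: (week_index, day_index, offering name).
Evidence = tuple[int, int, str]


@dataclass
class ItemRating:
    """Rating of one codebook item for one week (or cycle, for frequency rules)."""

    item_id: str
    value: Rating  # 'A' or points in [0, max_score]
    evidence: list[Evidence] = field(default_factory=list)
    exact: Optional[Fraction] = None  # numeric value as an exact fraction

    @property
    def is_absent(self) -> bool:
        return self.value == "A"

    def numeric(self) -> Fraction:
        """Contribution to the week total ('A' contributes 0)."""
        return Fraction(0) if self.is_absent else (self.exact or Fraction(0))


@dataclass
class WeekScoreSheet:
    week_index: int
    ratings: list[ItemRating]
    week_total_exact: Fraction

    @property
    def week_total(self) -> float:
        return round_half_up(self.week_total_exact, 1)


@dataclass
class MenuScore:
    provision_id: str
    subgroup: str
    healthiness_score: float
    week_sheets: list[WeekScoreSheet]
    anomaly: bool
    completeness: str
    notes: str = ""


def _scoped_offerings(week: MenuWeek, item: CodebookItem) -> list[tuple[int, Offering]]:
    return [
        (day.day_index, off)
        for day in week.days
        for off in day.offerings
        if item.slot is None or off.slot == item.slot
    ]


def _check_item_tags(item: CodebookItem) -> None:
    bad = (set(item.required_tags) | item.effective_relevance) - FOOD_TAGS
    if bad:
        raise ConfigurationError(
            f"item {item.item_id!r} references tags outside the vocabulary: {sorted(bad)}"
        )


def _make_rating(
    item: CodebookItem, fraction: Fraction, evidence: list[Evidence]
) -> ItemRating:
    exact = fraction * Fraction(str(item.max_score))
    return ItemRating(
        item_id=item.item_id, value=float(exact), evidence=evidence, exact=exact
    )


def prorated_threshold(item: CodebookItem, cycle_weeks: int) -> int:
    """Occurrences required of a frequency rule for a cycle of ``cycle_weeks``.

    The reference window (e.g. twice per four weeks for oily fish) is
    pro-rated to the actual cycle length: ceil(threshold * weeks / period).
    """
    rule = item.rule
    return max(1, math.ceil(rule.threshold * cycle_weeks / rule.period_weeks))


def rate_item(
    week: MenuWeek, item: CodebookItem, context: Optional[MenuCycle] = None
) -> ItemRating:
    """Rate one codebook item for one week.

    ``context`` (the whole cycle) is required for ``frequency_per_period``
    items, whose evidence is pooled across every week of the cycle.  Items
    scoped to the breakfast or break slot rate 'A' when the slot carries no
    offerings at all (provision not mentioned); lunch-scoped items rate 'A'
    when no offering carries any of the item's relevance tags.
    """
    _check_item_tags(item)
    rule = item.rule
    required = set(item.required_tags)
    relevance = item.effective_relevance
    scope = _scoped_offerings(week, item)

    if rule.kind == "frequency_per_period":
        weeks = context.weeks if context is not None and context.weeks else [week]
        pooled = [
            (w.week_index, d, off)
            for w in weeks
            for d, off in _scoped_offerings(w, item)
        ]
        if not any(off.tags & relevance for _, _, off in pooled):
            return ItemRating(item_id=item.item_id, value="A")
        hit_days = sorted(
            {(wi, d) for wi, d, off in pooled if off.tags & required}
        )
        evidence = [
            (wi, d, off.name) for wi, d, off in pooled if off.tags & required
        ]
        needed = prorated_threshold(item, len(weeks))
        met = len(hit_days) >= needed
        return _make_rating(item, Fraction(1 if met else 0), evidence)

    if item.slot in ("breakfast", "break"):
        mentioned = bool(scope)
    else:
        mentioned = any(off.tags & relevance for _, off in scope)

    hits = [(d, off) for d, off in scope if off.tags & required]
    evidence = [(week.week_index, d, off.name) for d, off in hits]

    if rule.kind == "binary":
        if not mentioned:
            return ItemRating(item_id=item.item_id, value="A")
        distinct = {normalise_name(off.name) for _, off in hits}
        met = len(distinct) >= rule.min_distinct
        return _make_rating(item, Fraction(1 if met else 0), evidence)

    if rule.kind == "per_day":
        if not mentioned:
            return ItemRating(item_id=item.item_id, value="A")
        days_met = len({d for d, _ in hits})
        return _make_rating(item, Fraction(days_met, DAYS_PER_WEEK), evidence)

    if rule.kind == "limit":
        if not mentioned and item.slot not in ("breakfast", "break"):
            if rule.absence_credit:
                return _make_rating(item, Fraction(1), [])
            return ItemRating(item_id=item.item_id, value="A")
        if not mentioned:  # breakfast/break slot empty all week
            return ItemRating(item_id=item.item_id, value="A")
        days_with = len({d for d, _ in hits})
        met = days_with <= rule.limit_max
        return _make_rating(item, Fraction(1 if met else 0), evidence)

    raise ConfigurationError(f"unknown rule kind {rule.kind!r}")  # pragma: no cover


def score_week(
    week: MenuWeek, codebook: Codebook, context: Optional[MenuCycle] = None
) -> WeekScoreSheet:
    """Code one menu week: one rating per codebook item plus the week total."""
    ratings = [rate_item(week, item, context) for item in codebook.items]
    total = sum((r.numeric() for r in ratings), Fraction(0))
    return WeekScoreSheet(week_index=week.week_index, ratings=ratings, week_total_exact=total)


def _pseudo_week_from_prices(cycle: MenuCycle) -> MenuWeek:
    """Treat each price-list entry as a single mention on day 1."""
    from .menu_model import MenuDay  # local import to avoid cycle at module load

    offerings = [
        Offering(name=e.name, slot="lunch", tags={e.category_tag}, price=e.price)
        for e in cycle.price_list.entries
    ]
    days = [MenuDay(day_index=1, offerings=offerings)] + [
        MenuDay(day_index=i) for i in range(2, DAYS_PER_WEEK + 1)
    ]
    return MenuWeek(week_index=1, days=days)


def score_menu(cycle: MenuCycle, codebook: Codebook) -> MenuScore:
    """Score a whole provision: mean of week totals, rounded once at the end."""
    if cycle.completeness == "prices_only":
        sheet = score_week(_pseudo_week_from_prices(cycle), codebook)
        return MenuScore(
            provision_id=cycle.provision_id,
            subgroup=cycle.subgroup,
            healthiness_score=round_half_up(sheet.week_total_exact, 1),
            week_sheets=[sheet],
            anomaly=True,
            completeness=cycle.completeness,
            notes=cycle.notes,
        )
    if not cycle.weeks:
        raise EmptyProvisionError(
            f"provision {cycle.provision_id!r} has no menu weeks and no price list"
        )
    sheets = [score_week(w, codebook, cycle) for w in cycle.weeks]
    mean = sum((s.week_total_exact for s in sheets), Fraction(0)) / len(sheets)
    return MenuScore(
        provision_id=cycle.provision_id,
        subgroup=cycle.subgroup,
        healthiness_score=round_half_up(mean, 1),
        week_sheets=sheets,
        anomaly=False,
        completeness=cycle.completeness,
        notes=cycle.notes,
    )


def aggregate_subgroup(scores: Sequence[MenuScore]) -> pd.DataFrame:
    """Summarise healthiness scores per provision subgroup.

    Anomaly-flagged scores (price-list-only provisions) are counted and
    listed but excluded from mean/SD/min/max so they do not skew the
    results.  SD is the sample standard deviation (n-1); it is absent (NaN)
    for subgroups with fewer than two included scores, as is the mean for
    subgroups with none.
    """
    if not scores:
        raise ValueError("aggregate_subgroup requires at least one score")
    rows = []
    for subgroup in sorted({s.subgroup for s in scores}):
        group = [s for s in scores if s.subgroup == subgroup]
        included = [s.healthiness_score for s in group if not s.anomaly]
        anomalies = [s.healthiness_score for s in group if s.anomaly]
        ser = pd.Series(included, dtype=float)
        rows.append(
            {
                "subgroup": subgroup,
                "n_total": len(group),
                "n_included": len(included),
                "n_anomalies": len(anomalies),
                "mean": ser.mean() if len(included) else float("nan"),
                "sd": ser.std(ddof=1) if len(included) >= 2 else float("nan"),
                "min": ser.min() if len(included) else float("nan"),
                "max": ser.max() if len(included) else float("nan"),
                "anomaly_scores": anomalies,
            }
        )
    return pd.DataFrame(rows).set_index("subgroup")


def score_report(score: MenuScore) -> pd.DataFrame:
    """Long-format report: one row per item per week, plus evidence."""
    rows = []
    for sheet in score.week_sheets:
        for rating in sheet.ratings:
            rows.append(
                {
                    "provision_id": score.provision_id,
                    "week": sheet.week_index,
                    "item_id": rating.item_id,
                    "rating": rating.value,
                    "evidence": "; ".join(
                        f"w{w}d{d}:{name}" for w, d, name in rating.evidence[:10]
                    ),
                }
            )
        rows.append(
            {
                "provision_id": score.provision_id,
                "week": sheet.week_index,
                "item_id": "__week_total__",
                "rating": sheet.week_total,
                "evidence": "",
            }
        )
    rows.append(
        {
            "provision_id": score.provision_id,
            "week": "",
            "item_id": "__healthiness_score__",
            "rating": score.healthiness_score,
            "evidence": "anomaly" if score.anomaly else "",
        }
    )
    return pd.DataFrame(rows)
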