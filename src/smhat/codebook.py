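"""The menu-auditing instrument (codebook) as data.

A codebook is an ordered list of food-based items, each with a scoring rule
expressed over the controlled food-tag vocabulary.  Four rule kinds exist:

``binary``
    'A' when no relevant offering is mentioned in the week, 1 when at least
    ``min_distinct`` distinct offerings carry a required tag, 0 when relevant
    offerings appear but the criterion is not met.
``per_day``
    Incremental credit: (days on which the criterion is met) / 5, so the
    possible scores are 'A', 0.0, 0.2, 0.4, 0.6, 0.8, 1.0 — used for
    criteria phrased "at least one portion per day".
``frequency_per_period``
    Cycle-scoped: 1 when the required tag appears on at least
    ``ceil(threshold * cycle_weeks / period_weeks)`` days across the whole
    cycle (e.g. oily fish twice over a four-week period), else 0;
    'A' when the relevant food class is never mentioned anywhere.
``limit``
    1 when the tag appears on at most ``limit_max`` days in the week, 0 when
    the limit is exceeded.  When the tag never appears the item scores 1 if
    ``absence_credit`` is set (prohibitions such as free salt), otherwise 'A'
    (absence of e.g. red meat is uninformative, not automatic credit).

Items may be scoped to one meal slot (breakfast / break / lunch); a
slot-scoped item rates 'A' when the slot carries no offerings at all in the
scoring window.  The two shipped instruments sum to 22 points (primary
phase) and 28 points (secondary phase).
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Optional

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from .errors import CodebookValidationError, SchemaError, VocabularyError
from .vocabulary import CATEGORIES, DAYS_PER_WEEK, FOOD_TAGS, PHASES, SLOTS

RuleKind = Literal["binary", "per_day", "frequency_per_period", "limit"]

#: Version identifiers of the instruments shipped with the package.
DEFAULT_VERSIONS = {"primary": "smhat_primary_v1", "secondary": "smhat_secondary_v1"}


class ScoringRule(BaseModel):
    """How one codebook item converts tagged offerings into a rating."""

    kind: RuleKind
    threshold: Optional[int] = None
    period_weeks: Optional[int] = None
    limit_max: Optional[int] = None
    min_distinct: int = 1
    absence_credit: bool = False
    days_per_week: int = DAYS_PER_WEEK

    @model_validator(mode="after")
    def _check_kind_fields(self) -> "ScoringRule":
        if self.days_per_week != DAYS_PER_WEEK:
            raise ValueError("the school week is fixed at 5 days")
        if self.kind == "frequency_per_period":
            if self.threshold is None or self.threshold < 1:
                raise ValueError("frequency_per_period requires threshold >= 1")
            if self.period_weeks is None or self.period_weeks < 1:
                raise ValueError("frequency_per_period requires period_weeks >= 1")
        if self.kind == "limit" and (self.limit_max is None or self.limit_max < 0):
            raise ValueError("limit rules require limit_max >= 0")
        if self.min_distinct < 1:
            raise ValueError("min_distinct must be >= 1")
        return self

    def possible_scores(self) -> set[float | str]:
        """The rating values this rule can emit (as fractions of max_score 1)."""
        if self.kind == "per_day":
            return {"A", 0.0, 0.2, 0.4, 0.6, 0.8, 1.0}
        return {"A", 0.0, 1.0}


class CodebookItem(BaseModel):
    """One food-based criterion of the instrument."""

    item_id: str
    category: str
    rule: ScoringRule
    max_score: float = 1.0
    required_tags: list[str] = Field(default_factory=list)
    relevance_tags: Optional[list[str]] = None
    slot: Optional[str] = None
    description: str = ""

    @field_validator("max_score")
    @classmethod
    def _positive_max(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("max_score must be > 0")
        return v

    @field_validator("category")
    @classmethod
    def _known_category(cls, v: str) -> str:
        if v not in CATEGORIES:
            raise ValueError(f"unknown category {v!r}; permitted: {CATEGORIES}")
        return v

    @field_validator("slot")
    @classmethod
    def _known_slot(cls, v: Optional[str]) -> Optional[str]:
        if v is not None and v not in SLOTS:
            raise ValueError(f"unknown slot {v!r}; permitted: {SLOTS}")
        return v

    @model_validator(mode="after")
    def _check_tags(self) -> "CodebookItem":
        for tag in list(self.required_tags) + list(self.relevance_tags or []):
            if tag not in FOOD_TAGS:
                raise ValueError(
                    f"item {self.item_id!r} references tag {tag!r} outside the "
                    f"controlled vocabulary"
                )
        return self

    @property
    def effective_relevance(self) -> frozenset[str]:
        """Tags whose presence means the item was 'mentioned' (defaults to required)."""
        return frozenset(self.relevance_tags or self.required_tags)


class Codebook(BaseModel):
    """A complete instrument: ordered items, phase, and declared maximum."""

    phase: Literal["primary", "secondary"]
    version: str = "custom"
    declared_max: float
    items: list[CodebookItem]

    @model_validator(mode="after")
    def _check_invariants(self) -> "Codebook":
        ids = [it.item_id for it in self.items]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate item_ids: {dupes}")
        total = sum(it.max_score for it in self.items)
        if abs(total - self.declared_max) > 1e-9:
            raise ValueError(
                f"item max_scores sum to {total}, declared_max is {self.declared_max}"
            )
        return self

    def item(self, item_id: str) -> CodebookItem:
        for it in self.items:
            if it.item_id == item_id:
                return it
        raise KeyError(item_id)


def max_score(codebook: Codebook) -> float:
    """Maximum attainable healthiness score (sum of item maxima)."""
    return sum(it.max_score for it in codebook.items)


#: Declared maxima for the two phases of the shipped instrument.
PHASE_MAXIMA = {"primary": 22.0, "secondary": 28.0}


def _codebook_from_mapping(data: dict, source: str) -> Codebook:
    if not isinstance(data, dict):
        raise SchemaError(f"{source}: codebook file must be a mapping at top level")
    for field in ("phase", "declared_max", "items"):
        if field not in data:
            raise SchemaError(f"{source}: missing required field {field!r}")
    try:
        return Codebook(**data)
    except ValueError as exc:  # pydantic ValidationError subclasses ValueError
        raise CodebookValidationError(f"{source}: {exc}") from exc


def load_codebook(path: str | Path, *, require_phase_max: bool = True) -> Codebook:
    """Load and validate a codebook from a YAML file.

    With ``require_phase_max`` (the default) the declared maximum must equal
    the instrument constant for the phase: 22 points for primary provision,
    28 for secondary.  Disable it only for experimental custom instruments.
    """
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise SchemaError(f"cannot read codebook file {path}: {exc}") from exc
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise SchemaError(f"{path}: not valid YAML: {exc}") from exc
    cb = _codebook_from_mapping(data, str(path))
    if require_phase_max and abs(cb.declared_max - PHASE_MAXIMA[cb.phase]) > 1e-9:
        raise CodebookValidationError(
            f"{path}: declared_max {cb.declared_max} does not equal the "
            f"{cb.phase}-phase maximum {PHASE_MAXIMA[cb.phase]}"
        )
    if cb.phase not in PHASES:  # pragma: no cover - guarded by pydantic Literal
        raise VocabularyError(f"unknown phase {cb.phase!r}")
    return cb


def write_codebook(codebook: Codebook, path: str | Path) -> None:
    """Serialise a codebook to YAML so that :func:`load_codebook` round-trips."""
    data = codebook.model_dump(exclude_none=True, exclude_defaults=False)
    for item in data["items"]:
        rule = item["rule"]
        for key in ("threshold", "period_weeks", "limit_max"):
            if rule.get(key) is None:
                rule.pop(key, None)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def default_codebook_path(phase: str) -> Path:
    """Filesystem path of the shipped instrument for ``phase``."""
    if phase not in PHASES:
        raise VocabularyError(f"unknown phase {phase!r}; permitted: {PHASES}")
    name = f"{DEFAULT_VERSIONS[phase]}.yaml"
    return Path(str(resources.files("smhat.data").joinpath(name)))


def default_codebook(phase: str) -> Codebook:
    """Load the shipped instrument for ``phase`` ('primary' or 'secondary')."""
    return load_codebook(default_codebook_path(phase))


def referenced_tags(items: Iterable[CodebookItem]) -> frozenset[str]:
    """All tags any of ``items`` inspects (required plus relevance)."""
    tags: set[str] = set()
    for it in items:
        tags |= set(it.required_tags)
        tags |= it.effective_relevance
    return frozenset(tags)
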