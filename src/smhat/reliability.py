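"""Intercoder reliability: dispersion, agreement and Cohen's kappa.

The instrument's 'A' code is non-numerical, so multi-coder agreement is
computed on binary-recoded ratings: a rating counts as 1 ("criterion met")
when it reaches the recode cutpoint (full marks by default) and 0 otherwise,
with 'A' recoding to 0.  Two reliability stages are supported:

* many coders — per-item sample SD of the recoded ratings across coders, and
  mean pairwise percent agreement;
* two coders — Cohen's kappa over pooled item x week rating units, with
  McHugh's interpretation bands for health research (0.60-0.79 moderate,
  0.80-0.90 strong, above 0.90 almost perfect).
"""

from __future__ import annotations

import itertools
import statistics
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence, Union

import pandas as pd

from ._rounding import round_half_up
from .errors import DegenerateMarginalsError, ReliabilityError, SchemaError

Rating = Union[str, float, int]  # 'A' or numeric

BANDS = ("below_moderate", "moderate", "strong", "almost_perfect")


@dataclass(frozen=True)
class KappaResult:
    """Cohen's kappa with its ingredients and interpretation band."""

    kappa: float
    p_o: float
    p_e: float
    band: str
    n_units: int


@dataclass
class CoderRatingSet:
    """Aligned ratings of one item of one menu by several coders."""

    menu_id: str
    item_id: str
    ratings: Mapping[str, Rating]  # coder_id -> 'A' or numeric

    def __post_init__(self) -> None:
        if len(self.ratings) < 2:
            raise ReliabilityError(
                f"{self.menu_id}/{self.item_id}: at least two coders are required"
            )


def binary_recode(rating: Rating, item_max: float = 1.0, cutpoint: float = 1.0) -> int:
    """Recode an 'A'/numeric rating to 0/1 for agreement statistics.

    Returns 1 when the numeric rating reaches ``cutpoint * item_max`` and 0
    otherwise; 'A' (absent) recodes to 0.  The default cutpoint of 1.0 means
    only full marks count as "criterion met".
    """
    if rating == "A":
        return 0
    value = float(rating)
    if not 0.0 <= value <= item_max + 1e-9:
        raise ReliabilityError(
            f"rating {value} outside [0, {item_max}]"
        )
    return 1 if value >= cutpoint * item_max - 1e-9 else 0


def _recoded(ratings: CoderRatingSet, item_max: float, cutpoint: float) -> list[int]:
    return [
        binary_recode(ratings.ratings[c], item_max, cutpoint)
        for c in sorted(ratings.ratings)
    ]


def item_sd(
    rating_set: CoderRatingSet, item_max: float = 1.0, cutpoint: float = 1.0
) -> float:
    """Sample SD (n-1) of the binary-recoded ratings across coders."""
    recoded = _recoded(rating_set, item_max, cutpoint)
    return statistics.stdev(recoded)


def pairwise_agreement(
    rating_set: CoderRatingSet, item_max: float = 1.0, cutpoint: float = 1.0
) -> float:
    """Mean over coder pairs of the recoded-rating match indicator."""
    recoded = _recoded(rating_set, item_max, cutpoint)
    pairs = list(itertools.combinations(recoded, 2))
    return sum(1 for a, b in pairs if a == b) / len(pairs)


def mchugh_band(kappa: float) -> str:
    """McHugh's interpretation band for a kappa value.

    Bands: below 0.60 below_moderate; 0.60-0.79 moderate; 0.80-0.90 strong;
    above 0.90 almost perfect.  The bands are printed at two-decimal
    precision, leaving 0.79 < kappa < 0.80 undefined; values in that gap are
    assigned by rounding kappa half-up to two decimals first.  The 0.90 edge
    is exact: anything strictly above 0.90 is almost perfect.
    """
    if not -1.0 - 1e-12 <= kappa <= 1.0 + 1e-12:
        raise ReliabilityError(f"kappa {kappa} outside [-1, 1]")
    if 0.79 < kappa < 0.80:
        kappa = round_half_up(kappa, 2)
    if kappa < 0.60:
        return "below_moderate"
    if kappa <= 0.79:
        return "moderate"
    if kappa <= 0.90:
        return "strong"
    return "almost_perfect"


def cohens_kappa(
    coder_a: Sequence[int], coder_b: Sequence[int]
) -> KappaResult:
    """Cohen's kappa for two coders' aligned binary ratings.

    kappa = (p_o - p_e) / (1 - p_e), where p_o is the observed proportion of
    agreeing units and p_e the agreement expected from the coders' marginal
    class proportions.  Degenerate unanimity (both coders constant and
    identical, p_e = 1 = p_o) is defined as kappa 1; the p_e = 1, p_o < 1
    error branch is defensive only — for binary data p_e = 1 forces both
    coders constant on the same class, hence p_o = 1.
    """
    if len(coder_a) != len(coder_b):
        raise ReliabilityError(
            f"rating vectors differ in length ({len(coder_a)} vs {len(coder_b)})"
        )
    n = len(coder_a)
    if n < 2:
        raise ReliabilityError("kappa needs at least two rating units")
    for v in itertools.chain(coder_a, coder_b):
        if v not in (0, 1):
            raise ReliabilityError(f"ratings must be binary 0/1, got {v!r}")
    p_o = sum(1 for a, b in zip(coder_a, coder_b) if a == b) / n
    p_e = sum(
        (sum(1 for a in coder_a if a == c) / n) * (sum(1 for b in coder_b if b == c) / n)
        for c in (0, 1)
    )
    if p_e >= 1.0 - 1e-12:
        if p_o >= 1.0 - 1e-12:
            return KappaResult(kappa=1.0, p_o=1.0, p_e=1.0, band="almost_perfect", n_units=n)
        raise DegenerateMarginalsError(
            "expected agreement is 1 (both coders constant) but observed agreement is not"
        )
    kappa = (p_o - p_e) / (1 - p_e)
    return KappaResult(kappa=kappa, p_o=p_o, p_e=p_e, band=mchugh_band(kappa), n_units=n)


# ---------------------------------------------------------------------------
# Rating-sheet table utilities (CSV with columns menu_id, item_id, week,
# coder_id, rating)

def read_ratings(path: str | Path) -> pd.DataFrame:
    """Load a coder rating sheet; ratings stay as strings ('A' or numbers)."""
    df = pd.read_csv(path, dtype={"rating": str})
    required = {"menu_id", "item_id", "week", "coder_id", "rating"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: rating sheet missing columns {sorted(missing)}")
    return df


def _recode_frame(df: pd.DataFrame, item_max: float, cutpoint: float) -> pd.DataFrame:
    out = df.copy()
    out["recoded"] = [
        binary_recode("A" if str(r).strip() == "A" else float(r), item_max, cutpoint)
        for r in out["rating"]
    ]
    return out


def item_sd_table(
    df: pd.DataFrame, item_max: float = 1.0, cutpoint: float = 1.0
) -> pd.DataFrame:
    """Per-item dispersion across coders, averaged over menus.

    For every (menu, item, week) unit the sample SD of the recoded ratings
    across coders is taken; the table reports each item's mean SD over units.
    High values flag items coders interpret differently.
    """
    recoded = _recode_frame(df, item_max, cutpoint)
    per_unit = (
        recoded.groupby(["menu_id", "item_id", "week"])["recoded"]
        .apply(lambda s: s.std(ddof=1))
        .reset_index(name="sd")
    )
    return (
        per_unit.groupby("item_id")["sd"].mean().reset_index(name="mean_sd")
        .sort_values("mean_sd", ascending=False, kind="stable")
        .reset_index(drop=True)
    )


def menu_kappas(
    df: pd.DataFrame,
    coder_a: str,
    coder_b: str,
    item_max: float = 1.0,
    cutpoint: float = 1.0,
) -> pd.DataFrame:
    """Per-menu Cohen's kappa between two coders.

    Units are the pooled item x week ratings of each menu, recoded to 0/1.
    """
    recoded = _recode_frame(df, item_max, cutpoint)
    wide = recoded.pivot_table(
        index=["menu_id", "item_id", "week"],
        columns="coder_id",
        values="recoded",
        aggfunc="first",
    )
    for coder in (coder_a, coder_b):
        if coder not in wide.columns:
            raise ReliabilityError(f"coder {coder!r} not present in the rating sheet")
    rows = []
    for menu_id, block in wide.groupby(level="menu_id"):
        a = block[coder_a].astype(int).tolist()
        b = block[coder_b].astype(int).tolist()
        res = cohens_kappa(a, b)
        rows.append(
            {
                "menu_id": menu_id,
                "kappa": res.kappa,
                "p_o": res.p_o,
                "p_e": res.p_e,
                "band": res.band,
                "n_units": res.n_units,
            }
        )
    return pd.DataFrame(rows)
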