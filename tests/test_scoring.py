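"""Scoring engine: rule semantics, week totals, cycle averages, aggregation."""

from __future__ import annotations

import math
from fractions import Fraction

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from smhat.codebook import Codebook, default_codebook
from smhat.errors import EmptyProvisionError
from smhat.menu_model import MenuCycle, Offering, PriceEntry, PriceList
from smhat.sample import SampleFrame, coverage_percent, study_population
from smhat.scoring_engine import (
    MenuScore,
    aggregate_subgroup,
    rate_item,
    score_menu,
    score_week,
)
from smhat.synthetic_data import MenuGenParams, generate_menu, ideal_menu

from .conftest import make_cycle, make_week, simple_item

VEG = ("carrots", {"vegetable"})


class TestPerDayRule:
    @pytest.mark.parametrize("days_met,expected", [(1, 0.2), (3, 0.6), (5, 1.0)])
    def test_incremental_vegetable_scores(self, primary_codebook, days_met, expected):
        week = make_week({d: [VEG] for d in range(1, days_met + 1)})
        rating = rate_item(week, primary_codebook.item("vegetable_daily"))
        assert rating.value == pytest.approx(expected)

    def test_absent_class_rates_a(self, primary_codebook):
        week = make_week({1: [("apple", {"fruit"})]})
        assert rate_item(week, primary_codebook.item("vegetable_daily")).value == "A"


class TestFrequencyRule:
    def _cycle(self, salmon_weeks: list[int], n_weeks: int = 4) -> MenuCycle:
        weeks = []
        for w in range(1, n_weeks + 1):
            spec = {1: [("breaded cod", {"fish"})]}  # class mentioned every week
            if w in salmon_weeks:
                spec[3] = [("grilled salmon", {"fish", "oily_fish"})]
            weeks.append(make_week(spec, week_index=w))
        return make_cycle(weeks)

    def test_oily_fish_twice_in_four_weeks_scores_one(self, primary_codebook):
        cycle = self._cycle([1, 3])
        item = primary_codebook.item("oily_fish_frequency")
        assert rate_item(cycle.weeks[0], item, cycle).value == 1.0

    def test_oily_fish_once_in_four_weeks_scores_zero(self, primary_codebook):
        cycle = self._cycle([2])
        item = primary_codebook.item("oily_fish_frequency")
        assert rate_item(cycle.weeks[0], item, cycle).value == 0.0

    def test_threshold_prorated_for_short_cycles(self, primary_codebook):
        # ceil(2 * 1 / 4) = 1 occurrence suffices in a one-week cycle
        cycle = self._cycle([1], n_weeks=1)
        item = primary_codebook.item("oily_fish_frequency")
        assert rate_item(cycle.weeks[0], item, cycle).value == 1.0

    def test_no_fish_anywhere_rates_a(self, primary_codebook):
        cycle = make_cycle([make_week({1: [VEG]})])
        item = primary_codebook.item("oily_fish_frequency")
        assert rate_item(cycle.weeks[0], item, cycle).value == "A"

    def test_same_rating_written_into_every_week(self, primary_codebook):
        cycle = self._cycle([1, 3])
        sheets = [score_week(w, primary_codebook, cycle) for w in cycle.weeks]
        values = {
            r.value
            for sheet in sheets
            for r in sheet.ratings
            if r.item_id == "oily_fish_frequency"
        }
        assert values == {1.0}


class TestLimitRule:
    def test_red_meat_absent_is_a_not_credit(self, primary_codebook):
        week = make_week({1: [("chicken curry", {"poultry"})]})
        assert rate_item(week, primary_codebook.item("red_meat_limit")).value == "A"

    def test_red_meat_within_limit(self, primary_codebook):
        week = make_week({d: [("beef casserole", {"red_meat"})] for d in (1, 2)})
        assert rate_item(week, primary_codebook.item("red_meat_limit")).value == 1.0

    def test_red_meat_over_limit(self, primary_codebook):
        week = make_week({d: [("beef casserole", {"red_meat"})] for d in (1, 2, 3)})
        assert rate_item(week, primary_codebook.item("red_meat_limit")).value == 0.0

    def test_prohibition_absence_scores_credit(self, primary_codebook):
        week = make_week({1: [VEG]})
        assert rate_item(week, primary_codebook.item("no_free_salt")).value == 1.0

    def test_prohibition_violated(self, primary_codebook):
        week = make_week({1: [("salt sachet", {"salt_sachet"})]})
        assert rate_item(week, primary_codebook.item("no_free_salt")).value == 0.0

    def test_daily_break_bacon_fails(self, secondary_codebook):
        item = secondary_codebook.item("break_processed_meat_not_daily")
        daily = make_week(
            {d: [("grilled bacon", {"processed_meat", "red_meat"}, "break")]
             for d in range(1, 6)}
        )
        assert rate_item(daily, item).value == 0.0
        four = make_week(
            {d: [("grilled bacon", {"processed_meat", "red_meat"}, "break")]
             for d in range(1, 5)}
        )
        assert rate_item(four, item).value == 1.0
        # break slot empty all week: provision not mentioned
        assert rate_item(make_week({1: [VEG]}), item).value == "A"


class TestBinaryRule:
    def test_variety_needs_three_distinct_fruits(self, primary_codebook):
        item = primary_codebook.item("fruit_variety_weekly")
        three = make_week(
            {1: [("apple", {"fruit"}), ("banana", {"fruit"}), ("orange", {"fruit"})]}
        )
        assert rate_item(three, item).value == 1.0
        repeated = make_week({d: [("apple", {"fruit"})] for d in range(1, 6)})
        assert rate_item(repeated, item).value == 0.0

    def test_relevance_class_distinguishes_zero_from_a(self, primary_codebook):
        item = primary_codebook.item("wholegrain_weekly")
        white_bread_only = make_week({1: [("white roll", {"bread"})]})
        assert rate_item(white_bread_only, item).value == 0.0
        no_starch_at_all = make_week({1: [VEG]})
        assert rate_item(no_starch_at_all, item).value == "A"


class TestWeekAndMenuScores:
    def test_week_meeting_every_criterion_scores_phase_maximum(self):
        for phase, expected in (("primary", 22.0), ("secondary", 28.0)):
            cycle = ideal_menu(phase, n_weeks=1, seed=0)
            sheet = score_week(cycle.weeks[0], default_codebook(phase), cycle)
            assert sheet.week_total == expected

    def test_all_absent_week_scores_zero(self):
        # a codebook without prohibition credits: an empty week is all-'A'
        cb = Codebook(
            phase="primary",
            declared_max=3.0,
            items=[
                simple_item("a", "binary", required=("fruit",)),
                simple_item("b", "per_day", required=("vegetable",)),
                simple_item("c", "limit", required=("red_meat",), limit_max=1),
            ],
        )
        sheet = score_week(make_week({}), cb)
        assert all(r.value == "A" for r in sheet.ratings)
        assert sheet.week_total == 0.0

    def test_empty_week_on_default_instrument_scores_only_prohibitions(
        self, primary_codebook
    ):
        # absence satisfies the three HFSS prohibitions; everything else is 'A'
        sheet = score_week(make_week({}), primary_codebook)
        numeric = {r.item_id: r.value for r in sheet.ratings if r.value != "A"}
        assert numeric == {
            "no_confectionery_or_crisps": 1.0,
            "sweet_snacks_compliant": 1.0,
            "no_free_salt": 1.0,
        }
        assert sheet.week_total == 3.0

    def test_healthiness_is_mean_of_week_totals(self):
        cb = Codebook(
            phase="primary", declared_max=1.0,
            items=[simple_item("veg", "per_day", required=("vegetable",))],
        )
        weeks = [
            make_week({d: [VEG] for d in range(1, n + 1)}, week_index=i + 1)
            for i, n in enumerate([1, 3, 5])
        ]
        score = score_menu(make_cycle(weeks), cb)
        assert [s.week_total for s in score.week_sheets] == [0.2, 0.6, 1.0]
        assert score.healthiness_score == pytest.approx(0.6)

    def test_final_rounding_is_half_up_after_averaging(self):
        cb = Codebook(
            phase="primary", declared_max=1.0,
            items=[simple_item("veg", "per_day", required=("vegetable",))],
        )
        # week totals 0.2 and 0.4 on a 2-week cycle -> mean 0.3 exactly;
        # 0.2/0.6 -> 0.4; 1.0/0.2/0.2 -> mean 7/15 = 0.4666... -> 0.5
        weeks = [
            make_week({d: [VEG] for d in range(1, n + 1)}, week_index=i + 1)
            for i, n in enumerate([5, 1, 1])
        ]
        score = score_menu(make_cycle(weeks), cb)
        assert score.healthiness_score == 0.5

    def test_perfect_three_week_primary_cycle_scores_22(self, primary_codebook):
        score = score_menu(ideal_menu("primary", 3, seed=2), primary_codebook)
        assert score.healthiness_score == 22.0
        assert not score.anomaly

    def test_empty_provision_is_an_error(self, primary_codebook):
        cycle = make_cycle([])
        with pytest.raises(EmptyProvisionError):
            score_menu(cycle, primary_codebook)


class TestPricesOnlyAnomaly:
    def test_price_list_only_scores_low_and_flags_anomaly(self, secondary_codebook):
        prices = PriceList(
            entries=[
                PriceEntry(name="slice of toast", category_tag="bread", price=35),
                PriceEntry(name="flapjack", category_tag="hfss_sweet_snack", price=92),
            ]
        )
        cycle = make_cycle([], subgroup="school_secondary", price_list=prices)
        score = score_menu(cycle, secondary_codebook)
        assert score.anomaly
        # hand-derived: bread_available 1; starch-daily 1 of 5 days = 0.2;
        # wholegrain mentioned-but-absent 0; confectionery+salt prohibitions 1+1;
        # sweet snacks fail 0; everything else 'A'
        assert score.healthiness_score == pytest.approx(3.2)


class TestAggregation:
    @staticmethod
    def _ms(value: float, anomaly: bool = False, subgroup: str = "LA_secondary"):
        return MenuScore(
            provision_id=f"p{value}", subgroup=subgroup, healthiness_score=value,
            week_sheets=[], anomaly=anomaly, completeness="full",
        )

    def test_anomalies_excluded_from_mean(self):
        table = aggregate_subgroup([self._ms(10), self._ms(12), self._ms(3, True)])
        row = table.loc["LA_secondary"]
        assert row["mean"] == pytest.approx(11.0)
        assert row["n_included"] == 2
        assert row["n_anomalies"] == 1
        assert row["anomaly_scores"] == [3]

    def test_single_score_has_no_sd(self):
        row = aggregate_subgroup([self._ms(15)]).loc["LA_secondary"]
        assert row["mean"] == 15
        assert math.isnan(row["sd"])

    def test_constant_scores_have_zero_sd(self):
        row = aggregate_subgroup([self._ms(10)] * 3).loc["LA_secondary"]
        assert row["sd"] == 0.0

    def test_all_anomalous_subgroup_reports_absent_mean(self):
        row = aggregate_subgroup([self._ms(3, True)]).loc["LA_secondary"]
        assert row["n_included"] == 0
        assert math.isnan(row["mean"])


class TestSampleFrame:
    def test_pan_region_population_and_coverage(self):
        # 22 LAs x 2 phases + 60 school-organised = 104; 22 unlocatable -> 82
        frame = SampleFrame(n_las=22, n_school_organised=60, n_unlocatable=22)
        assert frame.population == study_population(22, 60) == 104
        assert frame.n_analysed == 82
        assert frame.coverage == coverage_percent(82, 104) == 79


# ---------------------------------------------------------------------------
# Properties

@given(seed=st.integers(min_value=0, max_value=10**6))
@settings(max_examples=40, deadline=None)
def test_scores_bounded_by_codebook_maximum(seed):
    phase = "secondary" if seed % 2 else "primary"
    cb = default_codebook(phase)
    cycle = generate_menu(
        MenuGenParams(seed=seed, phase=phase, n_weeks=1 + seed % 3,
                      default_pass_prob=(seed % 10) / 10, absence_prob=0.2)
    )
    score = score_menu(cycle, cb)
    assert 0.0 <= score.healthiness_score <= cb.declared_max
    for sheet in score.week_sheets:
        assert Fraction(0) <= sheet.week_total_exact <= Fraction(str(cb.declared_max))


@given(seed=st.integers(min_value=0, max_value=10**6))
@settings(max_examples=25, deadline=None)
def test_adding_a_satisfying_day_never_decreases_score(seed):
    """One extra vegetable day can only raise (or keep) the healthiness score."""
    cb = default_codebook("primary")
    cycle = generate_menu(
        MenuGenParams(seed=seed, phase="primary", n_weeks=2, default_pass_prob=0.5)
    )
    before = score_menu(cycle, cb).healthiness_score
    grown = cycle.model_copy(deep=True)
    for week in grown.weeks:
        for day in week.days:
            if not any(
                o.tags & {"vegetable", "salad"} and o.slot == "lunch"
                for o in day.offerings
            ):
                day.offerings.append(
                    Offering(name="carrots", tags={"vegetable"}, slot="lunch")
                )
                assert score_menu(grown, cb).healthiness_score >= before
                return


# ---------------------------------------------------------------------------
# Brute-force oracle on tiny cycles

def _oracle_rate(cycle, week, item):
    """First-principles re-derivation, written independently of the engine."""
    def offerings_in(wk):
        out = []
        for day in wk.days:
            for off in day.offerings:
                if item.slot is None or off.slot == item.slot:
                    out.append((day.day_index, off))
        return out

    req = set(item.required_tags)
    rel = set(item.relevance_tags) if item.relevance_tags else req
    kind = item.rule.kind

    if kind == "frequency_per_period":
        everything = [(w.week_index, d, o) for w in cycle.weeks for d, o in offerings_in(w)]
        if not [o for _, _, o in everything if o.tags & rel]:
            return "A"
        occasions = {(wi, d) for wi, d, o in everything if o.tags & req}
        goal = math.ceil(item.rule.threshold * len(cycle.weeks) / item.rule.period_weeks)
        return 1.0 if len(occasions) >= max(1, goal) else 0.0

    scope = offerings_in(week)
    if item.slot in ("breakfast", "break"):
        mentioned = len(scope) > 0
    else:
        mentioned = any(o.tags & rel for _, o in scope)
    if kind == "binary":
        if not mentioned:
            return "A"
        names = {" ".join(o.name.lower().split()) for _, o in scope if o.tags & req}
        return 1.0 if len(names) >= item.rule.min_distinct else 0.0
    if kind == "per_day":
        if not mentioned:
            return "A"
        return len({d for d, o in scope if o.tags & req}) / 5
    if kind == "limit":
        if not mentioned:
            if item.slot in ("breakfast", "break"):
                return "A"
            return 1.0 if item.rule.absence_credit else "A"
        days = len({d for d, o in scope if o.tags & req})
        return 1.0 if days <= item.rule.limit_max else 0.0
    raise AssertionError(kind)


@given(seed=st.integers(min_value=0, max_value=10**6))
@settings(max_examples=30, deadline=None)
def test_engine_matches_brute_force_oracle_on_small_cycles(seed):
    items = [
        simple_item("veg_days", "per_day", required=("vegetable", "salad")),
        simple_item(
            "oily", "frequency_per_period", required=("oily_fish",),
            relevance=("fish", "oily_fish"), threshold=2, period_weeks=4,
        ),
        simple_item("red_limit", "limit", required=("red_meat",), limit_max=2),
    ]
    cycle = generate_menu(
        MenuGenParams(seed=seed, phase="primary", n_weeks=1 + seed % 2,
                      default_pass_prob=0.5, absence_prob=0.3)
    )
    for week in cycle.weeks:
        for item in items:
            got = rate_item(week, item, cycle).value
            want = _oracle_rate(cycle, week, item)
            if want == "A":
                assert got == "A", item.item_id
            else:
                assert got == pytest.approx(want), item.item_id
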