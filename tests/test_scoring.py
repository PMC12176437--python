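"""Scoring: component rules, totals, dichotomization, and rule invariants."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from guia_adherence.scoring import (
    IDEAL_MODEL,
    POSSIBLE_MODEL,
    UPF_ITEMS,
    WEEKLY_MARKERS,
    MarkerProfile,
    ScoringModel,
    dichotomize,
    score_both_variants,
    score_component,
    score_distribution,
    score_records,
    total_score,
    upf_daily_sum,
)


# --- independent brute-force oracle ---------------------------------------
# A literal transcription of the two published threshold columns, written
# without the rule machinery: used to cross-check the declarative models.
def oracle_totals(p: MarkerProfile) -> tuple[int, int]:
    upf = sum(p.upf_yesterday)
    ideal = (
        (p.beans_days == 7)
        + (p.fruit_days == 7)
        + (p.vegetables_days == 7)
        + (p.soda_days == 0)
        + (p.sweets_days == 0)
        + (upf == 0)
        + (p.breakfast_days == 7)
        + (p.family_meal_days == 7)
        + (p.screen_eating_days == 0)
        + (p.fastfood_days == 0)
    )
    possible = (
        (p.beans_days == 7)
        + (p.fruit_days == 7)
        + (p.vegetables_days == 7)
        + (p.soda_days <= 2)
        + (p.sweets_days <= 2)
        + (upf <= 3)
        + (p.breakfast_days == 7)
        + (p.family_meal_days == 7)
        + (p.screen_eating_days <= 2)
        + (p.fastfood_days <= 2)
    )
    return int(ideal), int(possible)


def random_profile(rng: np.random.Generator) -> MarkerProfile:
    days = rng.integers(0, 8, len(WEEKLY_MARKERS))
    flags = tuple(int(v) for v in rng.integers(0, 2, len(UPF_ITEMS)))
    return MarkerProfile(*map(int, days), upf_yesterday=flags)


def profile(upf_count=0, **overrides) -> MarkerProfile:
    """Profile meeting every ideal rule unless overridden."""
    base = dict(
        beans_days=7, fruit_days=7, vegetables_days=7, soda_days=0, sweets_days=0,
        breakfast_days=7, family_meal_days=7, screen_eating_days=0, fastfood_days=0,
    )
    base.update(overrides)
    flags = tuple(1 if i < upf_count else 0 for i in range(len(UPF_ITEMS)))
    return MarkerProfile(**base, upf_yesterday=flags)


class TestUpfDailySum:
    @pytest.mark.parametrize(
        "flags, expected",
        [
            ((0,) * 13, 0),
            ((1,) * 13, 13),
            ((1, 0, 0, 0, 0, 0, 0, 0, 0, 0, 1, 0, 0), 2),  # soda + margarine
        ],
    )
    def test_counts_yes_flags(self, flags, expected):
        assert upf_daily_sum(flags) == expected

    def test_missing_flag_propagates(self):
        assert upf_daily_sum((1,) * 12 + (None,)) is None

    def test_wrong_flag_count_is_fatal(self):
        with pytest.raises(ValueError):
            upf_daily_sum((0,) * 12)


class TestComponentRules:
    def test_daily_beans_scores_in_both_variants(self):
        p = profile()
        for model in (IDEAL_MODEL, POSSIBLE_MODEL):
            assert score_component(p, model.rule("1.1")) == 1

    def test_soda_twice_a_week_meets_only_the_possible_rule(self):
        p = profile(soda_days=2)
        assert score_component(p, IDEAL_MODEL.rule("2.1")) == 0
        assert score_component(p, POSSIBLE_MODEL.rule("2.1")) == 1

    def test_upf_sum_three_meets_only_the_possible_cutoff(self):
        p = profile(upf_count=3)
        assert score_component(p, POSSIBLE_MODEL.rule("2.3")) == 1
        assert score_component(p, IDEAL_MODEL.rule("2.3")) == 0

    def test_missing_marker_propagates(self):
        p = profile(soda_days=None)
        assert score_component(p, IDEAL_MODEL.rule("2.1")) is None


class TestTotalScore:
    def test_all_ideal_thresholds_met_scores_ten_in_both_variants(self):
        p = profile()
        assert total_score(p, IDEAL_MODEL).total == 10
        assert total_score(p, POSSIBLE_MODEL).total == 10

    def test_possible_thresholds_only(self):
        # at every possible cutoff but no ideal cutoff for the 5 tolerance items
        p = profile(
            soda_days=2, sweets_days=2, screen_eating_days=2, fastfood_days=2,
            upf_count=3,
        )
        assert total_score(p, POSSIBLE_MODEL).total == 10
        assert total_score(p, IDEAL_MODEL).total == 5

    def test_daily_soda_and_sweets_lose_two_points_in_both_variants(self):
        p = profile(soda_days=7, sweets_days=7)
        assert total_score(p, IDEAL_MODEL).total == 8
        assert total_score(p, POSSIBLE_MODEL).total == 8

    def test_any_missing_component_invalidates(self):
        res = total_score(profile(fruit_days=None), POSSIBLE_MODEL)
        assert not res.valid and res.total is None


class TestDichotomize:
    @pytest.mark.parametrize("total, expected", [(10, 1), (9, 0), (0, 0)])
    def test_greater_adherence_is_exactly_ten(self, total, expected):
        assert dichotomize(total) == expected

    def test_out_of_range_total_rejected(self):
        with pytest.raises(ValueError):
            dichotomize(11)


class TestOracleEquivalence:
    def test_ten_thousand_random_profiles_match_brute_force(self):
        rng = np.random.default_rng(0)
        for _ in range(10_000):
            p = random_profile(rng)
            ideal, possible = oracle_totals(p)
            assert total_score(p, IDEAL_MODEL).total == ideal
            assert total_score(p, POSSIBLE_MODEL).total == possible
            assert ideal <= possible


days = st.integers(0, 7)
flags13 = st.tuples(*([st.integers(0, 1)] * 13))


@given(days, days, days, days, days, days, days, days, days, flags13)
def test_ideal_never_exceeds_possible(b, f, v, s, sw, br, fm, sc, ff, upf):
    p = MarkerProfile(b, f, v, s, sw, br, fm, sc, ff, upf_yesterday=upf)
    assert total_score(p, IDEAL_MODEL).total <= total_score(p, POSSIBLE_MODEL).total


@given(days, days, days, days, days, days, days, days, days, flags13, st.integers(0, 12))
def test_dropping_a_upf_item_never_lowers_either_total(
    b, f, v, s, sw, br, fm, sc, ff, upf, idx
):
    p = MarkerProfile(b, f, v, s, sw, br, fm, sc, ff, upf_yesterday=upf)
    lowered = upf[:idx] + (0,) + upf[idx + 1 :]
    q = MarkerProfile(b, f, v, s, sw, br, fm, sc, ff, upf_yesterday=lowered)
    for model in (IDEAL_MODEL, POSSIBLE_MODEL):
        assert total_score(q, model).total >= total_score(p, model).total


@given(days, days, days, days, days, days, days, days, days, flags13, st.randoms())
def test_component_order_never_affects_the_total(
    b, f, v, s, sw, br, fm, sc, ff, upf, rand
):
    p = MarkerProfile(b, f, v, s, sw, br, fm, sc, ff, upf_yesterday=upf)
    rules = list(POSSIBLE_MODEL.rules)
    rand.shuffle(rules)
    shuffled = ScoringModel(
        "possible", tuple(sorted(rules, key=lambda r: r.component_id))
    )
    assert total_score(p, shuffled).total == total_score(p, POSSIBLE_MODEL).total


class TestVectorizedScoring:
    def test_frame_scoring_matches_profile_scoring(self):
        rng = np.random.default_rng(5)
        profiles = [random_profile(rng) for _ in range(300)]
        df = pd.DataFrame(
            [
                {m: getattr(p, m) for m in WEEKLY_MARKERS}
                | dict(zip(UPF_ITEMS, p.upf_yesterday))
                for p in profiles
            ]
        ).astype("Int64")
        both = score_both_variants(df)
        for i, p in enumerate(profiles):
            assert both.loc[i, "score_ideal"] == total_score(p, IDEAL_MODEL).total
            assert both.loc[i, "score_possible"] == total_score(p, POSSIBLE_MODEL).total

    def test_missing_cell_invalidates_row(self):
        df = pd.DataFrame(
            [{m: 7 for m in WEEKLY_MARKERS} | {u: 0 for u in UPF_ITEMS}] * 2
        ).astype("Int64")
        df.loc[1, "upf_margarine"] = pd.NA
        out = score_records(df, POSSIBLE_MODEL)
        assert out.loc[0, "score_valid"] and not out.loc[1, "score_valid"]
        assert pd.isna(out.loc[1, "total"])

    def test_upf_threshold_override(self):
        df = pd.DataFrame(
            [
                {m: 7 for m in WEEKLY_MARKERS}
                | {u: (1 if i < 5 else 0) for i, u in enumerate(UPF_ITEMS)}
            ]
        ).astype("Int64")
        strict = score_records(df, POSSIBLE_MODEL)
        relaxed = score_records(df, POSSIBLE_MODEL.with_upf_threshold(5))
        assert relaxed.loc[0, "total"] == strict.loc[0, "total"] + 1


class TestScoreDistribution:
    def test_identical_records_pile_on_one_level(self):
        assert score_distribution([10] * 5).loc[10] == 5

    def test_empty_set_gives_all_zero_counts(self):
        counts = score_distribution([])
        assert list(counts.index) == list(range(11)) and counts.sum() == 0

    def test_mixed_hand_tally(self):
        totals = [0, 0, 3, 7, 10, None]
        counts = score_distribution(totals)
        assert counts.loc[0] == 2 and counts.loc[3] == 1
        assert counts.loc[7] == 1 and counts.loc[10] == 1
        assert counts.sum() == 5  # the None record is excluded
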