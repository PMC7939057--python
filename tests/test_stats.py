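"""The disparity engine: contingency tables, ORs, CIs, chi-square."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tweetsurvey import (
    ContingencyTable,
    GroupSpec,
    attention_ratio,
    build_table,
    chi_square,
    emotion_or,
    group_sentiment,
    odds_ratio,
    or_result,
    run_analysis_suite,
    wald_ci,
)
from tweetsurvey.stats import EmptyStratumError, ZeroCellError, default_reference


def hand_chi2(a, b, c, d):
    """Independent 2x2 oracle: n(ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)).

    Arbitrary-precision integers throughout; the cross-product square
    overflows 64-bit arithmetic for cell counts in the 1e5 range.
    """
    a, b, c, d = int(a), int(b), int(c), int(d)
    n = a + b + c + d
    return n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))


def _frame(rows):
    df = pd.DataFrame(rows)
    for t in ("economics", "health", "politics", "education", "entertainment"):
        if f"concern_{t}" not in df.columns:
            df[f"concern_{t}"] = False
    return df


@pytest.fixture()
def four_record_frame():
    return _frame([
        {"user_type": "organization", "gender": None, "age_group": None,
         "covid": True, "polarity": 0.2, "sentiment_bin": "positive"},
        {"user_type": "organization", "gender": None, "age_group": None,
         "covid": False, "polarity": 0.0, "sentiment_bin": "neutral"},
        {"user_type": "person", "gender": "male", "age_group": "<=18",
         "covid": False, "polarity": -0.1, "sentiment_bin": "negative"},
        {"user_type": "person", "gender": "female", "age_group": "19-29",
         "covid": False, "polarity": 0.3, "sentiment_bin": "positive"},
    ])


# ---------------------------------------------------------------------------
# contingency tables

def test_build_table_manual_count(four_record_frame):
    t = build_table(
        four_record_frame,
        GroupSpec({"user_type": "organization"}),
        GroupSpec({"user_type": "person"}),
    )
    assert t.cells == (1, 1, 0, 2)


def test_build_table_conserves_counts(four_record_frame):
    t = build_table(four_record_frame, GroupSpec({"user_type": "organization"}), "rest")
    assert sum(t.cells) == len(four_record_frame)


def test_identical_group_and_reference_rejected(four_record_frame):
    g = GroupSpec({"user_type": "person"})
    with pytest.raises(ValueError, match="overlap"):
        build_table(four_record_frame, g, GroupSpec({"user_type": "person"}))


def test_empty_stratum_raises(four_record_frame):
    with pytest.raises(EmptyStratumError):
        build_table(
            four_record_frame,
            GroupSpec({"gender": "female", "age_group": ">=40"}),
            "rest",
        )


def test_groupspec_needs_one_to_three_conditions():
    with pytest.raises(ValueError):
        GroupSpec({})
    with pytest.raises(ValueError):
        GroupSpec({"user_type": "person", "gender": "male",
                   "age_group": "<=18", "concern": "health"})
    with pytest.raises(ValueError):
        GroupSpec({"nonsense": "x"})


# ---------------------------------------------------------------------------
# odds ratio and Wald CI

def test_odds_ratio_reproduces_user_type_contrast():
    t = ContingencyTable(7347, 94828, 19869, 893611)
    assert round(odds_ratio(t), 2) == 3.48
    lo, hi = wald_ci(t)
    assert (round(lo, 2), round(hi, 2)) == (3.39, 3.58)


def test_odds_ratio_trivial_cases():
    assert odds_ratio(ContingencyTable(5, 5, 5, 5)) == 1.0
    assert odds_ratio(ContingencyTable(2, 8, 1, 9)) == pytest.approx(2.25)


def test_wald_ci_contains_point_estimate_symmetric_table():
    t = ContingencyTable(5, 5, 5, 5)
    lo, hi = wald_ci(t)
    assert lo < 1.0 < hi


def test_zero_cell_raises_unless_corrected():
    t = ContingencyTable(0, 10, 5, 5)
    with pytest.raises(ZeroCellError, match="a"):
        odds_ratio(t)
    res = or_result(t, corrected=True)
    assert res.corrected is True
    assert res.or_estimate == pytest.approx((0.5 * 5.5) / (10.5 * 5.5))


def test_or_result_invariants():
    res = or_result(ContingencyTable(20, 80, 10, 90))
    assert res.ci_low <= res.or_estimate <= res.ci_high
    assert 0.0 <= res.p_value <= 1.0
    assert res.corrected is False


@settings(max_examples=150, deadline=None)
@given(st.tuples(*[st.integers(min_value=1, max_value=5000)] * 4))
def test_or_inversion_symmetry(cells):
    """Swapping group and reference rows inverts the OR exactly."""
    a, b, c, d = cells
    t = ContingencyTable(a, b, c, d)
    swapped = ContingencyTable(c, d, a, b)
    assert odds_ratio(t) * odds_ratio(swapped) == pytest.approx(1.0, rel=1e-12)


@settings(max_examples=150, deadline=None)
@given(
    st.tuples(*[st.integers(min_value=1, max_value=2000)] * 4),
    st.integers(min_value=2, max_value=50),
)
def test_or_row_scaling_invariance(cells, k):
    """Multiplying one row by a positive integer leaves the OR unchanged."""
    a, b, c, d = cells
    assert odds_ratio(ContingencyTable(a * k, b * k, c, d)) == pytest.approx(
        odds_ratio(ContingencyTable(a, b, c, d)), rel=1e-12
    )


@settings(max_examples=100, deadline=None)
@given(st.tuples(*[st.integers(min_value=1, max_value=1000)] * 4),
       st.integers(min_value=2, max_value=20))
def test_ci_shrinks_when_cells_scale_up(cells, k):
    a, b, c, d = cells
    lo1, hi1 = wald_ci(ContingencyTable(a, b, c, d))
    lo2, hi2 = wald_ci(ContingencyTable(a * k, b * k, c * k, d * k))
    assert np.log(hi2) - np.log(lo2) < np.log(hi1) - np.log(lo1)


# ---------------------------------------------------------------------------
# chi-square

def test_chi_square_exact_independence():
    stat, p = chi_square(ContingencyTable(10, 10, 10, 10))
    assert stat == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_chi_square_hand_value():
    stat, _ = chi_square(ContingencyTable(20, 10, 10, 20))
    assert round(stat, 2) == 6.67


def test_chi_square_user_type_table_significant():
    _, p = chi_square(ContingencyTable(7347, 94828, 19869, 893611))
    assert p < 0.001


def test_chi_square_rejects_degenerate_tables():
    with pytest.raises(ValueError):
        chi_square(np.zeros((2, 2)))
    with pytest.raises(ValueError):
        chi_square(np.array([[0, 0], [5, 5]]))


@settings(max_examples=300, deadline=None)
@given(st.tuples(*[st.integers(min_value=1, max_value=10000)] * 4))
def test_chi_square_matches_hand_formula(cells):
    """Oracle equivalence with the closed-form 2x2 Pearson statistic."""
    a, b, c, d = cells
    stat, _ = chi_square(ContingencyTable(a, b, c, d))
    assert stat == pytest.approx(hand_chi2(a, b, c, d), abs=1e-9, rel=1e-9)


def test_chi_square_supports_rxc():
    table = np.array([[30, 10], [25, 15], [20, 20]])
    stat, p = chi_square(table)
    # Pearson statistic from expected counts, 2 degrees of freedom
    expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
    assert stat == pytest.approx(((table - expected) ** 2 / expected).sum())
    assert 0 < p < 1


# ---------------------------------------------------------------------------
# ratios, sentiment, emotion ORs

def test_attention_ratio_values(four_record_frame):
    assert attention_ratio(four_record_frame, GroupSpec({"user_type": "organization"})) == 50.0
    assert attention_ratio(four_record_frame, GroupSpec({"user_type": "person"})) == 0.0
    with pytest.raises(EmptyStratumError):
        attention_ratio(four_record_frame, GroupSpec({"age_group": ">=40"}))


def test_group_sentiment_hand_computed():
    polarities = [0.1, 0.2, 0.3, 0.4, 0.5]
    df = _frame([
        {"user_type": "person", "gender": "male", "age_group": "<=18",
         "covid": True, "polarity": p,
         "sentiment_bin": "positive" if p >= 0.05 else "neutral"}
        for p in polarities
    ])
    s = group_sentiment(df, GroupSpec({"user_type": "person"}))
    assert s.n == 5
    assert s.mean == pytest.approx(np.mean(polarities))
    assert s.sd == pytest.approx(round(np.std(polarities, ddof=1), 4))
    assert s.bin_shares["positive"] == 1.0


def test_group_sentiment_constant_and_symmetric():
    df = _frame([
        {"user_type": "person", "gender": "male", "age_group": "<=18",
         "covid": True, "polarity": p, "sentiment_bin": "neutral"}
        for p in (-0.5, 0.5)
    ])
    s = group_sentiment(df, GroupSpec({"user_type": "person"}))
    assert s.mean == pytest.approx(0.0)


def _emotion_frame():
    rows = []
    for i in range(40):
        org = i % 4 == 0
        fear = (i % 8 == 0) if org else (i % 5 == 0)
        rows.append({
            "user_type": "organization" if org else "person",
            "gender": None if org else "male",
            "age_group": None if org else "<=18",
            "covid": True, "polarity": 0.0, "sentiment_bin": "neutral",
            "dominant_plutchik8": "fear" if fear else "joy",
        })
    return _frame(rows)


def test_emotion_or_direction_and_symmetry():
    df = _emotion_frame()
    g = GroupSpec({"user_type": "organization"})
    r = GroupSpec({"user_type": "person"})
    res = emotion_or(df, g, "fear", "plutchik8", reference=r)
    swapped = emotion_or(df, r, "fear", "plutchik8", reference=g)
    assert res.or_estimate > 1.0
    assert res.or_estimate * swapped.or_estimate == pytest.approx(1.0, rel=1e-12)


def test_emotion_or_unknown_label_rejected():
    with pytest.raises(ValueError):
        emotion_or(_emotion_frame(), GroupSpec({"user_type": "organization"}),
                   "depression", "plutchik8")


def test_emotion_or_degenerate_outcome_needs_correction():
    df = _emotion_frame().assign(dominant_plutchik8="fear")
    g = GroupSpec({"user_type": "organization"})
    with pytest.raises(ZeroCellError):
        emotion_or(df, g, "fear", "plutchik8")
    res = emotion_or(df, g, "fear", "plutchik8", corrected=True)
    assert res.corrected is True


# ---------------------------------------------------------------------------
# the analysis suite

def test_default_reference_is_all_baseline():
    ref = default_reference({"gender": "female", "age_group": ">=40"})
    assert dict(ref.conditions) == {"gender": "male", "age_group": "<=18"}
    ref2 = default_reference({"gender": "female", "concern": "economics"})
    assert dict(ref2.conditions) == {"gender": "male", "concern": "economics"}
    assert default_reference({"gender": "male", "age_group": "<=18"}) is None


def test_suite_trivariate_has_forty_strata(small_sets):
    from tweetsurvey import assemble, records_to_frame

    original, covid = small_sets
    df = records_to_frame(assemble(original, covid))
    suite = run_analysis_suite(df)
    tri = suite[suite.analysis == "trivariate"]
    assert len(tri) == 40
    assert (suite.analysis == "univariate").sum() == 10
    # every stratum is either analyzed or carries an explanatory note
    assert ((tri["or"].notna()) | (tri["note"] != "")).all()


def test_suite_is_deterministic(small_sets):
    from tweetsurvey import assemble, records_to_frame

    original, covid = small_sets
    df = records_to_frame(assemble(original, covid))
    a = run_analysis_suite(df, include=("univariate",))
    b = run_analysis_suite(df, include=("univariate",))
    assert a.to_csv() == b.to_csv()
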