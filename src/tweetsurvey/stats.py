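"""Cross-sectional disparity statistics over questionnaire records.

Groups are 1–3-way crossings of the population variables (user type,
gender, age group, concern topic).  For each group-vs-reference contrast
the engine forms the 2x2 contingency table of COVID attention, and reports
the attention ratio, the odds ratio with its Wald (Woolf) 95% CI on the
log-OR scale, the Pearson chi-square test without continuity correction,
and the group's sentiment summary.  Emotion disparities use the same
machinery with "dominant emotion equals <label>" as the outcome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency, norm

from .annotate import MODEL_LABELS
from .questionnaire import round_half_up
from .records import AGE_GROUPS, GENDERS, TOPICS, USER_TYPES

VARIABLES = ("user_type", "gender", "age_group", "concern")

# Reference levels of the univariate contrasts: persons, males, youngest.
BASELINE = {"user_type": "person", "gender": "male", "age_group": "<=18"}


class EmptyStratumError(ValueError):
    """A group or reference selects no records."""


class ZeroCellError(ValueError):
    """A 2x2 margin contains a zero cell and no correction was requested."""


@dataclass(frozen=True)
class GroupSpec:
    """1–3 variable conditions selecting a population group.

    Conditions map a variable to a required level; ``concern`` conditions
    require the named topic flag (topics are non-exclusive).
    """

    conditions: tuple[tuple[str, str], ...]

    def __init__(self, conditions: Mapping[str, str] | Iterable[tuple[str, str]]):
        items = tuple(sorted(dict(conditions).items()))
        if not 1 <= len(items) <= 3:
            raise ValueError("GroupSpec needs 1-3 conditions")
        for var, level in items:
            if var not in VARIABLES:
                raise ValueError(f"unknown variable {var!r}")
        object.__setattr__(self, "conditions", items)

    def mask(self, df: pd.DataFrame) -> pd.Series:
        m = pd.Series(True, index=df.index)
        for var, level in self.conditions:
            if var == "concern":
                m &= df[f"concern_{level}"].astype(bool)
            else:
                m &= df[var] == level
        return m

    def __str__(self) -> str:
        return " & ".join(f"{v}={l}" for v, l in self.conditions)


@dataclass
class ContingencyTable:
    """2x2 counts: rows group/reference, columns outcome yes/no."""

    a: int  # group, outcome
    b: int  # group, no outcome
    c: int  # reference, outcome
    d: int  # reference, no outcome
    group: str = "group"
    reference: str = "reference"
    outcome: str = "covid"

    def __post_init__(self) -> None:
        for name in "abcd":
            if getattr(self, name) < 0:
                raise ValueError(f"cell {name} is negative")

    @property
    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)

    def zero_cells(self) -> list[str]:
        return [name for name in "abcd" if getattr(self, name) == 0]


@dataclass
class ORResult:
    or_estimate: float
    ci_low: float
    ci_high: float
    alpha: float
    chi2: float
    p_value: float
    group: str
    reference: str
    corrected: bool = False
    table: ContingencyTable | None = field(default=None, repr=False)


def _reference_mask(df: pd.DataFrame, group: GroupSpec, reference) -> tuple[pd.Series, str]:
    gm = group.mask(df)
    if reference == "rest" or reference is None:
        return ~gm, "rest"
    rm = reference.mask(df)
    if (gm & rm).any():
        raise ValueError(
            f"group ({group}) and reference ({reference}) overlap; "
            "they must select disjoint record sets"
        )
    return rm, str(reference)


def build_table(
    df: pd.DataFrame,
    group: GroupSpec,
    reference="rest",
    outcome: str = "covid",
) -> ContingencyTable:
    """2x2 group/reference x outcome counts from the analysis frame."""
    gm = group.mask(df)
    rm, ref_name = _reference_mask(df, group, reference)
    if not gm.any():
        raise EmptyStratumError(f"empty stratum: group {group}")
    if not rm.any():
        raise EmptyStratumError(f"empty stratum: reference {ref_name}")
    out = df[outcome].astype(bool)
    return ContingencyTable(
        a=int((gm & out).sum()),
        b=int((gm & ~out).sum()),
        c=int((rm & out).sum()),
        d=int((rm & ~out).sum()),
        group=str(group),
        reference=ref_name,
        outcome=outcome,
    )


def _adjusted(t: ContingencyTable, corrected: bool) -> tuple[float, float, float, float, bool]:
    zeros = t.zero_cells()
    if zeros and not corrected:
        raise ZeroCellError(
            f"zero cell(s) {zeros} in 2x2 table {t.cells}; "
            "enable the 0.5 correction to proceed"
        )
    if zeros:
        # Haldane–Anscombe: add 0.5 to every cell when any cell is empty.
        return t.a + 0.5, t.b + 0.5, t.c + 0.5, t.d + 0.5, True
    return float(t.a), float(t.b), float(t.c), float(t.d), False


def odds_ratio(t: ContingencyTable, corrected: bool = False) -> float:
    """Cross-product ratio (a*d)/(b*c)."""
    a, b, c, d, _ = _adjusted(t, corrected)
    return (a * d) / (b * c)


def wald_ci(
    t: ContingencyTable, alpha: float = 0.05, corrected: bool = False
) -> tuple[float, float]:
    """Woolf interval: exp(ln OR +/- z * sqrt(1/a + 1/b + 1/c + 1/d))."""
    a, b, c, d, _ = _adjusted(t, corrected)
    log_or = math.log((a * d) / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = norm.ppf(1 - alpha / 2)
    return math.exp(log_or - z * se), math.exp(log_or + z * se)


def chi_square(table) -> tuple[float, float]:
    """Pearson chi-square of independence, no continuity correction.

    Accepts a ContingencyTable or any R x C array of counts; degrees of
    freedom are (R-1)(C-1).
    """
    if isinstance(table, ContingencyTable):
        arr = np.array([[table.a, table.b], [table.c, table.d]], dtype=float)
    else:
        arr = np.asarray(table, dtype=float)
    if arr.sum() == 0:
        raise ValueError("chi_square: empty table")
    expected = np.outer(arr.sum(axis=1), arr.sum(axis=0)) / arr.sum()
    if (expected <= 0).any():
        raise ValueError("chi_square: zero expected count")
    stat, p, _, _ = chi2_contingency(arr, correction=False)
    return float(stat), float(p)


def or_result(
    t: ContingencyTable, alpha: float = 0.05, corrected: bool = False
) -> ORResult:
    a, b, c, d, was_corrected = _adjusted(t, corrected)
    est = (a * d) / (b * c)
    lo, hi = wald_ci(t, alpha, corrected)
    try:
        stat, p = chi_square(t)
    except ValueError:
        stat, p = float("nan"), float("nan")
    return ORResult(
        or_estimate=est, ci_low=lo, ci_high=hi, alpha=alpha,
        chi2=stat, p_value=p, group=t.group, reference=t.reference,
        corrected=was_corrected, table=t,
    )


def attention_ratio(df: pd.DataFrame, group: GroupSpec) -> float:
    """Percentage of the group's tweets that are COVID-related (2 dp)."""
    gm = group.mask(df)
    n = int(gm.sum())
    if n == 0:
        raise EmptyStratumError(f"empty stratum: group {group}")
    return round_half_up(100.0 * int((gm & df["covid"]).sum()) / n, 2)


@dataclass
class GroupSentiment:
    n: int
    mean: float
    sd: float
    bin_shares: dict[str, float]


def group_sentiment(
    df: pd.DataFrame, group: GroupSpec, subset: str = "covid"
) -> GroupSentiment:
    """Sentiment summary (4 dp) over the group's COVID-related records.

    ``subset="all"`` summarizes the group's full record set instead.
    """
    gm = group.mask(df)
    if subset == "covid":
        gm &= df["covid"].astype(bool)
    sub = df[gm]
    if sub.empty:
        raise EmptyStratumError(f"empty stratum: group {group} (subset={subset})")
    shares = sub["sentiment_bin"].value_counts(normalize=True)
    return GroupSentiment(
        n=len(sub),
        mean=round_half_up(sub["polarity"].mean(), 4),
        sd=round_half_up(sub["polarity"].std(ddof=1), 4) if len(sub) > 1 else 0.0,
        bin_shares={b: float(shares.get(b, 0.0)) for b in ("negative", "neutral", "positive")},
    )


def emotion_or(
    df: pd.DataFrame,
    group: GroupSpec,
    emotion: str,
    model: str,
    reference="rest",
    subset: str = "covid",
    alpha: float = 0.05,
    corrected: bool = False,
) -> ORResult:
    """OR of expressing ``emotion`` as the dominant emotion, group vs reference.

    Computed over COVID-related records by default (the emotion disparity
    analysis concerns pandemic-related tweets).
    """
    if emotion not in MODEL_LABELS[model]:
        raise ValueError(f"{emotion!r} is not a label of model {model!r}")
    sub = df[df["covid"]] if subset == "covid" else df
    work = sub.assign(_outcome=sub[f"dominant_{model}"] == emotion)
    t = build_table(work, group, reference, outcome="_outcome")
    t.outcome = f"dominant_{model}=={emotion}"
    res = or_result(t, alpha=alpha, corrected=corrected)
    return res


def default_reference(conditions: Mapping[str, str]) -> GroupSpec | None:
    """All-baseline reference cell: swap every non-concern condition to its
    baseline level, keep the topic fixed.  None when the group already is
    the baseline cell."""
    ref = {
        var: (level if var == "concern" else BASELINE[var])
        for var, level in dict(conditions).items()
    }
    if ref == dict(conditions):
        return None
    return GroupSpec(ref)


def _levels(var: str) -> tuple[str, ...]:
    return {
        "user_type": USER_TYPES,
        "gender": GENDERS,
        "age_group": AGE_GROUPS,
        "concern": TOPICS,
    }[var]


def _suite_row(df, analysis, conditions, reference, alpha, corrected) -> dict:
    group = GroupSpec(conditions)
    row: dict = {
        "analysis": analysis,
        "conditions": str(group),
        "reference": "" if reference is None else str(reference),
        "note": "",
    }
    gm = group.mask(df)
    row["n_group"] = int(gm.sum())
    row["n_covid"] = int((gm & df["covid"]).sum())
    if row["n_group"] == 0:
        row["note"] = "skipped: empty stratum"
        return row
    row["ratio"] = attention_ratio(df, group)
    try:
        sent = group_sentiment(df, group)
        row["mean_polarity"] = sent.mean
        row["sd_polarity"] = sent.sd
    except EmptyStratumError:
        row["mean_polarity"] = np.nan
        row["sd_polarity"] = np.nan
    if reference is None:
        row["note"] = "reference stratum"
        return row
    try:
        t = build_table(df, group, reference)
        res = or_result(t, alpha=alpha, corrected=corrected)
    except (EmptyStratumError, ZeroCellError, ValueError) as exc:
        row["note"] = f"skipped: {exc}"
        return row
    row["or"] = round_half_up(res.or_estimate, 2)
    row["ci_low"] = round_half_up(res.ci_low, 2)
    row["ci_high"] = round_half_up(res.ci_high, 2)
    row["chi2"] = round_half_up(res.chi2, 2)
    row["p"] = res.p_value
    return row


def run_analysis_suite(
    df: pd.DataFrame,
    include: tuple[str, ...] = ("univariate", "bivariate", "trivariate"),
    alpha: float = 0.05,
    corrected: bool = False,
) -> pd.DataFrame:
    """The full disparity battery over an analysis frame.

    Univariate: organization vs person, female vs male, each age group vs
    the youngest, each topic vs the rest.  Bivariate: every pair of
    variables, each level combination against the all-baseline cell.
    Trivariate: gender x age x topic (40 combinations, persons only by
    construction since organizations carry no gender/age).  Strata failing
    preconditions are reported with a note, never fatal.
    """
    rows: list[dict] = []

    if "univariate" in include:
        rows.append(_suite_row(
            df, "univariate", {"user_type": "organization"},
            GroupSpec({"user_type": "person"}), alpha, corrected))
        rows.append(_suite_row(
            df, "univariate", {"gender": "female"},
            GroupSpec({"gender": "male"}), alpha, corrected))
        for age in AGE_GROUPS[1:]:
            rows.append(_suite_row(
                df, "univariate", {"age_group": age},
                GroupSpec({"age_group": "<=18"}), alpha, corrected))
        for topic in TOPICS:
            rows.append(_suite_row(
                df, "univariate", {"concern": topic}, "rest", alpha, corrected))

    if "bivariate" in include:
        for v1, v2 in combinations(VARIABLES, 2):
            for l1 in _levels(v1):
                for l2 in _levels(v2):
                    conditions = {v1: l1, v2: l2}
                    rows.append(_suite_row(
                        df, "bivariate", conditions,
                        default_reference(conditions), alpha, corrected))

    if "trivariate" in include:
        for gender in GENDERS:
            for age in AGE_GROUPS:
                for topic in TOPICS:
                    conditions = {"gender": gender, "age_group": age, "concern": topic}
                    rows.append(_suite_row(
                        df, "trivariate", conditions,
                        default_reference(conditions), alpha, corrected))

    out = pd.DataFrame(rows)
    cols = [
        "analysis", "conditions", "reference", "n_group", "n_covid", "ratio",
        "or", "ci_low", "ci_high", "chi2", "p", "mean_polarity", "sd_polarity",
        "note",
    ]
    for c in cols:
        if c not in out.columns:
            out[c] = np.nan
    return out[cols]
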