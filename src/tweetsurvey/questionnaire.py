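"""Assemble filtered, annotated tweets into cross-sectional questionnaire
records, and summarize their marginal distributions.

Each retained tweet becomes one completed "questionnaire": population
characteristics (user type, gender, age group), concern flags for the five
life domains, a COVID-attention flag, sentiment polarity with its bin, and
three emotion intensity vectors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from . import annotate as ann
from .annotate import (
    ContractViolation,
    Demographics,
    EmotionVector,
    SentimentScore,
    dominant_emotion,
)
from .lexicon import Lexicon, bundled_topic_lexicons
from .records import AGE_GROUPS, GENDERS, SENTIMENT_BINS, TOPICS, TweetRecord

logger = logging.getLogger(__name__)


@dataclass
class QuestionnaireRecord:
    tweet_id: str
    demographics: Demographics
    concerns: set[str]
    covid_related: bool
    sentiment: SentimentScore
    emotions: dict[str, EmotionVector]

    def to_dict(self) -> dict:
        return {
            "tweet_id": self.tweet_id,
            "user_type": self.demographics.user_type,
            "gender": self.demographics.gender,
            "age_group": self.demographics.age_group,
            "concerns": sorted(self.concerns),
            "covid_related": self.covid_related,
            "polarity": self.sentiment.polarity,
            "sentiment_bin": self.sentiment.bin,
            "emotions": {m: v.scores for m, v in self.emotions.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "QuestionnaireRecord":
        return cls(
            tweet_id=d["tweet_id"],
            demographics=Demographics(d["user_type"], d.get("gender"), d.get("age_group")),
            concerns=set(d.get("concerns", [])),
            covid_related=bool(d["covid_related"]),
            sentiment=SentimentScore(d["polarity"], d["sentiment_bin"]),
            emotions={
                m: EmotionVector(m, dict(scores))
                for m, scores in d.get("emotions", {}).items()
            },
        )


def _resolve(registry: Mapping, backend):
    if callable(backend):
        return backend
    try:
        return registry[backend]()
    except KeyError:
        raise ContractViolation(f"unknown backend {backend!r}") from None


def assemble(
    original_set: Iterable[TweetRecord],
    covid_set: Iterable[TweetRecord],
    *,
    demographic_backend="truth",
    sentiment_backend="lexicon",
    emotion_backend="lexicon",
    lexicons: Mapping[str, Lexicon] | None = None,
    models: tuple[str, ...] = ann.MODELS,
    counts: dict | None = None,
) -> list[QuestionnaireRecord]:
    """One questionnaire record per tweet in the original set.

    ``covid_related`` is membership of the COVID set.  Backends may be
    registry names or callables.  A backend failure on a record excludes
    that record (reason counted under ``counts['excluded']``) but never
    aborts the run.
    """
    if counts is None:
        counts = {}
    counts.update(input=0, records=0)
    excluded = counts.setdefault("excluded", {})
    demo_b = _resolve(ann.DEMOGRAPHIC_BACKENDS, demographic_backend)
    sent_b = _resolve(ann.SENTIMENT_BACKENDS, sentiment_backend)
    emo_b = _resolve(ann.EMOTION_BACKENDS, emotion_backend)
    if lexicons is None:
        lexicons = bundled_topic_lexicons()
    covid_ids = {t.id for t in covid_set}

    out: list[QuestionnaireRecord] = []
    for rec in original_set:
        counts["input"] += 1
        try:
            demo = ann.annotate_demographics(rec, demo_b)
        except ContractViolation as exc:
            excluded["demographics_unavailable"] = (
                excluded.get("demographics_unavailable", 0) + 1)
            logger.debug("excluding %s: %s", rec.id, exc)
            continue
        try:
            concerns = ann.classify_concern(rec.text, lexicons)
            sentiment = ann.score_sentiment(rec, sent_b)
            emotions = {m: ann.detect_emotions(rec, m, emo_b) for m in models}
        except ContractViolation as exc:
            excluded["annotation_failed"] = excluded.get("annotation_failed", 0) + 1
            logger.debug("excluding %s: %s", rec.id, exc)
            continue
        out.append(
            QuestionnaireRecord(
                tweet_id=rec.id,
                demographics=demo,
                concerns=concerns,
                covid_related=rec.id in covid_ids,
                sentiment=sentiment,
                emotions=emotions,
            )
        )
    counts["records"] = len(out)
    logger.info(
        "assembled %d questionnaire records from %d tweets (%s excluded)",
        counts["records"], counts["input"], sum(excluded.values()),
    )
    return out


def records_to_frame(records: Iterable[QuestionnaireRecord]) -> pd.DataFrame:
    """Flatten questionnaire records into the analysis DataFrame."""
    rows = []
    for r in records:
        row = {
            "tweet_id": r.tweet_id,
            "user_type": r.demographics.user_type,
            "gender": r.demographics.gender,
            "age_group": r.demographics.age_group,
            "covid": r.covid_related,
            "polarity": r.sentiment.polarity,
            "sentiment_bin": r.sentiment.bin,
        }
        for t in TOPICS:
            row[f"concern_{t}"] = t in r.concerns
        for m, v in r.emotions.items():
            row[f"dominant_{m}"] = dominant_emotion(v)
        rows.append(row)
    return pd.DataFrame(rows)


def round_half_up(x: float, places: int) -> float:
    """Decimal half-up rounding, the printed-table convention."""
    q = Decimal(10) ** -places
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def _pct(count: int, denom: int) -> float:
    return round_half_up(100.0 * count / denom, 2) if denom else float("nan")


def summarize_table3(records_or_frame) -> pd.DataFrame:
    """Marginal distributions of the questionnaire, total vs COVID subset.

    One row per (variable, level) with counts, percentages (2 dp, half-up)
    and a chi-square p-value per main variable testing level x
    COVID-attention independence.  Gender and age rows are computed over
    persons only (organizations carry no such attributes); concern topics
    are non-exclusive flags with corpus-wide denominators.
    """
    df = (
        records_or_frame
        if isinstance(records_or_frame, pd.DataFrame)
        else records_to_frame(records_or_frame)
    )
    if df.empty:
        raise ValueError("summarize_table3: no records")
    cov = df[df["covid"]]

    rows: list[dict] = []

    def add_block(variable: str, levels, total_counts, covid_counts,
                  total_denom: int, covid_denom: int) -> None:
        tbl = np.array(
            [[covid_counts[l], total_counts[l] - covid_counts[l]] for l in levels]
        )
        keep = tbl.sum(axis=1) > 0
        p_value = np.nan
        if keep.sum() >= 2 and tbl[keep].sum(axis=0).min() > 0:
            p_value = chi2_contingency(tbl[keep], correction=False)[1]
        for i, level in enumerate(levels):
            rows.append({
                "variable": variable,
                "level": level,
                "count_total": int(total_counts[level]),
                "pct_total": _pct(total_counts[level], total_denom),
                "count_covid": int(covid_counts[level]),
                "pct_covid": _pct(covid_counts[level], covid_denom),
                "p_value": p_value if i == 0 else np.nan,
            })

    n_total, n_covid = len(df), len(cov)
    rows.append({
        "variable": "overall", "level": "overall",
        "count_total": n_total, "pct_total": 100.0,
        "count_covid": n_covid, "pct_covid": 100.0, "p_value": np.nan,
    })

    ut_counts = df["user_type"].value_counts()
    add_block(
        "user_type", ["person", "organization"],
        {l: ut_counts.get(l, 0) for l in ("person", "organization")},
        {l: cov["user_type"].value_counts().get(l, 0) for l in ("person", "organization")},
        n_total, n_covid,
    )

    persons = df[df["user_type"] == "person"]
    persons_cov = cov[cov["user_type"] == "person"]
    for var, levels in (("gender", GENDERS), ("age_group", AGE_GROUPS)):
        add_block(
            var, list(levels),
            {l: persons[var].value_counts().get(l, 0) for l in levels},
            {l: persons_cov[var].value_counts().get(l, 0) for l in levels},
            len(persons), len(persons_cov),
        )

    add_block(
        "concern", list(TOPICS),
        {t: int(df[f"concern_{t}"].sum()) for t in TOPICS},
        {t: int(cov[f"concern_{t}"].sum()) for t in TOPICS},
        n_total, n_covid,
    )

    add_block(
        "sentiment", list(SENTIMENT_BINS),
        {b: df["sentiment_bin"].value_counts().get(b, 0) for b in SENTIMENT_BINS},
        {b: cov["sentiment_bin"].value_counts().get(b, 0) for b in SENTIMENT_BINS},
        n_total, n_covid,
    )

    rows.append({
        "variable": "sentiment_polarity", "level": "mean (SD)",
        "count_total": n_total,
        "pct_total": round_half_up(df["polarity"].mean(), 4),
        "count_covid": n_covid,
        "pct_covid": round_half_up(cov["polarity"].mean(), 4) if n_covid else np.nan,
        "p_value": np.nan,
    })
    rows.append({
        "variable": "sentiment_polarity", "level": "sd",
        "count_total": n_total,
        "pct_total": round_half_up(df["polarity"].std(ddof=1), 4) if n_total > 1 else 0.0,
        "count_covid": n_covid,
        "pct_covid": round_half_up(cov["polarity"].std(ddof=1), 4) if n_covid > 1 else np.nan,
        "p_value": np.nan,
    })
    return pd.DataFrame(rows)
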