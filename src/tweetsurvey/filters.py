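"""Stream preprocessing: the original-English and COVID-keyword filters.

Two passes turn a raw tweet stream into the two study data sets: the
*original set* (English-language tweets that are not retweets, replies or
quotes — original posts best reflect an author's own thoughts) and the
*COVID set*, the subset of the original set matching a COVID-19
keyword/hashtag pattern.
"""

from __future__ import annotations

import logging
from typing import Iterable

from .lexicon import KeywordPattern
from .records import RecordError, TweetRecord

logger = logging.getLogger(__name__)


def is_original_english(t: TweetRecord) -> bool:
    """True iff the tweet is in English and is not a retweet, reply or quote."""
    if t.lang is None:
        raise RecordError(f"record {t.id}: missing lang field")
    return t.lang == "en" and not (t.is_retweet or t.is_reply or t.is_quote)


def matches_covid(t: TweetRecord, pattern: KeywordPattern) -> bool:
    """True iff any COVID keyword matches the tweet text at a word boundary."""
    return pattern.matches(t.text)


def split_datasets(
    stream: Iterable[TweetRecord],
    pattern: KeywordPattern,
    *,
    counts: dict | None = None,
) -> tuple[list[TweetRecord], list[TweetRecord]]:
    """Partition a stream into the original and COVID data sets.

    Order-preserving; the COVID set is a subset of the original set by
    construction.  Records failing validation are skipped and counted under
    ``counts['invalid']``.
    """
    if counts is None:
        counts = {}
    counts.update(input=0, original=0, covid=0, invalid=0)
    original: list[TweetRecord] = []
    covid: list[TweetRecord] = []
    for rec in stream:
        counts["input"] += 1
        try:
            keep = is_original_english(rec)
        except RecordError as exc:
            counts["invalid"] += 1
            logger.debug("skipping record: %s", exc)
            continue
        if not keep:
            continue
        original.append(rec)
        if matches_covid(rec, pattern):
            covid.append(rec)
    counts["original"] = len(original)
    counts["covid"] = len(covid)
    logger.info(
        "filtered %d records -> %d original, %d COVID (%d invalid)",
        counts["input"], counts["original"], counts["covid"], counts["invalid"],
    )
    return original, covid
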