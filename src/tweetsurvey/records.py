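"""Core record types for the tweet-questionnaire pipeline.

A tweet stream is represented as line-delimited JSON, one tweet object per
line.  Synthetic corpora carry a ``truth`` sub-object holding the
ground-truth labels the generator intended (demographics, topics, COVID
flag, polarity, emotion intensities), which the oracle annotator backends
read back.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from typing import IO, Iterable, Iterator

logger = logging.getLogger(__name__)

USER_TYPES = ("person", "organization")
GENDERS = ("male", "female")
AGE_GROUPS = ("<=18", "19-29", "30-39", ">=40")
TOPICS = ("economics", "health", "politics", "education", "entertainment")
SENTIMENT_BINS = ("negative", "neutral", "positive")


class RecordError(ValueError):
    """A malformed tweet record or truth block."""


@dataclass
class UserProfile:
    """Author profile attributes used for demographic inference."""

    screen_name: str
    name: str = ""
    biography: str = ""
    profile_image_ref: str | None = None

    def __post_init__(self) -> None:
        if not self.screen_name:
            raise RecordError("UserProfile.screen_name must be non-empty")


@dataclass
class TweetRecord:
    """One raw tweet: text, language, originality flags and author profile.

    ``truth`` is an optional ground-truth label block (present on synthetic
    corpora); ``annotations`` is filled by the annotation stage.
    """

    id: str
    text: str
    lang: str
    author: UserProfile
    is_retweet: bool = False
    is_reply: bool = False
    is_quote: bool = False
    truth: dict | None = None
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.id:
            raise RecordError("TweetRecord.id must be non-empty")
        for flag in ("is_retweet", "is_reply", "is_quote"):
            if getattr(self, flag) is None:
                raise RecordError(f"TweetRecord.{flag} must not be null")
        if self.lang is None:
            raise RecordError("TweetRecord.lang is missing")

    def to_dict(self) -> dict:
        d = {
            "id": self.id,
            "text": self.text,
            "lang": self.lang,
            "is_retweet": self.is_retweet,
            "is_reply": self.is_reply,
            "is_quote": self.is_quote,
            "author": asdict(self.author),
        }
        if self.truth is not None:
            d["truth"] = self.truth
        if self.annotations:
            d["annotations"] = self.annotations
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TweetRecord":
        try:
            author = UserProfile(**d["author"])
            return cls(
                id=d["id"],
                text=d.get("text", ""),
                lang=d["lang"],
                author=author,
                is_retweet=bool(d["is_retweet"]),
                is_reply=bool(d["is_reply"]),
                is_quote=bool(d["is_quote"]),
                truth=d.get("truth"),
                annotations=d.get("annotations", {}),
            )
        except (KeyError, TypeError) as exc:
            raise RecordError(f"malformed tweet record: {exc}") from exc


def write_jsonl(records: Iterable[TweetRecord], fh: IO[str]) -> int:
    """Write records as line-delimited JSON; returns the number written."""
    n = 0
    for rec in records:
        fh.write(json.dumps(rec.to_dict(), ensure_ascii=False, sort_keys=True))
        fh.write("\n")
        n += 1
    return n


def read_jsonl(fh: IO[str], *, counts: dict | None = None) -> Iterator[TweetRecord]:
    """Parse line-delimited tweet records, skipping unreadable lines.

    Skipped lines are counted under ``counts['skipped']`` (and logged);
    ``counts['read']`` holds the number of records yielded.
    """
    if counts is None:
        counts = {}
    counts.setdefault("read", 0)
    counts.setdefault("skipped", 0)
    for lineno, line in enumerate(fh, 1):
        line = line.strip()
        if not line:
            continue
        try:
            rec = TweetRecord.from_dict(json.loads(line))
        except (json.JSONDecodeError, RecordError) as exc:
            counts["skipped"] += 1
            logger.debug("skipping unreadable line %d: %s", lineno, exc)
            continue
        counts["read"] += 1
        yield rec
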