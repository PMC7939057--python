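"""Term lists compiled to word-boundary matching patterns.

Keyword and vocabulary files are plain text, one term per line; lines
starting with ``;`` are comments.  Terms are matched case-insensitively at
word boundaries after NFKC normalization, so e.g. ``covid-19`` matches
"COVID-19 cases" but not "covidiom"; a ``#``-prefixed term matches with or
without its hash sign.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

_WORD = r"[0-9A-Za-z_]"


def normalize(text: str) -> str:
    """NFKC-normalize and case-fold, the canonical form all matching uses."""
    return unicodedata.normalize("NFKC", text).casefold()


def _term_regex(term: str) -> str:
    core = re.escape(term.lstrip("#"))
    return core


@dataclass
class KeywordPattern:
    """A named term list with a compiled word-boundary matcher."""

    name: str
    terms: list[str]
    _pattern: re.Pattern = field(init=False, repr=False)

    def __post_init__(self) -> None:
        cleaned: list[str] = []
        seen = set()
        for t in self.terms:
            t = normalize(t.strip())
            if t and t not in seen:
                seen.add(t)
                cleaned.append(t)
        if not cleaned:
            raise ValueError(f"lexicon {self.name!r}: term list is empty")
        self.terms = cleaned
        # Longest-first keeps multi-word/hyphenated terms from being
        # shadowed by shorter alternatives.
        alts = "|".join(_term_regex(t) for t in sorted(cleaned, key=len, reverse=True))
        self._pattern = re.compile(
            rf"(?<!{_WORD})(?<!#)#?(?:{alts})(?!{_WORD})"
        )

    def matches(self, text: str) -> bool:
        if not text:
            return False
        return self._pattern.search(normalize(text)) is not None

    def find_terms(self, text: str) -> list[str]:
        """All distinct matched spans (hash sign stripped), in text order."""
        if not text:
            return []
        out: list[str] = []
        for m in self._pattern.finditer(normalize(text)):
            t = m.group(0).lstrip("#")
            if t not in out:
                out.append(t)
        return out


# A concern-topic vocabulary is structurally identical to a keyword pattern;
# the alias keeps call sites honest about which role a term list plays.
Lexicon = KeywordPattern


def load_terms(path: str | Path) -> list[str]:
    terms = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith(";"):
            continue
        terms.append(line)
    return terms


def load_pattern(path: str | Path, name: str | None = None) -> KeywordPattern:
    p = Path(path)
    return KeywordPattern(name or p.stem, load_terms(p))


def load_topic_lexicons(directory: str | Path, topics: Iterable[str]) -> dict[str, Lexicon]:
    """Load ``<topic>.txt`` for each topic from a lexicon directory."""
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"lexicon directory not found: {directory}")
    out = {}
    for topic in topics:
        out[topic] = load_pattern(directory / f"{topic}.txt", topic)
    return out


def bundled_path(filename: str) -> Path:
    """Path of a bundled lexicon file shipped with the package."""
    return Path(resources.files("tweetsurvey").joinpath("data", "lexicons", filename))


def bundled_covid_pattern() -> KeywordPattern:
    return load_pattern(bundled_path("covid.txt"), "covid")


def bundled_topic_lexicons() -> dict[str, Lexicon]:
    from .records import TOPICS

    return {t: load_pattern(bundled_path(f"{t}.txt"), t) for t in TOPICS}


def load_valence(path: str | Path | None = None) -> dict[str, float]:
    """Valence word list: ``word<TAB>valence`` with valence in [-1, 1]."""
    p = Path(path) if path is not None else bundled_path("valence.txt")
    out: dict[str, float] = {}
    for line in p.read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith(";"):
            continue
        word, value = line.split("\t")
        v = float(value)
        if not -1.0 <= v <= 1.0:
            raise ValueError(f"valence out of range for {word!r}: {v}")
        out[normalize(word)] = v
    return out


def load_emotion_words(model: str, path: str | Path | None = None) -> dict[str, list[str]]:
    """Emotion word list for a model: ``label<TAB>word`` per line."""
    p = Path(path) if path is not None else bundled_path(f"{model}.txt")
    out: dict[str, list[str]] = {}
    for line in p.read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith(";"):
            continue
        label, word = line.split("\t")
        out.setdefault(label, []).append(normalize(word))
    return out
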