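"""The four per-tweet annotators of the emulated questionnaire.

* demographics — user type (person/organization), gender, 4-level age group.
  The production systems for this are large multimodal classifiers working
  on profile images, names and biographies; here the annotator is a
  pluggable contract.  The bundled ``truth`` backend reads the ground-truth
  block carried by synthetic corpora.
* concern classification — dictionary regular-expression matching of five
  life-domain vocabularies (economics, health, politics, education,
  entertainment); a tweet may carry several topics or none.
* sentiment — scalar polarity in [-1, 1], binned negative/neutral/positive
  at +/-0.05; the default scorer is the bundled valence-lexicon mean.
* emotion — intensity vectors in [0, 1] under three label spaces: the six
  basic emotions, the eight-emotion wheel, and the six mood states.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Callable, Mapping

from .lexicon import Lexicon, load_emotion_words, load_valence, normalize
from .records import AGE_GROUPS, GENDERS, TOPICS, TweetRecord, USER_TYPES, UserProfile

logger = logging.getLogger(__name__)

# Label order is significant: it is the tie-break order for the dominant
# emotion.
MODEL_LABELS: dict[str, tuple[str, ...]] = {
    "ekman6": ("anger", "disgust", "fear", "joy", "sadness", "surprise"),
    "plutchik8": (
        "anger", "disgust", "fear", "joy", "sadness", "surprise",
        "trust", "anticipation",
    ),
    "poms6": ("anger", "depression", "fatigue", "vigor", "tension", "confusion"),
}
MODELS = tuple(MODEL_LABELS)

NEUTRAL_BAND = 0.05


class ContractViolation(ValueError):
    """An annotator backend broke its output contract."""


# ---------------------------------------------------------------------------
# demographics

@dataclass(frozen=True)
class Demographics:
    user_type: str
    gender: str | None
    age_group: str | None

    def __post_init__(self) -> None:
        if self.user_type not in USER_TYPES:
            raise ContractViolation(f"unknown user type {self.user_type!r}")
        if self.gender is not None and self.gender not in GENDERS:
            raise ContractViolation(f"unknown gender label {self.gender!r}")
        if self.age_group is not None and self.age_group not in AGE_GROUPS:
            raise ContractViolation(f"unknown age label {self.age_group!r}")


def truth_demographics(record: TweetRecord) -> Demographics:
    """Oracle backend: read the synthetic ground-truth block."""
    truth = record.truth
    if not truth:
        raise ContractViolation(f"record {record.id}: no ground-truth block")
    return Demographics(
        user_type=truth.get("user_type"),
        gender=truth.get("gender"),
        age_group=truth.get("age_group"),
    )


def annotate_demographics(
    record: TweetRecord,
    backend: Callable[[TweetRecord], Demographics] = truth_demographics,
) -> Demographics:
    """Run a demographic backend and enforce the output contract.

    Organizations carry no gender/age attributes; whatever the backend
    returns for them is nulled so downstream group analyses see a
    consistent schema.
    """
    demo = backend(record)
    if not isinstance(demo, Demographics):
        demo = Demographics(*demo)  # accepts (user_type, gender, age) tuples
    if demo.user_type == "organization":
        if demo.gender is not None or demo.age_group is not None:
            demo = Demographics("organization", None, None)
    return demo


# ---------------------------------------------------------------------------
# concern classification

def classify_concern(text: str, lexicons: Mapping[str, Lexicon]) -> set[str]:
    """Topics whose vocabulary matches the text at word boundaries.

    Multi-topic tweets keep every matching label; the empty set is a valid
    outcome.
    """
    if not text:
        return set()
    return {topic for topic, lex in lexicons.items() if lex.matches(text)}


# ---------------------------------------------------------------------------
# sentiment

@dataclass(frozen=True)
class SentimentScore:
    polarity: float
    bin: str


def bin_sentiment(polarity: float) -> str:
    """Map polarity to negative / neutral / positive.

    The three sub-ranges of [-1, 1] meet at +/-0.05; the boundary values
    belong to the outer bins (positive iff polarity >= 0.05, negative iff
    polarity <= -0.05), the convention of the rule-based scorers this
    pipeline emulates.
    """
    if not -1.0 <= polarity <= 1.0:
        raise ValueError(f"polarity {polarity} outside [-1, 1]")
    if polarity >= NEUTRAL_BAND:
        return "positive"
    if polarity <= -NEUTRAL_BAND:
        return "negative"
    return "neutral"


class ValenceLexiconScorer:
    """Default sentiment backend: mean valence of known words in the text."""

    def __init__(self, valence: Mapping[str, float] | None = None):
        self.valence = dict(valence) if valence is not None else load_valence()

    def __call__(self, record: TweetRecord) -> float:
        tokens = re.split(r"[^\w#-]+", normalize(record.text))
        vals = [self.valence[t] for t in tokens if t in self.valence]
        if not vals:
            return 0.0
        return sum(vals) / len(vals)


def truth_sentiment(record: TweetRecord) -> float:
    if not record.truth or "polarity" not in record.truth:
        raise ContractViolation(f"record {record.id}: no ground-truth polarity")
    return float(record.truth["polarity"])


def _as_record(text_or_record: str | TweetRecord) -> TweetRecord:
    if isinstance(text_or_record, TweetRecord):
        return text_or_record
    return TweetRecord(
        id="_inline", text=text_or_record, lang="en",
        author=UserProfile(screen_name="_inline"),
    )


def score_sentiment(
    text_or_record: str | TweetRecord,
    scorer: Callable[[TweetRecord], float] | None = None,
) -> SentimentScore:
    """Score polarity with a pluggable backend and bin it."""
    record = _as_record(text_or_record)
    if scorer is None:
        scorer = ValenceLexiconScorer()
    polarity = float(scorer(record))
    if not -1.0 <= polarity <= 1.0:
        raise ContractViolation(
            f"sentiment backend returned polarity {polarity} outside [-1, 1]"
        )
    return SentimentScore(polarity=polarity, bin=bin_sentiment(polarity))


# ---------------------------------------------------------------------------
# emotion

@dataclass(frozen=True)
class EmotionVector:
    model: str
    scores: dict[str, float]

    def __post_init__(self) -> None:
        if self.model not in MODEL_LABELS:
            raise ContractViolation(f"unknown emotion model {self.model!r}")
        expected = set(MODEL_LABELS[self.model])
        if set(self.scores) != expected:
            raise ContractViolation(
                f"{self.model} scores must cover exactly {sorted(expected)}, "
                f"got {sorted(self.scores)}"
            )
        for label, s in self.scores.items():
            if not 0.0 <= s <= 1.0:
                raise ContractViolation(
                    f"{self.model}/{label} score {s} outside [0, 1]"
                )


class EmotionLexiconScorer:
    """Default emotion backend: share of emotion words per label.

    score(label) = (matching tokens of that label) / (all emotion-word
    tokens matched under the model); all-zero when the text contains no
    emotion words.
    """

    def __init__(self, words: Mapping[str, Mapping[str, list[str]]] | None = None):
        if words is None:
            words = {m: load_emotion_words(m) for m in MODELS}
        self._sets = {
            m: {lab: set(ws) for lab, ws in words[m].items()} for m in words
        }

    def __call__(self, record: TweetRecord, model: str) -> dict[str, float]:
        tokens = re.split(r"[^\w#-]+", normalize(record.text))
        counts = {lab: 0 for lab in MODEL_LABELS[model]}
        for t in tokens:
            for lab, ws in self._sets[model].items():
                if t in ws:
                    counts[lab] += 1
        total = sum(counts.values())
        if total == 0:
            return {lab: 0.0 for lab in counts}
        return {lab: c / total for lab, c in counts.items()}


def truth_emotions(record: TweetRecord, model: str) -> dict[str, float]:
    if not record.truth or "emotions" not in record.truth:
        raise ContractViolation(f"record {record.id}: no ground-truth emotions")
    return {k: float(v) for k, v in record.truth["emotions"][model].items()}


def detect_emotions(
    text_or_record: str | TweetRecord,
    model: str,
    backend: Callable[[TweetRecord, str], Mapping[str, float]] | None = None,
) -> EmotionVector:
    if model not in MODEL_LABELS:
        raise ValueError(f"unknown emotion model {model!r}")
    record = _as_record(text_or_record)
    if backend is None:
        backend = EmotionLexiconScorer()
    scores = dict(backend(record, model))
    return EmotionVector(model=model, scores=scores)


def dominant_emotion(v: EmotionVector) -> str:
    """Label with the maximal intensity; ``"none"`` for an all-zero vector.

    Ties are broken by the model's fixed label order (the questionnaire
    listing order) and logged.
    """
    order = MODEL_LABELS[v.model]
    best = max(v.scores.values())
    if best == 0.0:
        return "none"
    winners = [lab for lab in order if v.scores[lab] == best]
    if len(winners) > 1:
        logger.debug("emotion tie in %s between %s", v.model, winners)
    return winners[0]


# ---------------------------------------------------------------------------
# backend registries (selected by name in run configuration)

DEMOGRAPHIC_BACKENDS: dict[str, Callable] = {"truth": lambda: truth_demographics}
SENTIMENT_BACKENDS: dict[str, Callable] = {
    "lexicon": ValenceLexiconScorer,
    "truth": lambda: truth_sentiment,
}
EMOTION_BACKENDS: dict[str, Callable] = {
    "lexicon": EmotionLexiconScorer,
    "truth": lambda: truth_emotions,
}
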