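"""Synthetic tweet-corpus generator with controlled joint distributions.

The raw tweet stream behind the emulated-questionnaire study is not
distributable, so every downstream stage is exercised against corpora
generated here.  The generator draws, per tweet: user type, gender and age
group (persons only), a COVID-attention flag, concern topics, a sentiment
polarity and per-model emotion intensity vectors — then assembles a
bag-of-terms text that *encodes* those labels using the same bundled
lexicons the annotators match against, so the regex classifiers have exact
known ground truth.

Joint structure (the published summary table gives only marginals):

* demographics are drawn independently (gender x age independence is an
  explicit assumption, overridable via the config);
* the per-person COVID rate is multiplicative in risk,
  ``p(gender, age) = r_gender * r_age / r_person``, which makes every
  configured marginal attention ratio exact in expectation and gives the
  implied "true" marginal odds ratios in closed form (see
  :func:`expected_group_rates`);
* concern topics are drawn from COVID-conditional rates so both the
  marginal topic shares and the per-topic attention ratios are matched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Iterator

import numpy as np
from scipy.stats import truncnorm

from .lexicon import bundled_path, load_terms, load_valence
from .records import (
    AGE_GROUPS,
    GENDERS,
    TOPICS,
    TweetRecord,
    USER_TYPES,
    UserProfile,
)
from .annotate import MODEL_LABELS, MODELS

# Filler words: neutral vocabulary disjoint from every bundled lexicon, so
# they never trip a classifier.
FILLERS = (
    "the", "and", "with", "this", "that", "today", "tomorrow", "morning",
    "evening", "afternoon", "people", "folks", "thoughts", "update", "daily",
    "note", "thread", "okay", "well", "just", "really", "quite", "some",
    "many", "about", "around", "during", "while", "since", "again", "still",
    "now", "then", "here", "there",
)

_OTHER_LANGS = ("es", "pt", "ar", "hi", "fr")

_DEFAULT_SENTIMENT = {"default": (0.1, 0.45)}

_DEFAULT_EMOTION_MEANS = {
    "ekman6": {
        "anger": 0.12, "disgust": 0.08, "fear": 0.18,
        "joy": 0.30, "sadness": 0.15, "surprise": 0.22,
    },
    "plutchik8": {
        "anger": 0.12, "disgust": 0.08, "fear": 0.18,
        "joy": 0.30, "sadness": 0.15, "surprise": 0.22,
        "trust": 0.35, "anticipation": 0.25,
    },
    "poms6": {
        "anger": 0.15, "depression": 0.30, "fatigue": 0.18,
        "vigor": 0.22, "tension": 0.16, "confusion": 0.12,
    },
}


class ConfigError(ValueError):
    """An invalid corpus configuration; the message names the field."""


def _check_probs(name: str, probs: dict, keys: tuple[str, ...]) -> None:
    if set(probs) != set(keys):
        raise ConfigError(f"{name}: expected keys {keys}, got {sorted(probs)}")
    for k, v in probs.items():
        if not 0.0 <= v <= 1.0:
            raise ConfigError(f"{name}[{k}] = {v} outside [0, 1]")
    if abs(sum(probs.values()) - 1.0) > 1e-9:
        raise ConfigError(f"{name}: probabilities sum to {sum(probs.values())}, not 1")


@dataclass
class CorpusConfig:
    """Distributional knobs of a synthetic corpus.

    ``covid_rate_by_group`` maps group keys (``person``, ``organization``,
    a gender, an age group, or a topic) to the probability that a tweet
    from that group carries a COVID keyword.  ``sentiment_params`` maps a
    lookup key (``"<user_type>:covid"``, ``"covid"``, ``"<user_type>"`` or
    ``"default"``, tried in that order) to a (mean, sd) pair of the
    truncated-normal polarity.  ``emotion_shift_by_group`` adds per-label
    mean shifts for records matching a group key (user type, gender, age
    group or ``"covid"``).
    """

    n_tweets: int = 10_000
    seed: int = 0
    user_type_probs: dict = field(
        default_factory=lambda: {"person": 0.9, "organization": 0.1})
    gender_probs: dict = field(
        default_factory=lambda: {"male": 0.5, "female": 0.5})
    age_probs: dict = field(
        default_factory=lambda: {g: 0.25 for g in AGE_GROUPS})
    covid_rate_by_group: dict = field(
        default_factory=lambda: {"person": 0.02, "organization": 0.07})
    topic_rate: dict = field(
        default_factory=lambda: {t: 0.1 for t in TOPICS})
    topic_covid_rate: dict | None = None
    sentiment_params: dict = field(
        default_factory=lambda: dict(_DEFAULT_SENTIMENT))
    emotion_params: dict = field(
        default_factory=lambda: {m: dict(v) for m, v in _DEFAULT_EMOTION_MEANS.items()})
    emotion_shift_by_group: dict = field(default_factory=dict)
    emotion_concentration: float = 8.0
    # Stream realism: probability of non-original / non-English records.
    retweet_rate: float = 0.0
    reply_rate: float = 0.0
    quote_rate: float = 0.0
    non_english_rate: float = 0.0

    def validate(self) -> None:
        if self.n_tweets < 0:
            raise ConfigError(f"n_tweets = {self.n_tweets} must be >= 0")
        _check_probs("user_type_probs", self.user_type_probs, USER_TYPES)
        _check_probs("gender_probs", self.gender_probs, GENDERS)
        _check_probs("age_probs", self.age_probs, AGE_GROUPS)
        for name in ("covid_rate_by_group", "topic_rate"):
            rates = getattr(self, name)
            for k, v in rates.items():
                if not 0.0 <= v <= 1.0:
                    raise ConfigError(f"{name}[{k}] = {v} outside [0, 1]")
        if self.topic_covid_rate is not None:
            for k, v in self.topic_covid_rate.items():
                if not 0.0 <= v <= 1.0:
                    raise ConfigError(f"topic_covid_rate[{k}] = {v} outside [0, 1]")
        for key, (mu, sd) in self.sentiment_params.items():
            if not -1.0 <= mu <= 1.0 or sd < 0:
                raise ConfigError(f"sentiment_params[{key}] = {(mu, sd)} invalid")
        for name in ("retweet_rate", "reply_rate", "quote_rate", "non_english_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} = {v} outside [0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CorpusConfig":
        cfg = cls(**d)
        if cfg.sentiment_params:
            cfg.sentiment_params = {
                k: tuple(v) for k, v in cfg.sentiment_params.items()}
        return cfg


def table3_default_config(n_tweets: int = 100_000, seed: int = 0) -> CorpusConfig:
    """Defaults calibrated to the published questionnaire summary table.

    Marginal probabilities equal the printed total-column percentages;
    per-group COVID rates equal the printed attention ratios; topic rates
    conditional on COVID attention are derived from the printed COVID-column
    shares; sentiment and emotion parameters encode the reported group
    contrasts (organizations more positive and more fearful; depression and
    fear elevated under COVID).
    """
    return CorpusConfig(
        n_tweets=n_tweets,
        seed=seed,
        user_type_probs={"person": 0.8994, "organization": 0.1006},
        gender_probs={"male": 0.5274, "female": 0.4726},
        age_probs={"<=18": 0.3793, "19-29": 0.3842, "30-39": 0.1141, ">=40": 0.1224},
        covid_rate_by_group={
            "person": 0.0218,
            "organization": 0.0719,
            "male": 0.0249,
            "female": 0.0182,
            "<=18": 0.0102,
            "19-29": 0.0165,
            "30-39": 0.0349,
            ">=40": 0.0616,
            "politics": 0.0736,
            "education": 0.0661,
            "economics": 0.0657,
            "health": 0.0436,
            "entertainment": 0.0219,
        },
        topic_rate={
            "economics": 0.1399,
            "health": 0.1390,
            "politics": 0.0727,
            "education": 0.0638,
            "entertainment": 0.0779,
        },
        topic_covid_rate={
            "economics": 0.3430,
            "health": 0.2260,
            "politics": 0.1997,
            "education": 0.1574,
            "entertainment": 0.0638,
        },
        sentiment_params={
            "person:covid": (0.0483, 0.4941),
            "organization:covid": (0.1135, 0.4941),
            "covid": (0.0659, 0.4941),
            "default": (0.1078, 0.4647),
        },
        emotion_shift_by_group={
            "organization": {
                "ekman6": {"fear": 0.15},
                "plutchik8": {"fear": 0.15},
                "poms6": {"depression": 0.15},
            },
            "covid": {
                "ekman6": {"fear": 0.10},
                "plutchik8": {"fear": 0.10},
                "poms6": {"depression": 0.08},
            },
        },
    )


# ---------------------------------------------------------------------------
# expectations implied by a config (closed form)

def _person_cell_rate(cfg: CorpusConfig, gender: str, age: str) -> float:
    r = cfg.covid_rate_by_group
    base = r.get("person", 0.0)
    rg, ra = r.get(gender), r.get(age)
    if base and rg is not None and ra is not None:
        return min(1.0, max(0.0, rg * ra / base))
    return base


def expected_group_rates(cfg: CorpusConfig) -> dict[str, float]:
    """Expected marginal COVID rates per group under the generating model.

    Gender and age marginals are over persons (organizations carry no such
    attributes); ``person`` and ``organization`` marginals are over the
    whole corpus; ``overall`` is the corpus-wide expectation.
    """
    pg = cfg.gender_probs
    pa = cfg.age_probs
    rates: dict[str, float] = {}
    person = 0.0
    for g in GENDERS:
        rates[g] = sum(pa[a] * _person_cell_rate(cfg, g, a) for a in AGE_GROUPS)
        person += pg[g] * rates[g]
    for a in AGE_GROUPS:
        rates[a] = sum(pg[g] * _person_cell_rate(cfg, g, a) for g in GENDERS)
    rates["person"] = person
    rates["organization"] = cfg.covid_rate_by_group.get("organization", 0.0)
    rates["overall"] = (
        cfg.user_type_probs["person"] * person
        + cfg.user_type_probs["organization"] * rates["organization"]
    )
    return rates


def true_odds_ratio(cfg: CorpusConfig, group: str, reference: str) -> float:
    """Config-implied marginal attention OR of ``group`` vs ``reference``."""
    r = expected_group_rates(cfg)
    odds = lambda p: p / (1.0 - p)
    return odds(r[group]) / odds(r[reference])


# ---------------------------------------------------------------------------
# generation

def _nearest_valence_words() -> tuple[np.ndarray, list[str]]:
    val = load_valence()
    items = sorted(val.items(), key=lambda kv: (kv[1], kv[0]))
    return np.array([v for _, v in items]), [w for w, _ in items]


def generate_corpus(config: CorpusConfig) -> Iterator[TweetRecord]:
    """Generate ``config.n_tweets`` tweet records, deterministically.

    One pseudo-random stream (PCG64 seeded with ``config.seed``) is consumed
    in a fixed field-major order — user type, gender, age, originality,
    language, COVID flag, topics, polarity, emotions, then text assembly —
    so identical (config, seed) pairs reproduce identical corpora
    byte-for-byte across platforms.
    """
    config.validate()
    n = config.n_tweets
    if n == 0:
        return
    rng = np.random.Generator(np.random.PCG64(config.seed))

    def draw_cat(probs: dict, keys: tuple[str, ...]) -> np.ndarray:
        p = np.array([probs[k] for k in keys])
        return rng.choice(len(keys), size=n, p=p / p.sum())

    ut_idx = draw_cat(config.user_type_probs, USER_TYPES)
    gender_idx = draw_cat(config.gender_probs, GENDERS)
    age_idx = draw_cat(config.age_probs, AGE_GROUPS)
    is_person = ut_idx == 0

    is_retweet = rng.random(n) < config.retweet_rate
    is_reply = rng.random(n) < config.reply_rate
    is_quote = rng.random(n) < config.quote_rate
    non_en = rng.random(n) < config.non_english_rate
    lang_pick = rng.integers(0, len(_OTHER_LANGS), size=n)

    # COVID flag: organizations use their group rate; persons use the
    # multiplicative-risk cell rate r_g * r_a / r_person.
    cell = np.empty((len(GENDERS), len(AGE_GROUPS)))
    for i, g in enumerate(GENDERS):
        for j, a in enumerate(AGE_GROUPS):
            cell[i, j] = _person_cell_rate(config, g, a)
    covid_p = np.where(
        is_person,
        cell[gender_idx, age_idx],
        config.covid_rate_by_group.get("organization", 0.0),
    )
    covid = rng.random(n) < covid_p

    # Topics, conditionally on the COVID flag when conditional rates are
    # configured (back-solved so the configured marginal is preserved).
    overall = expected_group_rates(config)["overall"]
    topic_flags = np.zeros((n, len(TOPICS)), dtype=bool)
    for j, t in enumerate(TOPICS):
        marginal = config.topic_rate.get(t, 0.0)
        if config.topic_covid_rate is not None and t in config.topic_covid_rate:
            p_cov = config.topic_covid_rate[t]
            p_non = (
                (marginal - overall * p_cov) / (1.0 - overall)
                if overall < 1.0 else marginal
            )
            p_non = min(1.0, max(0.0, p_non))
        else:
            p_cov = p_non = marginal
        p_t = np.where(covid, p_cov, p_non)
        topic_flags[:, j] = rng.random(n) < p_t

    # Polarity: truncated normal on [-1, 1], parameters by lookup key.
    mu = np.empty(n)
    sd = np.empty(n)
    sp = config.sentiment_params
    default = sp.get("default", _DEFAULT_SENTIMENT["default"])
    for ui, ut in enumerate(USER_TYPES):
        for cov_val in (False, True):
            if cov_val:
                params = sp.get(f"{ut}:covid") or sp.get("covid") or sp.get(ut) or default
            else:
                params = sp.get(ut) or default
            mask = (ut_idx == ui) & (covid == cov_val)
            mu[mask], sd[mask] = params
    sd = np.maximum(sd, 1e-9)
    a_trunc = (-1.0 - mu) / sd
    b_trunc = (1.0 - mu) / sd
    polarity = truncnorm.rvs(a_trunc, b_trunc, loc=mu, scale=sd, random_state=rng)

    # Emotion intensities: Beta(mean*k, (1-mean)*k) per model and label,
    # with additive mean shifts for matching group keys.
    k = config.emotion_concentration
    emotions: dict[str, np.ndarray] = {}
    for model in MODELS:
        labels = MODEL_LABELS[model]
        means = np.empty((n, len(labels)))
        base = config.emotion_params.get(model, _DEFAULT_EMOTION_MEANS[model])
        for j, lab in enumerate(labels):
            means[:, j] = base.get(lab, 0.1)
        for key, shifts in config.emotion_shift_by_group.items():
            model_shifts = shifts.get(model, {})
            if not model_shifts:
                continue
            if key == "covid":
                mask = covid
            elif key in USER_TYPES:
                mask = ut_idx == USER_TYPES.index(key)
            elif key in GENDERS:
                mask = is_person & (gender_idx == GENDERS.index(key))
            elif key in AGE_GROUPS:
                mask = is_person & (age_idx == AGE_GROUPS.index(key))
            else:
                raise ConfigError(f"emotion_shift_by_group: unknown key {key!r}")
            for j, lab in enumerate(labels):
                if lab in model_shifts:
                    means[mask, j] += model_shifts[lab]
        means = np.clip(means, 0.01, 0.99)
        emotions[model] = rng.beta(means * k, (1.0 - means) * k)

    # Text-assembly draws (vectorized; consumed per record below).
    topic_lists = {t: load_terms(bundled_path(f"{t}.txt")) for t in TOPICS}
    covid_terms = load_terms(bundled_path("covid.txt"))
    val_values, val_words = _nearest_valence_words()
    emo_words = {m: load_emotion_words_cached(m) for m in MODELS}

    n_fill = rng.integers(2, 5, size=n)
    fill_idx = rng.integers(0, len(FILLERS), size=int(n_fill.sum()))
    covid_idx = rng.integers(0, len(covid_terms), size=n)
    topic_term_idx = rng.integers(0, 1 << 30, size=(n, len(TOPICS)))
    emo_word_idx = rng.integers(0, 1 << 30, size=(n, len(MODELS), 2))

    # Nearest valence word per polarity (vectorized).
    hi = np.clip(np.searchsorted(val_values, polarity), 1, len(val_values) - 1)
    lo = hi - 1
    nearest = np.where(
        np.abs(val_values[lo] - polarity) <= np.abs(val_values[hi] - polarity),
        lo, hi,
    )
    dom_idx = {m: np.argmax(emotions[m], axis=1) for m in ("plutchik8", "poms6")}

    # Scalar access into numpy arrays dominates the assembly loop; plain
    # lists are several times faster.
    ut_l = ut_idx.tolist()
    gender_l = gender_idx.tolist()
    age_l = age_idx.tolist()
    covid_l = covid.tolist()
    topic_l = topic_flags.tolist()
    pol_l = polarity.tolist()
    nearest_l = nearest.tolist()
    n_fill_l = n_fill.tolist()
    fill_l = fill_idx.tolist()
    covid_i_l = covid_idx.tolist()
    topic_term_l = topic_term_idx.tolist()
    emo_word_l = emo_word_idx.tolist()
    dom_l = {m: dom_idx[m].tolist() for m in dom_idx}
    emo_round = {
        m: np.round(emotions[m], 4).tolist() for m in MODELS
    }
    flags_l = (is_retweet.tolist(), is_reply.tolist(), is_quote.tolist())
    non_en_l = non_en.tolist()
    lang_l = lang_pick.tolist()

    fill_pos = 0
    for i in range(n):
        ut = USER_TYPES[ut_l[i]]
        person = ut == "person"
        gender = GENDERS[gender_l[i]] if person else None
        age = AGE_GROUPS[age_l[i]] if person else None
        flags_i = topic_l[i]
        my_topics = [TOPICS[j] for j in range(len(TOPICS)) if flags_i[j]]

        words: list[str] = []
        nf = n_fill_l[i]
        fillers = [FILLERS[j] for j in fill_l[fill_pos:fill_pos + nf]]
        fill_pos += nf
        words.append(fillers[0])
        for j, t in enumerate(TOPICS):
            if flags_i[j]:
                terms = topic_lists[t]
                words.append(terms[topic_term_l[i][j] % len(terms)])
        words.extend(fillers[1:2])
        if covid_l[i]:
            words.append(covid_terms[covid_i_l[i]])
        words.append(val_words[nearest_l[i]])
        for mj, model in enumerate(("plutchik8", "poms6")):
            labels = MODEL_LABELS[model]
            dom = labels[dom_l[model][i]]
            pool = emo_words[model][dom]
            idx2 = emo_word_l[i][mj]
            words.append(pool[idx2[0] % len(pool)])
            words.append(pool[idx2[1] % len(pool)])
        words.extend(fillers[2:])

        truth = {
            "user_type": ut,
            "gender": gender,
            "age_group": age,
            "topics": my_topics,
            "covid": covid_l[i],
            "polarity": round(pol_l[i], 6),
            "emotions": {
                model: dict(zip(MODEL_LABELS[model], emo_round[model][i]))
                for model in MODELS
            },
        }
        yield TweetRecord(
            id=f"syn-{config.seed}-{i:07d}",
            text=" ".join(words),
            lang="en" if not non_en_l[i] else _OTHER_LANGS[lang_l[i]],
            author=UserProfile(screen_name=f"user{i}", name=f"User {i}"),
            is_retweet=flags_l[0][i],
            is_reply=flags_l[1][i],
            is_quote=flags_l[2][i],
            truth=truth,
        )


_EMO_CACHE: dict[str, dict[str, list[str]]] = {}


def load_emotion_words_cached(model: str) -> dict[str, list[str]]:
    if model not in _EMO_CACHE:
        from .lexicon import load_emotion_words

        _EMO_CACHE[model] = load_emotion_words(model)
    return _EMO_CACHE[model]
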