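import pytest

from tweetsurvey import (
    TweetRecord,
    UserProfile,
    generate_corpus,
    split_datasets,
    table3_default_config,
)
from tweetsurvey.lexicon import bundled_covid_pattern, bundled_topic_lexicons


def make_tweet(
    id="t1",
    text="",
    lang="en",
    is_retweet=False,
    is_reply=False,
    is_quote=False,
    truth=None,
):
    return TweetRecord(
        id=id,
        text=text,
        lang=lang,
        author=UserProfile(screen_name=f"u_{id}"),
        is_retweet=is_retweet,
        is_reply=is_reply,
        is_quote=is_quote,
        truth=truth,
    )


@pytest.fixture(scope="session")
def covid_pattern():
    return bundled_covid_pattern()


@pytest.fixture(scope="session")
def topic_lexicons():
    return bundled_topic_lexicons()


@pytest.fixture(scope="session")
def small_corpus():
    """10k-tweet synthetic corpus under the default study conditions."""
    cfg = table3_default_config(n_tweets=10_000, seed=42)
    return cfg, list(generate_corpus(cfg))


@pytest.fixture(scope="session")
def small_sets(small_corpus, covid_pattern):
    _, corpus = small_corpus
    return split_datasets(corpus, covid_pattern)
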