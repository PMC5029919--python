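from datetime import date, datetime, timedelta

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from adindex import PostRecord, SyntheticConfig

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

CITY = "testville"
DAY0 = date(2012, 3, 1)


def mkpost(i: int, day_offset: int, text: str, city: str = CITY) -> PostRecord:
    return PostRecord(
        post_id=f"p{i}",
        timestamp=datetime.combine(DAY0 + timedelta(days=day_offset), datetime.min.time()),
        city=city,
        text=text,
    )


def make_corpus(texts_by_day: dict[int, list[str]], city: str = CITY) -> list[PostRecord]:
    """Posts from {day_offset: [text, ...]}, ids sequential in input order."""
    posts, i = [], 0
    for off in sorted(texts_by_day):
        for text in texts_by_day[off]:
            posts.append(mkpost(i, off, text, city))
            i += 1
    return posts


@pytest.fixture
def rng():
    return np.random.default_rng(20120301)


@pytest.fixture
def small_synth_config():
    """Scaled-down corpus for fast end-to-end tests: same structure, smaller sizes."""
    return SyntheticConfig(
        n_days=120,
        posts_per_day_mean=400.0,
        vocab_noise_size=200,
        n_signal_pos=5,
        n_signal_neg=5,
        base_term_rate=0.01,
        seed=7,
    )
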