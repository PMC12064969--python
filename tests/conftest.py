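from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

from soclisten.corpus_io import normalize
from soclisten.screening import ScreeningCriteria
from soclisten.synthetic_corpus import SyntheticSpec, generate_corpus

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def criteria() -> ScreeningCriteria:
    return ScreeningCriteria()


@pytest.fixture(scope="session")
def small_corpus():
    """A small seeded synthetic corpus shared across unit tests."""
    spec = SyntheticSpec(seed=42, n_authors=150, n_duplicates=10)
    return spec, *generate_corpus(spec)


@pytest.fixture(scope="session")
def small_normalized(small_corpus):
    _, records, _, _ = small_corpus
    return [normalize(r) for r in records]
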