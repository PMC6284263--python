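import numpy as np
import pytest

from disner.corpus_io import Mention, Token, tokenize
from disner.synthetic import FixtureConfig, generate_ner_corpus


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_corpus():
    """Eight short annotated documents shared across training smoke tests."""
    return generate_ner_corpus(FixtureConfig(n_docs=8, sentences_per_doc=4, seed=5))


def make_tokens(text: str) -> list[Token]:
    return tokenize(text)


def mention(text: str, phrase: str, occurrence: int = 0) -> Mention:
    """Gold mention for the nth occurrence of ``phrase`` in ``text``."""
    start = -1
    for _ in range(occurrence + 1):
        start = text.index(phrase, start + 1)
    return Mention(start, start + len(phrase), phrase)
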