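import numpy as np
import pytest

from stimlabel.annotations import WordAnnotation, build_sentences
from stimlabel.sentiment import Lexicon


@pytest.fixture(scope="session")
def lexicon():
    return Lexicon.demo()


@pytest.fixture
def toy_words():
    """Three sentences: positive, negative, neutral; explicit end flags."""
    rows = [
        ("what", 0.0, 0.4), ("a", 0.5, 0.6), ("wonderful", 0.7, 1.3),
        ("morning", 1.4, 2.0, True),
        ("i", 3.0, 3.2), ("hate", 3.3, 3.7), ("this", 3.8, 4.0),
        ("street", 4.1, 5.0, True),
        ("the", 6.0, 6.2), ("door", 6.3, 7.0, True),
    ]
    return [
        WordAnnotation(token=r[0], onset=r[1], offset=r[2],
                       is_sentence_end=len(r) > 3)
        for r in rows
    ]


@pytest.fixture
def toy_sentences(toy_words):
    return build_sentences(toy_words)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
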