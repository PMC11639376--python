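import numpy as np
import pytest

from mhqa import CategoryLexicon, Corpus, Post
from mhqa.lexicon import DEFAULT_FUNCTION_CATEGORIES


@pytest.fixture
def tiny_corpus() -> Corpus:
    """Two questions, three answers."""
    return Corpus(
        [
            Post("q1", "question", "", "title one", "body of question one", reply_count=2),
            Post("a1", "answer", "q1", "", "first answer body", like_count=3),
            Post("a2", "answer", "q1", "", "second answer body", like_count=0),
            Post("q2", "question", "", "", "body of question two", reply_count=1),
            Post("a3", "answer", "q2", "", "third answer body", like_count=12),
        ]
    )


@pytest.fixture
def tiny_lexicon() -> CategoryLexicon:
    """One word per function category plus two overlapping content categories."""
    cats = {c: frozenset({f"f_{c}"}) for c in DEFAULT_FUNCTION_CATEGORIES}
    cats["negemo"] = frozenset({"sad", "cry", "worry"})
    cats["family"] = frozenset({"mum", "dad", "cry"})  # "cry" overlaps
    return CategoryLexicon(cats, DEFAULT_FUNCTION_CATEGORIES)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
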