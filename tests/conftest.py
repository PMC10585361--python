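import numpy as np
import pytest

from topicfuse.corpus import (
    BowMatrix,
    RawDocument,
    TokenizedDocument,
    Vocabulary,
    build_bow,
    build_vocabulary,
)
from topicfuse.synthetic import make_separable_preset


def whitespace_tokenize(docs):
    """Tokenize pre-normalized synthetic documents by whitespace."""
    return [
        TokenizedDocument(d.doc_id, tuple(d.text.split()), d.label)
        for d in docs
    ]


def count_bow_from_array(counts):
    """Wrap an integer array as a count BowMatrix with a dummy vocabulary."""
    counts = np.asarray(counts, dtype=float)
    vocab = Vocabulary(terms=tuple(f"t{j}" for j in range(counts.shape[1])))
    return BowMatrix(
        doc_ids=[f"d{i}" for i in range(counts.shape[0])],
        vocab=vocab,
        values=counts,
        weighting="count",
    )


@pytest.fixture(scope="session")
def separable_preset():
    return make_separable_preset(seed=11)


@pytest.fixture(scope="session")
def separable_tokenized(separable_preset):
    return whitespace_tokenize(separable_preset.documents)


@pytest.fixture
def tiny_labeled_corpus():
    """40 two-token documents with a class-linked vocabulary."""
    rng = np.random.default_rng(5)
    docs = []
    for i in range(40):
        label = i % 2
        words = (
            ["apple", "banana"] if label == 0 else ["carrot", "daikon"]
        )
        toks = rng.choice(words, size=4).tolist() + ["common"]
        docs.append(
            RawDocument(doc_id=f"d{i}", text=" ".join(toks), label=label)
        )
    return docs
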