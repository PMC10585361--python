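"""Synthetic short-text corpora from the mixture-of-unigrams model.

Each document draws a binary class, then a single topic from a
class-conditional topic distribution, then a Poisson-distributed number of
tokens (truncated at one, mean 8 by default to mimic article-title lengths)
i.i.d. from that topic's word distribution.  Because the generator matches
the one-topic-per-document assumption of the DMM sampler, it provides exact
ground truth for sampler recovery, topic scoring and end-to-end tests.

Synthetic terms are the strings "w0000".."w{V-1}" and bypass text
preprocessing; ``realistic=True`` instead emits purely consonantal term
aliases wrapped in decoy punctuation, digits and stopwords so the full
normalization chain can be exercised end to end (consonant-only aliases are
invariant under the stemmer).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .corpus import RawDocument, ValidationError

__all__ = [
    "GeneratorConfig",
    "SyntheticCorpus",
    "generate_dmm_corpus",
    "make_separable_preset",
    "write_corpus_files",
]

_CONSONANTS = "bcdfghjklmnpqrstvwxz"
_DECOYS = ("the", "of", "a", "in", "and", "is", "to", "on", "for", "at")


@dataclass
class GeneratorConfig:
    K_true: int = 5
    V: int = 300
    D: int = 2000
    class_prior: float = 0.5
    topic_given_class: np.ndarray | None = None  # (2, K_true), rows sum to 1
    doc_length_lambda: float = 8.0
    topic_word_concentration: float = 0.05
    exclusive_vocab: bool = True
    realistic: bool = False
    seed: int = 0

    def __post_init__(self):
        if min(self.K_true, self.V, self.D) < 1:
            raise ValidationError("K_true, V and D must be positive")
        if not 0 < self.class_prior < 1:
            raise ValidationError("class_prior must be in (0, 1)")
        if self.topic_given_class is None:
            uniform = np.full((2, self.K_true), 1.0 / self.K_true)
            self.topic_given_class = uniform
        else:
            self.topic_given_class = np.asarray(
                self.topic_given_class, dtype=np.float64
            )
        tgc = self.topic_given_class
        if tgc.shape != (2, self.K_true):
            raise ValidationError("topic_given_class must be 2 x K_true")
        if not np.allclose(tgc.sum(axis=1), 1.0):
            raise ValidationError("topic_given_class rows must sum to 1")


@dataclass
class SyntheticCorpus:
    documents: list[RawDocument]
    true_topic: np.ndarray          # (D,)
    true_phi: np.ndarray            # (K_true, V)
    config: GeneratorConfig = field(repr=False, default=None)


def _term_name(j: int, V: int, realistic: bool) -> str:
    if not realistic:
        width = max(4, len(str(V - 1)))
        return f"w{j:0{width}d}"
    # base-20 consonant alias, fixed width, no vowels -> stemmer-invariant
    base = len(_CONSONANTS)
    width = 1
    while base**width < V:
        width += 1
    digits = []
    x = j
    for _ in range(width):
        digits.append(_CONSONANTS[x % base])
        x //= base
    return "x" + "".join(reversed(digits))


def generate_dmm_corpus(config: GeneratorConfig) -> SyntheticCorpus:
    """Draw a labeled corpus from the one-topic-per-document model."""
    rng = np.random.default_rng(config.seed)
    K, V, D = config.K_true, config.V, config.D

    if config.exclusive_vocab:
        # disjoint contiguous vocabulary blocks per topic
        phi = np.zeros((K, V))
        bounds = np.linspace(0, V, K + 1).astype(int)
        for k in range(K):
            lo, hi = bounds[k], bounds[k + 1]
            block = rng.dirichlet(
                np.full(hi - lo, config.topic_word_concentration)
            )
            phi[k, lo:hi] = block
    else:
        phi = rng.dirichlet(
            np.full(V, config.topic_word_concentration), size=K
        )

    labels = (rng.random(D) < config.class_prior).astype(int)
    topics = np.empty(D, dtype=np.int64)
    docs: list[RawDocument] = []
    names = [_term_name(j, V, config.realistic) for j in range(V)]
    for d in range(D):
        k = rng.choice(K, p=config.topic_given_class[labels[d]])
        topics[d] = k
        length = max(1, int(rng.poisson(config.doc_length_lambda)))
        words = rng.choice(V, size=length, p=phi[k])
        toks = [names[j] for j in words]
        if config.realistic:
            out = []
            for t in toks:
                if rng.random() < 0.3:
                    out.append(_DECOYS[int(rng.integers(len(_DECOYS)))])
                out.append(t.capitalize() if rng.random() < 0.2 else t)
                if rng.random() < 0.1:
                    out.append(str(int(rng.integers(100))))
            text = " ".join(out) + ("." if rng.random() < 0.5 else "")
        else:
            text = " ".join(toks)
        docs.append(RawDocument(doc_id=f"d{d:05d}", text=text, label=int(labels[d])))
    return SyntheticCorpus(
        documents=docs, true_topic=topics, true_phi=phi, config=config
    )


def make_separable_preset(seed: int = 0, realistic: bool = False) -> SyntheticCorpus:
    """Six-topic benchmark with class-linked structure and disjoint vocabularies.

    Topics 0–1 occur only under class 0, topics 2–3 only under class 1, and
    topics 4–5 are shared noise appearing with equal (small) probability
    under both classes.  Classes are balanced; accumulating both exclusive
    topics of a class covers nearly all of its documents, so the corpus is
    close to perfectly classifiable, while shared-topic documents are
    irreducibly ambiguous.
    """
    tgc = np.array(
        [
            [0.45, 0.45, 0.00, 0.00, 0.05, 0.05],
            [0.00, 0.00, 0.45, 0.45, 0.05, 0.05],
        ]
    )
    # concentration 0.5 keeps each 100-term topic block rich enough that a
    # topic's observed vocabulary always exceeds a 20-word topic list;
    # sparser topics would pad their top-m lists with zero-count filler
    # terms (uniform-posterior ties), which belong to other topics' blocks
    config = GeneratorConfig(
        K_true=6, V=600, D=2000, class_prior=0.5,
        topic_given_class=tgc, doc_length_lambda=8.0,
        topic_word_concentration=0.5, exclusive_vocab=True,
        realistic=realistic, seed=seed,
    )
    return generate_dmm_corpus(config)


def write_corpus_files(
    corpus: SyntheticCorpus,
    corpus_path: str | Path,
    truth_path: str | Path | None = None,
    sep: str = "\t",
) -> None:
    """Write the corpus in the dialect read_corpus consumes, plus ground truth."""
    with open(corpus_path, "w", encoding="utf-8") as fh:
        fh.write(f"id{sep}text{sep}label\n")
        for d in corpus.documents:
            fh.write(f"{d.doc_id}{sep}{d.text}{sep}{d.label}\n")
    if truth_path is not None:
        with open(truth_path, "w", encoding="utf-8") as fh:
            fh.write("doc_id\tclass\ttrue_topic\n")
            for d, k in zip(corpus.documents, corpus.true_topic):
                fh.write(f"{d.doc_id}\t{d.label}\t{int(k)}\n")
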