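"""Corpus reading and the short-text preprocessing pipeline.

Turns labeled raw documents (id, text, binary label) into normalized token
lists, a frequency-filtered vocabulary, and bag-of-words matrices in either
raw-count or relative term-frequency weighting.  The normalization chain is:
case-fold, strip punctuation/digits/non-alphanumerics, tokenize on
whitespace, drop tokens shorter than three characters, drop stopwords, then
Snowball-stem.  The length filter is applied before stemming; stems that end
up shorter than three characters are kept.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.feature_extraction.text import ENGLISH_STOP_WORDS

from .stemmer import stem

logger = logging.getLogger(__name__)

__all__ = [
    "RawDocument",
    "TokenizedDocument",
    "Vocabulary",
    "BowMatrix",
    "PreprocessConfig",
    "read_corpus",
    "preprocess_document",
    "tokenize_corpus",
    "build_vocabulary",
    "build_bow",
    "write_vocabulary",
    "write_bow_sparse",
    "write_bow_dense",
]

_NON_ALPHA = re.compile(r"[^a-z]+")


class ValidationError(ValueError):
    """Raised when input data violates a documented contract."""


@dataclass(frozen=True)
class RawDocument:
    doc_id: str
    text: str
    label: int


@dataclass(frozen=True)
class TokenizedDocument:
    doc_id: str
    tokens: tuple[str, ...]
    label: int


@dataclass(frozen=True)
class Vocabulary:
    """Ordered set of terms with a contiguous 0-based index."""

    terms: tuple[str, ...]
    index: dict[str, int] = field(repr=False, default_factory=dict)

    def __post_init__(self):
        if not self.index:
            object.__setattr__(
                self, "index", {t: i for i, t in enumerate(self.terms)}
            )
        if len(self.index) != len(self.terms):
            raise ValidationError("vocabulary contains duplicate terms")

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, term: str) -> bool:
        return term in self.index


@dataclass
class BowMatrix:
    doc_ids: list[str]
    vocab: Vocabulary
    values: np.ndarray  # dense (D, V)
    weighting: Literal["count", "relative_tf"]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class PreprocessConfig:
    """Options for text normalization.

    min_token_length applies before stemming; stopwords defaults to the
    scikit-learn English list and can be overridden with a file of one word
    per line.
    """

    min_token_length: int = 3
    stopwords: frozenset[str] = frozenset(ENGLISH_STOP_WORDS)
    stem_language: str = "english"
    apply_stemming: bool = True

    @classmethod
    def from_stopword_file(cls, path: str | Path, **kw) -> "PreprocessConfig":
        words = frozenset(
            w.strip().lower()
            for w in Path(path).read_text(encoding="utf-8").splitlines()
            if w.strip()
        )
        return cls(stopwords=words, **kw)


def read_corpus(
    path: str | Path,
    sep: str = "\t",
    id_col: str = "id",
    text_col: str = "text",
    label_col: str = "label",
    label_map: dict[str, int] | None = None,
) -> list[RawDocument]:
    """Read a delimited labeled corpus into RawDocuments.

    Labels must form a binary set, mapped to {0, 1} either via label_map or,
    if already {0, 1}-valued, directly.
    """
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    for col in (id_col, text_col, label_col):
        if col not in df.columns:
            raise KeyError(
                f"required column {col!r} missing from {path} "
                f"(found {list(df.columns)})"
            )
    if df.empty:
        logger.warning("corpus file %s contains no rows", path)
        return []
    raw_labels = df[label_col]
    if label_map is not None:
        unknown = set(raw_labels) - set(label_map)
        if unknown:
            raise ValidationError(
                f"labels {sorted(unknown)} not covered by the label map"
            )
        labels = raw_labels.map(label_map)
    else:
        uniq = sorted(set(raw_labels))
        if not set(uniq) <= {"0", "1"}:
            raise ValidationError(
                f"non-binary or unmapped label values {uniq}; "
                "supply a label_map"
            )
        labels = raw_labels.astype(int)
    bad = set(labels) - {0, 1}
    if bad:
        raise ValidationError(f"labels map outside {{0,1}}: {sorted(bad)}")
    if df[id_col].duplicated().any():
        dups = df[id_col][df[id_col].duplicated()].tolist()
        raise ValidationError(f"duplicate document ids: {dups[:5]}")
    return [
        RawDocument(doc_id=i, text=t, label=int(y))
        for i, t, y in zip(df[id_col], df[text_col], labels)
    ]


def preprocess_document(
    text: str, config: PreprocessConfig | None = None
) -> list[str]:
    """Normalize one document into an ordered list of term strings."""
    if config is None:
        config = PreprocessConfig()
    lowered = text.lower()
    cleaned = _NON_ALPHA.sub(" ", lowered)
    out = []
    for tok in cleaned.split():
        if len(tok) < config.min_token_length:
            continue
        if tok in config.stopwords:
            continue
        out.append(stem(tok) if config.apply_stemming else tok)
    return out


def tokenize_corpus(
    docs: Iterable[RawDocument], config: PreprocessConfig | None = None
) -> list[TokenizedDocument]:
    return [
        TokenizedDocument(
            doc_id=d.doc_id,
            tokens=tuple(preprocess_document(d.text, config)),
            label=d.label,
        )
        for d in docs
    ]


def build_vocabulary(
    docs: Sequence[TokenizedDocument],
    min_corpus_frequency: int = 1,
    mode: Literal["term_frequency", "document_frequency"] = "term_frequency",
) -> Vocabulary:
    """Build the term index, dropping rare terms.

    min_corpus_frequency=1 disables the filter.  By default a term's corpus
    frequency is its total occurrence count; document_frequency counts the
    number of documents containing it.  Terms are ordered by first occurrence
    in the corpus scan, which makes the index deterministic for fixed input.
    """
    if min_corpus_frequency < 1:
        raise ValidationError("min_corpus_frequency must be >= 1")
    if not docs:
        logger.warning("building vocabulary from an empty document list")
        return Vocabulary(terms=())
    counts: dict[str, int] = {}
    if mode == "term_frequency":
        for d in docs:
            for t in d.tokens:
                counts[t] = counts.get(t, 0) + 1
    else:
        for d in docs:
            for t in dict.fromkeys(d.tokens):
                counts[t] = counts.get(t, 0) + 1
    # dict preserves first-occurrence insertion order
    terms = tuple(t for t, c in counts.items() if c >= min_corpus_frequency)
    return Vocabulary(terms=terms)


def build_bow(
    docs: Sequence[TokenizedDocument],
    vocab: Vocabulary,
    weighting: Literal["count", "relative_tf"] = "count",
    relative_tf_denominator: Literal["in_vocab", "raw_length"] = "in_vocab",
) -> BowMatrix:
    """Project tokenized documents onto the vocabulary.

    relative_tf divides each term count by the document's in-vocabulary token
    count (rows then sum to 1; raw_length uses the full token count instead).
    Out-of-vocabulary tokens are ignored.
    """
    if len(vocab) == 0:
        raise ValidationError("vocabulary is empty")
    D, V = len(docs), len(vocab)
    values = np.zeros((D, V), dtype=np.float64)
    idx = vocab.index
    for r, d in enumerate(docs):
        for t in d.tokens:
            j = idx.get(t)
            if j is not None:
                values[r, j] += 1.0
    if weighting == "relative_tf":
        if relative_tf_denominator == "in_vocab":
            denom = values.sum(axis=1)
        else:
            denom = np.array([len(d.tokens) for d in docs], dtype=np.float64)
        nz = denom > 0
        values[nz] /= denom[nz, None]
    return BowMatrix(
        doc_ids=[d.doc_id for d in docs],
        vocab=vocab,
        values=values,
        weighting=weighting,
    )


def write_vocabulary(vocab: Vocabulary, path: str | Path) -> None:
    Path(path).write_text("\n".join(vocab.terms) + "\n", encoding="utf-8")


def write_bow_dense(bow: BowMatrix, path: str | Path) -> None:
    """Write a BOW matrix as a dense TSV with a doc_id column and a header."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("doc_id\t" + "\t".join(bow.vocab.terms) + "\n")
        for i, row in enumerate(bow.values):
            cells = "\t".join(f"{v:.10g}" for v in row)
            fh.write(f"{bow.doc_ids[i]}\t{cells}\n")


def write_bow_sparse(bow: BowMatrix, path: str | Path) -> None:
    """Write a BOW matrix as (doc_id, term, value) triplets, tab-separated."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("doc_id\tterm\tvalue\n")
        rows, cols = np.nonzero(bow.values)
        for r, c in zip(rows, cols):
            fh.write(
                f"{bow.doc_ids[r]}\t{bow.vocab.terms[c]}\t"
                f"{bow.values[r, c]:.10g}\n"
            )
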