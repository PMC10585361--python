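"""Grouping, scoring and accumulation of topics (the G, S and C stages).

Each topic's terms slice a per-topic sub-dataset out of the training
bag-of-words table; an internal stratified cross-validation of a random
forest scores the topic by mean fold accuracy; topics are ranked by score;
and the top-i topics' term unions (optionally fused with the K
document-topic columns) form the nested accumulated feature sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import accuracy_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .corpus import BowMatrix, ValidationError
from .gsdmm import DocTopicMatrix, TopicWordMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "TopicSubDataset",
    "TopicScore",
    "AccumulatedDataset",
    "build_topic_subdatasets",
    "score_topic",
    "rank_topics",
    "accumulate_features",
    "compute_topic_overlap",
    "write_topic_scores",
]


@dataclass
class TopicSubDataset:
    topic_id: int
    terms: list[str]                # topic terms present in the vocabulary
    matrix: np.ndarray              # (n_train, len(terms))
    labels: np.ndarray
    degenerate: bool = False        # no in-vocabulary terms


@dataclass
class TopicScore:
    topic_id: int
    score: float
    fold_scores: list[float] = field(default_factory=list)
    rank: int = 0
    degenerate: bool = False
    n_terms_in_vocab: int = 0


@dataclass
class AccumulatedDataset:
    i: int
    terms: list[str]
    matrix: np.ndarray
    labels: np.ndarray
    mode: str  # "tw_only" | "tw_plus_td"


def build_topic_subdatasets(
    bow: BowMatrix, tw: TopicWordMatrix, labels: np.ndarray
) -> list[TopicSubDataset]:
    """Slice one two-class sub-dataset per topic out of the training BOW."""
    labels = np.asarray(labels)
    if labels.shape[0] != bow.values.shape[0]:
        raise ValidationError("label vector does not match BOW row count")
    out = []
    for k in range(tw.K):
        cols, kept = [], []
        for term in tw.terms(k):
            j = bow.vocab.index.get(term)
            if j is None:
                continue
            cols.append(j)
            kept.append(term)
        dropped = len(tw.terms(k)) - len(kept)
        if dropped:
            logger.debug("topic %d: %d terms not in vocabulary", k, dropped)
        if not cols:
            logger.warning("topic %d has no in-vocabulary terms", k)
            out.append(
                TopicSubDataset(
                    topic_id=k, terms=[],
                    matrix=np.zeros((bow.values.shape[0], 0)),
                    labels=labels, degenerate=True,
                )
            )
        else:
            out.append(
                TopicSubDataset(
                    topic_id=k, terms=kept,
                    matrix=bow.values[:, cols], labels=labels,
                )
            )
    return out


def _make_scorer_forest(seed: int) -> RandomForestClassifier:
    return RandomForestClassifier(n_estimators=100, random_state=seed, n_jobs=1)


def score_topic(
    sub: TopicSubDataset,
    folds: int = 5,
    seed: int = 0,
    metric: str = "accuracy",
) -> TopicScore:
    """Mean stratified-CV accuracy (or AUC) of a random forest on the slice.

    A degenerate (all-out-of-vocabulary) topic scores the majority-class
    proportion so that ranking still covers every topic.
    """
    y = np.asarray(sub.labels)
    if sub.degenerate:
        score = float(np.bincount(y).max() / y.shape[0])
        return TopicScore(
            topic_id=sub.topic_id, score=score, fold_scores=[score],
            degenerate=True, n_terms_in_vocab=0,
        )
    if folds < 2:
        raise ValidationError("folds must be >= 2")
    if np.bincount(y, minlength=2).min() < 2:
        raise ValidationError("need at least 2 examples per class")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_scores = []
    # canonicalize column order so the score is invariant to how the
    # sub-dataset's columns were laid out
    order = np.argsort(np.asarray(sub.terms, dtype=object))
    X = sub.matrix[:, order]
    for f, (tr, te) in enumerate(skf.split(X, y)):
        clf = _make_scorer_forest(seed + f)
        clf.fit(X[tr], y[tr])
        if metric == "accuracy":
            fold_scores.append(float(accuracy_score(y[te], clf.predict(X[te]))))
        elif metric == "auc":
            pos = list(clf.classes_).index(1)
            fold_scores.append(
                float(roc_auc_score(y[te], clf.predict_proba(X[te])[:, pos]))
            )
        else:
            raise ValidationError(f"unknown scoring metric {metric!r}")
    return TopicScore(
        topic_id=sub.topic_id,
        score=float(np.mean(fold_scores)),
        fold_scores=fold_scores,
        n_terms_in_vocab=len(sub.terms),
    )


def rank_topics(scores: list[TopicScore]) -> list[TopicScore]:
    """Descending by score; ties break by topic_id ascending; ranks 1..K."""
    ordered = sorted(scores, key=lambda s: (-s.score, s.topic_id))
    for pos, s in enumerate(ordered, start=1):
        s.rank = pos
    return ordered


def accumulate_features(
    bow: BowMatrix,
    tw: TopicWordMatrix,
    ranked: list[TopicScore],
    i: int,
    labels: np.ndarray,
    td: DocTopicMatrix | None = None,
) -> AccumulatedDataset:
    """Union of the top-i ranked topics' terms, plus TD columns when fused.

    Term order follows ranked-topic traversal with duplicates dropped, so
    the column layout is stable across accumulation levels.
    """
    if not 1 <= i <= len(ranked):
        raise ValidationError(f"i={i} outside 1..{len(ranked)}")
    if td is not None and td.values.shape[0] != bow.values.shape[0]:
        raise ValidationError("TD row count does not match BOW row count")
    terms: dict[str, None] = {}
    for s in ranked[:i]:
        for term in tw.terms(s.topic_id):
            if term in bow.vocab:
                terms.setdefault(term)
    term_list = list(terms)
    cols = [bow.vocab.index[t] for t in term_list]
    X = bow.values[:, cols] if cols else np.zeros((bow.values.shape[0], 0))
    if td is not None:
        X = np.hstack([X, td.values])
        mode = "tw_plus_td"
    else:
        mode = "tw_only"
    return AccumulatedDataset(
        i=i, terms=term_list, matrix=X,
        labels=np.asarray(labels), mode=mode,
    )


def compute_topic_overlap(
    twA: TopicWordMatrix, twB: TopicWordMatrix
) -> dict:
    """Shared-term percentage between two models' unique-term pools.

    With A the set of unique terms over all of twA's topics, returns
    100·|A∩B|/|A| — asymmetric: it answers "what fraction of A's terms does
    B also surface".  The identity overlap(A,B)·|A| = overlap(B,A)·|B|
    (= 100·|A∩B|) links the two directions.
    """
    A = set(twA.all_unique_terms())
    B = set(twB.all_unique_terms())
    if not A:
        raise ValidationError("first topic-word matrix has no terms")
    shared = len(A & B)
    return {
        "n_unique_a": len(A),
        "n_unique_b": len(B),
        "n_shared": shared,
        "overlap_a_in_b_pct": 100.0 * shared / len(A),
        "overlap_b_in_a_pct": (100.0 * shared / len(B)) if B else float("nan"),
    }


def write_topic_scores(ranked: list[TopicScore], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("topic_id\trank\tscore\tn_terms_in_vocab\n")
        for s in ranked:
            fh.write(
                f"{s.topic_id}\t{s.rank}\t{s.score:.6f}\t{s.n_terms_in_vocab}\n"
            )
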