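"""Final-model evaluation: MCCV protocol, metrics, and the full pipeline.

The experimental protocol is stratified Monte-Carlo cross-validation
(default 10 repetitions of a 90/10 split).  Within each repetition the
vocabulary and the topic model are fitted on the training split only, the
topics are scored and ranked on training data, and for every accumulation
level i a random forest is trained on the accumulated feature set and
evaluated on the held-out split with seven metrics.  Means per level across
repetitions form the performance table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier

from .corpus import (
    BowMatrix,
    PreprocessConfig,
    RawDocument,
    TokenizedDocument,
    ValidationError,
    build_bow,
    build_vocabulary,
    tokenize_corpus,
)
from .gsdmm import (
    DocTopicMatrix,
    TopicWordMatrix,
    extract_doc_topic,
    extract_topic_word,
    fit_gsdmm,
    import_topic_artifacts,
)
from .selector import (
    TopicScore,
    accumulate_features,
    build_topic_subdatasets,
    rank_topics,
    score_topic,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "ConfusionCounts",
    "MetricSet",
    "PerformanceTable",
    "mccv_split",
    "compute_metrics",
    "run_pipeline",
    "select_best_subset",
    "write_performance_table",
]

METRIC_NAMES = (
    "accuracy", "recall", "specificity", "precision", "f1", "auc",
    "cohens_kappa",
)


@dataclass
class PipelineConfig:
    """Hyperparameters of the full pipeline.

    Defaults follow the framework's reference configuration: 20 topics of 20
    words, α=0.1, β=0.01, 1,000 Gibbs sweeps, 10 stratified 90/10 MCCV
    repetitions, 5-fold internal scoring CV.  The rare-term cutoff defaults
    to 20 in tw_only mode and is disabled (1) when fusing TD features, where
    preserving the full vocabulary helps.
    """

    K: int = 20
    words_per_topic: int = 20
    alpha: float = 0.1
    beta: float = 0.01
    gibbs_iterations: int = 1000
    mccv_reps: int = 10
    train_fraction: float = 0.9
    internal_cv_folds: int = 5
    mode: Literal["tw_only", "tw_plus_td"] = "tw_plus_td"
    min_corpus_frequency: int | None = None  # None -> 20 tw_only, 1 tw_plus_td
    topic_model_source: Literal["native_gsdmm", "import"] = "native_gsdmm"
    tw_path: str | None = None
    td_path: str | None = None
    preprocessing: Literal["standard", "none"] = "standard"
    fit_on_full_corpus: bool = False
    max_accumulation: int | None = None  # r; defaults to K
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.train_fraction < 1:
            raise ValidationError("train_fraction must be in (0, 1)")
        for name in ("K", "words_per_topic", "mccv_reps", "internal_cv_folds"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be positive")
        if self.gibbs_iterations < 0:
            raise ValidationError("gibbs_iterations must be >= 0")

    @property
    def resolved_min_frequency(self) -> int:
        if self.min_corpus_frequency is not None:
            return self.min_corpus_frequency
        return 20 if self.mode == "tw_only" else 1


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    @classmethod
    def from_predictions(cls, truth, predicted) -> "ConfusionCounts":
        y = np.asarray(truth, dtype=int)
        p = np.asarray(predicted, dtype=int)
        return cls(
            TP=int(np.sum((y == 1) & (p == 1))),
            FP=int(np.sum((y == 0) & (p == 1))),
            TN=int(np.sum((y == 0) & (p == 0))),
            FN=int(np.sum((y == 1) & (p == 0))),
        )

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass
class MetricSet:
    accuracy: float
    recall: float
    specificity: float
    precision: float
    f1: float
    auc: float
    cohens_kappa: float
    undefined: list[str] = field(default_factory=list)

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


@dataclass
class PerformanceTable:
    """Per-accumulation-level means over MCCV repetitions.

    ``summary`` has one row per level i with the mean term count and mean of
    each metric; ``per_rep`` retains every (rep, i) measurement.
    """

    summary: pd.DataFrame
    per_rep: pd.DataFrame
    metadata: dict


def mccv_split(
    labels: Sequence[int],
    reps: int = 10,
    train_fraction: float = 0.9,
    seed: int = 0,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Independent stratified random splits.

    Per class the training count is round(train_fraction × class size)
    (half-up); the remainder goes to the test side.
    """
    y = np.asarray(labels)
    if reps < 1:
        raise ValidationError("reps must be >= 1")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValidationError("both classes must be present")
    if counts.min() < 2:
        raise ValidationError("each class needs at least 2 members")
    rng = np.random.default_rng(seed)
    splits = []
    for _ in range(reps):
        train_idx, test_idx = [], []
        for c in classes:
            members = np.nonzero(y == c)[0]
            perm = rng.permutation(members)
            n_train = int(np.floor(train_fraction * members.size + 0.5))
            train_idx.append(perm[:n_train])
            test_idx.append(perm[n_train:])
        splits.append(
            (np.sort(np.concatenate(train_idx)),
             np.sort(np.concatenate(test_idx)))
        )
    return splits


def compute_metrics(
    truth: Sequence[int],
    predicted: Sequence[int],
    positive_scores: Sequence[float] | None = None,
) -> MetricSet:
    """The seven evaluation metrics from a binary prediction.

    AUC is the Mann–Whitney rank statistic of the positive-class scores
    (ties get half credit).  Ratios with zero denominators are reported as 0
    and flagged in ``undefined`` instead of propagating NaN.
    """
    y = np.asarray(truth, dtype=int)
    p = np.asarray(predicted, dtype=int)
    if y.shape != p.shape:
        raise ValidationError("truth and prediction lengths differ")
    cc = ConfusionCounts.from_predictions(y, p)
    n = cc.total
    tp, tn, fp, fn = cc.TP, cc.TN, cc.FP, cc.FN
    undefined: list[str] = []

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            undefined.append(name)
            return 0.0
        return num / den

    accuracy = (tp + tn) / n
    recall = ratio(tp, tp + fn, "recall")
    specificity = ratio(tn, tn + fp, "specificity")
    precision = ratio(tp, tp + fp, "precision")
    if precision + recall > 0:
        f1 = 2 * precision * recall / (precision + recall)
    else:
        undefined.append("f1")
        f1 = 0.0

    n_pos, n_neg = tp + fn, tn + fp
    if positive_scores is None or n_pos == 0 or n_neg == 0:
        undefined.append("auc")
        auc = 0.0
    else:
        s = np.asarray(positive_scores, dtype=float)
        ranks = rankdata(s)  # average ranks -> half credit for ties
        auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    p_o = accuracy
    p_e = ((tp + fn) * (tp + fp) + (tn + fp) * (tn + fn)) / (n * n)
    if p_e == 1.0:
        undefined.append("cohens_kappa")
        kappa = 0.0
    else:
        kappa = (p_o - p_e) / (1 - p_e)

    return MetricSet(
        accuracy=accuracy, recall=recall, specificity=specificity,
        precision=precision, f1=f1, auc=float(auc),
        cohens_kappa=kappa, undefined=undefined,
    )


def _counts_for_docs(
    docs: Sequence[TokenizedDocument], vocab
) -> np.ndarray:
    bow = build_bow(docs, vocab, weighting="count")
    return np.asarray(np.rint(bow.values), dtype=np.int64)


def _final_forest(seed: int) -> RandomForestClassifier:
    return RandomForestClassifier(n_estimators=100, random_state=seed, n_jobs=1)


def run_pipeline(
    corpus: Sequence[RawDocument],
    config: PipelineConfig,
    preprocess_config: PreprocessConfig | None = None,
) -> PerformanceTable:
    """The full grouping–scoring–modeling evaluation loop.

    Per MCCV repetition: build vocabulary and fit the topic model on the
    training split only (no test leakage; ``fit_on_full_corpus`` restores
    whole-corpus fitting for compatibility), score and rank topics on the
    training BOW, then for each accumulation level train the final forest
    and evaluate it on held-out documents projected into the training
    feature space (unseen terms ignored; test TD rows from the posterior
    with full counts).
    """
    y_all = np.asarray([d.label for d in corpus])
    if set(np.unique(y_all)) - {0, 1}:
        raise ValidationError("corpus labels must be binary 0/1")
    if config.preprocessing == "standard":
        tokenized = tokenize_corpus(corpus, preprocess_config)
    else:
        tokenized = [
            TokenizedDocument(
                doc_id=d.doc_id, tokens=tuple(d.text.split()), label=d.label
            )
            for d in corpus
        ]

    ss = np.random.SeedSequence(config.seed)
    split_seed, model_seed, score_seed, final_seed = (
        int(s) for s in ss.generate_state(4) >> 1  # keep below 2**31
    )
    splits = mccv_split(
        y_all, reps=config.mccv_reps,
        train_fraction=config.train_fraction, seed=split_seed,
    )
    r = config.max_accumulation or config.K

    per_rep_rows = []
    rep_meta = []
    for rep, (train_idx, test_idx) in enumerate(splits):
        y_train, y_test = y_all[train_idx], y_all[test_idx]
        if len(np.unique(y_test)) < 2 or len(np.unique(y_train)) < 2:
            logger.warning("rep %d: a split lacks a class; skipped", rep)
            continue
        train_docs = [tokenized[i] for i in train_idx]
        test_docs = [tokenized[i] for i in test_idx]
        vocab_docs = tokenized if config.fit_on_full_corpus else train_docs
        vocab = build_vocabulary(
            vocab_docs, min_corpus_frequency=config.resolved_min_frequency
        )
        if len(vocab) == 0:
            logger.warning("rep %d: empty vocabulary; skipped", rep)
            continue

        count_train = build_bow(train_docs, vocab, weighting="count")
        if config.topic_model_source == "import":
            if not (config.tw_path and config.td_path):
                raise ValidationError(
                    "import topic source requires tw_path and td_path"
                )
            tw, td_all = import_topic_artifacts(
                config.tw_path, config.td_path,
                vocab=vocab, doc_ids=[d.doc_id for d in tokenized],
            )
            td_train = DocTopicMatrix(
                doc_ids=[tokenized[i].doc_id for i in train_idx],
                values=td_all.values[train_idx],
            )
            td_test = DocTopicMatrix(
                doc_ids=[tokenized[i].doc_id for i in test_idx],
                values=td_all.values[test_idx],
            )
            state = None
        else:
            if config.fit_on_full_corpus:
                count_fit = build_bow(tokenized, vocab, weighting="count")
            else:
                count_fit = count_train
            state = fit_gsdmm(
                count_fit, K=config.K, alpha=config.alpha, beta=config.beta,
                iterations=config.gibbs_iterations,
                seed=(model_seed + rep) % 2**31,
            )
            tw = extract_topic_word(state, vocab, m=config.words_per_topic)
            if config.fit_on_full_corpus:
                td_full = extract_doc_topic(state, count_fit, held_in=True)
                td_train = DocTopicMatrix(
                    doc_ids=[tokenized[i].doc_id for i in train_idx],
                    values=td_full.values[train_idx],
                )
                td_test = DocTopicMatrix(
                    doc_ids=[tokenized[i].doc_id for i in test_idx],
                    values=td_full.values[test_idx],
                )
            else:
                td_train = extract_doc_topic(state, count_train, held_in=True)
                count_test = build_bow(test_docs, vocab, weighting="count")
                td_test = extract_doc_topic(state, count_test, held_in=False)

        rel_train = build_bow(train_docs, vocab, weighting="relative_tf")
        rel_test = build_bow(test_docs, vocab, weighting="relative_tf")

        subs = build_topic_subdatasets(rel_train, tw, y_train)
        scores = [
            score_topic(
                sub, folds=config.internal_cv_folds,
                seed=(score_seed + 1000 * rep + sub.topic_id) % 2**31,
            )
            for sub in subs
        ]
        ranked = rank_topics(scores)
        rep_meta.append(
            {
                "rep": rep,
                "vocab_size": len(vocab),
                "topic_scores": {s.topic_id: s.score for s in ranked},
                "topic_ranks": {s.topic_id: s.rank for s in ranked},
            }
        )

        use_td = config.mode == "tw_plus_td"
        for i in range(1, min(r, config.K) + 1):
            acc_train = accumulate_features(
                rel_train, tw, ranked, i, y_train,
                td=td_train if use_td else None,
            )
            acc_test = accumulate_features(
                rel_test, tw, ranked, i, y_test,
                td=td_test if use_td else None,
            )
            clf = _final_forest((final_seed + 100 * rep + i) % 2**31)
            clf.fit(acc_train.matrix, y_train)
            pred = clf.predict(acc_test.matrix)
            pos = list(clf.classes_).index(1)
            prob = clf.predict_proba(acc_test.matrix)[:, pos]
            ms = compute_metrics(y_test, pred, prob)
            row = {"rep": rep, "i": i, "n_terms": len(acc_train.terms)}
            row.update(ms.as_dict())
            per_rep_rows.append(row)

    if not per_rep_rows:
        raise ValidationError("no MCCV repetition completed")
    per_rep = pd.DataFrame(per_rep_rows)
    summary = (
        per_rep.groupby("i")
        .agg({"n_terms": "mean", **{m: "mean" for m in METRIC_NAMES}})
        .reset_index()
        .rename(columns={"n_terms": "n_terms_mean"})
    )
    metadata = {
        "config": asdict(config),
        "seeds": {
            "split": split_seed, "model": model_seed,
            "scoring": score_seed, "final": final_seed,
        },
        "n_documents": len(corpus),
        "completed_reps": sorted(per_rep["rep"].unique().tolist()),
        "per_rep_detail": rep_meta,
    }
    return PerformanceTable(summary=summary, per_rep=per_rep, metadata=metadata)


def select_best_subset(
    table: PerformanceTable, criterion: str = "f1"
) -> tuple[int, float]:
    """Accumulation level maximizing the criterion's mean; ties -> smaller i.

    Note: picking i on the same table used for reporting is optimistic;
    honest subset selection needs a nested or separate validation split.
    """
    if criterion not in METRIC_NAMES:
        raise ValidationError(f"unknown criterion {criterion!r}")
    s = table.summary
    if s.empty:
        raise ValidationError("empty performance table")
    col = s[criterion].to_numpy()
    best = int(np.argmax(col))  # argmax returns the first max -> smallest i
    return int(s["i"].iloc[best]), float(col[best])


def write_performance_table(table: PerformanceTable, path: str | Path) -> None:
    """Write the summary as TSV with metric values in percent (2 decimals)."""
    cols = [
        ("i", "n_accumulated_topics"),
        ("n_terms_mean", "n_terms_mean"),
        ("accuracy", "accuracy_pct"),
        ("recall", "recall_pct"),
        ("specificity", "specificity_pct"),
        ("f1", "f1_pct"),
        ("auc", "auc_pct"),
        ("precision", "precision_pct"),
        ("cohens_kappa", "cohens_kappa_pct"),
    ]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(name for _, name in cols) + "\n")
        for _, row in table.summary.iterrows():
            cells = [str(int(row["i"])), f"{row['n_terms_mean']:.1f}"]
            for src, _ in cols[2:]:
                cells.append(f"{100.0 * row[src]:.2f}")
            fh.write("\t".join(cells) + "\n")
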