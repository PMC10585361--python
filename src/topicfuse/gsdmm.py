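"""Dirichlet-multinomial mixture topic model with collapsed Gibbs sampling.

The model (GSDMM) assumes every document is generated by exactly one latent
topic: cluster proportions carry a symmetric Dirichlet(α) prior and each
cluster's word distribution a symmetric Dirichlet(β) prior.  After
integrating both out, Gibbs sampling reassigns whole documents between
clusters.  The fitted state yields the two byproducts downstream components
consume: a topic-word matrix (top-m terms per topic by posterior-mean
probability φ) and a document-topic matrix of posterior cluster
probabilities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.special import gammaln

from . import _gibbs
from .corpus import BowMatrix, ValidationError, Vocabulary

logger = logging.getLogger(__name__)

__all__ = [
    "GsdmmState",
    "TopicWordMatrix",
    "DocTopicMatrix",
    "fit_gsdmm",
    "extract_topic_word",
    "doc_topic_posterior",
    "extract_doc_topic",
    "import_topic_artifacts",
    "write_topic_word",
    "write_doc_topic",
]


@dataclass
class GsdmmState:
    """Sufficient statistics of the collapsed sampler.

    Invariants (checked by :meth:`check_invariants`): Σ_k m[k] = D;
    Σ_w n_kw[k, w] = n_k[k] for every k; Σ_k n_k[k] = total token count.
    """

    K: int
    alpha: float
    beta: float
    V: int
    D: int
    z: np.ndarray        # (D,) cluster assignment
    m: np.ndarray        # (K,) documents per cluster
    n_kw: np.ndarray     # (K, V) token counts
    n_k: np.ndarray      # (K,) total tokens per cluster
    rng_seed: int
    doc_counts: np.ndarray | None = None  # (D, V) training counts, for held-in TD

    def check_invariants(self, total_tokens: int | None = None) -> None:
        if int(self.m.sum()) != self.D:
            raise AssertionError("cluster document counts do not sum to D")
        if not np.array_equal(self.n_kw.sum(axis=1), self.n_k):
            raise AssertionError("per-cluster token counts inconsistent")
        if total_tokens is not None and int(self.n_k.sum()) != total_tokens:
            raise AssertionError("total token count not conserved")
        if (self.m < 0).any() or (self.n_kw < 0).any() or (self.n_k < 0).any():
            raise AssertionError("negative count encountered")


@dataclass
class TopicWordMatrix:
    """Per-topic top-m terms with their posterior-mean probabilities φ."""

    topics: list[list[tuple[str, float]]]  # K lists of (term, phi), phi desc
    m: int

    @property
    def K(self) -> int:
        return len(self.topics)

    def terms(self, k: int) -> list[str]:
        return [t for t, _ in self.topics[k]]

    def all_unique_terms(self) -> list[str]:
        seen: dict[str, None] = {}
        for topic in self.topics:
            for t, _ in topic:
                seen.setdefault(t)
        return list(seen)


@dataclass
class DocTopicMatrix:
    doc_ids: list[str]
    values: np.ndarray  # (D, K), rows sum to 1


def _bow_to_csr(counts: np.ndarray):
    """Pack an integer count matrix into the CSR arrays the kernel expects."""
    D = counts.shape[0]
    ptr = np.zeros(D + 1, dtype=np.int64)
    terms_l, cnts_l = [], []
    for d in range(D):
        nz = np.nonzero(counts[d])[0]
        terms_l.append(nz)
        cnts_l.append(counts[d, nz].astype(np.int64))
        ptr[d + 1] = ptr[d] + nz.size
    doc_terms = (
        np.concatenate(terms_l) if terms_l else np.empty(0, dtype=np.int64)
    ).astype(np.int64)
    doc_cnts = (
        np.concatenate(cnts_l) if cnts_l else np.empty(0, dtype=np.int64)
    ).astype(np.int64)
    doc_len = counts.sum(axis=1).astype(np.int64)
    return ptr, doc_terms, doc_cnts, doc_len


def fit_gsdmm(
    bow: BowMatrix,
    K: int,
    alpha: float = 0.1,
    beta: float = 0.01,
    iterations: int = 1000,
    seed: int = 0,
    check_every: int | None = None,
) -> GsdmmState:
    """Fit the mixture by ``iterations`` full Gibbs sweeps.

    Starts from a seeded uniform-random assignment and visits documents in
    index order.  The final sweep's state is the point estimate.  When
    ``check_every`` is set, count invariants are asserted after every that
    many sweeps (used by the test suite at 1).
    """
    if bow.weighting != "count":
        raise ValidationError("fit_gsdmm requires a count-weighted BOW")
    if K < 1:
        raise ValidationError("K must be >= 1")
    if alpha <= 0 or beta <= 0:
        raise ValidationError("alpha and beta must be positive")
    counts = np.asarray(np.rint(bow.values), dtype=np.int64)
    if not np.allclose(bow.values, counts):
        raise ValidationError("count BOW contains non-integer values")
    D, V = counts.shape
    n_empty = int((counts.sum(axis=1) == 0).sum())
    if n_empty:
        logger.warning(
            "%d documents have no in-vocabulary tokens; they are assigned "
            "by the cluster-size prior only", n_empty,
        )

    rng = np.random.default_rng(seed)
    z = rng.integers(0, K, size=D).astype(np.int64)
    m = np.bincount(z, minlength=K).astype(np.int64)
    n_kw = np.zeros((K, V), dtype=np.int64)
    np.add.at(n_kw, z, counts)
    n_k = n_kw.sum(axis=1)

    ptr, doc_terms, doc_cnts, doc_len = _bow_to_csr(counts)
    total_tokens = int(doc_len.sum())
    state = np.uint64(_gibbs.seed_state(seed))
    gs = GsdmmState(
        K=K, alpha=float(alpha), beta=float(beta), V=V, D=D,
        z=z, m=m, n_kw=n_kw, n_k=n_k, rng_seed=seed, doc_counts=counts,
    )
    if iterations == 0:
        gs.check_invariants(total_tokens)
        return gs
    if check_every is None:
        _gibbs.sweep(
            ptr, doc_terms, doc_cnts, doc_len, z, m, n_kw, n_k,
            float(alpha), float(beta), iterations, state,
        )
    else:
        done = 0
        while done < iterations:
            step = min(check_every, iterations - done)
            state = np.uint64(_gibbs.sweep(
                ptr, doc_terms, doc_cnts, doc_len, z, m, n_kw, n_k,
                float(alpha), float(beta), step, state,
            ))
            gs.check_invariants(total_tokens)
            done += step
    gs.check_invariants(total_tokens)
    return gs


def sample_assignment_trace(
    bow: BowMatrix,
    K: int,
    alpha: float,
    beta: float,
    burn_in: int,
    n_samples: int,
    seed: int = 0,
) -> np.ndarray:
    """Record the assignment vector after each post-burn-in sweep.

    Returns an (n_samples, D) integer array; used to compare the sampler's
    stationary distribution with the exactly enumerated posterior on tiny
    corpora.
    """
    if bow.weighting != "count":
        raise ValidationError("requires a count-weighted BOW")
    counts = np.asarray(np.rint(bow.values), dtype=np.int64)
    D, V = counts.shape
    rng = np.random.default_rng(seed)
    z = rng.integers(0, K, size=D).astype(np.int64)
    m = np.bincount(z, minlength=K).astype(np.int64)
    n_kw = np.zeros((K, V), dtype=np.int64)
    np.add.at(n_kw, z, counts)
    n_k = n_kw.sum(axis=1)
    ptr, doc_terms, doc_cnts, doc_len = _bow_to_csr(counts)
    state = np.uint64(_gibbs.seed_state(seed))
    if burn_in > 0:
        state = np.uint64(_gibbs.sweep(
            ptr, doc_terms, doc_cnts, doc_len, z, m, n_kw, n_k,
            float(alpha), float(beta), burn_in, state,
        ))
    trace = np.empty((n_samples, D), dtype=np.int64)
    for s in range(n_samples):
        state = np.uint64(_gibbs.sweep(
            ptr, doc_terms, doc_cnts, doc_len, z, m, n_kw, n_k,
            float(alpha), float(beta), 1, state,
        ))
        trace[s] = z
    return trace


def exact_assignment_log_posterior(
    counts: np.ndarray, K: int, alpha: float, beta: float
) -> np.ndarray:
    """Enumerate the posterior over all K^D assignments (tiny corpora only).

    Uses the collapsed Dirichlet-multinomial joint
    log p(z) = Σ_k lgamma(m_k + α) + Σ_k [Σ_w lgamma(n_kw + β) −
    lgamma(n_k + Vβ)] up to an additive constant, normalized over the full
    enumeration.  Independent of the sweep kernel: a brute-force oracle.
    """
    counts = np.asarray(counts, dtype=np.int64)
    D, V = counts.shape
    n_conf = K**D
    logp = np.empty(n_conf, dtype=np.float64)
    for idx in range(n_conf):
        rem = idx
        assign = np.empty(D, dtype=np.int64)
        for d in range(D):
            assign[d] = rem % K
            rem //= K
        lp = 0.0
        for k in range(K):
            members = counts[assign == k]
            m_k = members.shape[0]
            n_kw = members.sum(axis=0) if m_k else np.zeros(V, dtype=np.int64)
            lp += gammaln(m_k + alpha)
            lp += gammaln(n_kw + beta).sum() - gammaln(n_kw.sum() + V * beta)
        logp[idx] = lp
    logp -= logp.max()
    p = np.exp(logp)
    return p / p.sum()


def encode_assignments(trace: np.ndarray, K: int) -> np.ndarray:
    """Map assignment vectors to configuration indices (d-th digit base K)."""
    D = trace.shape[1]
    weights = K ** np.arange(D, dtype=np.int64)
    return trace @ weights


def symmetrize_configuration_distribution(
    p: np.ndarray, D: int, K: int
) -> np.ndarray:
    """Average a configuration distribution over cluster-label permutations.

    Cluster labels are non-identifiable, so the meaningful comparison
    between an MCMC estimate and the (label-symmetric) exact posterior is on
    the permutation-averaged distribution; otherwise finite chains that
    rarely swap labels show pure mode-allocation noise.
    """
    from itertools import permutations

    digits = np.empty((K**D, D), dtype=np.int64)
    idx = np.arange(K**D)
    rem = idx.copy()
    for d in range(D):
        digits[:, d] = rem % K
        rem //= K
    weights = K ** np.arange(D, dtype=np.int64)
    out = np.zeros_like(p, dtype=np.float64)
    perms = list(permutations(range(K)))
    for perm in perms:
        lut = np.asarray(perm, dtype=np.int64)
        codes = lut[digits] @ weights
        out[codes] += p
    return out / len(perms)


def extract_topic_word(
    state: GsdmmState, vocab: Vocabulary, m: int = 20
) -> TopicWordMatrix:
    """Top-m terms per topic by posterior-mean φ = (n_kw+β)/(n_k+Vβ).

    Ties break by vocabulary index ascending; an empty cluster has uniform
    φ = 1/V, so its top terms are the first m vocabulary terms.
    """
    if m < 1:
        raise ValidationError("m must be >= 1")
    phi = (state.n_kw + state.beta) / (
        state.n_k[:, None] + state.V * state.beta
    )
    topics = []
    for k in range(state.K):
        order = np.argsort(-phi[k], kind="stable")[:m]
        topics.append([(vocab.terms[j], float(phi[k, j])) for j in order])
    return TopicWordMatrix(topics=topics, m=m)


def doc_topic_posterior(
    state: GsdmmState,
    doc_counts: np.ndarray,
    held_in: bool = False,
    doc_index: int | None = None,
) -> np.ndarray:
    """Posterior cluster probabilities for one document.

    held_in=True treats the document as part of the training set: its own
    counts (and its document slot) are removed from its assigned cluster
    before evaluation, which requires ``doc_index`` into the fitted state.
    Unseen documents use the state as-is.  An all-out-of-vocabulary document
    falls back to the normalized cluster-size prior (m_k + α).
    """
    doc_counts = np.asarray(doc_counts, dtype=np.int64)
    m = state.m.astype(np.float64).copy()
    n_kw = state.n_kw
    n_k = state.n_k.astype(np.float64).copy()
    delta_kw = None
    if held_in:
        if doc_index is None:
            raise ValidationError("held_in=True requires doc_index")
        k_own = int(state.z[doc_index])
        m[k_own] -= 1
        delta_kw = (k_own, doc_counts)
        n_k[k_own] -= doc_counts.sum()

    n_d = int(doc_counts.sum())
    logp = np.log(m + state.alpha)
    if n_d == 0:
        logger.warning("document with no in-vocabulary tokens: prior-only TD row")
    else:
        nz = np.nonzero(doc_counts)[0]
        vbeta = state.V * state.beta
        for k in range(state.K):
            for w in nz:
                base = n_kw[k, w] + state.beta
                if delta_kw is not None and k == delta_kw[0]:
                    base -= delta_kw[1][w]
                c = int(doc_counts[w])
                logp[k] += gammaln(base + c) - gammaln(base)
            denom = n_k[k] + vbeta
            logp[k] -= gammaln(denom + n_d) - gammaln(denom)
    logp -= logp.max()
    p = np.exp(logp)
    return p / p.sum()


def extract_doc_topic(
    state: GsdmmState,
    bow: BowMatrix,
    held_in: bool = False,
    one_hot: bool = False,
) -> DocTopicMatrix:
    """Row-wise posterior TD matrix; row order follows the BOW.

    one_hot replaces each row by an indicator of its argmax (held-in rows
    use the sampled assignment directly).
    """
    counts = np.asarray(np.rint(bow.values), dtype=np.int64)
    D = counts.shape[0]
    values = np.empty((D, state.K), dtype=np.float64)
    for d in range(D):
        values[d] = doc_topic_posterior(
            state, counts[d], held_in=held_in,
            doc_index=d if held_in else None,
        )
    if one_hot:
        hard = np.zeros_like(values)
        if held_in:
            hard[np.arange(D), state.z] = 1.0
        else:
            hard[np.arange(D), values.argmax(axis=1)] = 1.0
        values = hard
    return DocTopicMatrix(doc_ids=list(bow.doc_ids), values=values)


def write_topic_word(tw: TopicWordMatrix, path: str | Path,
                     with_probs: bool = False) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for k, topic in enumerate(tw.topics):
            if with_probs:
                body = " ".join(f"{t}:{p:.10g}" for t, p in topic)
            else:
                body = " ".join(t for t, _ in topic)
            fh.write(f"{k}\t{body}\n")


def write_doc_topic(td: DocTopicMatrix, path: str | Path,
                    with_ids: bool = True) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for i, row in enumerate(td.values):
            cells = " ".join(f"{v:.10g}" for v in row)
            if with_ids:
                fh.write(f"{td.doc_ids[i]}\t{cells}\n")
            else:
                fh.write(cells + "\n")


def import_topic_artifacts(
    tw_path: str | Path,
    td_path: str | Path,
    vocab: Vocabulary | None = None,
    doc_ids: list[str] | None = None,
) -> tuple[TopicWordMatrix, DocTopicMatrix]:
    """Load externally produced topic-word and document-topic artifacts.

    The TW file holds one topic per line, ``index<TAB>term term ...`` with
    optional ``term:prob`` annotation; the TD file is a whitespace-delimited
    D × K matrix, optionally with a leading doc-id column.  TD rows within
    1e-3 of summing to 1 are renormalized; anything farther off is an error.
    """
    topics: list[list[tuple[str, float]]] = []
    for line in Path(tw_path).read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        _, _, body = line.partition("\t")
        if not body:
            body = line.split(None, 1)[1] if len(line.split(None, 1)) > 1 else ""
        entries = []
        for rank, tok in enumerate(body.split()):
            if ":" in tok:
                term, _, prob = tok.rpartition(":")
                entries.append((term, float(prob)))
            else:
                entries.append((tok, float("nan")))
        topics.append(entries)
    if not topics:
        raise ValidationError(f"no topics parsed from {tw_path}")
    m = max(len(t) for t in topics)
    tw = TopicWordMatrix(topics=topics, m=m)
    if vocab is not None:
        oov = [t for t, _ in (e for tp in topics for e in tp) if t not in vocab]
        if oov:
            logger.warning(
                "%d imported topic terms are outside the corpus vocabulary "
                "(e.g., %s)", len(oov), oov[:5],
            )

    rows = []
    ids = []
    for i, line in enumerate(
        Path(td_path).read_text(encoding="utf-8").splitlines()
    ):
        if not line.strip():
            continue
        parts = line.split()
        try:
            vals = [float(x) for x in parts]
        except ValueError:
            ids.append(parts[0])
            vals = [float(x) for x in parts[1:]]
        else:
            ids.append(str(i))
        rows.append(vals)
    values = np.asarray(rows, dtype=np.float64)
    if values.ndim != 2 or values.shape[1] != tw.K:
        raise ValidationError(
            f"TD has {values.shape[1] if values.ndim == 2 else '?'} columns "
            f"but TW defines {tw.K} topics"
        )
    if (values < 0).any():
        raise ValidationError("TD contains negative entries")
    sums = values.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 1e-3):
        bad = int(np.argmax(np.abs(sums - 1.0)))
        raise ValidationError(
            f"TD row {bad} sums to {sums[bad]:.6f}, outside the 1e-3 "
            "renormalization tolerance"
        )
    values = values / sums[:, None]
    if doc_ids is not None:
        if len(doc_ids) != values.shape[0]:
            raise ValidationError(
                f"TD has {values.shape[0]} rows but the corpus has "
                f"{len(doc_ids)} documents"
            )
        ids = list(doc_ids)
    return tw, DocTopicMatrix(doc_ids=ids, values=values)
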