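"""Numba kernels for the collapsed Gibbs sweep of the DMM sampler.

Documents are stored CSR-style: ``doc_ptr`` delimits each document's slice
of ``doc_terms`` (vocabulary indices of its distinct terms) and
``doc_cnts`` (their counts); ``doc_len`` is the total in-vocabulary token
count.  Randomness comes from an explicit PCG32 state threaded through the
calls, so sweeps are reproducible independently of any global RNG.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_PCG_MULT = np.uint64(6364136223846793005)
_PCG_INC = np.uint64(1442695040888963407)


@njit(cache=True)
def _pcg32_next(state):
    """Advance the PCG32 state; return (new_state, uniform in [0, 1))."""
    state = state * _PCG_MULT + _PCG_INC
    xorshifted = np.uint32(((state >> np.uint64(18)) ^ state) >> np.uint64(27))
    rot = np.uint32(state >> np.uint64(59))
    r = np.uint32(
        (xorshifted >> rot) | (xorshifted << (np.uint32(32 - rot) & np.uint32(31)))
    )
    return state, np.float64(r) / 4294967296.0


@njit(cache=True)
def seed_state(seed):
    """Initialize a PCG32 state from a nonnegative integer (splitmix64)."""
    z = np.uint64(seed) + np.uint64(0x9E3779B97F4A7C15)
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    return z ^ (z >> np.uint64(31))


@njit(cache=True)
def sweep(
    doc_ptr,
    doc_terms,
    doc_cnts,
    doc_len,
    z,
    m,
    n_kw,
    n_k,
    alpha,
    beta,
    n_sweeps,
    rng_state,
):
    """Run ``n_sweeps`` full Gibbs sweeps in document-index order, in place.

    For each document the collapsed conditional is
    p(z_d = k | rest) ∝ (m_k + α) ·
        Π_{w∈d} Π_{j=1..c_w} (n_kw + β + j − 1) /
        Π_{i=1..N_d} (n_k + Vβ + i − 1)
    with the document's own counts removed, evaluated in log space.
    Returns the advanced RNG state.
    """
    D = z.shape[0]
    K = m.shape[0]
    V = n_kw.shape[1]
    vbeta = V * beta
    logp = np.empty(K, dtype=np.float64)
    for _ in range(n_sweeps):
        for d in range(D):
            k_old = z[d]
            m[k_old] -= 1
            for idx in range(doc_ptr[d], doc_ptr[d + 1]):
                n_kw[k_old, doc_terms[idx]] -= doc_cnts[idx]
            n_k[k_old] -= doc_len[d]

            for k in range(K):
                acc = np.log(m[k] + alpha)
                for idx in range(doc_ptr[d], doc_ptr[d + 1]):
                    nb = n_kw[k, doc_terms[idx]] + beta
                    c = doc_cnts[idx]
                    if c == 1:
                        acc += np.log(nb)
                    else:
                        for j in range(c):
                            acc += np.log(nb + j)
                base = n_k[k] + vbeta
                n_d = doc_len[d]
                if n_d == 1:
                    acc -= np.log(base)
                else:
                    for i in range(n_d):
                        acc -= np.log(base + i)
                logp[k] = acc

            mx = logp[0]
            for k in range(1, K):
                if logp[k] > mx:
                    mx = logp[k]
            total = 0.0
            for k in range(K):
                logp[k] = np.exp(logp[k] - mx)
                total += logp[k]
            rng_state, u = _pcg32_next(rng_state)
            target = u * total
            k_new = K - 1
            csum = 0.0
            for k in range(K):
                csum += logp[k]
                if target < csum:
                    k_new = k
                    break

            z[d] = k_new
            m[k_new] += 1
            for idx in range(doc_ptr[d], doc_ptr[d + 1]):
                n_kw[k_new, doc_terms[idx]] += doc_cnts[idx]
            n_k[k_new] += doc_len[d]
    return rng_state
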