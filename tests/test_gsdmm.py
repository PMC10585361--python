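"""The DMM Gibbs sampler: exactness, invariants, byproducts, artifact IO."""

import numpy as np
import pytest

from topicfuse.corpus import ValidationError, Vocabulary, build_bow, \
    build_vocabulary
from topicfuse.gsdmm import (
    GsdmmState,
    doc_topic_posterior,
    encode_assignments,
    exact_assignment_log_posterior,
    extract_doc_topic,
    extract_topic_word,
    fit_gsdmm,
    import_topic_artifacts,
    sample_assignment_trace,
    symmetrize_configuration_distribution,
    write_doc_topic,
    write_topic_word,
)
from topicfuse.synthetic import GeneratorConfig, generate_dmm_corpus

from conftest import count_bow_from_array, whitespace_tokenize


def _random_small_corpus(rng, D, V, max_len=3):
    counts = np.zeros((D, V), dtype=int)
    for d in range(D):
        for w in rng.integers(0, V, int(rng.integers(1, max_len + 1))):
            counts[d, w] += 1
    return counts


class TestFit:
    def test_single_cluster_forced(self):
        bow = count_bow_from_array([[1, 0], [0, 2], [1, 1]])
        st = fit_gsdmm(bow, K=1, iterations=20, seed=0)
        assert np.all(st.z == 0)
        assert st.m.tolist() == [3]

    def test_zero_iterations_keeps_random_init_invariants(self):
        bow = count_bow_from_array(
            _random_small_corpus(np.random.default_rng(1), 10, 4)
        )
        st = fit_gsdmm(bow, K=3, iterations=0, seed=7)
        st.check_invariants(int(bow.values.sum()))

    def test_seed_determinism(self):
        bow = count_bow_from_array(
            _random_small_corpus(np.random.default_rng(2), 30, 6)
        )
        a = fit_gsdmm(bow, K=3, iterations=50, seed=9)
        b = fit_gsdmm(bow, K=3, iterations=50, seed=9)
        assert np.array_equal(a.z, b.z)
        assert np.array_equal(a.n_kw, b.n_kw)

    def test_rejects_relative_bow(self):
        bow = count_bow_from_array([[1.0, 0.0]])
        bow.weighting = "relative_tf"
        with pytest.raises(ValidationError):
            fit_gsdmm(bow, K=2)

    def test_invariants_after_every_sweep(self):
        bow = count_bow_from_array(
            _random_small_corpus(np.random.default_rng(3), 20, 5)
        )
        # check_every=1 asserts the count invariants after each sweep
        fit_gsdmm(bow, K=4, iterations=30, seed=4, check_every=1)


class TestExactPosterior:
    def test_sampler_matches_enumeration(self):
        """Empirical assignment distribution vs brute-force enumeration.

        Label permutations are averaged out on the sampler side because the
        mixture labels are non-identifiable.
        """
        rng = np.random.default_rng(7)
        for trial in range(3):
            D, V = int(rng.integers(4, 8)), int(rng.integers(3, 7))
            counts = _random_small_corpus(rng, D, V)
            exact = exact_assignment_log_posterior(counts, 2, 0.1, 0.01)
            tr = sample_assignment_trace(
                count_bow_from_array(counts), K=2, alpha=0.1, beta=0.01,
                burn_in=1000, n_samples=20000, seed=trial,
            )
            emp = np.bincount(
                encode_assignments(tr, 2), minlength=exact.size
            ) / tr.shape[0]
            emp = symmetrize_configuration_distribution(emp, D, 2)
            tv = 0.5 * np.abs(emp - exact).sum()
            assert tv < 0.05

    def test_enumeration_is_normalized_and_symmetric(self):
        counts = np.array([[2, 0], [0, 1], [1, 1]])
        p = exact_assignment_log_posterior(counts, 2, 0.1, 0.01)
        assert np.isclose(p.sum(), 1.0)
        sym = symmetrize_configuration_distribution(p, 3, 2)
        assert np.allclose(sym, p)  # posterior already label-symmetric


class TestTopicWord:
    def test_phi_arithmetic(self):
        vocab = Vocabulary(terms=("liver", "renal"))
        st = GsdmmState(K=1, alpha=0.1, beta=0.01, V=2, D=2,
                        z=np.zeros(2, dtype=int), m=np.array([2]),
                        n_kw=np.array([[10, 0]]), n_k=np.array([10]),
                        rng_seed=0)
        tw = extract_topic_word(st, vocab, m=1)
        term, phi = tw.topics[0][0]
        assert term == "liver"
        assert np.isclose(phi, 10.01 / 10.02)

    def test_empty_cluster_uniform(self):
        vocab = Vocabulary(terms=tuple("abcde"))
        st = GsdmmState(K=1, alpha=0.1, beta=0.01, V=5, D=0,
                        z=np.zeros(0, dtype=int), m=np.array([0]),
                        n_kw=np.zeros((1, 5), dtype=int),
                        n_k=np.array([0]), rng_seed=0)
        tw = extract_topic_word(st, vocab, m=3)
        assert tw.terms(0) == ["a", "b", "c"]
        assert all(np.isclose(p, 0.2) for _, p in tw.topics[0])

    def test_tie_broken_by_vocab_index(self):
        vocab = Vocabulary(terms=("z_first", "a_second", "b_third"))
        st = GsdmmState(K=1, alpha=0.1, beta=0.01, V=3, D=1,
                        z=np.zeros(1, dtype=int), m=np.array([1]),
                        n_kw=np.array([[2, 2, 1]]), n_k=np.array([5]),
                        rng_seed=0)
        tw = extract_topic_word(st, vocab, m=3)
        assert tw.terms(0) == ["z_first", "a_second", "b_third"]

    def test_phi_sums_to_one_over_full_vocab(self):
        bow = count_bow_from_array(
            _random_small_corpus(np.random.default_rng(8), 25, 6)
        )
        st = fit_gsdmm(bow, K=3, iterations=30, seed=1)
        phi = (st.n_kw + st.beta) / (st.n_k[:, None] + st.V * st.beta)
        assert np.allclose(phi.sum(axis=1), 1.0, atol=1e-9)


class TestDocTopic:
    def _state(self):
        return GsdmmState(
            K=2, alpha=0.1, beta=0.01, V=2, D=4,
            z=np.array([0, 0, 0, 1]), m=np.array([3, 1]),
            n_kw=np.array([[4, 0], [0, 2]]), n_k=np.array([4, 2]),
            rng_seed=0,
        )

    def test_hand_example(self):
        p = doc_topic_posterior(self._state(), np.array([1, 0]),
                                held_in=False)
        u = np.array([3.1 * 4.01 / 4.02, 1.1 * 0.01 / 2.02])
        assert np.allclose(p, u / u.sum())

    def test_single_cluster_degenerate(self):
        st = GsdmmState(K=1, alpha=0.1, beta=0.01, V=2, D=1,
                        z=np.zeros(1, dtype=int), m=np.array([1]),
                        n_kw=np.array([[1, 0]]), n_k=np.array([1]),
                        rng_seed=0)
        assert doc_topic_posterior(st, np.array([1, 0]))[0] == 1.0

    def test_symmetric_state_gives_uniform(self):
        st = GsdmmState(K=2, alpha=0.1, beta=0.01, V=1, D=4,
                        z=np.array([0, 0, 1, 1]), m=np.array([2, 2]),
                        n_kw=np.array([[3], [3]]), n_k=np.array([3, 3]),
                        rng_seed=0)
        p = doc_topic_posterior(st, np.array([1]))
        assert np.allclose(p, [0.5, 0.5])

    def test_all_oov_uses_prior(self):
        p = doc_topic_posterior(self._state(), np.array([0, 0]))
        assert np.allclose(p, [3.1 / 4.2, 1.1 / 4.2])

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(11)
        bow = count_bow_from_array(_random_small_corpus(rng, 40, 5))
        st = fit_gsdmm(bow, K=4, iterations=20, seed=2)
        for held_in in (True, False):
            td = extract_doc_topic(st, bow, held_in=held_in)
            assert np.allclose(td.values.sum(axis=1), 1.0)

    def test_argmax_matches_assignment_on_separated_corpus(self):
        corpus = generate_dmm_corpus(GeneratorConfig(
            K_true=2, V=40, D=200, doc_length_lambda=8.0,
            exclusive_vocab=True, seed=3,
        ))
        toks = whitespace_tokenize(corpus.documents)
        bow = build_bow(toks, build_vocabulary(toks, 1), weighting="count")
        st = fit_gsdmm(bow, K=2, iterations=200, seed=3)
        td = extract_doc_topic(st, bow, held_in=True)
        agree = (td.values.argmax(axis=1) == st.z).mean()
        assert agree >= 0.95


class TestArtifacts:
    def test_roundtrip(self, tmp_path):
        bow = count_bow_from_array(
            _random_small_corpus(np.random.default_rng(13), 12, 5)
        )
        st = fit_gsdmm(bow, K=3, iterations=20, seed=0)
        tw = extract_topic_word(st, bow.vocab, m=4)
        td = extract_doc_topic(st, bow, held_in=True)
        write_topic_word(tw, tmp_path / "tw.txt")
        write_doc_topic(td, tmp_path / "td.txt", with_ids=False)
        tw2, td2 = import_topic_artifacts(
            tmp_path / "tw.txt", tmp_path / "td.txt", vocab=bow.vocab
        )
        assert [tw2.terms(k) for k in range(3)] == [
            tw.terms(k) for k in range(3)
        ]
        assert np.allclose(td2.values, td.values, atol=1e-9)

    def test_renormalizes_near_one(self, tmp_path):
        (tmp_path / "tw.txt").write_text("0\ta b\n1\tc d\n")
        (tmp_path / "td.txt").write_text("0.5 0.5004\n0.2 0.8\n")
        _, td = import_topic_artifacts(tmp_path / "tw.txt",
                                       tmp_path / "td.txt")
        assert np.allclose(td.values.sum(axis=1), 1.0)

    def test_rejects_far_from_one(self, tmp_path):
        (tmp_path / "tw.txt").write_text("0\ta b\n")
        (tmp_path / "td.txt").write_text("0.7\n")
        with pytest.raises(ValidationError, match="sums to"):
            import_topic_artifacts(tmp_path / "tw.txt", tmp_path / "td.txt")

    def test_rejects_column_mismatch(self, tmp_path):
        (tmp_path / "tw.txt").write_text("0\ta\n1\tb\n")  # K=2
        (tmp_path / "td.txt").write_text("1.0\n")  # one column
        with pytest.raises(ValidationError, match="columns"):
            import_topic_artifacts(tmp_path / "tw.txt", tmp_path / "td.txt")

    def test_rejects_negative_entries(self, tmp_path):
        (tmp_path / "tw.txt").write_text("0\ta\n1\tb\n")
        (tmp_path / "td.txt").write_text("1.2 -0.2\n")
        with pytest.raises(ValidationError, match="negative"):
            import_topic_artifacts(tmp_path / "tw.txt", tmp_path / "td.txt")

    def test_rejects_row_count_mismatch(self, tmp_path):
        (tmp_path / "tw.txt").write_text("0\ta\n1\tb\n")
        (tmp_path / "td.txt").write_text("0.5 0.5\n")
        with pytest.raises(ValidationError, match="rows"):
            import_topic_artifacts(tmp_path / "tw.txt", tmp_path / "td.txt",
                                   doc_ids=["d0", "d1"])
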