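"""Compare the unique-term pools surfaced by two topic models.

The shared-term percentage is asymmetric: overlap(A,B) = 100·|A∩B|/|A|
answers "how much of model A's vocabulary does model B also surface".
The two directions are linked by overlap(A,B)·|A| = overlap(B,A)·|B|.
"""

from topicfuse import (GeneratorConfig, build_bow, build_vocabulary,
                       compute_topic_overlap, extract_topic_word, fit_gsdmm,
                       generate_dmm_corpus)
from topicfuse.corpus import TokenizedDocument

corpus = generate_dmm_corpus(GeneratorConfig(
    K_true=4, V=150, D=600, exclusive_vocab=True, seed=9,
))
toks = [TokenizedDocument(d.doc_id, tuple(d.text.split()), d.label)
        for d in corpus.documents]
vocab = build_vocabulary(toks, 1)
bow = build_bow(toks, vocab, weighting="count")

# two fits differing only in K act as two "methods"
tw_a = extract_topic_word(fit_gsdmm(bow, K=4, iterations=300, seed=1),
                          vocab, m=20)
tw_b = extract_topic_word(fit_gsdmm(bow, K=8, iterations=300, seed=2),
                          vocab, m=20)

rep = compute_topic_overlap(tw_a, tw_b)
print(f"|A| unique terms: {rep['n_unique_a']}")
print(f"|B| unique terms: {rep['n_unique_b']}")
print(f"shared terms:     {rep['n_shared']}")
print(f"overlap(A,B):     {rep['overlap_a_in_b_pct']:.1f}%")
rev = compute_topic_overlap(tw_b, tw_a)
print(f"overlap(B,A):     {rev['overlap_a_in_b_pct']:.1f}%")
print("\nBoth directions recover the same shared-term count:",
      f"{rep['overlap_a_in_b_pct']:.0f}% of {rep['n_unique_a']} ≈ "
      f"{rev['overlap_a_in_b_pct']:.0f}% of {rep['n_unique_b']} ≈ "
      f"{rep['n_shared']}")
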