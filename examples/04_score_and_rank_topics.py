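"""Group words by topic, score each topic, and rank.

Each topic's terms slice a sub-dataset out of the training bag-of-words;
a stratified 5-fold random-forest cross-validation scores the topic by
mean accuracy.  On the separable preset, topics tied to one class score
well above the shared-noise topics.
"""

import numpy as np

from topicfuse import (build_bow, build_vocabulary,
                       build_topic_subdatasets, extract_topic_word,
                       make_separable_preset, rank_topics, score_topic)
from topicfuse.corpus import TokenizedDocument
from topicfuse.gsdmm import GsdmmState

preset = make_separable_preset(seed=7)
toks = [TokenizedDocument(d.doc_id, tuple(d.text.split()), d.label)
        for d in preset.documents]
vocab = build_vocabulary(toks, 1)
counts = build_bow(toks, vocab, weighting="count").values.astype(int)

# align clusters with the generator's true topics to show the ideal case
z = preset.true_topic
n_kw = np.zeros((6, len(vocab)), dtype=int)
np.add.at(n_kw, z, counts)
state = GsdmmState(K=6, alpha=0.1, beta=0.01, V=len(vocab), D=len(toks),
                   z=z, m=np.bincount(z, minlength=6), n_kw=n_kw,
                   n_k=n_kw.sum(axis=1), rng_seed=0)

tw = extract_topic_word(state, vocab, m=20)
rel = build_bow(toks, vocab, weighting="relative_tf")
labels = np.array([d.label for d in toks])

subs = build_topic_subdatasets(rel, tw, labels)
ranked = rank_topics([score_topic(s, seed=40 + s.topic_id) for s in subs])

kind = {0: "class-0", 1: "class-0", 2: "class-1", 3: "class-1",
        4: "shared", 5: "shared"}
print("rank  topic  kind     score")
for s in ranked:
    print(f"{s.rank:>4}  {s.topic_id:>5}  {kind[s.topic_id]:<8} {s.score:.3f}")
print("\nClass-linked topics separate the labels (score ≈ 0.72: a single")
print("topic covers ~45% of its class, so its ceiling is 0.5·0.45+0.5);")
print("shared topics score at chance (~0.5).")
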