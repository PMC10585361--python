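"""Generate a synthetic short-text corpus with known topic structure.

Documents follow the mixture-of-unigrams model: one latent topic per
document, class-linked topic proportions, Poisson title lengths.  The
separable preset has six topics — two exclusive to each class and two
shared-noise topics — so downstream components can be validated against
ground truth.
"""

import numpy as np

from topicfuse import GeneratorConfig, generate_dmm_corpus, \
    make_separable_preset, write_corpus_files

corpus = make_separable_preset(seed=7)
labels = np.array([d.label for d in corpus.documents])
lengths = np.array([len(d.text.split()) for d in corpus.documents])

print(f"documents:            {len(corpus.documents)}")
print(f"class balance:        {labels.mean():.3f}  (positive fraction)")
print(f"mean title length:    {lengths.mean():.2f} tokens "
      "(Poisson mean 8, truncated at 1)")
print(f"true topics:          {corpus.true_phi.shape[0]} "
      "(0-1 class 0 only, 2-3 class 1 only, 4-5 shared)")
print("first document:      ", corpus.documents[0].text[:60], "...")

write_corpus_files(corpus, "separable_corpus.tsv", "separable_truth.tsv")
print("wrote separable_corpus.tsv / separable_truth.tsv")

# a smaller custom corpus in 'realistic' mode: decoy stopwords/punctuation
# exercise the full preprocessing chain
small = generate_dmm_corpus(GeneratorConfig(
    K_true=3, V=90, D=200, doc_length_lambda=6.9, realistic=True, seed=7,
))
print("\nrealistic-mode text: ", small.documents[0].text[:70], "...")
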