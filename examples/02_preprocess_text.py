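"""Normalize raw titles into term vectors.

The chain: case-fold, strip punctuation/digits, tokenize, drop tokens
shorter than 3 characters and stopwords, Snowball-stem; then a corpus
frequency cutoff prunes rare terms and documents become relative
term-frequency vectors (each row sums to 1).
"""

from topicfuse import (RawDocument, build_bow, build_vocabulary,
                       preprocess_document, tokenize_corpus)

titles = [
    ("t1", "Drug-Induced Liver Injury: 2 Case Reports", 1),
    ("t2", "Deep learning for liver lesion classification", 1),
    ("t3", "A survey of graph neural networks", 0),
    ("t4", "Liver injury induced by herbal drugs", 1),
]

print("normalized tokens:")
for doc_id, text, _ in titles:
    print(f"  {doc_id}: {text!r}\n      -> {preprocess_document(text)}")

docs = [RawDocument(i, t, y) for i, t, y in titles]
tokenized = tokenize_corpus(docs)
vocab = build_vocabulary(tokenized, min_corpus_frequency=1)
bow = build_bow(tokenized, vocab, weighting="relative_tf")

print(f"\nvocabulary ({len(vocab)} stems): {list(vocab.terms)}")
print("relative-TF row sums (1.0 when any term is in vocabulary):",
      bow.values.sum(axis=1).round(6).tolist())
print("row t1:", dict(zip(vocab.terms, bow.values[0].round(3))))
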