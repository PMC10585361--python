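# Methods

## The model

`topicfuse` classifies binary-labeled short texts by selecting features at
the level of *topics* rather than individual words. The topic model is a
Dirichlet-multinomial mixture (DMM): each document d is generated by
exactly one latent topic z_d, with

- cluster proportions θ ~ Dirichlet(α) (symmetric, per-cluster α),
- per-cluster word distributions φ_k ~ Dirichlet(β) (symmetric, per-term β),
- tokens of d drawn i.i.d. from φ_{z_d}.

The one-topic-per-document assumption is what makes the model suitable for
titles: a sentence-length document rarely mixes topics, and pooling whole
documents into clusters gives the word-count statistics the density that
per-token topic models lack on sparse data.

Collapsing θ and φ analytically leaves a Gibbs sampler over the assignment
vector z alone. A sweep visits documents in index order; removing document
d's counts and sampling its cluster from

p(z_d = k | z_−d, data) ∝ (m_k + α) ·
  Π_{w∈d} Π_{j=1..N_d^w} (n_kw + β + j − 1) /
  Π_{i=1..N_d} (n_k + Vβ + i − 1)

where m_k counts documents in cluster k, n_kw tokens of term w in cluster
k, n_k all tokens in cluster k, V the vocabulary size and N_d^w, N_d the
document's term and total counts. The conditional is evaluated in log
space with max-subtraction before exponentiation. Clusters may empty and
re-populate naturally; no resurrection heuristic is applied. The final
sweep's state is the point estimate — no burn-in discard or averaging for
point estimates, keeping the estimate a single self-consistent state.

Two byproducts feed the selection stages:

- **TW**: per topic, the m most probable terms under the posterior mean
  φ̂_kw = (n_kw + β)/(n_k + Vβ); ties break by vocabulary index, so an
  empty cluster (uniform φ̂ = 1/V) lists the first m vocabulary terms.
- **TD**: per document, the posterior cluster probabilities computed from
  the same collapsed conditional. Training documents are scored with
  their own counts removed (leave-own-counts-out) to avoid
  self-reinforcement; unseen documents use the state as-is. The soft
  probability vector is the default (a one-hot option exists) because the
  fused feature block is meant to carry "how much of each topic" rather
  than a hard cluster id.

## The selection-and-classification pipeline

Per Monte-Carlo cross-validation repetition (default 10 stratified 90/10
splits; per class the training count is round(0.9 · class size)):

1. vocabulary and topic model are fitted on the **training split only** —
   the methodologically sound default; a `fit_on_full_corpus` flag
   reproduces whole-corpus fitting for compatibility with workflows that
   model first and split later;
2. each of the K topics' term lists slices a sub-dataset from the
   training relative-term-frequency table; a stratified 5-fold CV of a
   random forest (100 trees) scores the topic by mean accuracy (AUC
   optional); a fully out-of-vocabulary topic scores the majority-class
   proportion so ranks remain a permutation;
3. topics are ranked (descending score, ties by topic id); for each
   i = 1..r the union of the top-i topics' terms — in ranked traversal
   order, duplicates dropped, so columns are stable — forms the feature
   set, fused with the K TD columns in `tw_plus_td` mode;
4. a 100-tree random forest is trained per level and evaluated on the
   held-out documents projected into the training feature space (unseen
   terms ignored; test TD rows from the posterior with full counts);
   seven metrics are computed from the confusion counts, AUC as the
   Mann–Whitney rank statistic with half credit for ties, Cohen's κ from
   the marginal-product chance agreement. Ratios with empty denominators
   report 0 with an `undefined` flag rather than NaN.

Means per level over repetitions form the performance table (written as
percentages with two decimals). `select_best_subset` takes the argmax of
a chosen metric's mean, preferring smaller i on ties. Because the table
is computed on the same test splits used to report performance, selecting
i from it is optimistic; honest subset selection requires a nested or
separate validation split.

Inside `score_topic` the sub-dataset's columns are sorted canonically
(by term string) before fitting, making the score invariant to the
column order in which a topic's terms arrive.

## Preprocessing

Case-fold; replace every non-alphabetic character with a space; tokenize
on whitespace; drop tokens shorter than 3 characters; drop stopwords
(scikit-learn's English list by default, overridable by file); stem with
a native implementation of the Porter2 (Snowball English) algorithm.
The length filter runs before stemming; stems that end up shorter than
three characters are kept. A corpus frequency cutoff (default 20 in
words-only mode) prunes rare terms; it counts total term occurrences by
default, with a document-frequency option, and is disabled (cutoff 1) in
fused mode, where preserving vocabulary helps. Document vectors are
relative term frequencies: count divided by the document's
*in-vocabulary* token count, so every non-empty row sums to exactly 1
(the raw-length denominator is available as an option).

## Hyperparameters

| parameter | default | meaning / why |
|---|---|---|
| K | 20 | clusters in the mixture; generous relative to expected topic count — surplus clusters empty out |
| m (words/topic) | 20 | terms kept per topic in TW |
| α | 0.1 | Dirichlet prior on cluster proportions; small values let clusters empty |
| β | 0.01 | Dirichlet prior on word distributions; small values keep topics lexically sharp |
| Gibbs sweeps | 1000 | comfortably past convergence for 10³–10⁴ short documents |
| MCCV | 10 × 90/10 | stratified random splits |
| internal CV folds | 5 | topic scoring |
| forests | 100 trees | both the topic scorer and the final classifier |

α and β are taken as given symmetric per-topic/per-term priors (no
scaling of α by K).

## The synthetic generator

`generate_dmm_corpus` emulates labeled title-length corpora from the same
generative model the sampler assumes: class ~ Bernoulli(class prior),
topic ~ class-conditional topic distribution, length ~ max(1, Poisson(λ))
with λ = 8 by default (title-length statistics; E[max(1,Poisson(λ))] =
λ + e^{−λ}), tokens i.i.d. from the topic's word distribution. With
`exclusive_vocab` the topics occupy disjoint vocabulary blocks, giving
unambiguous ground truth for recovery tests. Terms are synthetic strings
(`w0000`…) that bypass preprocessing; `realistic=True` instead emits
consonant-only aliases (invariant under the stemmer by construction)
wrapped in decoy stopwords, digits and punctuation so the full
normalization chain can be exercised end to end.

The separable benchmark (`make_separable_preset`): 6 topics, V=600,
D=2000, balanced classes; topics 0–1 occur only under class 0, 2–3 only
under class 1, and 4–5 are shared noise at probability 0.05 each under
both classes. Within a class the two exclusive topics are equally likely
(0.45 each). Word-distribution concentration is 0.5 per term so that
every topic exhibits well over 20 distinct terms in a 2,000-document
corpus; with much sparser topics a topic's 20-word list would be padded
through the zero-count tie rule with other topics' terms, an artifact
unrelated to what the benchmark is meant to probe. Roughly 10% of
documents come from shared topics and are irreducibly ambiguous, so the
Bayes-optimal F1 is about 0.95.

What passing on this generator does and does not show: the corpus
matches the sampler's model family exactly — real titles have burstier
word repetition, correlated topics, and vocabulary mismatch between
splits. Results on the benchmark validate the machinery (inference,
selection, evaluation plumbing, leakage-freedom), not expected
performance on any real corpus.

A single class-exclusive topic cannot score near 1.0 here: it covers
only ~45% of its class (its sibling covers the rest), so the Bayes
accuracy of its sub-dataset is 0.5·0.45 + 0.5 ≈ 0.72 — exactly where the
scores land. Shared-noise topics score at chance. Near-perfect
single-topic scores arise only when one topic covers essentially all of
a class, a construction exercised separately in the unit tests.

## Numerical and design notes

- The Gibbs kernel (numba-jitted) threads an explicit PCG32 state through
  all draws, so fits are bit-reproducible from a seed and independent of
  global RNG state. Initialization assigns documents uniformly at random
  from a seeded generator.
- Verifying the sampler against the exactly enumerated posterior
  (all K^D assignments scored by the collapsed Dirichlet-multinomial
  joint) compares *label-permutation-averaged* distributions: mixture
  labels are non-identifiable, and a finite chain allocates visits
  between the K! symmetric modes with large variance even when the
  within-mode distribution is correct.
- Documents with no in-vocabulary tokens are assigned by the cluster-size
  prior alone (and produce prior-proportional TD rows) with a warning.
- Degenerate ties: equal φ̂ values order by vocabulary index; equal topic
  scores order by topic id; equal performance-table values select the
  smaller accumulation level.
- Imported TD rows are renormalized when within 1e-3 of summing to 1 and
  rejected otherwise; imported TW terms outside the corpus vocabulary are
  kept but logged (they simply never match a bag-of-words column).
- Test-suite and acceptance-script problem sizes: the sampler-exactness
  suite uses corpora of 4–8 documents over 3–6 terms with 20,000 recorded
  sweeps; recovery uses D=2000, V=300, K_true=5 with K=10 over 5 seeds;
  pipeline checks run the full reference configuration on the separable
  benchmark; the determinism check uses a reduced configuration (3
  repetitions, 200 sweeps), since reproducibility is
  configuration-independent.

## Known limitations

- Binary classification only; multi-class scoring and metrics are out of
  scope.
- Only the DMM family is implemented natively; other short-text topic
  models participate through the TW/TD import interface.
- The final-classifier and scorer hyperparameters (100-tree forests) are
  fixed rather than tuned; the scorer is pluggable in code but no model
  search is provided.
- Relative term frequency is the only weighting (no TF-IDF, no n-grams).
- The stemmer implements the Porter2 algorithm for English only.
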