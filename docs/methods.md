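# Methods

This note records the model, the numerical choices, and the limits of
what the test suite demonstrates.

## Model and assumptions

The pipeline treats topic modeling as weighted bag-of-words clustering
followed by probabilistic normalization. Its assumptions, in order of
appearance:

- **Exchangeable tokens.** Only counts matter; word order, syntax and
  n-grams are ignored.
- **Discrimination lives in rarity.** The FP-IDF global weight
  `log(M·N·(N−n_t)/n_t²)` assumes a term's usefulness for separating
  topics decays with its document frequency `n_t`. It is the sum (log of
  the product) of a hybrid IDF `log(M·N/n_t)` and a probabilistic IDF
  `log((N−n_t)/n_t)`, so it falls twice as fast in `log n_t` as a plain
  IDF and crosses zero well before `n_t = N` (at the root of
  `M·N·(N−n_t) = n_t²`); sufficiently common terms are floored to zero
  weight and effectively removed.
- **Topics are geometric clusters.** After PCA, documents of one topic
  are assumed to form a cluster in the weighted-count geometry; the
  fuzzy membership `v_jk` of document *j* in cluster *k* is read
  directly as `P(T_k|D_j)`. No generative story (and hence no held-out
  inference for unseen documents) is attached.
- **Kernel combination.** Cluster shape is captured by a convex
  combination of unit-diagonal kernels rather than a single metric; the
  per-iteration weight update `z_g ∝ 1/β_g` rewards kernels under which
  the current partition is tight.

## Interpretation choices in the weighting algebra

- `M` (the `max n_t'` factor) is read at corpus level — the maximum
  document frequency over the whole vocabulary — so FP-IDF stays a
  per-term vector. A per-document reading (`M_j` = max over the terms of
  document *j*) is available via `apply_weights(per_document_max=True)`.
- Logarithms are natural; any fixed base only rescales all weights.
- The boundary `n_t = N` would give `log 0`; the `(N − n_t)` factor is
  guarded by `ε = 1/(2N)` inside the log (keeping the sum identity exact
  everywhere), and all global weights are floored at 0 before
  multiplication so downstream probability tables stay nonnegative.
- Default local weight is raw `tf`; per-document cosine normalization
  (`local_scheme="cosine_normalized"`) is the alternative when document
  length variation should be removed before weighting.

## PCA

Documents are observations; only mean-centering is applied (per-term
standardization would undo the term weighting). The default retains the
components explaining 95 % of variance, capped at `min(n−1, 200)`;
an integer component count is accepted too. Components are computed by
LAPACK SVD and sign-fixed so the largest-magnitude loading of each
component is positive, making every run bit-reproducible. Probabilities
are always computed from the **pre-PCA** weighted matrix — scores are
signed and only feed the clustering geometry.

## Clustering

- **Kernel bank**: three Gaussians with bandwidths {0.5, 1, 2} × the
  median pairwise distance of the reduced documents — self-scaling and
  unit-diagonal. Linear and polynomial kernels are available and are
  diagonal-normalized (`G/√(G_ii G_jj)`) so all kernels are
  commensurable.
- **Hyperparameters**: fuzzifier `s = 2`, tolerance `ε = 1e-5` on the
  Frobenius norm of the membership change, `max_iter = 100`. These are
  the conventional fuzzy-c-means defaults.
- **Initialization**: the uniform membership matrix `V = 1/F` is a fixed
  point of the update, and on high-dimensional document vectors it is
  *attracting*: near-uniform random starts (e.g. Dirichlet(1) rows)
  frequently collapse into it, merging clusters. The default start
  therefore picks `F` documents by the k-means++ rule and sets
  memberships by the inverse-distance update applied to those seed
  points — far from the uniform fixed point, deterministic given the
  seed. `init="random"` restores the Dirichlet(1) start for comparison.
- **Degeneracies**: `β_g = 0` (a kernel fits perfectly) is guarded by
  `1e-12` before inversion; a zero combined distance assigns membership
  uniformly over the zero-distance clusters; a cluster whose membership
  column dies falls back to uniform centroid weights. Squared
  feature-space distances are clipped at 0 (they are nonnegative up to
  round-off for PSD kernels). Hard assignments break ties toward the
  lowest cluster index.

## Probability tables

All five tables are exact normalizations, so the invariants
(`ΣP(D)=1`, row-stochastic `P(T|D)`, column-stochastic `P(D|T)`,
`P(W|D)`, `P(W|T)`) hold to round-off after every fit. A topic with zero
joint mass keeps a uniform `P(D|T)` column (with a warning) so K is
preserved. The corpus log-likelihood is the *training* likelihood
`Σ tf_ij log(Σ_k P(w_i|T_k)P(T_k|d_j) + 1e-12)`; the epsilon keeps it
finite when a count falls on a zero-probability mixture entry.

## Evaluation

- The Calinski–Harabasz index uses squared Euclidean distances (the
  classic variance-ratio form); `squared=False` gives the literal
  unsquared reading. Zero within-cluster scatter returns `+inf`, zero
  between-cluster scatter returns 0. The clustering protocol for CH is
  seeded k-means on the `P(T|D)` rows, with argmax membership as the
  alternative.
- The classifier is a linear (shared-covariance) Gaussian discriminant
  with ridge `λ = 1e-6 · trace/dim`, empirical priors, and the
  expected-cost decision rule; with the default 0–1 cost it is exactly
  the posterior argmax. Cross-validation is stratified, shuffled with
  the given seed, and macro-averaged over pooled out-of-fold
  predictions. Hyperparameter search over the classifier is deliberately
  out of scope.

## Synthetic corpora: what they emulate and what they do not

The generator plants `K_true` topics as Dirichlet-drawn word
distributions (by default over **disjoint** vocabulary blocks,
concentration 0.05 — sharp, nearly non-overlapping topics), draws each
document's topic mixture from Dirichlet(0.08) (nearly pure documents),
samples token counts multinomially with Poisson(60) lengths, and
emulates redundancy by duplicating a fraction of documents with 10 %
token dropout. Defaults: `K_true=5`, `vocab_size=500`, `n_docs=200`.

These corpora reproduce the *sparsity* and *redundancy* of biomedical
text, but not Zipfian word frequencies, topic correlation, polysemy,
stopword noise or document-length skew. Passing recovery tests therefore
shows the pipeline separates well-posed mixtures under realistic noise
and duplication; it does not bound performance on real corpora. Note the
regime's own ceiling: with Dirichlet(0.08) mixtures a few documents are
genuinely ambiguous (near 50/50 topics), so even an oracle partition
scores ARI ≈ 0.92–0.95 against the argmax labels, and measured ARI
varies with the generator seed in that band.

The recovery score matches recovered to planted topics greedily by
cosine of word distributions (one-to-one) and reports the adjusted Rand
index between dominant-topic assignments and planted labels; both are
invariant to topic relabeling and document order.

## Problem sizes

Unit tests run on compact instances (tens of documents, vocabulary
≤ 100); recovery and normalization checks run the generator's default
200-document, 500-word conditions over three seeds, and the full suite
plus the acceptance script complete in a few seconds on one CPU.

## Known limitations

- No out-of-sample inference: topics describe the training corpus only.
- The membership collapse described above means results with
  `init="random"` can depend strongly on the seed; the k-means++ start
  removes most but not all sensitivity (fuzzy c-means remains a local
  optimizer).
- FP-IDF's zero-flooring silently deletes terms occurring in more than
  about half the documents (where the probabilistic component is
  negative enough); on tiny corpora this can remove informative words.
- The log-likelihood is comparable across models only on the identical
  corpus and vocabulary.
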