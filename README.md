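# mkftm — multiple-kernel fuzzy topic modeling

`mkftm` discovers latent topics in text corpora — aimed at biomedical
collections (abstracts, clinical notes, case reports), which are sparse,
redundant and noisy — by combining a discriminative global term weighting
with fuzzy clustering in a learned multiple-kernel feature space. It is a
library plus a small CLI for text-mining practitioners who want a topic
model whose every stage is an inspectable linear-algebra step rather than
a latent-variable sampler.

## The method

Starting from a preprocessed corpus (punctuation stripping, lowercasing,
stopword and short-token removal, Porter stemming), the pipeline is:

1. **Bag-of-words counts** `tf_ij` (term *i*, document *j*).
2. **Fusion probabilistic IDF (FP-IDF)** global term weights. With *N*
   documents, document frequency `n_t`, and `M = max_t n_t`:

   `fp_idf(t) = log( M · N · (N − n_t) / n_t² )
              = log(M · N / n_t) + log((N − n_t) / n_t)`

   — the log-product fusion of a hybrid IDF and a probabilistic IDF.
   It decays strictly with `n_t`, so ubiquitous high-frequency terms
   (which carry no discrimination value) are driven to zero, more
   aggressively than either component alone. The weighted matrix is
   `w_ij = tf_ij · max(fp_idf(i), 0)`.
3. **PCA de-noising** of the weighted document vectors (components
   explaining 95 % of variance by default), which removes redundant
   directions before clustering.
4. **Multiple-kernel fuzzy c-means (MKFCM)**: documents are clustered in
   the feature space of a convex combination of Gaussian kernels
   (bandwidths {0.5, 1, 2} × median pairwise distance). Each iteration
   computes feature-space distances `α_ifg` of every document to every
   fuzzy centroid under every kernel, re-weights the kernels
   (`z_g ∝ 1/β_g`, favoring kernels that fit the current partition), and
   updates the row-stochastic membership matrix `V` with the classic
   inverse-distance rule (fuzzifier `s = 2`).
5. **Probability tables**. Reading the converged membership as `P(T|D)`,
   the model derives `P(D)`, `P(D,T)`, `P(D|T)`, `P(W|D)` and
   `P(W|T) = Σ_j P(W|D_j) P(D_j|T)` — a complete probabilistic topic
   model: every topic is a distribution over words, every document a
   distribution over topics.

Evaluation utilities cover the Calinski–Harabasz cluster validity index,
the training-corpus log-likelihood under the topic mixture, and a
cost-sensitive linear discriminant classifier
(`ŷ = argmin_y Σ_k p̂(k|x) C(y|k)`) on the `P(T|D)` features with
stratified cross-validation. A synthetic-corpus generator with planted
topics (Dirichlet-multinomial mixture, optional near-duplicate
redundancy) makes every stage testable end to end.

## Worked example

```python
from mkftm import synthetic, topic_model, evaluation, weighting

truth = synthetic.generate(synthetic.SyntheticSpec(seed=1))   # 200 docs, 5 planted topics
model = topic_model.fit_mkftm(truth.corpus, K=5,
                              config=topic_model.PipelineConfig(seed=1))
report = synthetic.score_recovery(model, truth)

print('iterations:', model.meta['n_iter'], ' converged:', model.meta['converged'])
print('kernel weights:', [round(z, 3) for z in model.meta['kernel_weights']])
print('topic 0 top words:', topic_model.top_words(model, 0, 5))
print('ARI vs planted labels: %.3f' % report['ari'])
print('mean matched topic cosine: %.3f' % report['mean_matched_cosine'])
dtm = weighting.build_doc_term_matrix(truth.corpus)
print('corpus log-likelihood: %.1f' % evaluation.corpus_log_likelihood(model, dtm))
```

prints

```
iterations: 20  converged: True
kernel weights: [0.068, 0.203, 0.729]
topic 0 top words: ['w0343', 'w0300', 'w0382', 'w0320', 'w0392']
ARI vs planted labels: 0.933
mean matched topic cosine: 0.954
corpus log-likelihood: -38179.8
```

The adjusted Rand index (0.93) says the dominant-topic partition of the
200 documents almost coincides with the planted one; the matched cosine
(0.95) says the recovered topic-word distributions align with the planted
distributions after the best one-to-one topic matching; the
log-likelihood is the (always nonpositive) score of the observed counts
under the fitted mixture — useful for comparing fits, e.g. across K.

The same run from the shell:

```sh
mkftm synth --out corpus.txt --truth truth.json --seed 1
mkftm fit corpus.txt --k 5 --seed 1 --pretokenized --out model/
mkftm evaluate model/ corpus.txt --mode loglik --pretokenized --out ll.json
```

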