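"""Cluster validity, corpus likelihood, and the discriminant classifier."""

import numpy as np
import pytest
from sklearn.metrics import calinski_harabasz_score

from mkftm import evaluation as ev, topic_model as tm
from mkftm.exceptions import ConfigError, StateError, UndefinedIndexError
from mkftm.weighting import build_doc_term_matrix

from conftest import make_corpus, make_dtm


def test_ch_hand_computed_value():
    # 1-D points {0,1,10,11} in two pairs: between = 2*25 + 2*25 = 100,
    # within = 4 * 0.25 = 1, factor (4-2)/(2-1) = 2  ->  CH = 200
    points = np.array([0.0, 1.0, 10.0, 11.0])
    labels = np.array(["A", "A", "B", "B"])
    assert np.isclose(ev.calinski_harabasz(points, labels), 200.0)


def test_ch_degenerate_cases():
    assert ev.calinski_harabasz(np.array([0.0, 5.0]), np.array([0, 1])) == np.inf
    assert ev.calinski_harabasz(np.zeros(4), np.array([0, 0, 1, 1])) == 0.0
    with pytest.raises(UndefinedIndexError):
        ev.calinski_harabasz(np.arange(4.0), np.zeros(4))


def test_ch_matches_sklearn():
    rng = np.random.default_rng(21)
    X = np.vstack([rng.normal(0, 1, (15, 3)), rng.normal(4, 1, (20, 3))])
    labels = np.array([0] * 15 + [1] * 20)
    assert np.isclose(
        ev.calinski_harabasz(X, labels), calinski_harabasz_score(X, labels), rtol=1e-10
    )


def test_ch_invariances():
    rng = np.random.default_rng(22)
    X = rng.normal(size=(12, 2))
    labels = rng.integers(0, 2, 12)
    while len(np.unique(labels)) < 2:
        labels = rng.integers(0, 2, 12)
    base = ev.calinski_harabasz(X, labels)
    theta = 0.7
    R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    moved = X @ R.T + np.array([3.0, -2.0])
    assert np.isclose(ev.calinski_harabasz(moved, labels), base, rtol=1e-8)
    assert np.isclose(ev.calinski_harabasz(X, 1 - labels), base, rtol=1e-12)


def build_model_from_tables(P_W_given_T, P_T_given_D, vocab, doc_ids):
    import scipy.sparse as sp

    n, K = P_T_given_D.shape
    return tm.TopicModel(
        K=K,
        P_D=np.full(n, 1.0 / n),
        P_T_given_D=P_T_given_D,
        P_D_joint_T=P_T_given_D / n,
        P_D_given_T=np.full((n, K), 1.0 / n),
        P_W_given_D=sp.csr_matrix(np.full((len(vocab), n), 1.0 / len(vocab))),
        P_W_given_T=P_W_given_T,
        vocabulary=vocab,
        doc_ids=doc_ids,
    )


def test_log_likelihood_certainty_and_uniform():
    dtm = make_dtm([[3]], vocab=["w"], docs=["0"])
    model = build_model_from_tables(np.array([[1.0]]), np.array([[1.0]]), ["w"], ["0"])
    assert abs(ev.corpus_log_likelihood(model, dtm)) < 1e-9
    # uniform mixture over m words: LL = total_tokens * log(1/m)
    counts = np.array([[2, 1], [0, 3], [1, 1]])
    dtm = make_dtm(counts)
    m, n = counts.shape
    model = build_model_from_tables(
        np.full((m, 2), 1.0 / m), np.full((n, 2), 0.5), dtm.vocabulary, dtm.doc_ids
    )
    expected = counts.sum() * np.log(1.0 / m)
    assert np.isclose(ev.corpus_log_likelihood(model, dtm), expected, atol=1e-6)


def test_log_likelihood_hand_sum():
    counts = np.array([[2, 0], [1, 1], [0, 3]])
    dtm = make_dtm(counts)
    PWT = np.array([[0.7, 0.1], [0.2, 0.3], [0.1, 0.6]])
    PTD = np.array([[0.9, 0.1], [0.2, 0.8]])
    model = build_model_from_tables(PWT, PTD, dtm.vocabulary, dtm.doc_ids)
    hand = 0.0
    for j in range(2):
        for i in range(3):
            if counts[i, j]:
                mix = sum(PWT[i, k] * PTD[j, k] for k in range(2))
                hand += counts[i, j] * np.log(mix + 1e-12)
    assert np.isclose(ev.corpus_log_likelihood(model, dtm), hand, atol=1e-12)
    assert ev.corpus_log_likelihood(model, dtm) <= 0


def test_log_likelihood_vocabulary_mismatch():
    dtm = make_dtm([[1]], vocab=["x"], docs=["0"])
    model = build_model_from_tables(np.array([[1.0]]), np.array([[1.0]]), ["y"], ["0"])
    with pytest.raises(StateError):
        ev.corpus_log_likelihood(model, dtm)


def test_planted_tables_score_no_worse_than_fit(small_model, small_truth):
    """The generator's own tables should explain the corpus at least as
    well as the fitted ones, up to sampling noise."""
    corpus = small_truth.corpus
    dtm = build_doc_term_matrix(corpus)
    fitted_ll = ev.corpus_log_likelihood(small_model, dtm)
    index = {t: i for i, t in enumerate(small_truth.vocab)}
    rows = [index[t] for t in dtm.vocabulary]
    PWT = small_truth.planted_topic_word.T[rows]
    PWT = PWT / PWT.sum(axis=0, keepdims=True)
    planted = build_model_from_tables(
        PWT, small_truth.planted_doc_topic, dtm.vocabulary, dtm.doc_ids
    )
    planted_ll = ev.corpus_log_likelihood(planted, dtm)
    n_tokens = dtm.counts.sum()
    assert planted_ll >= fitted_ll - 0.5 * n_tokens  # generous sampling-noise slack


def test_discriminant_separable_and_validation():
    X = np.vstack([np.tile([0.0, 0.0], (5, 1)), np.tile([10.0, 10.0], (5, 1))])
    X += np.random.default_rng(0).normal(0, 0.01, X.shape)
    y = np.array(["a"] * 5 + ["b"] * 5)
    model = ev.train_discriminant(X, y)
    assert list(ev.classify_batch(model, X)) == list(y)
    with pytest.raises(ConfigError):
        ev.train_discriminant(X, np.array(["a"] * 10))


def test_discriminant_mean_recovery():
    rng = np.random.default_rng(30)
    mu_a, mu_b = np.array([0.0, 1.0]), np.array([2.0, -1.0])
    n = 400
    X = np.vstack([rng.normal(mu_a, 1.0, (n, 2)), rng.normal(mu_b, 1.0, (n, 2))])
    y = np.array([0] * n + [1] * n)
    model = ev.train_discriminant(X, y)
    se = 1.0 / np.sqrt(n)
    assert np.all(np.abs(model.means[0] - mu_a) < 3 * se)
    assert np.all(np.abs(model.means[1] - mu_b) < 3 * se)


def test_cost_sensitive_decision():
    # 0-1 cost: argmax posterior
    assert ev.min_expected_cost_class(np.array([0.9, 0.1]), ev.zero_one_cost(2)) == 0
    # tied posterior; C[y, k] is the cost of predicting y when k is true.
    # Predicting class 0 risks cost 10 (if truth is 1), predicting class 1
    # risks cost 1: expected costs [5.0, 0.5] -> choose class 1.
    cost = np.array([[0.0, 10.0], [1.0, 0.0]])
    assert ev.min_expected_cost_class(np.array([0.5, 0.5]), cost) == 1


def test_zero_one_cost_equals_argmax_bruteforce():
    rng = np.random.default_rng(31)
    K = 4
    cost = ev.zero_one_cost(K)
    for _ in range(1000):
        p = rng.dirichlet(np.ones(K))
        assert ev.min_expected_cost_class(p, cost) == int(np.argmax(p))


def test_cross_validate_separable_and_deterministic():
    rng = np.random.default_rng(32)
    X = np.vstack([rng.normal(0, 0.2, (30, 2)), rng.normal(5, 0.2, (30, 2))])
    y = np.array(["x"] * 30 + ["y"] * 30)
    rep = ev.cross_validate(X, y, folds=5, seed=1)
    assert rep["accuracy"] == 1.0 and rep["f1"] == 1.0
    rep2 = ev.cross_validate(X, y, folds=5, seed=1)
    assert rep == rep2
    with pytest.raises(ConfigError):
        ev.cross_validate(X[:31], y[:31], folds=5, seed=1)  # class "y" too small


def test_cross_validate_permutation_null():
    rng = np.random.default_rng(33)
    X = rng.normal(size=(200, 3))
    accs = []
    for rep in range(10):
        y = rng.permutation([0] * 100 + [1] * 100)
        accs.append(ev.cross_validate(X, y, folds=5, seed=rep)["accuracy"])
    assert abs(np.mean(accs) - 0.5) < 0.05


def test_hard_cluster_labels_modes(small_model):
    arg = ev.hard_cluster_labels(small_model.P_T_given_D, method="argmax")
    assert np.array_equal(arg, np.argmax(small_model.P_T_given_D, axis=1))
    km = ev.hard_cluster_labels(small_model.P_T_given_D, K=3, method="kmeans", seed=0)
    assert len(np.unique(km)) >= 2
    km2 = ev.hard_cluster_labels(small_model.P_T_given_D, K=3, method="kmeans", seed=0)
    assert np.array_equal(km, km2)
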