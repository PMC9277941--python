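"""Evaluation utilities: cluster validity, corpus likelihood, and a
cost-sensitive discriminant classifier on topic features.

The Calinski-Harabasz index is the classic variance-ratio criterion

    CH = [(N - K) / (K - 1)] * [sum_k |C_k| d(c_k, x_bar)] /
                               [sum_k sum_{x in C_k} d(x, c_k)]

with d the squared Euclidean distance by default (an unsquared variant
is available behind a flag).  The corpus log-likelihood scores counts
under the mixture P(w|d) = sum_k P(w|T_k) P(T_k|d).  Classification on
P(T|D) rows uses a shared-covariance Gaussian (linear discriminant)
model with the expected-cost decision rule

    y_hat = argmin_y sum_k p(k|x) C(y|k),

which with 0-1 costs reduces to the maximum-posterior class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.sparse as sp
from sklearn.cluster import KMeans
from sklearn.metrics import precision_recall_fscore_support
from sklearn.model_selection import StratifiedKFold

from .exceptions import ConfigError, InputError, NumericError, StateError, UndefinedIndexError
from .topic_model import TopicModel
from .weighting import DocTermMatrix

_LL_EPS = 1e-12


def calinski_harabasz(points: np.ndarray, labels: np.ndarray, squared: bool = True) -> float:
    """Variance-ratio cluster validity index (higher = better separated).

    Degenerate partitions: zero within-cluster scatter with positive
    between-cluster scatter returns +inf; zero between-cluster scatter
    returns 0.0.
    """
    X = np.atleast_2d(np.asarray(points, dtype=float))
    if X.shape[0] == 1:
        X = X.T
    labels = np.asarray(labels)
    if labels.shape[0] != X.shape[0]:
        raise InputError("labels and points disagree in length")
    uniq, inv = np.unique(labels, return_inverse=True)
    K = len(uniq)
    N = X.shape[0]
    if K < 2:
        raise UndefinedIndexError("CH index needs at least 2 clusters")

    def d(a, b):
        sq = np.sum((a - b) ** 2, axis=-1)
        return sq if squared else np.sqrt(sq)

    grand = X.mean(axis=0)
    between = 0.0
    within = 0.0
    for k in range(K):
        members = X[inv == k]
        centroid = members.mean(axis=0)
        between += len(members) * float(d(centroid, grand))
        within += float(np.sum(d(members, centroid)))
    if between == 0.0:
        return 0.0
    if within == 0.0:
        return float("inf")
    return ((N - K) / (K - 1)) * between / within


def hard_cluster_labels(
    P_T_given_D: np.ndarray, K: int | None = None, method: str = "kmeans", seed: int = 0
) -> np.ndarray:
    """Hard document clusters from the topic proportions.

    ``method="kmeans"`` (the evaluation protocol: seeded k-means on the
    P(T|D) rows) or ``method="argmax"`` (maximum-membership topic).
    """
    P = np.asarray(P_T_given_D, dtype=float)
    if method == "argmax":
        return np.argmax(P, axis=1)
    if method == "kmeans":
        k = K if K is not None else P.shape[1]
        return KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(P)
    raise ConfigError(f"unknown clustering method: {method!r}")


def corpus_log_likelihood(model: TopicModel, dtm: DocTermMatrix) -> float:
    """Training-corpus log-likelihood under the topic mixture.

    LL = sum_j sum_i tf_ij * log( sum_k P(W_i|T_k) P(T_k|D_j) + eps ),
    always finite and nonpositive for proper mixture probabilities.
    """
    if model.vocabulary != dtm.vocabulary or model.doc_ids != dtm.doc_ids:
        raise StateError("model and count matrix must share vocabulary and documents")
    mix = model.P_W_given_T @ model.P_T_given_D.T  # (m, n)
    coo = sp.coo_matrix(dtm.counts)
    return float(np.sum(coo.data * np.log(mix[coo.row, coo.col] + _LL_EPS)))


@dataclass
class ClassifierModel:
    """Shared-covariance Gaussian discriminant over topic features."""

    classes: list
    means: np.ndarray  # (K_cls, d)
    precision: np.ndarray  # (d, d) inverse of the pooled covariance
    log_priors: np.ndarray  # (K_cls,)
    cost_matrix: np.ndarray  # (K_cls, K_cls), C[y, k] = cost of predicting y when k is true


def zero_one_cost(n_classes: int) -> np.ndarray:
    return np.ones((n_classes, n_classes)) - np.eye(n_classes)


def train_discriminant(
    features: np.ndarray,
    labels: np.ndarray,
    cost_matrix: np.ndarray | None = None,
    ridge_scale: float = 1e-6,
) -> ClassifierModel:
    """Fit class means, empirical priors and a ridge-regularized pooled
    covariance (lambda = ridge_scale * trace / dim)."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes = sorted(set(y.tolist()))
    if len(classes) < 2:
        raise ConfigError("need at least 2 classes")
    d = X.shape[1]
    means = np.empty((len(classes), d))
    priors = np.empty(len(classes))
    scatter = np.zeros((d, d))
    for c, cls in enumerate(classes):
        members = X[y == cls]
        if len(members) < 2:
            raise ConfigError(f"class {cls!r} has fewer than 2 examples")
        means[c] = members.mean(axis=0)
        priors[c] = len(members) / len(X)
        centered = members - means[c]
        scatter += centered.T @ centered
    cov = scatter / (len(X) - len(classes))
    lam = ridge_scale * np.trace(cov) / d
    if lam <= 0:
        lam = ridge_scale
    cov = cov + lam * np.eye(d)
    try:
        precision = scipy.linalg.inv(cov)
    except scipy.linalg.LinAlgError as exc:  # pragma: no cover - ridge prevents this
        raise NumericError("pooled covariance is singular") from exc
    cost = zero_one_cost(len(classes)) if cost_matrix is None else np.asarray(cost_matrix, float)
    if cost.shape != (len(classes), len(classes)):
        raise ConfigError("cost matrix shape must be (K_cls, K_cls)")
    if (cost < 0).any() or np.any(np.diag(cost) != 0):
        raise ConfigError("cost matrix must be nonnegative with zero diagonal")
    return ClassifierModel(
        classes=classes,
        means=means,
        precision=precision,
        log_priors=np.log(priors),
        cost_matrix=cost,
    )


def posterior(model: ClassifierModel, X: np.ndarray) -> np.ndarray:
    """Class posteriors p(k|x) for each row of X."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.means.shape[1]:
        raise InputError("feature dimension mismatch")
    diff = X[:, None, :] - model.means[None, :, :]  # (n, K, d)
    maha = np.einsum("nkd,de,nke->nk", diff, model.precision, diff)
    logp = -0.5 * maha + model.log_priors[None, :]
    logp -= logp.max(axis=1, keepdims=True)
    p = np.exp(logp)
    return p / p.sum(axis=1, keepdims=True)


def min_expected_cost_class(post: np.ndarray, cost_matrix: np.ndarray) -> int:
    """Index of the class minimizing expected cost; ties go to the lowest
    class index."""
    expected = cost_matrix @ np.asarray(post, dtype=float)
    return int(np.argmin(expected))


def classify(model: ClassifierModel, x: np.ndarray):
    """Predicted class label for one feature vector."""
    p = posterior(model, x)[0]
    return model.classes[min_expected_cost_class(p, model.cost_matrix)]


def classify_batch(model: ClassifierModel, X: np.ndarray) -> np.ndarray:
    P = posterior(model, X)
    idx = [min_expected_cost_class(p, model.cost_matrix) for p in P]
    return np.asarray([model.classes[i] for i in idx])


def cross_validate(
    features: np.ndarray,
    labels: np.ndarray,
    folds: int = 10,
    seed: int = 0,
    cost_matrix: np.ndarray | None = None,
) -> dict:
    """Stratified k-fold evaluation of the discriminant classifier.

    Returns accuracy and macro-averaged precision/recall/F1, computed on
    the pooled out-of-fold predictions; deterministic given the seed.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if folds < 2:
        raise ConfigError("folds must be >= 2")
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        raise ConfigError(
            f"smallest class has {counts.min()} examples; cannot stratify into {folds} folds"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    pred = np.empty(len(y), dtype=object)
    for train_idx, test_idx in skf.split(X, y):
        model = train_discriminant(X[train_idx], y[train_idx], cost_matrix)
        pred[test_idx] = classify_batch(model, X[test_idx])
    accuracy = float(np.mean(pred == y))
    precision, recall, f1, _ = precision_recall_fscore_support(
        y.astype(str), pred.astype(str), average="macro", zero_division=0
    )
    return {
        "accuracy": accuracy,
        "precision": float(precision),
        "recall": float(recall),
        "f1": float(f1),
        "folds": folds,
        "seed": seed,
    }
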