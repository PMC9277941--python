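"""Multiple-kernel fuzzy c-means (MKFCM) clustering.

Points are clustered in the feature space induced by a convex
combination of kernels.  Each iteration, from the current membership
matrix V (rows = points, columns = clusters, row-stochastic):

1. normalize membership powers per cluster:
       v_hat[i, f] = V[i, f]^s / sum_i V[i, f]^s
2. squared feature-space distance of point i to the fuzzy centroid of
   cluster f under kernel g:
       alpha[i, f, g] = G_g(i, i) - 2 sum_j v_hat[j, f] G_g(i, j)
                        + sum_{j, j'} v_hat[j, f] v_hat[j', f] G_g(j, j')
3. per-kernel dispersion beta[g] = sum_{i, f} V[i, f]^s alpha[i, f, g]
   and kernel weights z[g] proportional to 1 / beta[g] (kernels that fit
   the current partition tightly get more weight)
4. combined distance T2[i, f] = sum_g alpha[i, f, g] z[g]^2
5. membership update V[i, f] = 1 / sum_f' (T2[i,f] / T2[i,f'])^(1/(s-1))

until the Frobenius norm of the membership change falls below the
tolerance.  All kernels are normalized to unit diagonal so they are
commensurable; the default bank is three Gaussians with bandwidths
{0.5, 1, 2} x the median pairwise distance of the data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .exceptions import ConfigError, NumericError, StateError

logger = logging.getLogger(__name__)

_BETA_EPS = 1e-12


@dataclass
class KernelSpec:
    """One kernel of the bank.

    gaussian: ``sigma`` (bandwidth) or, if None, ``factor`` x median
    pairwise distance of the data; polynomial: ``degree`` and ``offset``;
    linear: no parameters.  Linear and polynomial Gram matrices are
    diagonal-normalized to unit diagonal.
    """

    kind: str = "gaussian"
    sigma: float | None = None
    factor: float = 1.0
    degree: int = 2
    offset: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian", "polynomial", "linear"):
            raise ConfigError(f"unknown kernel kind: {self.kind!r}")
        if self.sigma is not None and self.sigma <= 0:
            raise ConfigError("gaussian bandwidth must be > 0")
        if self.factor <= 0:
            raise ConfigError("bandwidth factor must be > 0")
        if self.degree < 1:
            raise ConfigError("polynomial degree must be >= 1")
        if self.offset < 0:
            raise ConfigError("polynomial offset must be >= 0")


def default_kernel_bank() -> list[KernelSpec]:
    """Three Gaussians at {0.5, 1, 2} x median pairwise distance."""
    return [KernelSpec(kind="gaussian", factor=f) for f in (0.5, 1.0, 2.0)]


@dataclass
class MKFCMConfig:
    """Clustering hyperparameters; the defaults are the conventional
    fuzzy-c-means choices (fuzzifier 2, tolerance 1e-5)."""

    n_clusters: int = 2
    fuzzifier: float = 2.0
    tol: float = 1e-5
    max_iter: int = 100
    seed: int = 0
    kernels: list[KernelSpec] | None = None
    init: str = "kpp"  # "kpp" (inverse-distance from k-means++ seeds) or "random"
    validate: bool = False  # assert simplex invariants at every iteration

    def __post_init__(self) -> None:
        if self.n_clusters < 1:
            raise ConfigError("n_clusters must be >= 1")
        if self.init not in ("kpp", "random"):
            raise ConfigError(f"unknown init scheme: {self.init!r}")
        if self.fuzzifier <= 1:
            raise ConfigError("fuzzifier must be > 1")
        if self.tol <= 0:
            raise ConfigError("tolerance must be > 0")
        if self.max_iter < 1:
            raise ConfigError("max_iter must be >= 1")
        if self.kernels is not None and len(self.kernels) < 1:
            raise ConfigError("kernel bank must contain at least one kernel")


@dataclass
class MKFCMResult:
    """Converged memberships, learned kernel weights and the run trace."""

    membership: np.ndarray  # (B, F) row-stochastic
    kernel_weights: np.ndarray  # (S,) on the simplex
    n_iter: int
    converged: bool
    membership_change_trace: list[float]
    kernel_params: list[dict] = field(default_factory=list)

    def hard_assignments(self) -> np.ndarray:
        """Argmax cluster per point; ties go to the lowest cluster index."""
        return np.argmax(self.membership, axis=1)


def median_pairwise_distance(points: np.ndarray) -> float:
    d = pdist(np.asarray(points, dtype=float))
    med = float(np.median(d)) if d.size else 0.0
    return med if med > 0 else 1.0


def gram_matrices(points: np.ndarray, kernels: list[KernelSpec]) -> list[np.ndarray]:
    """Evaluate each kernel on all point pairs (unit-diagonal matrices)."""
    X = np.asarray(points, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ConfigError("need a 2-D array with at least 2 points")
    if not np.isfinite(X).all():
        raise NumericError("non-finite input points")
    D2 = squareform(pdist(X, "sqeuclidean"))
    med = None
    grams: list[np.ndarray] = []
    for spec in kernels:
        if spec.kind == "gaussian":
            sigma = spec.sigma
            if sigma is None:
                if med is None:
                    med = median_pairwise_distance(X)
                sigma = spec.factor * med
            G = np.exp(-D2 / (2.0 * sigma**2))
        else:
            raw = X @ X.T
            if spec.kind == "polynomial":
                raw = (raw + spec.offset) ** spec.degree
            d = np.sqrt(np.clip(np.diag(raw), 1e-300, None))
            G = raw / np.outer(d, d)
        if not np.isfinite(G).all():
            raise NumericError(f"non-finite Gram matrix for kernel {spec.kind}")
        G = 0.5 * (G + G.T)
        np.fill_diagonal(G, 1.0)
        grams.append(G)
    return grams


def resolved_kernel_params(points: np.ndarray, kernels: list[KernelSpec]) -> list[dict]:
    """Kernel parameters with any median-heuristic bandwidths filled in."""
    med = median_pairwise_distance(points)
    out = []
    for spec in kernels:
        if spec.kind == "gaussian":
            sigma = spec.sigma if spec.sigma is not None else spec.factor * med
            out.append({"kind": "gaussian", "sigma": float(sigma)})
        elif spec.kind == "polynomial":
            out.append({"kind": "polynomial", "degree": spec.degree, "offset": spec.offset})
        else:
            out.append({"kind": "linear"})
    return out


def normalized_membership(V: np.ndarray, s: float) -> np.ndarray:
    """Per-cluster normalization of membership powers (fuzzy centroid weights)."""
    Vs = V**s
    col = Vs.sum(axis=0)
    dead = col <= 0
    if dead.any():
        # a cluster with zero total membership: fall back to uniform weights
        Vs[:, dead] = 1.0
        col = Vs.sum(axis=0)
    return Vs / col


def alpha_coefficients(gram: np.ndarray, vhat: np.ndarray) -> np.ndarray:
    """Squared feature-space distances of each point to each fuzzy centroid."""
    colsums = vhat.sum(axis=0)
    if not np.allclose(colsums, 1.0, atol=1e-6):
        raise StateError("normalized membership columns must sum to 1")
    diag = np.diag(gram)
    cross = gram @ vhat  # (B, F)
    centroid = np.einsum("jf,jk,kf->f", vhat, gram, vhat)  # (F,)
    alpha = diag[:, None] - 2.0 * cross + centroid[None, :]
    # squared distances in feature space: tiny negatives are round-off
    return np.clip(alpha, 0.0, None)


def kernel_weight_update(
    alpha: np.ndarray, V: np.ndarray, s: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-kernel dispersions beta and simplex weights z ~ 1/beta."""
    Vs = V**s
    beta = np.einsum("if,ifg->g", Vs, alpha)
    if np.all(beta < _BETA_EPS):
        logger.info("all kernel dispersions ~0 (perfect fit); uniform weights")
        z = np.full(beta.shape, 1.0 / beta.size)
        return beta, z
    inv = 1.0 / np.maximum(beta, _BETA_EPS)
    return beta, inv / inv.sum()


def membership_update(T2: np.ndarray, s: float) -> np.ndarray:
    """Inverse-distance membership update; rows sum to 1.

    Points at zero combined distance from one or more clusters get their
    membership split uniformly over those clusters.
    """
    B, F = T2.shape
    V = np.empty((B, F))
    expo = 1.0 / (s - 1.0)
    with np.errstate(divide="ignore", over="ignore"):
        w = np.where(T2 > 0, T2, np.inf) ** (-expo)
    for i in range(B):
        zero = T2[i] <= 0
        if zero.any():
            V[i] = np.where(zero, 1.0 / zero.sum(), 0.0)
        elif np.isinf(w[i]).any():
            inf = np.isinf(w[i])
            V[i] = np.where(inf, 1.0 / inf.sum(), 0.0)
        else:
            V[i] = w[i] / w[i].sum()
    return V


def kpp_init_membership(X: np.ndarray, F: int, seed: int, s: float = 2.0) -> np.ndarray:
    """Seeded k-means++ membership initialization.

    F data points are chosen by the k-means++ rule (each next seed drawn
    with probability proportional to its squared distance from the
    nearest seed so far) and memberships are set by the inverse-distance
    rule applied to the seed points.  The uniform membership matrix
    V = 1/F is a fixed point of the fuzzy iteration and attracts nearby
    random starts on high-dimensional data; this start begins far from
    it while remaining fully reproducible given the seed.
    """
    rng = np.random.default_rng(seed)
    B = X.shape[0]
    centers = [int(rng.integers(B))]
    d2 = np.sum((X - X[centers[0]]) ** 2, axis=1)
    for _ in range(F - 1):
        total = d2.sum()
        if total <= 0:  # all points coincide with the chosen seeds
            centers.append(int(rng.integers(B)))
            continue
        c = int(rng.choice(B, p=d2 / total))
        centers.append(c)
        d2 = np.minimum(d2, np.sum((X - X[c]) ** 2, axis=1))
    D2 = np.stack([np.sum((X - X[c]) ** 2, axis=1) for c in centers], axis=1)
    return membership_update(D2, s)


def _check_simplex(V: np.ndarray, z: np.ndarray) -> None:
    if not np.allclose(V.sum(axis=1), 1.0, atol=1e-9):
        raise NumericError("membership rows left the simplex")
    if (V < -1e-12).any():
        raise NumericError("negative membership")
    if not np.isclose(z.sum(), 1.0, atol=1e-9) or (z < 0).any():
        raise NumericError("kernel weights left the simplex")


def fit(
    points: np.ndarray,
    config: MKFCMConfig,
    init_membership: np.ndarray | None = None,
) -> MKFCMResult:
    """Run MKFCM to convergence.

    ``init_membership`` overrides the seeded Dirichlet(1) random start
    (used for reproducing a run or comparing against a reference
    implementation with the same initialization).
    """
    X = np.asarray(points, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if not np.isfinite(X).all():
        raise NumericError("non-finite input points")
    B = X.shape[0]
    F = config.n_clusters
    if B < F:
        raise ConfigError(f"need at least as many points ({B}) as clusters ({F})")
    kernels = config.kernels if config.kernels is not None else default_kernel_bank()
    S = len(kernels)
    grams = gram_matrices(X, kernels)
    s = config.fuzzifier

    if init_membership is not None:
        V = np.asarray(init_membership, dtype=float)
        if V.shape != (B, F):
            raise ConfigError("init_membership has the wrong shape")
        if not np.allclose(V.sum(axis=1), 1.0, atol=1e-9) or (V < 0).any():
            raise ConfigError("init_membership rows must lie on the simplex")
        V = V.copy()
    elif config.init == "kpp":
        V = kpp_init_membership(X, F, config.seed, s)
    else:
        rng = np.random.default_rng(config.seed)
        V = rng.dirichlet(np.ones(F), size=B)

    z = np.full(S, 1.0 / S)
    trace: list[float] = []
    converged = False
    n_iter = 0
    for n_iter in range(1, config.max_iter + 1):
        vhat = normalized_membership(V, s)
        alpha = np.empty((B, F, S))
        for g in range(S):
            alpha[:, :, g] = alpha_coefficients(grams[g], vhat)
        _, z = kernel_weight_update(alpha, V, s)
        T2 = alpha @ (z**2)
        V_new = membership_update(T2, s)
        delta = float(np.linalg.norm(V_new - V))
        trace.append(delta)
        V = V_new
        if config.validate:
            _check_simplex(V, z)
        if delta < config.tol:
            converged = True
            break
    return MKFCMResult(
        membership=V,
        kernel_weights=z,
        n_iter=n_iter,
        converged=converged,
        membership_change_trace=trace,
        kernel_params=resolved_kernel_params(X, kernels),
    )
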