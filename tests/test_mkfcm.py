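"""Multiple-kernel fuzzy c-means: kernel algebra, updates, convergence."""

import numpy as np
import pytest

from mkftm import mkfcm
from mkftm.exceptions import ConfigError, StateError


def gaussian(x, y, sigma):
    return float(np.exp(-np.sum((x - y) ** 2) / (2 * sigma**2)))


def reference_kfcm(gram, V0, s=2.0, tol=1e-5, max_iter=100):
    """Loop-based single-kernel fuzzy c-means with feature-space distances
    to fuzzy centroids; the independent oracle for the S=1 reduction."""
    G = np.asarray(gram)
    V = np.asarray(V0, dtype=float).copy()
    B, F = V.shape
    for _ in range(max_iter):
        Vs = V**s
        vhat = Vs / Vs.sum(axis=0)
        alpha = np.zeros((B, F))
        for i in range(B):
            for f in range(F):
                a = G[i, i]
                a -= 2 * sum(vhat[j, f] * G[i, j] for j in range(B))
                a += sum(
                    vhat[j, f] * vhat[jp, f] * G[j, jp]
                    for j in range(B)
                    for jp in range(B)
                )
                alpha[i, f] = max(a, 0.0)
        Vn = np.zeros((B, F))
        for i in range(B):
            if np.any(alpha[i] == 0):
                zero = alpha[i] == 0
                Vn[i] = zero / zero.sum()
            else:
                for f in range(F):
                    Vn[i, f] = 1.0 / sum(
                        (alpha[i, f] / alpha[i, fp]) ** (1 / (s - 1)) for fp in range(F)
                    )
        delta = np.linalg.norm(Vn - V)
        V = Vn
        if delta < tol:
            break
    return V


def test_gaussian_gram_unit_diagonal_and_identical_points():
    X = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 2.0]])
    (G,) = mkfcm.gram_matrices(X, [mkfcm.KernelSpec("gaussian", sigma=0.7)])
    assert np.allclose(np.diag(G), 1.0)
    assert np.isclose(G[0, 1], 1.0)  # coincident points
    assert np.allclose(G, G.T, atol=1e-10)


def test_gram_matches_per_pair_evaluation():
    rng = np.random.default_rng(4)
    X = rng.normal(size=(5, 2))
    sigma = 0.9
    specs = [
        mkfcm.KernelSpec("gaussian", sigma=sigma),
        mkfcm.KernelSpec("polynomial", degree=2, offset=1.0),
        mkfcm.KernelSpec("linear"),
    ]
    G_gauss, G_poly, G_lin = mkfcm.gram_matrices(X, specs)
    for i in range(5):
        for j in range(5):
            assert np.isclose(G_gauss[i, j], gaussian(X[i], X[j], sigma), atol=1e-10)
            raw = lambda a, b: (a @ b + 1.0) ** 2
            expect = raw(X[i], X[j]) / np.sqrt(raw(X[i], X[i]) * raw(X[j], X[j]))
            if i != j:
                assert np.isclose(G_poly[i, j], expect, atol=1e-10)
            lin = (X[i] @ X[j]) / np.linalg.norm(X[i]) / np.linalg.norm(X[j])
            if i != j:
                assert np.isclose(G_lin[i, j], lin, atol=1e-10)


def test_alpha_zero_for_own_centroid_and_coincident_points():
    # membership concentrated on one point: distance to own centroid is 0
    X = np.array([[1.0, 0.0], [5.0, 5.0]])
    (G,) = mkfcm.gram_matrices(X, [mkfcm.KernelSpec("gaussian", sigma=1.0)])
    vhat = np.array([[1.0, 0.0], [0.0, 1.0]])
    alpha = mkfcm.alpha_coefficients(G, vhat)
    assert np.isclose(alpha[0, 0], 0.0) and np.isclose(alpha[1, 1], 0.0)
    # two coincident points with uniform centroid weights: all distances 0
    X2 = np.zeros((2, 2))
    (G2,) = mkfcm.gram_matrices(X2, [mkfcm.KernelSpec("gaussian", sigma=1.0)])
    alpha2 = mkfcm.alpha_coefficients(G2, np.full((2, 1), 0.5))
    assert np.allclose(alpha2, 0.0, atol=1e-12)


def test_alpha_matches_triple_loop():
    rng = np.random.default_rng(9)
    X = rng.normal(size=(6, 2))
    specs = [mkfcm.KernelSpec("gaussian", sigma=1.0), mkfcm.KernelSpec("gaussian", sigma=2.5)]
    grams = mkfcm.gram_matrices(X, specs)
    V = rng.dirichlet(np.ones(2), size=6)
    vhat = mkfcm.normalized_membership(V, 2.0)
    for G in grams:
        fast = mkfcm.alpha_coefficients(G, vhat)
        for i in range(6):
            for f in range(2):
                slow = G[i, i]
                slow -= 2 * sum(vhat[j, f] * G[i, j] for j in range(6))
                slow += sum(
                    vhat[j, f] * vhat[jp, f] * G[j, jp]
                    for j in range(6)
                    for jp in range(6)
                )
                assert abs(fast[i, f] - max(slow, 0.0)) < 1e-10


def test_alpha_rejects_unnormalized_membership():
    G = np.eye(3)
    with pytest.raises(StateError):
        mkfcm.alpha_coefficients(G, np.full((3, 2), 0.9))


def test_kernel_weight_update_arithmetic():
    V = np.full((2, 1), 1.0)
    # alpha slabs chosen so beta = [1], [1,1], [1,3]
    _, z = mkfcm.kernel_weight_update(np.full((2, 1, 1), 0.5), V, 2.0)
    assert np.allclose(z, [1.0])
    _, z = mkfcm.kernel_weight_update(np.full((2, 1, 2), 0.5), V, 2.0)
    assert np.allclose(z, [0.5, 0.5])
    alpha = np.stack([np.full((2, 1), 0.5), np.full((2, 1), 1.5)], axis=2)
    beta, z = mkfcm.kernel_weight_update(alpha, V, 2.0)
    assert np.allclose(beta, [1.0, 3.0])
    assert np.allclose(z, [0.75, 0.25])


def test_membership_update_cases():
    assert np.allclose(mkfcm.membership_update(np.array([[1.0, 1.0]]), 2.0), [[0.5, 0.5]])
    assert np.allclose(mkfcm.membership_update(np.array([[0.0, 4.0]]), 2.0), [[1.0, 0.0]])
    assert np.allclose(mkfcm.membership_update(np.array([[1.0, 4.0]]), 2.0), [[0.8, 0.2]])
    rows = mkfcm.membership_update(np.abs(np.random.default_rng(0).normal(size=(7, 3))), 1.7)
    assert np.allclose(rows.sum(axis=1), 1.0, atol=1e-12)


def test_fit_recovers_blobs(blobs):
    X, labels = blobs
    for seed in (0, 1, 2):
        cfg = mkfcm.MKFCMConfig(n_clusters=2, seed=seed, validate=True)
        res = mkfcm.fit(X, cfg)
        hard = res.hard_assignments()
        same = (hard == labels).mean()
        assert max(same, 1 - same) == 1.0  # up to label swap
        assert res.converged and res.n_iter < 100
        assert np.all(np.isfinite(res.membership_change_trace))


def test_single_cluster_all_ones(blobs):
    X, _ = blobs
    res = mkfcm.fit(X, mkfcm.MKFCMConfig(n_clusters=1, seed=0))
    assert np.allclose(res.membership, 1.0)


def test_single_kernel_matches_reference_kfcm():
    rng = np.random.default_rng(12)
    X = np.vstack([rng.normal(0, 0.5, (5, 2)), rng.normal(4, 0.5, (5, 2))])
    spec = [mkfcm.KernelSpec("gaussian", sigma=1.5)]
    V0 = rng.dirichlet(np.ones(2), size=10)
    cfg = mkfcm.MKFCMConfig(n_clusters=2, seed=0, kernels=spec)
    res = mkfcm.fit(X, cfg, init_membership=V0)
    (G,) = mkfcm.gram_matrices(X, spec)
    ref = reference_kfcm(G, V0, s=2.0, tol=cfg.tol, max_iter=cfg.max_iter)
    assert np.max(np.abs(res.membership - ref)) < 1e-6
    assert np.allclose(res.kernel_weights, [1.0])


def test_fit_seed_determinism(blobs):
    X, _ = blobs
    cfg = mkfcm.MKFCMConfig(n_clusters=2, seed=3)
    a = mkfcm.fit(X, cfg)
    b = mkfcm.fit(X, cfg)
    assert np.array_equal(a.membership, b.membership)
    assert a.membership_change_trace == b.membership_change_trace


def test_permutation_equivariance(blobs):
    X, _ = blobs
    rng = np.random.default_rng(8)
    perm = rng.permutation(len(X))
    V0 = rng.dirichlet(np.ones(2), size=len(X))
    cfg = mkfcm.MKFCMConfig(n_clusters=2, seed=0)
    res = mkfcm.fit(X, cfg, init_membership=V0)
    res_p = mkfcm.fit(X[perm], cfg, init_membership=V0[perm])
    assert np.allclose(res.membership[perm], res_p.membership, atol=1e-9)


def test_config_validation():
    with pytest.raises(ConfigError):
        mkfcm.MKFCMConfig(n_clusters=0)
    with pytest.raises(ConfigError):
        mkfcm.MKFCMConfig(fuzzifier=1.0)
    with pytest.raises(ConfigError):
        mkfcm.KernelSpec("gaussian", sigma=-1.0)
    with pytest.raises(ConfigError):
        mkfcm.fit(np.zeros((2, 2)), mkfcm.MKFCMConfig(n_clusters=3))
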