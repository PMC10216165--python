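"""Unit and property tests for the DEC solver and its baselines."""

import itertools

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from decparc import (
    DECConfig,
    DiscriminativeEmbeddedClustering,
    FeatureMatrix,
    baseline_cluster,
    center_and_scatter,
    dec_objective,
    fit_dec,
    update_assignments,
    update_subspace_and_centroids,
)


# ---------------------------------------------------------------------------
# center_and_scatter
# ---------------------------------------------------------------------------


def test_center_and_scatter_hand_case():
    Xc, St = center_and_scatter(np.array([[1.0, -1.0], [0.0, 0.0]]))
    np.testing.assert_allclose(Xc, [[1, -1], [0, 0]])
    np.testing.assert_allclose(St, [[2, 0], [0, 0]])


def test_scatter_zero_for_identical_columns():
    X = np.tile(np.array([[1.0], [2.0], [3.0]]), (1, 5))
    _, St = center_and_scatter(X)
    np.testing.assert_allclose(St, 0.0)


def test_scatter_trace_matches_elementwise_sum(rng):
    X = rng.standard_normal((5, 10))
    _, St = center_and_scatter(X)
    expected = sum(
        np.sum((X[i] - X[i].mean()) ** 2) for i in range(5)
    )
    assert np.isclose(np.trace(St), expected)
    # positive semidefinite
    assert np.min(np.linalg.eigvalsh(St)) > -1e-10


@pytest.mark.parametrize("bad", [np.array([[np.nan, 1.0]]), np.array([[np.inf, 0.0]])])
def test_center_rejects_nonfinite(bad):
    with pytest.raises(ValueError):
        center_and_scatter(bad)


def test_center_rejects_single_sample():
    with pytest.raises(ValueError):
        center_and_scatter(np.array([[1.0], [2.0]]))


# ---------------------------------------------------------------------------
# objective
# ---------------------------------------------------------------------------


def test_objective_hand_case_and_lambda_scaling():
    Xc = np.array([[1.0, -1.0], [0.0, 0.0]])
    Q = np.array([[1.0], [0.0]])
    F = np.eye(2)
    G = np.array([[1.0, -1.0]])
    # zero residual: value = Tr(QᵀStQ) = 2 for any λ
    assert dec_objective(Xc, Q, G, F, 3.0) == pytest.approx(2.0)
    assert dec_objective(Xc, Q, G, F, 0.0) == pytest.approx(2.0)
    # perturbing G introduces residual 1 → 2 − 3·1 = −1
    G2 = np.array([[0.0, -1.0]])
    assert dec_objective(Xc, Q, G2, F, 3.0) == pytest.approx(-1.0)


def test_objective_lambda_zero_equals_trace_term(rng):
    Xc, St = center_and_scatter(rng.standard_normal((6, 12)))
    Q = np.linalg.qr(rng.standard_normal((6, 3)))[0]
    G = rng.standard_normal((3, 2))
    F = np.zeros((12, 2))
    F[np.arange(12), rng.integers(0, 2, 12)] = 1
    assert dec_objective(Xc, Q, G, F, 0.0) == pytest.approx(np.trace(Q.T @ St @ Q))


def test_objective_shape_mismatch_raises(rng):
    Xc = rng.standard_normal((4, 6))
    with pytest.raises(ValueError):
        dec_objective(Xc, np.eye(3), np.zeros((3, 2)), np.zeros((6, 2)), 1.0)


# ---------------------------------------------------------------------------
# assignment update
# ---------------------------------------------------------------------------


def test_assignment_nearest_and_tiebreak():
    F = update_assignments(np.array([[0.0, 10.0]]), np.array([[0.0, 10.0]]))
    np.testing.assert_array_equal(np.argmax(F, axis=1), [0, 1])
    # equidistant point goes to the lowest cluster index
    F = update_assignments(np.array([[5.0, 0.0, 10.0]]), np.array([[0.0, 10.0]]))
    assert np.argmax(F[0]) == 0


def test_assignment_matches_bruteforce(rng):
    # both centroids attract samples, so the exhaustive optimum has no empty
    # cluster and the reseeding rule stays inactive
    Y = rng.standard_normal((2, 6)) + np.array([[3.0, 3.0, 3.0, -3.0, -3.0, -3.0]] * 2)
    G = np.array([[3.0, -3.0], [3.0, -3.0]])
    F = update_assignments(Y, G)
    best_cost, best_labels = np.inf, None
    for labels in itertools.product(range(2), repeat=6):
        Fc = np.zeros((6, 2))
        Fc[np.arange(6), labels] = 1
        cost = np.sum((Y - G @ Fc.T) ** 2)
        if cost < best_cost - 1e-12:
            best_cost, best_labels = cost, labels
    got_cost = np.sum((Y - G @ F.T) ** 2)
    assert got_cost == pytest.approx(best_cost)


def test_assignment_reseeds_empty_cluster():
    # all samples nearest to centroid 0; farthest sample must fill cluster 1
    Y = np.array([[0.0, 0.1, 5.0]])
    G = np.array([[0.0, 100.0]])
    F = update_assignments(Y, G)
    labels = np.argmax(F, axis=1)
    assert np.bincount(labels, minlength=2).min() >= 1
    assert labels[2] == 1  # farthest from its centroid


def test_assignment_rejects_more_clusters_than_samples():
    with pytest.raises(ValueError):
        update_assignments(np.array([[0.0]]), np.array([[0.0, 1.0]]))


# ---------------------------------------------------------------------------
# subspace/centroid update
# ---------------------------------------------------------------------------


def test_update_lambda_zero_gives_pca_directions(rng):
    X = rng.standard_normal((5, 20))
    Xc, St = center_and_scatter(X)
    F = np.zeros((20, 2))
    F[np.arange(20), rng.integers(0, 2, 20)] = 1
    Q, _ = update_subspace_and_centroids(Xc, F, 0.0, 2)
    w, V = np.linalg.eigh(St)
    top = V[:, ::-1][:, :2]
    # same subspace up to column sign
    overlap = np.abs(np.diag(top.T @ Q))
    np.testing.assert_allclose(overlap, 1.0, atol=1e-8)


def test_update_centroids_are_embedded_means(rng):
    X = rng.standard_normal((4, 15))
    Xc, _ = center_and_scatter(X)
    labels = rng.integers(0, 3, 15)
    labels[:3] = [0, 1, 2]
    F = np.zeros((15, 3))
    F[np.arange(15), labels] = 1
    Q, G = update_subspace_and_centroids(Xc, F, 1.5, 2)
    Y = Q.T @ Xc
    for c in range(3):
        np.testing.assert_allclose(G[:, c], Y[:, labels == c].mean(axis=1))


def test_update_optimal_over_random_orthonormal_candidates(rng):
    X = rng.standard_normal((3, 8))
    Xc, _ = center_and_scatter(X)
    labels = rng.integers(0, 2, 8)
    labels[:2] = [0, 1]
    F = np.zeros((8, 2))
    F[np.arange(8), labels] = 1
    Q_star, G_star = update_subspace_and_centroids(Xc, F, 2.0, 2)
    best = dec_objective(Xc, Q_star, G_star, F, 2.0)
    counts = F.sum(axis=0)
    means = (Xc @ F) / counts
    for _ in range(1000):
        Q = np.linalg.qr(rng.standard_normal((3, 2)))[0]
        G = Q.T @ means  # optimal G for this Q
        assert best >= dec_objective(Xc, Q, G, F, 2.0) - 1e-9


# ---------------------------------------------------------------------------
# fit_dec
# ---------------------------------------------------------------------------


def test_fit_recovers_separated_blobs(blob_data):
    X, truth = blob_data
    model = fit_dec(X, DECConfig(C=2, d=2, lam=2.0, seed=0))
    assert adjusted_rand_score(truth, model.labels) == 1.0


def test_fit_attains_exhaustive_partition_optimum(rng):
    X = rng.standard_normal((4, 6))
    cfg = DECConfig(C=2, d=2, lam=2.0, n_restarts=10, seed=0)
    model = fit_dec(X, cfg)
    Xc, _ = center_and_scatter(X)
    best = -np.inf
    for bits in range(1, 2**5):
        labels = np.array([(bits >> i) & 1 for i in range(6)])
        if labels.min() == labels.max():
            continue
        F = np.zeros((6, 2))
        F[np.arange(6), labels] = 1
        Q, G = update_subspace_and_centroids(Xc, F, cfg.lam, cfg.d)
        best = max(best, dec_objective(Xc, Q, G, F, cfg.lam))
    assert model.objective_trace[-1] == pytest.approx(best, abs=1e-8)


def test_fit_deterministic_given_seed(blob_data):
    X, _ = blob_data
    cfg = DECConfig(C=2, d=2, lam=2.0, seed=5)
    m1, m2 = fit_dec(X, cfg), fit_dec(X, cfg)
    np.testing.assert_array_equal(m1.labels, m2.labels)
    assert m1.objective_trace == m2.objective_trace


def test_fit_invariants_over_random_instances():
    for s in range(30):
        X = np.random.default_rng(s).standard_normal((6, 25))
        m = fit_dec(X, DECConfig(C=3, d=3, lam=1.5, n_restarts=3, seed=s))
        assert np.max(np.abs(m.Q.T @ m.Q - np.eye(3))) < 1e-8
        assert np.all(np.diff(m.objective_trace) >= 0)
        np.testing.assert_array_equal(m.F.sum(axis=1), 1)
        assert np.bincount(m.labels, minlength=3).min() >= 1


def test_fit_permutation_invariance(rng):
    X = rng.standard_normal((5, 20))
    cfg = DECConfig(C=2, d=2, lam=2.0, n_restarts=3, seed=3)
    m = fit_dec(X, cfg)
    perm = rng.permutation(20)
    m_p = fit_dec(X[:, perm], cfg)
    # permuting samples permutes labels identically (up to cluster renaming)
    assert adjusted_rand_score(m.labels[perm], m_p.labels) == 1.0
    assert m.objective_trace[-1] == pytest.approx(m_p.objective_trace[-1], rel=1e-9)


def test_fit_rejects_bad_configs(blob_data):
    X, _ = blob_data
    with pytest.raises(ValueError):
        fit_dec(X, DECConfig(C=2, d=11, lam=1.0))  # d > D
    with pytest.raises(ValueError):
        fit_dec(X, DECConfig(C=61, d=2, lam=1.0))  # C > n
    with pytest.raises(ValueError):
        fit_dec(np.ones((4, 10)), DECConfig(C=2, d=2, lam=1.0))  # constant X


def test_lambda_zero_reproduces_pca_kmeans(blob_data):
    X, _ = blob_data
    for s in range(5):
        m = fit_dec(X, DECConfig(C=2, d=2, lam=0.0, n_restarts=1, seed=s))
        lb = baseline_cluster(X, "pca_kmeans", C=2, d=2, seed=s)
        assert adjusted_rand_score(m.labels, lb) == 1.0


# ---------------------------------------------------------------------------
# estimator API
# ---------------------------------------------------------------------------


def test_estimator_fit_predict_and_params(blob_data):
    X, truth = blob_data
    est = DiscriminativeEmbeddedClustering(
        n_clusters=2, n_components=2, lam=2.0, random_state=0
    )
    labels = est.fit_predict(X.T)
    assert adjusted_rand_score(truth, labels) == 1.0
    assert est.Q_.shape == (10, 2)
    assert est.cluster_centers_.shape == (2, 2)
    # predict on training data agrees with labels_
    np.testing.assert_array_equal(est.predict(X.T), est.labels_)
    # sklearn get/set params round-trip
    params = est.get_params()
    assert params["lam"] == 2.0
    est.set_params(lam=1.0)
    assert est.lam == 1.0
    assert est.transform(X.T).shape == (60, 2)


# ---------------------------------------------------------------------------
# baselines
# ---------------------------------------------------------------------------


def test_baselines_recover_blobs(blob_data):
    X, truth = blob_data
    for method in ("pca_kmeans", "kmeans", "spectral"):
        labels = baseline_cluster(X, method, C=2, d=2, seed=0)
        assert adjusted_rand_score(truth, labels) == 1.0, method


def test_baseline_unknown_method_raises(blob_data):
    X, _ = blob_data
    with pytest.raises(ValueError):
        baseline_cluster(X, "pca-kmeans ", C=2, d=2)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def test_feature_matrix_tsv_roundtrip(tmp_path, rng):
    fm = FeatureMatrix(rng.standard_normal((4, 7)),
                       feature_names=[f"roi{i}" for i in range(4)],
                       sample_ids=[f"v{i}" for i in range(7)])
    fm.to_tsv(tmp_path / "fm.tsv")
    back = FeatureMatrix.from_tsv(tmp_path / "fm.tsv")
    np.testing.assert_allclose(back.X, fm.X)
    assert back.feature_names == fm.feature_names


def test_dec_model_roundtrip(tmp_path, blob_data):
    X, _ = blob_data
    cfg = DECConfig(C=2, d=2, lam=2.0, seed=0)
    m = fit_dec(X, cfg)
    m.save(tmp_path / "model")
    back = type(m).load(tmp_path / "model")
    np.testing.assert_allclose(back.Q, m.Q)
    np.testing.assert_array_equal(back.labels, m.labels)
    assert back.objective_trace == pytest.approx(m.objective_trace)
    assert back.config.lam == cfg.lam
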