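"""Discriminative embedded clustering (DEC).

DEC couples linear subspace learning with K-means clustering in a single
objective.  Given a feature-centered data matrix ``Xc`` (D features ×
n samples) with scatter matrix ``St = Xc Xcᵀ``, DEC seeks an orthonormal
transformation ``Q`` (D×d), centroids ``G`` (d×C) and a hard cluster
indicator ``F`` (n×C) maximizing

    Tr(Qᵀ St Q) − λ ‖Qᵀ Xc − G Fᵀ‖_F²      s.t.  QᵀQ = I

The first term is the PCA objective (variance retained in the subspace),
the second the K-means distortion measured *in* that subspace; λ ≥ 0
balances the two.  At λ → 0 the method degenerates to PCA followed by
K-means; at larger λ the subspace is bent toward directions that make the
clusters tight.

The problem is solved by block coordinate ascent with closed-form block
updates:

* fixing F, the optimal centroids are the per-cluster means of the embedded
  samples, ``G = Qᵀ Xc F (FᵀF)⁻¹``, and substituting them back reduces the
  objective to ``Tr(Qᵀ M Q)`` with
  ``M = St − λ Xc (I − F(FᵀF)⁻¹Fᵀ) Xcᵀ``, maximized by the top-d
  eigenvectors of M;
* fixing Q and G, each sample is assigned to its nearest centroid in the
  embedded space.

Each block update is an exact maximizer, so the objective never decreases
across iterations.  Multiple restarts (PCA/K-means initialization plus
random indicator matrices) guard against local optima.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.sparse.csgraph import connected_components
from scipy.sparse import coo_matrix
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "FeatureMatrix",
    "DECConfig",
    "DECModel",
    "DiscriminativeEmbeddedClustering",
    "center_and_scatter",
    "dec_objective",
    "update_assignments",
    "update_subspace_and_centroids",
    "fit_dec",
    "baseline_cluster",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class FeatureMatrix:
    """Feature matrix X with D features (rows) by n samples (columns).

    In connectivity-based parcellation the rows are target-ROI Fisher-z
    connectivity values and the columns are voxels.
    """

    X: np.ndarray
    feature_names: list[str] | None = None
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("FeatureMatrix.X must be 2-D (features × samples)")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("FeatureMatrix.X contains non-finite entries")
        if self.X.shape[0] < 1:
            raise ValueError("FeatureMatrix needs at least one feature")
        if self.feature_names is not None and len(self.feature_names) != self.X.shape[0]:
            raise ValueError("feature_names length must equal number of features")
        if self.sample_ids is not None and len(self.sample_ids) != self.X.shape[1]:
            raise ValueError("sample_ids length must equal number of samples")

    @property
    def n_features(self) -> int:
        return self.X.shape[0]

    @property
    def n_samples(self) -> int:
        return self.X.shape[1]

    def to_tsv(self, path: str | Path) -> None:
        """Write one row per feature with a header of sample ids."""
        cols = self.sample_ids or [f"s{i}" for i in range(self.n_samples)]
        idx = self.feature_names or [f"f{i}" for i in range(self.n_features)]
        df = pd.DataFrame(self.X, index=idx, columns=cols)
        df.to_csv(path, sep="\t", index_label="feature")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FeatureMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.to_numpy(float), list(df.index.astype(str)), list(df.columns.astype(str)))


@dataclass
class DECConfig:
    """Run configuration for DEC.

    Parameters mirror the method's three knobs — number of clusters ``C``,
    embedding dimensionality ``d`` and balance ``lam`` (λ) — plus the usual
    iterative-solver controls.
    """

    C: int = 3
    d: int = 2
    lam: float = 2.0
    n_restarts: int = 10
    max_iter: int = 100
    tol: float = 1e-6
    seed: int = 0

    def validate(self, D: int | None = None, n: int | None = None) -> None:
        if self.C < 2:
            raise ValueError("C must be at least 2")
        if self.d < 1:
            raise ValueError("d must be at least 1")
        if self.lam < 0:
            raise ValueError("lam must be nonnegative")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be at least 1")
        if D is not None and self.d > D:
            raise ValueError(f"d={self.d} exceeds number of features D={D}")
        if n is not None and self.d > n:
            raise ValueError(f"d={self.d} exceeds number of samples n={n}")
        if n is not None and self.C > n:
            raise ValueError(f"C={self.C} exceeds number of samples n={n}")


@dataclass
class DECModel:
    """Fitted DEC solution.

    Q is D×d orthonormal, G is d×C, F is the n×C one-hot indicator; labels
    is the equivalent integer vector.  objective_trace records the objective
    after each outer iteration of the winning restart (non-decreasing).
    """

    Q: np.ndarray
    G: np.ndarray
    F: np.ndarray
    labels: np.ndarray
    objective_trace: list[float]
    converged: bool
    restart_index: int
    config: DECConfig | None = None

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, arr in (("Q", self.Q), ("G", self.G), ("F", self.F)):
            pd.DataFrame(arr).to_csv(out / f"{name}.tsv", sep="\t", index=False)
        pd.DataFrame({"label": self.labels}).to_csv(out / "labels.tsv", sep="\t", index=False)
        meta = {
            "objective_trace": [float(v) for v in self.objective_trace],
            "converged": bool(self.converged),
            "restart_index": int(self.restart_index),
            "config": vars(self.config) if self.config is not None else None,
        }
        (out / "model.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, out_dir: str | Path) -> "DECModel":
        out = Path(out_dir)
        arrs = {
            name: pd.read_csv(out / f"{name}.tsv", sep="\t").to_numpy(float)
            for name in ("Q", "G", "F")
        }
        labels = pd.read_csv(out / "labels.tsv", sep="\t")["label"].to_numpy(int)
        meta = json.loads((out / "model.json").read_text())
        cfg = DECConfig(**meta["config"]) if meta.get("config") else None
        return cls(
            Q=arrs["Q"],
            G=arrs["G"],
            F=arrs["F"],
            labels=labels,
            objective_trace=list(meta["objective_trace"]),
            converged=meta["converged"],
            restart_index=meta["restart_index"],
            config=cfg,
        )


# ---------------------------------------------------------------------------
# primitive operations
# ---------------------------------------------------------------------------


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, FeatureMatrix):
        return X.X
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a 2-D features × samples matrix")
    return X


def center_and_scatter(X) -> tuple[np.ndarray, np.ndarray]:
    """Feature-center X (D×n) and return (Xc, St) with St = Xc Xcᵀ.

    St is the (unnormalized) scatter / variance matrix whose subspace trace
    PCA maximizes.
    """
    X = _as_matrix(X)
    if not np.all(np.isfinite(X)):
        raise ValueError("input contains non-finite entries")
    if X.shape[1] < 2:
        raise ValueError("need at least 2 samples to form a scatter matrix")
    Xc = X - X.mean(axis=1, keepdims=True)
    St = Xc @ Xc.T
    St = (St + St.T) / 2.0  # enforce exact symmetry
    return Xc, St


def dec_objective(Xc, Q, G, F, lam: float) -> float:
    """Evaluate Tr(QᵀStQ) − λ‖QᵀXc − GFᵀ‖_F² for given blocks."""
    Xc = _as_matrix(Xc)
    Q = np.asarray(Q, float)
    G = np.asarray(G, float)
    F = np.asarray(F, float)
    D, n = Xc.shape
    if Q.shape[0] != D:
        raise ValueError("Q rows must match number of features")
    d = Q.shape[1]
    if G.shape[0] != d or F.shape[0] != n or F.shape[1] != G.shape[1]:
        raise ValueError("shape mismatch among Q, G, F")
    Y = Q.T @ Xc
    trace_term = float(np.sum(Y * Y))  # Tr(Qᵀ Xc Xcᵀ Q)
    resid = Y - G @ F.T
    return trace_term - float(lam) * float(np.sum(resid * resid))


def _labels_to_indicator(labels: np.ndarray, C: int) -> np.ndarray:
    F = np.zeros((labels.size, C))
    F[np.arange(labels.size), labels] = 1.0
    return F


def update_assignments(Y, G) -> np.ndarray:
    """Assign each embedded sample to its nearest centroid.

    Returns the n×C one-hot indicator.  Ties break toward the lowest cluster
    index; an empty cluster is re-seeded with the sample farthest from its
    assigned centroid (repeated until all clusters are populated).
    """
    Y = np.asarray(Y, float)
    G = np.asarray(G, float)
    if Y.ndim == 1:
        Y = Y[None, :]
    if G.ndim == 1:
        G = G[None, :]
    if not (np.all(np.isfinite(Y)) and np.all(np.isfinite(G))):
        raise ValueError("non-finite input")
    n = Y.shape[1]
    C = G.shape[1]
    if C > n:
        raise ValueError(f"cannot place C={C} clusters with only n={n} samples")
    # squared distances, C × n
    d2 = (
        np.sum(G * G, axis=0)[:, None]
        - 2.0 * (G.T @ Y)
        + np.sum(Y * Y, axis=0)[None, :]
    )
    labels = np.argmin(d2, axis=0)  # argmin takes the lowest index on ties
    assigned_d2 = d2[labels, np.arange(n)]
    while True:
        counts = np.bincount(labels, minlength=C)
        empty = np.flatnonzero(counts == 0)
        if empty.size == 0:
            break
        far = int(np.argmax(assigned_d2))
        labels[far] = empty[0]
        assigned_d2[far] = -np.inf  # do not move the same sample twice
    return _labels_to_indicator(labels, C)


def _fix_eigvec_signs(Q: np.ndarray) -> np.ndarray:
    """Make each column's largest-magnitude entry positive (sign convention)."""
    idx = np.argmax(np.abs(Q), axis=0)
    signs = np.sign(Q[idx, np.arange(Q.shape[1])])
    signs[signs == 0] = 1.0
    return Q * signs


def update_subspace_and_centroids(Xc, F, lam: float, d: int) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form optimal (Q, G) for a fixed indicator F.

    G is the matrix of per-cluster means in the embedded space; Q collects
    the top-d eigenvectors of M = St − λ·Xc(I − F(FᵀF)⁻¹Fᵀ)Xcᵀ, which using
    St = XcXcᵀ simplifies to (1−λ)·St + λ·Σ_c n_c m_c m_cᵀ with m_c the
    centered within-cluster mean columns.
    """
    Xc = _as_matrix(Xc)
    F = np.asarray(F, float)
    D, n = Xc.shape
    counts = F.sum(axis=0)
    if np.any(counts == 0):
        raise ValueError("indicator F has an empty cluster")
    means = (Xc @ F) / counts  # D × C cluster means
    St = Xc @ Xc.T
    M = (1.0 - lam) * St + lam * (means * counts) @ means.T
    M = (M + M.T) / 2.0
    try:
        w, V = scipy.linalg.eigh(M)
    except scipy.linalg.LinAlgError as e:  # pragma: no cover - rare
        raise ArithmeticError(
            f"eigendecomposition failed (cond~{np.linalg.cond(M):.3g}): {e}"
        ) from e
    Q = _fix_eigvec_signs(V[:, ::-1][:, :d])
    G = Q.T @ means
    return Q, G


# ---------------------------------------------------------------------------
# solver
# ---------------------------------------------------------------------------


def _random_indicator(n: int, C: int, rng: np.random.Generator) -> np.ndarray:
    labels = rng.integers(0, C, size=n)
    # guarantee no empty cluster
    for c in range(C):
        if not np.any(labels == c):
            donor = np.argmax(np.bincount(labels, minlength=C))
            idx = rng.choice(np.flatnonzero(labels == donor))
            labels[idx] = c
    return _labels_to_indicator(labels, C)


def _reduced_objective(Xc: np.ndarray, St: np.ndarray, F: np.ndarray, lam: float, d: int) -> float:
    """Objective at indicator F with Q and G eliminated in closed form.

    Equals the sum of the top-d eigenvalues of
    M(F) = (1−λ)·St + λ·Σ_c n_c m_c m_cᵀ.
    """
    counts = F.sum(axis=0)
    means = (Xc @ F) / counts
    M = (1.0 - lam) * St + lam * (means * counts) @ means.T
    w = scipy.linalg.eigvalsh((M + M.T) / 2.0)
    return float(np.sum(w[-d:]))


def _polish_assignments(Xc: np.ndarray, St: np.ndarray, F: np.ndarray,
                        lam: float, d: int) -> np.ndarray:
    """Exact single-sample local search on the reduced objective.

    Hartigan-style moves: relabel one sample at a time, accepting any move
    that increases the closed-form objective, until a full pass yields no
    improvement.  Worth its eigendecomposition cost only on small problems;
    the solver gates it on n·C.
    """
    n, C = F.shape
    labels = np.argmax(F, axis=1).copy()
    current = _reduced_objective(Xc, St, F, lam, d)
    improved = True
    while improved:
        improved = False
        for i in range(n):
            src = labels[i]
            if np.sum(labels == src) == 1:
                continue  # keep clusters non-empty
            for c in range(C):
                if c == src:
                    continue
                labels[i] = c
                cand = _reduced_objective(Xc, St, _labels_to_indicator(labels, C), lam, d)
                if cand > current + 1e-12:
                    current = cand
                    src = c
                    improved = True
                else:
                    labels[i] = src
    return _labels_to_indicator(labels, C)


def _run_alternation(
    Xc: np.ndarray,
    F: np.ndarray,
    lam: float,
    d: int,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[float], bool]:
    """One restart of block coordinate ascent from indicator F.

    The trace is non-decreasing by construction: a step that would lower the
    objective (possible only through empty-cluster re-seeding or numerical
    noise) terminates the run with the previous state retained.
    """
    trace: list[float] = []
    Q = G = None
    converged = False
    for _ in range(max_iter):
        Q_new, G_new = update_subspace_and_centroids(Xc, F, lam, d)
        obj = dec_objective(Xc, Q_new, G_new, F, lam)
        if trace and obj < trace[-1]:
            converged = True
            break
        Q, G = Q_new, G_new
        trace.append(obj)
        if len(trace) >= 2:
            prev = trace[-2]
            denom = max(abs(prev), 1.0)
            if (trace[-1] - prev) / denom < tol:
                converged = True
                break
        F_new = update_assignments(Q.T @ Xc, G)
        if np.array_equal(F_new, F):
            converged = True
            break
        F = F_new
    return Q, G, F, trace, converged


def _fit_dec_arrays(X: np.ndarray, cfg: DECConfig) -> DECModel:
    D, n = X.shape
    cfg.validate(D=D, n=n)
    if n < 2:
        raise ValueError("need at least 2 samples")
    Xc, St = center_and_scatter(X)
    if np.allclose(St, 0):
        raise ValueError("degenerate input: all samples identical (zero scatter)")
    rng = np.random.default_rng(cfg.seed)
    # PCA initialization: top-d eigenvectors of the scatter matrix
    w, V = scipy.linalg.eigh(St)
    Q0 = _fix_eigvec_signs(V[:, ::-1][:, : cfg.d])
    km = KMeans(n_clusters=cfg.C, n_init=10, random_state=cfg.seed)
    labels0 = km.fit_predict((Q0.T @ Xc).T)

    def make_init(r: int) -> np.ndarray:
        if r == 0:
            return _labels_to_indicator(labels0, cfg.C)
        if r % 2 == 0:
            # K-means on a random orthonormal d-projection: diverse but
            # geometrically plausible partitions, much better at escaping
            # local optima than uniform random labels alone
            Qr, _ = np.linalg.qr(rng.standard_normal((D, cfg.d)))
            lab = KMeans(n_clusters=cfg.C, n_init=1,
                         random_state=int(rng.integers(2**31))).fit_predict((Qr.T @ Xc).T)
            if np.unique(lab).size < cfg.C:
                return _random_indicator(n, cfg.C, rng)
            return _labels_to_indicator(lab, cfg.C)
        return _random_indicator(n, cfg.C, rng)

    do_polish = n * cfg.C <= 200  # exact local search only where eigh per move is cheap
    best = None
    for r in range(cfg.n_restarts):
        Q, G, F, trace, converged = _run_alternation(
            Xc, make_init(r), cfg.lam, cfg.d, cfg.max_iter, cfg.tol
        )
        if do_polish:
            F_pol = _polish_assignments(Xc, St, F, cfg.lam, cfg.d)
            if not np.array_equal(F_pol, F):
                Q, G = update_subspace_and_centroids(Xc, F_pol, cfg.lam, cfg.d)
                F = F_pol
                obj = dec_objective(Xc, Q, G, F, cfg.lam)
                if obj > trace[-1]:
                    trace.append(obj)
        if best is None or trace[-1] > best[0]:
            best = (trace[-1], Q, G, F, trace, converged, r)
    _, Q, G, F, trace, converged, r = best
    labels = np.argmax(F, axis=1)
    return DECModel(
        Q=Q, G=G, F=F, labels=labels,
        objective_trace=trace, converged=converged, restart_index=r, config=cfg,
    )


def fit_dec(X, cfg: DECConfig) -> DECModel:
    """Fit DEC to a D×n feature matrix with the alternating scheme.

    Runs the PCA + K-means initialization plus ``cfg.n_restarts − 1`` random
    indicator initializations and returns the restart with the largest final
    objective.  Fully reproducible given ``cfg.seed``.
    """
    return _fit_dec_arrays(_as_matrix(X), cfg)


class DiscriminativeEmbeddedClustering(ClusterMixin, BaseEstimator):
    """Joint orthonormal subspace learning and K-means clustering.

    scikit-learn-style estimator: ``X`` is (n_samples, n_features).  After
    ``fit``, ``labels_`` holds hard cluster assignments, ``Q_`` the D×d
    orthonormal transformation, ``cluster_centers_`` the C×d centroids in
    the embedded space.

    Parameters
    ----------
    n_clusters : int
        Number of clusters C.
    n_components : int
        Embedding dimensionality d (1 ≤ d ≤ min(n_features, n_samples)).
    lam : float
        Balance λ ≥ 0 between retained variance and in-subspace K-means fit.
        λ = 0 reduces to PCA followed by K-means.
    n_restarts : int
        Number of initializations (first is PCA + K-means, rest random).
    max_iter, tol : solver controls.
    random_state : int
        Seed for K-means and the random restarts.
    """

    def __init__(
        self,
        n_clusters: int = 3,
        n_components: int = 2,
        lam: float = 2.0,
        n_restarts: int = 10,
        max_iter: int = 100,
        tol: float = 1e-6,
        random_state: int = 0,
    ):
        self.n_clusters = n_clusters
        self.n_components = n_components
        self.lam = lam
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def _config(self) -> DECConfig:
        return DECConfig(
            C=self.n_clusters,
            d=self.n_components,
            lam=self.lam,
            n_restarts=self.n_restarts,
            max_iter=self.max_iter,
            tol=self.tol,
            seed=self.random_state,
        )

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (n_samples, n_features)")
        model = _fit_dec_arrays(X.T, self._config())
        self.mean_ = X.mean(axis=0)
        self.Q_ = model.Q
        self.components_ = model.Q.T
        self.cluster_centers_ = model.G.T
        self.labels_ = model.labels
        self.indicator_ = model.F
        self.objective_trace_ = model.objective_trace
        self.converged_ = model.converged
        self.restart_index_ = model.restart_index
        self.n_iter_ = len(model.objective_trace)
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "Q_")
        X = np.asarray(X, dtype=float)
        return (X - self.mean_) @ self.Q_

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).transform(X)

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "Q_")
        Y = self.transform(X)
        d2 = ((Y[:, None, :] - self.cluster_centers_[None, :, :]) ** 2).sum(axis=2)
        return np.argmin(d2, axis=1)


# ---------------------------------------------------------------------------
# baselines
# ---------------------------------------------------------------------------


def _spectral_cluster(Xs: np.ndarray, C: int, seed: int, k: int = 10) -> np.ndarray:
    """Normalized spectral clustering on a kNN Gaussian-similarity graph.

    Samples are rows.  Affinity: symmetric kNN graph (k = 10 or n−1 if
    smaller), Gaussian kernel with bandwidth equal to the median nonzero
    neighbor distance; K-means on the top-C eigenvectors of the symmetric
    normalized Laplacian (row-normalized).
    """
    n = Xs.shape[0]
    k = min(k, n - 1)
    from scipy.spatial.distance import squareform, pdist

    Dmat = squareform(pdist(Xs))
    # kNN mask (symmetric): keep edge if either endpoint lists the other
    order = np.argsort(Dmat, axis=1)
    mask = np.zeros_like(Dmat, dtype=bool)
    rows = np.repeat(np.arange(n), k)
    cols = order[:, 1 : k + 1].ravel()
    mask[rows, cols] = True
    mask |= mask.T
    nz = Dmat[mask]
    sigma = np.median(nz[nz > 0]) if np.any(nz > 0) else 1.0
    W = np.where(mask, np.exp(-(Dmat**2) / (2.0 * sigma**2)), 0.0)
    np.fill_diagonal(W, 0.0)
    deg = W.sum(axis=1)
    deg[deg == 0] = 1.0
    Dm12 = 1.0 / np.sqrt(deg)
    L = np.eye(n) - (Dm12[:, None] * W) * Dm12[None, :]
    w, V = scipy.linalg.eigh(L)
    U = V[:, :C]
    norms = np.linalg.norm(U, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    U = U / norms
    return KMeans(n_clusters=C, n_init=10, random_state=seed).fit_predict(U)


def baseline_cluster(X, method: str, C: int, d: int | None = None, seed: int = 0) -> np.ndarray:
    """Stepwise clustering baselines on a D×n feature matrix.

    ``pca_kmeans`` — project onto the top-d scatter eigenvectors then
    K-means; ``kmeans`` — K-means on raw feature columns; ``spectral`` —
    normalized spectral clustering on a kNN Gaussian-similarity graph.
    """
    X = _as_matrix(X)
    methods = {"pca_kmeans", "kmeans", "spectral"}
    if method not in methods:
        raise ValueError(f"unknown method {method!r}; expected one of {sorted(methods)}")
    if method == "pca_kmeans":
        if d is None:
            raise ValueError("pca_kmeans requires d")
        Xc, St = center_and_scatter(X)
        w, V = scipy.linalg.eigh(St)
        Q = _fix_eigvec_signs(V[:, ::-1][:, :d])
        return KMeans(n_clusters=C, n_init=10, random_state=seed).fit_predict((Q.T @ Xc).T)
    if method == "kmeans":
        return KMeans(n_clusters=C, n_init=10, random_state=seed).fit_predict(X.T)
    return _spectral_cluster(X.T, C, seed)
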