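"""Parcellation stability and validity metrics, grid search and templates.

Stability of a parcellation across repeated scans is quantified by the mean
discrete entropy of each voxel's label distribution: with aligned labels
``ls⁽ˢ⁾`` over SC scans,

    Pr(vᵢ = c) = (1/SC) Σ_s δ(ls⁽ˢ⁾(i), c)
    H(i)       = −Σ_c Pr log Pr          (natural log, 0·log 0 := 0)
    H          = mean_i H(i)

Internal validity uses a cluster-level silhouette:

    SI = (1/C) Σ_i (bᵢ − aᵢ) / max(aᵢ, bᵢ)

with aᵢ the mean Euclidean distance over within-cluster pairs of cluster i
and bᵢ the mean distance between cluster-i members and all other samples.
The embedding dimensionality d and balance λ are chosen on a grid by
maximizing SI − H.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist, pdist

from .connectivity import VoxelTimeSeries, ROITimeSeries, voxel_roi_connectivity, half_scan_starts
from .dec import DECConfig, FeatureMatrix, fit_dec

__all__ = [
    "ScanLabelSet",
    "ConsistencyResult",
    "SilhouetteResult",
    "GroupTemplate",
    "ParcellationResult",
    "align_labels",
    "cluster_consistency",
    "silhouette_width",
    "grid_search_params",
    "parcellate_subject",
    "majority_vote_template",
]


@dataclass
class ScanLabelSet:
    """Aligned cluster labels of n voxels across SC scans (n × SC)."""

    LS: np.ndarray
    C: int
    aligned: bool = False

    def __post_init__(self) -> None:
        self.LS = np.asarray(self.LS, int)
        if self.LS.ndim != 2 or self.LS.shape[1] < 2:
            raise ValueError("LS must be n × SC with SC ≥ 2")
        if self.LS.min() < 0 or self.LS.max() >= self.C:
            raise ValueError("labels out of range for C clusters")

    @property
    def SC(self) -> int:
        return self.LS.shape[1]


@dataclass
class ConsistencyResult:
    """Per-voxel label probabilities and entropies across scans."""

    Pr: np.ndarray
    H_voxel: np.ndarray
    H_mean: float
    log_base: str = "e"


@dataclass
class SilhouetteResult:
    a: np.ndarray
    b: np.ndarray
    SI: float


@dataclass
class GroupTemplate:
    """Across-subject majority-voting template.

    prob: n × C voxel-wise cluster frequencies; winner: argmax labels;
    roi_mask: winner probability strictly greater than the threshold.
    """

    prob: np.ndarray
    winner: np.ndarray
    roi_mask: np.ndarray
    threshold: float = 0.6


def align_labels(reference: np.ndarray, target: np.ndarray,
                 coords: np.ndarray | None = None, axis: int = 1) -> np.ndarray:
    """Rename target clusters to correspond with the reference labeling.

    With voxel coordinates given, clusters are renamed by ascending centroid
    coordinate along ``axis`` (default the anteroposterior axis), which makes
    labels comparable across scans and subjects by anatomy.  Otherwise the
    permutation maximizing label agreement with the reference is found by
    optimal assignment on the C×C confusion matrix.
    """
    reference = np.asarray(reference, int)
    target = np.asarray(target, int)
    if reference.shape != target.shape:
        raise ValueError("reference and target labelings differ in length")
    C = int(max(reference.max(), target.max())) + 1
    if coords is not None:
        coords = np.asarray(coords, float)
        if coords.shape[0] != target.shape[0]:
            raise ValueError("coords length mismatch")
        centroids = np.array([
            coords[target == c, axis].mean() if np.any(target == c) else np.inf
            for c in range(C)
        ])
        order = np.argsort(centroids, kind="stable")
        mapping = np.empty(C, int)
        mapping[order] = np.arange(C)
        return mapping[target]
    conf = np.zeros((C, C))
    np.add.at(conf, (target, reference), 1.0)
    rows, cols = linear_sum_assignment(-conf)
    mapping = np.empty(C, int)
    mapping[rows] = cols
    return mapping[target]


def cluster_consistency(lset: ScanLabelSet) -> ConsistencyResult:
    """Voxel-wise label probabilities and entropies over aligned scans."""
    if not lset.aligned:
        raise RuntimeError("labels must be aligned across scans before entropy")
    n, SC = lset.LS.shape
    Pr = np.zeros((n, lset.C))
    for c in range(lset.C):
        Pr[:, c] = np.sum(lset.LS == c, axis=1) / SC
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(Pr > 0, Pr * np.log(Pr), 0.0)
    H_voxel = -plogp.sum(axis=1)
    return ConsistencyResult(Pr=Pr, H_voxel=H_voxel, H_mean=float(H_voxel.mean()))


def silhouette_width(X, labels: np.ndarray) -> SilhouetteResult:
    """Cluster-level silhouette on a D×n feature matrix.

    aᵢ averages Euclidean distances over all unordered within-cluster pairs;
    bᵢ averages distances from cluster-i members to all out-of-cluster
    samples.  Singleton clusters contribute aᵢ = 0; a term with
    aᵢ = bᵢ = 0 contributes 0.
    """
    if isinstance(X, FeatureMatrix):
        X = X.X
    X = np.asarray(X, float)
    labels = np.asarray(labels, int)
    samples = X.T  # n × D
    C = int(labels.max()) + 1
    if C < 2:
        raise ValueError("silhouette needs at least 2 clusters")
    a = np.zeros(C)
    b = np.zeros(C)
    terms = np.zeros(C)
    for c in range(C):
        inside = samples[labels == c]
        outside = samples[labels != c]
        if inside.shape[0] == 0:
            raise ValueError(f"cluster {c} is empty")
        if inside.shape[0] > 1:
            a[c] = float(pdist(inside).mean())
        if outside.shape[0] > 0:
            b[c] = float(cdist(inside, outside).mean())
        denom = max(a[c], b[c])
        terms[c] = 0.0 if denom == 0 else (b[c] - a[c]) / denom
    return SilhouetteResult(a=a, b=b, SI=float(terms.mean()))


def grid_search_params(d_values, lam_values, SI: np.ndarray, H: np.ndarray) -> tuple[float, float]:
    """Pick (d*, λ*) maximizing SI − H over the parameter grid.

    SI and H are len(d) × len(λ) arrays.  Ties break toward smaller d, then
    smaller λ.  The default grid in the parcellation pipeline is
    d ∈ {2, 4, …, 40}, λ ∈ {0, 2, …, 40} (420 cells).
    """
    d_values = list(d_values)
    lam_values = list(lam_values)
    SI = np.asarray(SI, float)
    H = np.asarray(H, float)
    if SI.shape != (len(d_values), len(lam_values)) or H.shape != SI.shape:
        raise ValueError("SI/H grids must be len(d) × len(lam)")
    bad = ~(np.isfinite(SI) & np.isfinite(H))
    if np.any(bad):
        i, j = np.argwhere(bad)[0]
        raise ValueError(f"non-finite metric at grid cell d={d_values[i]}, lam={lam_values[j]}")
    score = SI - H
    best = None
    for i, dv in enumerate(d_values):
        for j, lv in enumerate(lam_values):
            if best is None or score[i, j] > best[0]:
                best = (score[i, j], dv, lv)
    return best[1], best[2]


def default_grid() -> tuple[list[int], list[int]]:
    """Default grid: d from 2 to 40 step 2, λ from 0 to 40 step 2."""
    return list(range(2, 41, 2)), list(range(0, 41, 2))


@dataclass
class ParcellationResult:
    """Per-subject parcellation output: aligned labels per scan plus metrics."""

    full_labels: np.ndarray
    scan_labels: ScanLabelSet
    consistency: ConsistencyResult
    silhouette: SilhouetteResult
    scan_starts: np.ndarray = field(default_factory=lambda: np.array([], int))


def parcellate_subject(vts: VoxelTimeSeries, rts: ROITimeSeries,
                       cfg: DECConfig | None = None, n_scans: int = 20,
                       align_axis: int = 1) -> ParcellationResult:
    """Parcellate one subject and score stability and validity.

    Builds Fisher-z voxel×ROI connectivity for the full scan and for
    ``n_scans`` random half-length windows, fits DEC to each, aligns labels
    along the anatomical axis (ascending centroid mm coordinate, default
    anteroposterior), and returns the cross-scan entropy plus the silhouette
    of the full-scan parcellation on its connectivity features.
    """
    cfg = cfg or DECConfig()
    mm = vts.mm_coords()

    def features(v: VoxelTimeSeries, r: ROITimeSeries) -> FeatureMatrix:
        return FeatureMatrix(voxel_roi_connectivity(v, r).z.T)

    full_X = features(vts, rts)
    full_model = fit_dec(full_X, cfg)
    full_labels = align_labels(full_model.labels, full_model.labels, coords=mm, axis=align_axis)

    starts, length = half_scan_starts(vts.n_timepoints, n_scans, cfg.seed)
    cols = []
    for s in starts:
        v = vts.window(int(s), length)
        r = rts.window(int(s), length)
        model = fit_dec(features(v, r), cfg)
        cols.append(align_labels(model.labels, model.labels, coords=mm, axis=align_axis))
    lset = ScanLabelSet(np.stack(cols, axis=1), C=cfg.C, aligned=True)
    return ParcellationResult(
        full_labels=full_labels,
        scan_labels=lset,
        consistency=cluster_consistency(lset),
        silhouette=silhouette_width(full_X, full_labels),
        scan_starts=np.asarray(starts, int),
    )


def majority_vote_template(subject_labels: list[np.ndarray], C: int | None = None,
                           threshold: float = 0.6) -> GroupTemplate:
    """Across-subject majority-voting template.

    Each voxel's cluster frequency over subjects is computed; the winner is
    the argmax (ties to the lowest index); the ROI mask keeps voxels whose
    winning probability strictly exceeds the threshold (default 0.6).
    """
    mat = np.stack([np.asarray(l, int) for l in subject_labels], axis=1)  # n × S
    if C is None:
        C = int(mat.max()) + 1
    n, S = mat.shape
    prob = np.zeros((n, C))
    for c in range(C):
        prob[:, c] = np.sum(mat == c, axis=1) / S
    winner = np.argmax(prob, axis=1)
    win_p = prob[np.arange(n), winner]
    return GroupTemplate(prob=prob, winner=winner, roi_mask=win_p > threshold, threshold=threshold)
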