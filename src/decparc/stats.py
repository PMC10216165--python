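"""Seed-based connectivity maps and voxelwise group statistics.

Implements the inferential layer of the parcellation pipeline: seed maps
(Fisher-z correlation of a subregion's mean time series with every in-mask
voxel), one-sample t-maps with Benjamini–Hochberg FDR and a cluster-size
filter, network-level paired t-tests with Bonferroni correction, and
two-sample t-maps with a Monte-Carlo cluster-extent threshold (the classic
AlphaSim scheme: smoothed Gaussian-noise volumes, voxelwise threshold,
distribution of the maximum cluster size under an rmm-distance neighbor
rule).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from statsmodels.stats.multitest import multipletests

from .connectivity import R_CLIP_DEFAULT, _rowwise_corr, fisher_z

__all__ = [
    "ZMap",
    "StatMap",
    "NetworkFC",
    "seed_connectivity_map",
    "bh_fdr",
    "one_sample_map",
    "network_paired_tests",
    "two_sample_map",
    "monte_carlo_cluster_threshold",
    "label_clusters",
]


@dataclass
class ZMap:
    """Per-voxel Fisher-z seed-connectivity volume with its brain mask."""

    values: np.ndarray
    mask: np.ndarray
    subject_id: str = ""
    seed_name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        self.mask = np.asarray(self.mask, bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        if not np.all(np.isfinite(self.values[self.mask])):
            raise ValueError("non-finite z values inside mask")


@dataclass
class StatMap:
    """Voxelwise statistic map with correction metadata."""

    t: np.ndarray
    p: np.ndarray
    df: float
    mask: np.ndarray
    significant: np.ndarray
    correction: str
    alpha: float
    min_cluster_voxels: int


@dataclass
class NetworkFC:
    """Mean subregion-to-network Fisher-z connectivity.

    data: subjects × subregions × networks.
    """

    data: np.ndarray
    subregion_names: list[str] | None = None
    network_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, float)
        if self.data.ndim != 3:
            raise ValueError("NetworkFC.data must be subjects × subregions × networks")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite connectivity values")


# ---------------------------------------------------------------------------
# seed maps
# ---------------------------------------------------------------------------


def seed_connectivity_map(seed_mask: np.ndarray, volume4d: np.ndarray,
                          brain_mask: np.ndarray, subject_id: str = "",
                          seed_name: str = "", r_clip: float = R_CLIP_DEFAULT) -> ZMap:
    """Fisher-z correlation of the seed's mean series with every brain voxel."""
    volume4d = np.asarray(volume4d, float)
    seed_mask = np.asarray(seed_mask, bool)
    brain_mask = np.asarray(brain_mask, bool)
    if volume4d.ndim != 4:
        raise ValueError("volume4d must be 4-D")
    if seed_mask.shape != volume4d.shape[:3] or brain_mask.shape != volume4d.shape[:3]:
        raise ValueError("mask grids do not match the 4-D volume")
    if not np.any(seed_mask):
        raise ValueError("seed mask is empty")
    seed_series = volume4d[seed_mask].mean(axis=0)[None, :]
    vox = volume4d[brain_mask]
    r = _rowwise_corr(vox, seed_series)[:, 0]
    z = np.zeros(brain_mask.shape)
    z[brain_mask] = fisher_z(r, r_clip)
    return ZMap(values=z, mask=brain_mask, subject_id=subject_id, seed_name=seed_name)


# ---------------------------------------------------------------------------
# multiple-testing helpers
# ---------------------------------------------------------------------------


def bh_fdr(p: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini–Hochberg step-up rejection mask at level q."""
    p = np.asarray(p, float)
    if p.size == 0:
        return np.zeros(0, bool)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


def _neighbor_offsets(voxel_size_mm, rmm_mm: float) -> np.ndarray:
    """Integer voxel offsets whose center distance is ≤ rmm_mm (excluding 0)."""
    voxel_size_mm = np.broadcast_to(np.asarray(voxel_size_mm, float), (3,))
    if rmm_mm < voxel_size_mm.min():
        raise ValueError(
            f"rmm={rmm_mm} mm is smaller than the voxel size {voxel_size_mm}; no neighbors"
        )
    reach = np.floor(rmm_mm / voxel_size_mm).astype(int)
    offs = []
    for dx in range(-reach[0], reach[0] + 1):
        for dy in range(-reach[1], reach[1] + 1):
            for dz in range(-reach[2], reach[2] + 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                dist = np.linalg.norm(np.array([dx, dy, dz]) * voxel_size_mm)
                if dist <= rmm_mm:
                    offs.append((dx, dy, dz))
    return np.asarray(offs, int)


def label_clusters(binary: np.ndarray, voxel_size_mm=3.0, rmm_mm: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Connected components of a binary volume under the rmm distance rule.

    Voxels are neighbors iff their center distance is ≤ rmm_mm.  Default rmm
    = voxel_size·√3 + ε, i.e. 26-connectivity.  Returns (labels volume with
    0 = background and components numbered from 1, component sizes).
    """
    binary = np.asarray(binary, bool)
    vs = np.broadcast_to(np.asarray(voxel_size_mm, float), (3,))
    if rmm_mm is None:
        rmm_mm = float(vs.max() * np.sqrt(3.0) + 1e-6)
    offsets = _neighbor_offsets(vs, rmm_mm)
    idx_vol = -np.ones(binary.shape, int)
    coords = np.argwhere(binary)
    m = coords.shape[0]
    if m == 0:
        return np.zeros(binary.shape, int), np.zeros(0, int)
    idx_vol[binary] = np.arange(m)
    rows, cols = [], []
    shape = np.asarray(binary.shape)
    for off in offsets:
        lo = np.maximum(0, -off)
        hi = shape - np.maximum(0, off)
        if np.any(hi <= lo):
            continue
        src = idx_vol[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        dst = idx_vol[lo[0] + off[0]:hi[0] + off[0],
                      lo[1] + off[1]:hi[1] + off[1],
                      lo[2] + off[2]:hi[2] + off[2]]
        both = (src >= 0) & (dst >= 0)
        rows.append(src[both])
        cols.append(dst[both])
    if rows:
        r = np.concatenate(rows)
        c = np.concatenate(cols)
        graph = coo_matrix((np.ones(r.size), (r, c)), shape=(m, m))
    else:
        graph = coo_matrix((m, m))
    n_comp, comp = connected_components(graph, directed=False)
    labels = np.zeros(binary.shape, int)
    labels[binary] = comp + 1
    sizes = np.bincount(comp, minlength=n_comp)
    return labels, sizes


def _apply_cluster_filter(sig: np.ndarray, min_cluster: int, voxel_size_mm, rmm_mm,
                          strict: bool = True) -> np.ndarray:
    """Drop significant components not exceeding min_cluster voxels."""
    labels, sizes = label_clusters(sig, voxel_size_mm, rmm_mm)
    keep = np.zeros(sig.shape, bool)
    for comp_id, size in enumerate(sizes, start=1):
        ok = size > min_cluster if strict else size >= min_cluster
        if ok:
            keep |= labels == comp_id
    return keep


# ---------------------------------------------------------------------------
# t-maps
# ---------------------------------------------------------------------------


def _check_common_mask(zmaps: list[ZMap]) -> np.ndarray:
    mask = zmaps[0].mask
    if any(not np.array_equal(z.mask, mask) for z in zmaps):
        raise ValueError("z-maps must share a common mask")
    return mask


def one_sample_map(zmaps: list[ZMap], alpha: float = 0.05, min_cluster: int = 10,
                   voxel_size_mm=3.0, rmm_mm: float | None = None) -> StatMap:
    """Voxelwise one-sample t-test against 0 with BH-FDR and cluster filter.

    Surviving FDR voxels are grouped into connected components (default
    26-connectivity, i.e. rmm = voxel_size·√3) and components with size not
    exceeding ``min_cluster`` are removed (strict "> min_cluster" rule).
    """
    if len(zmaps) < 3:
        raise ValueError("need at least 3 z-maps for a one-sample t-test")
    mask = _check_common_mask(zmaps)
    data = np.stack([z.values[mask] for z in zmaps])  # S × m
    S = data.shape[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_1samp(data, 0.0, axis=0)
    t = np.nan_to_num(res.statistic, nan=0.0)
    p = np.nan_to_num(res.pvalue, nan=1.0)
    reject = bh_fdr(p, alpha)
    sig = np.zeros(mask.shape, bool)
    sig[mask] = reject
    sig = _apply_cluster_filter(sig, min_cluster, voxel_size_mm, rmm_mm, strict=True)
    t_vol = np.zeros(mask.shape)
    p_vol = np.ones(mask.shape)
    t_vol[mask] = t
    p_vol[mask] = p
    return StatMap(t=t_vol, p=p_vol, df=S - 1, mask=mask, significant=sig,
                   correction="fdr_bh", alpha=alpha, min_cluster_voxels=min_cluster)


def network_paired_tests(nfc: NetworkFC, alpha: float = 0.05) -> pd.DataFrame:
    """Paired t-tests between subregions' network-level connectivity.

    One test per (subregion pair, network); Bonferroni correction over all
    pairs × networks in the table (3 pairs × 6 networks = 18 for the default
    three-way parcellation per hemisphere).  Zero-variance nonzero paired
    differences are degenerate: flagged, with p reported below machine floor.
    """
    S, K, Nnet = nfc.data.shape
    if S < 3:
        raise ValueError("need at least 3 subjects for paired tests")
    pairs = [(i, j) for i in range(K) for j in range(i + 1, K)]
    m = len(pairs) * Nnet
    rows = []
    sub = nfc.subregion_names or [f"sub{i}" for i in range(K)]
    nets = nfc.network_names or [f"net{i}" for i in range(Nnet)]
    for (i, j) in pairs:
        for k in range(Nnet):
            d = nfc.data[:, i, k] - nfc.data[:, j, k]
            degenerate = False
            if np.allclose(d.std(), 0.0):
                if np.allclose(d.mean(), 0.0):
                    t, p = 0.0, 1.0
                else:
                    degenerate = True
                    t = np.inf if d.mean() > 0 else -np.inf
                    p = np.nextafter(0.0, 1.0)
                    warnings.warn(
                        f"degenerate paired test ({sub[i]} vs {sub[j]}, {nets[k]}): "
                        "constant nonzero differences; p below machine floor"
                    )
            else:
                res = stats.ttest_rel(nfc.data[:, i, k], nfc.data[:, j, k])
                t, p = float(res.statistic), float(res.pvalue)
            rows.append({
                "subregion_a": sub[i], "subregion_b": sub[j], "network": nets[k],
                "t": t, "p": p, "p_bonferroni": min(1.0, p * m),
                "significant": p * m < alpha, "degenerate": degenerate,
            })
    df = pd.DataFrame(rows)
    df.attrs["bonferroni_m"] = m
    return df


def two_sample_map(group1: list[ZMap], group2: list[ZMap],
                   union_mask: np.ndarray | None = None, alpha: float = 0.05,
                   n_sim: int = 1000, rmm_mm: float = 7.0, voxel_size_mm=3.0,
                   smoothness_fwhm_mm: float = 6.0, seed: int | None = None) -> StatMap:
    """Two-sample t-map with Monte-Carlo (AlphaSim-style) cluster correction.

    Pooled-variance t per voxel inside ``union_mask`` (typically the union of
    the two groups' one-sample maps), two-sided voxel threshold at ``alpha``,
    then removal of suprathreshold clusters smaller than the Monte-Carlo
    minimum cluster size.
    """
    if len(group1) < 2 or len(group2) < 2:
        raise ValueError("each group needs at least 2 z-maps")
    mask = _check_common_mask(group1 + group2)
    if union_mask is not None:
        union_mask = np.asarray(union_mask, bool)
        mask = mask & union_mask
    if not np.any(mask):
        raise ValueError("analysis mask is empty")
    A = np.stack([z.values[mask] for z in group1])
    B = np.stack([z.values[mask] for z in group2])
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(A, B, axis=0, equal_var=True)
    t = np.nan_to_num(res.statistic, nan=0.0)
    p = np.nan_to_num(res.pvalue, nan=1.0)
    k_min = monte_carlo_cluster_threshold(
        mask, voxel_alpha=alpha, n_sim=n_sim, rmm_mm=rmm_mm,
        voxel_size_mm=voxel_size_mm, smoothness_fwhm_mm=smoothness_fwhm_mm, seed=seed,
    )
    sig = np.zeros(mask.shape, bool)
    sig[mask] = p < alpha
    sig = _apply_cluster_filter(sig, k_min - 1, voxel_size_mm, rmm_mm, strict=True)
    t_vol = np.zeros(mask.shape)
    p_vol = np.ones(mask.shape)
    t_vol[mask] = t
    p_vol[mask] = p
    return StatMap(t=t_vol, p=p_vol, df=A.shape[0] + B.shape[0] - 2, mask=mask,
                   significant=sig, correction="monte_carlo_cluster", alpha=alpha,
                   min_cluster_voxels=k_min)


def monte_carlo_cluster_threshold(mask: np.ndarray, voxel_alpha: float = 0.05,
                                  n_sim: int = 1000, rmm_mm: float = 7.0,
                                  voxel_size_mm=3.0, smoothness_fwhm_mm: float = 6.0,
                                  seed: int | None = None) -> int:
    """Minimum cluster size for corrected p < 0.05 by Monte-Carlo simulation.

    Simulates ``n_sim`` Gaussian-noise volumes smoothed to the given FWHM and
    re-standardized within the mask, thresholds each two-sided at
    ``voxel_alpha``, records the maximum suprathreshold cluster size under
    the rmm neighbor rule, and returns the smallest cluster size whose
    simulated corrected p — the fraction of null volumes with a maximum
    cluster at least that large — is at most 0.05.
    """
    mask = np.asarray(mask, bool)
    if not np.any(mask):
        raise ValueError("mask is empty")
    vs = np.broadcast_to(np.asarray(voxel_size_mm, float), (3,))
    if rmm_mm < vs.min():
        raise ValueError("rmm smaller than voxel size: no voxel has neighbors")
    rng = np.random.default_rng(seed)
    sigma_vox = smoothness_fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / vs
    # exact unit-variance restandardization: scale by the smoothing kernel's
    # root sum of squares (an impulse response), not the per-realization
    # sample std — the latter shrinks the field's natural density
    # fluctuations and makes the cluster threshold anticonservative
    impulse = np.zeros(mask.shape)
    impulse[tuple(np.asarray(mask.shape) // 2)] = 1.0
    scale = float(np.sqrt(np.sum(ndimage.gaussian_filter(impulse, sigma=sigma_vox) ** 2)))
    zcrit = stats.norm.ppf(1.0 - voxel_alpha / 2.0)
    max_sizes = np.zeros(n_sim, int)
    for s in range(n_sim):
        noise = rng.standard_normal(mask.shape)
        smooth = ndimage.gaussian_filter(noise, sigma=sigma_vox) / scale
        supra = np.zeros(mask.shape, bool)
        supra[mask] = np.abs(smooth[mask]) > zcrit
        _, sizes = label_clusters(supra, vs, rmm_mm)
        max_sizes[s] = sizes.max() if sizes.size else 0
    # smallest s with P̂(max cluster ≥ s) ≤ 0.05
    sorted_max = np.sort(max_sizes)
    k = sorted_max[int(np.ceil(0.95 * n_sim)) - 1] + 1
    return int(k)
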