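"""Synthetic multi-subject, multi-scan voxel time series with planted structure.

Emulates the statistical structure connectivity-based parcellation assumes:
voxels within a cluster share an ROI-connectivity profile.  ROI time series
are independent Gaussian processes; each voxel's series is a cluster-specific
linear combination of ROI series (with small within-cluster jitter) plus
Gaussian noise.  The mask is three abutting blocks along one axis (~300
voxels, mirroring an elongated structure subdivided along its long axis),
giving C_true = 3 planted, spatially contiguous clusters.

Optional planted effects:

* ``boundary_flip_prob`` — per time epoch, voxels adjacent to a cluster
  boundary swap to the neighboring cluster's loading with this probability,
  planting genuine cross-scan label instability;
* ``group_effect`` — group-1 subjects gain extra coupling between a chosen
  voxel set and a reference signal, planting a connectivity group difference.

The generator makes no claim to hemodynamic realism: there is no
autocorrelation beyond the block structure, no physiological noise, no
spatial smoothness of the noise field.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .connectivity import ROITimeSeries, VoxelTimeSeries

__all__ = ["SyntheticSpec", "generate_subject", "generate_two_group", "generate_group_zmaps"]

_NETWORKS = ["visual", "somatomotor", "dorsal_attention", "ventral_attention", "default", "control"]


@dataclass
class SyntheticSpec:
    """Study-design parameters for the synthetic cohort.

    Defaults mirror the HCP-style acquisition shape the pipeline targets:
    T = 1200 time points, 20 subjects, 20 half-length scans for the
    stability analysis, 114 target ROIs, three clusters over ~300 voxels.
    noise_sigma = 1.0 puts the voxel noise standard deviation at the signal
    standard deviation; loading_jitter = 0.1 makes within-cluster voxels
    similar but not identical.
    """

    n_subjects: int = 20
    n_scans_per_subject: int = 20
    grid_shape: tuple[int, int, int] = (5, 30, 2)
    block_axis: int = 1
    C_true: int = 3
    n_rois: int = 114
    T: int = 1200
    loading_jitter: float = 0.1
    noise_sigma: float = 1.0
    boundary_flip_prob: float = 0.0
    n_epochs: int = 20
    group_effect: tuple[np.ndarray, float] | None = None  # (voxel index set, coupling)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_subjects, self.n_scans_per_subject, self.C_true, self.n_rois, self.T) < 1:
            raise ValueError("all counts must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")
        if not 0.0 <= self.boundary_flip_prob <= 1.0:
            raise ValueError("boundary_flip_prob must be in [0, 1]")
        if self.grid_shape[self.block_axis] < self.C_true:
            raise ValueError("block axis too short for C_true blocks")

    # -- planted geometry ---------------------------------------------------

    def voxel_coords(self) -> np.ndarray:
        g = self.grid_shape
        return np.argwhere(np.ones(g, bool))

    def true_labels(self) -> np.ndarray:
        """Block label of every voxel: C_true abutting slabs along block_axis."""
        coords = self.voxel_coords()
        extent = self.grid_shape[self.block_axis]
        edges = np.linspace(0, extent, self.C_true + 1)
        return np.clip(np.searchsorted(edges, coords[:, self.block_axis], side="right") - 1,
                       0, self.C_true - 1)

    def boundary_voxels(self) -> np.ndarray:
        """Indices of voxels within one slab of a cluster boundary."""
        coords = self.voxel_coords()
        labels = self.true_labels()
        extent = self.grid_shape[self.block_axis]
        edges = np.linspace(0, extent, self.C_true + 1)[1:-1]
        pos = coords[:, self.block_axis]
        near = np.zeros(len(coords), bool)
        for e in edges:
            near |= (pos == np.floor(e) - 1) | (pos == np.floor(e))
        return np.flatnonzero(near & (labels >= 0))

    def _loadings(self) -> np.ndarray:
        """Cluster loading vectors over ROIs: random Gaussian, then decorrelated.

        QR orthonormalization makes the planted connectivity profiles
        orthogonal-ish so clusters are separable at moderate noise.
        """
        rng = np.random.default_rng(self.seed)
        W = rng.standard_normal((self.n_rois, self.C_true))
        Qmat, _ = np.linalg.qr(W)
        return Qmat.T  # C × R, orthonormal rows


def _subject_rng(spec: SyntheticSpec, subject_index: int, salt: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([spec.seed, subject_index, salt]))


def generate_subject(spec: SyntheticSpec, subject_index: int,
                     group_shift: bool = False) -> tuple[VoxelTimeSeries, ROITimeSeries, np.ndarray]:
    """Generate one subject's voxel and ROI time series plus planted labels.

    Deterministic given (spec.seed, subject_index).  ROI series are iid
    standard Gaussian; voxel series mix the cluster's (jittered, normalized)
    loading over ROI series with additive Gaussian noise.  With
    ``boundary_flip_prob`` > 0 the full scan is split into ``n_epochs``
    epochs and boundary voxels swap to an adjacent cluster's loading with
    that probability per epoch.
    """
    rng = _subject_rng(spec, subject_index)
    coords = spec.voxel_coords()
    labels = spec.true_labels()
    n = len(coords)
    W = spec._loadings()  # C × R

    roi = rng.standard_normal((spec.n_rois, spec.T))
    # per-voxel loading: cluster loading + jitter, renormalized
    w = W[labels] + spec.loading_jitter * rng.standard_normal((n, spec.n_rois))
    w /= np.linalg.norm(w, axis=1, keepdims=True)

    if spec.boundary_flip_prob > 0:
        vox = np.empty((n, spec.T))
        bounds = np.linspace(0, spec.T, spec.n_epochs + 1).astype(int)
        bvox = spec.boundary_voxels()
        w_alt = w.copy()
        for v in bvox:
            c = labels[v]
            alt = c + 1 if c + 1 < spec.C_true else c - 1
            w_alt[v] = W[alt] + spec.loading_jitter * rng.standard_normal(spec.n_rois)
        w_alt /= np.linalg.norm(w_alt, axis=1, keepdims=True)
        for e in range(spec.n_epochs):
            sl = slice(bounds[e], bounds[e + 1])
            w_e = w.copy()
            flip = bvox[rng.random(len(bvox)) < spec.boundary_flip_prob]
            w_e[flip] = w_alt[flip]
            vox[:, sl] = w_e @ roi[:, sl]
    else:
        vox = w @ roi

    vox = vox + spec.noise_sigma * rng.standard_normal((n, spec.T))

    if group_shift and spec.group_effect is not None:
        effect_voxels, coupling = spec.group_effect
        effect_voxels = np.asarray(effect_voxels, int)
        if effect_voxels.size and (effect_voxels.min() < 0 or effect_voxels.max() >= n):
            raise ValueError("group-effect voxels outside the mask")
        # extra shared signal between the effect voxels and ROI 0 raises
        # their connectivity with it by ~arctanh step proportional to coupling
        vox[effect_voxels] += coupling * roi[0]

    nets = [_NETWORKS[i % len(_NETWORKS)] for i in range(spec.n_rois)]
    names = [f"roi{i:03d}" for i in range(spec.n_rois)]
    affine = np.diag([3.0, 3.0, 3.0, 1.0])
    vts = VoxelTimeSeries(vox, coords, affine=affine, tr_seconds=0.72)
    rts = ROITimeSeries(roi, names, nets)
    return vts, rts, labels


def generate_two_group(spec: SyntheticSpec):
    """Two subject cohorts; the planted connectivity shift applies to group 1 only.

    Returns (group1, group2), each a list of (VoxelTimeSeries, ROITimeSeries,
    labels).  Group-2 subjects use distinct subject indices so the cohorts
    are independent.
    """
    if spec.group_effect is None:
        raise ValueError("spec.group_effect must be set for a two-group design")
    g1 = [generate_subject(spec, i, group_shift=True) for i in range(spec.n_subjects)]
    g2 = [generate_subject(spec, spec.n_subjects + i, group_shift=False)
          for i in range(spec.n_subjects)]
    return g1, g2


def generate_group_zmaps(grid_shape: tuple[int, int, int], effect_block: tuple[slice, slice, slice] | None,
                         shift: float, sigma: float, n1: int, n2: int, seed: int = 0):
    """Synthetic seed-map cohorts at the z-map level for calibration studies.

    Both groups are voxelwise Gaussian noise with standard deviation
    ``sigma``; group 1 additionally carries a mean shift inside
    ``effect_block``.  Returns (group1 ZMap values list, group2 list, mask,
    effect mask) — deliberately simple so t-map calibration is exact.
    """
    from .stats import ZMap

    rng = np.random.default_rng(seed)
    mask = np.ones(grid_shape, bool)
    effect = np.zeros(grid_shape, bool)
    if effect_block is not None:
        effect[effect_block] = True
    g1 = []
    g2 = []
    for i in range(n1):
        v = sigma * rng.standard_normal(grid_shape)
        v[effect] += shift
        g1.append(ZMap(v, mask, subject_id=f"g1-{i}"))
    for i in range(n2):
        g2.append(ZMap(sigma * rng.standard_normal(grid_shape), mask, subject_id=f"g2-{i}"))
    return g1, g2, mask, effect
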