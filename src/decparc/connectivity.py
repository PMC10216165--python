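"""Voxel × ROI functional-connectivity features and scan-stability tools.

Connectivity features for parcellation are Fisher-z transformed Pearson
correlations between each voxel's BOLD time series inside a region mask and
the mean time series of a set of target ROIs (114 cortical regions in the
default atlas table).  Half-length scans drawn from the full series support
the cross-scan stability analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "VoxelTimeSeries",
    "ROITimeSeries",
    "ConnectivityMatrix",
    "R_CLIP_DEFAULT",
    "fisher_z",
    "roi_mean_timeseries",
    "voxel_roi_connectivity",
    "half_scan_starts",
    "split_half_scans",
    "loo_stability",
]

# correlations are clipped to ±(1 − 1e−7) before arctanh to keep z finite
R_CLIP_DEFAULT = 1.0 - 1e-7


@dataclass
class VoxelTimeSeries:
    """Time series of the voxels inside a region mask.

    data: n voxels × T; voxel_coords: n × 3 integer (i, j, k) indices into
    the volume grid; affine: voxel-to-mm transform; tr_seconds: repetition
    time.
    """

    data: np.ndarray
    voxel_coords: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    tr_seconds: float = 0.72

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, float)
        self.voxel_coords = np.asarray(self.voxel_coords, int)
        self.affine = np.asarray(self.affine, float)
        if self.data.ndim != 2 or self.data.shape[1] < 2:
            raise ValueError("voxel data must be n×T with T ≥ 2")
        if self.voxel_coords.shape != (self.data.shape[0], 3):
            raise ValueError("voxel_coords must be n×3")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("voxel data contains non-finite values")

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]

    def mm_coords(self) -> np.ndarray:
        """Voxel centers in millimeters via the affine."""
        hom = np.c_[self.voxel_coords, np.ones(len(self.voxel_coords))]
        return (hom @ self.affine.T)[:, :3]

    def window(self, start: int, length: int) -> "VoxelTimeSeries":
        return VoxelTimeSeries(
            self.data[:, start : start + length],
            self.voxel_coords,
            self.affine,
            self.tr_seconds,
        )


@dataclass
class ROITimeSeries:
    """Mean time series of the target ROIs (R × T) with network lookup."""

    data: np.ndarray
    roi_names: list[str] | None = None
    network_of_roi: list[str] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, float)
        if self.data.ndim != 2:
            raise ValueError("ROI data must be R×T")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("ROI data contains non-finite values")
        if self.roi_names is not None and len(self.roi_names) != self.data.shape[0]:
            raise ValueError("roi_names length mismatch")
        if self.network_of_roi is not None and len(self.network_of_roi) != self.data.shape[0]:
            raise ValueError("network_of_roi length mismatch")

    @property
    def n_rois(self) -> int:
        return self.data.shape[0]

    def window(self, start: int, length: int) -> "ROITimeSeries":
        return ROITimeSeries(self.data[:, start : start + length], self.roi_names, self.network_of_roi)


@dataclass
class ConnectivityMatrix:
    """n voxels × R ROIs Fisher-z correlation matrix."""

    z: np.ndarray
    r_clip: float = R_CLIP_DEFAULT
    voxel_coords: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, float)
        if not np.all(np.isfinite(self.z)):
            raise ValueError("connectivity contains non-finite z values")


def fisher_z(r: np.ndarray, r_clip: float = R_CLIP_DEFAULT) -> np.ndarray:
    """Variance-stabilizing arctanh transform with clipping at ±r_clip."""
    return np.arctanh(np.clip(r, -r_clip, r_clip))


def roi_mean_timeseries(volume4d: np.ndarray, atlas_labels: np.ndarray,
                        roi_values: list[int] | None = None,
                        roi_names: list[str] | None = None,
                        network_of_roi: list[str] | None = None) -> ROITimeSeries:
    """Average a 4-D volume's time series within each atlas label.

    ``roi_values`` gives the positive label values defining the ROIs (default:
    all distinct nonzero values, sorted).  ROIs with zero voxels are excluded
    with a warning (and dropped from the name/network lists).
    """
    volume4d = np.asarray(volume4d, float)
    atlas_labels = np.asarray(atlas_labels)
    if volume4d.ndim != 4:
        raise ValueError("volume4d must be 4-D (i, j, k, t)")
    if atlas_labels.shape != volume4d.shape[:3]:
        raise ValueError("atlas grid does not match the 4-D volume grid")
    if roi_values is None:
        roi_values = sorted(int(v) for v in np.unique(atlas_labels) if v > 0)
    series, kept = [], []
    for i, v in enumerate(roi_values):
        m = atlas_labels == v
        if not np.any(m):
            warnings.warn(f"ROI label {v} has no voxels; excluded")
            continue
        series.append(volume4d[m].mean(axis=0))
        kept.append(i)
    names = [roi_names[i] for i in kept] if roi_names else None
    nets = [network_of_roi[i] for i in kept] if network_of_roi else None
    return ROITimeSeries(np.asarray(series), names, nets)


def _rowwise_corr(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pearson correlation between every row of A (n×T) and of B (R×T).

    Zero-variance rows yield correlation 0 (callers warn separately).
    """
    A = A - A.mean(axis=1, keepdims=True)
    B = B - B.mean(axis=1, keepdims=True)
    sa = np.sqrt(np.sum(A * A, axis=1))
    sb = np.sqrt(np.sum(B * B, axis=1))
    sa_safe = np.where(sa == 0, 1.0, sa)
    sb_safe = np.where(sb == 0, 1.0, sb)
    r = (A @ B.T) / sa_safe[:, None] / sb_safe[None, :]
    r[sa == 0, :] = 0.0
    r[:, sb == 0] = 0.0
    return r


def voxel_roi_connectivity(vts: VoxelTimeSeries, rts: ROITimeSeries,
                           r_clip: float = R_CLIP_DEFAULT) -> ConnectivityMatrix:
    """Fisher-z voxel-to-ROI Pearson correlations.

    Rows with zero temporal variance get a zero z-row and a warning rather
    than an error — region masks routinely touch flat voxels.
    """
    if vts.n_timepoints != rts.data.shape[1]:
        raise ValueError(
            f"time dimension mismatch: voxels T={vts.n_timepoints}, ROIs T={rts.data.shape[1]}"
        )
    var_v = vts.data.var(axis=1)
    if np.any(var_v == 0):
        warnings.warn(f"{int(np.sum(var_v == 0))} zero-variance voxel series; z set to 0")
    if np.any(rts.data.var(axis=1) == 0):
        warnings.warn("zero-variance ROI series; z set to 0")
    r = _rowwise_corr(vts.data, rts.data)
    return ConnectivityMatrix(fisher_z(r, r_clip), r_clip, vts.voxel_coords)


def half_scan_starts(T: int, n_scans: int, seed: int) -> tuple[np.ndarray, int]:
    """Seeded uniform start offsets for contiguous half-length windows."""
    if T < 4:
        raise ValueError("need T ≥ 4 to form half-length scans")
    if n_scans < 2:
        raise ValueError("n_scans must be at least 2")
    length = T // 2
    rng = np.random.default_rng(seed)
    starts = rng.integers(0, T - length + 1, size=n_scans)
    return starts, length


def split_half_scans(vts: VoxelTimeSeries, n_scans: int = 20, seed: int = 0) -> list[VoxelTimeSeries]:
    """Draw n_scans contiguous half-length windows (with replacement).

    Windows preserve temporal autocorrelation; starts are uniform over the
    valid range, reproducible given the seed.
    """
    starts, length = half_scan_starts(vts.n_timepoints, n_scans, seed)
    return [vts.window(int(s), length) for s in starts]


def loo_stability(conns: list[ConnectivityMatrix]) -> tuple[np.ndarray, float]:
    """Leave-one-out connectivity stability per voxel.

    For each left-out scan, correlate every voxel's ROI-connectivity row with
    the element-wise mean row over the remaining scans; average the per-voxel
    correlations over all leave-one-out passes.  Returns (per-voxel vector,
    mean).
    """
    if len(conns) < 3:
        raise ValueError("need at least 3 connectivity matrices")
    Z = np.stack([c.z for c in conns])  # SC × n × R
    if any(c.z.shape != Z[0].shape for c in conns):
        raise ValueError("connectivity matrices differ in shape")
    SC, n, R = Z.shape
    total = Z.sum(axis=0)
    corrs = np.empty((SC, n))
    for s in range(SC):
        mean_rest = (total - Z[s]) / (SC - 1)
        A = Z[s] - Z[s].mean(axis=1, keepdims=True)
        B = mean_rest - mean_rest.mean(axis=1, keepdims=True)
        num = np.sum(A * B, axis=1)
        den = np.sqrt(np.sum(A * A, axis=1) * np.sum(B * B, axis=1))
        corrs[s] = np.where(den == 0, 0.0, num / np.where(den == 0, 1.0, den))
    per_voxel = corrs.mean(axis=0)
    return per_voxel, float(per_voxel.mean())
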