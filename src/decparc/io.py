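"""NIfTI / TSV / YAML plumbing for the parcellation pipeline.

Conventions: label volumes on disk carry values 1..C inside the mask with 0
reserved for background; in-memory label vectors are 0-based (the writer and
reader own the shift).  Voxel indices are 0-based; millimeter coordinates go
through the image affine.
"""

from __future__ import annotations

import json
import platform
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .connectivity import ConnectivityMatrix, ROITimeSeries, VoxelTimeSeries

__all__ = [
    "load_voxel_timeseries",
    "save_voxel_timeseries",
    "load_roi_lookup",
    "load_atlas",
    "write_labels_nifti",
    "read_labels_nifti",
    "write_prob_nifti",
    "write_scalar_nifti",
    "connectivity_to_tsv",
    "connectivity_from_tsv",
    "roi_ts_to_tsv",
    "roi_ts_from_tsv",
    "load_config",
    "dump_config",
    "write_run_log",
]


# ---------------------------------------------------------------------------
# NIfTI
# ---------------------------------------------------------------------------


def load_voxel_timeseries(image_path: str | Path, mask_path: str | Path,
                          tr_seconds: float | None = None) -> VoxelTimeSeries:
    """Extract in-mask voxel time series from a 4-D NIfTI image."""
    img = nib.load(str(image_path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{image_path}: expected a 4-D image, got {data.ndim}-D")
    mask_img = nib.load(str(mask_path))
    mask = np.asarray(mask_img.dataobj) > 0
    if mask.shape != data.shape[:3]:
        raise ValueError("mask grid does not match the 4-D image grid")
    coords = np.argwhere(mask)
    if tr_seconds is None:
        zooms = img.header.get_zooms()
        tr_seconds = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
    return VoxelTimeSeries(data[mask], coords, affine=img.affine, tr_seconds=tr_seconds)


def save_voxel_timeseries(vts: VoxelTimeSeries, grid_shape, image_path: str | Path,
                          mask_path: str | Path | None = None) -> None:
    """Write a VoxelTimeSeries back to a 4-D NIfTI (plus its mask)."""
    vol = np.zeros(tuple(grid_shape) + (vts.n_timepoints,), dtype=np.float32)
    i, j, k = vts.voxel_coords.T
    vol[i, j, k, :] = vts.data
    img = nib.Nifti1Image(vol, vts.affine)
    img.header.set_zooms(tuple(np.abs(np.diag(vts.affine)[:3])) + (vts.tr_seconds,))
    nib.save(img, str(image_path))
    if mask_path is not None:
        mask = np.zeros(tuple(grid_shape), dtype=np.uint8)
        mask[i, j, k] = 1
        nib.save(nib.Nifti1Image(mask, vts.affine), str(mask_path))


def load_roi_lookup(path: str | Path) -> pd.DataFrame:
    """ROI lookup TSV with columns label_value, roi_name, network."""
    df = pd.read_csv(path, sep="\t")
    required = {"label_value", "roi_name", "network"}
    if not required.issubset(df.columns):
        raise ValueError(f"ROI lookup must have columns {sorted(required)}")
    return df


def load_atlas(atlas_path: str | Path, lookup_path: str | Path):
    """Load a labeled atlas volume and its lookup table."""
    img = nib.load(str(atlas_path))
    labels = np.asarray(img.dataobj).astype(int)
    lookup = load_roi_lookup(lookup_path)
    return labels, lookup, img.affine


def write_labels_nifti(labels: np.ndarray, coords: np.ndarray, grid_shape,
                       affine: np.ndarray, path: str | Path) -> None:
    """Write 0-based in-mask labels as a 1..C volume (0 = background)."""
    vol = np.zeros(tuple(grid_shape), dtype=np.int16)
    i, j, k = np.asarray(coords, int).T
    vol[i, j, k] = np.asarray(labels, int) + 1
    nib.save(nib.Nifti1Image(vol, affine), str(path))


def read_labels_nifti(path: str | Path, coords: np.ndarray) -> np.ndarray:
    """Read a 1..C label volume back to a 0-based in-mask label vector."""
    vol = np.asarray(nib.load(str(path)).dataobj).astype(int)
    i, j, k = np.asarray(coords, int).T
    vals = vol[i, j, k]
    if np.any(vals < 1):
        raise ValueError("label volume has background voxels at mask coordinates")
    return vals - 1


def write_prob_nifti(prob: np.ndarray, coords: np.ndarray, grid_shape,
                     affine: np.ndarray, path: str | Path) -> None:
    """Write an n × C probability matrix as a 4-D volume (4th axis = cluster)."""
    C = prob.shape[1]
    vol = np.zeros(tuple(grid_shape) + (C,), dtype=np.float32)
    i, j, k = np.asarray(coords, int).T
    vol[i, j, k, :] = prob
    nib.save(nib.Nifti1Image(vol, affine), str(path))


def write_scalar_nifti(values: np.ndarray, coords: np.ndarray, grid_shape,
                       affine: np.ndarray, path: str | Path) -> None:
    vol = np.zeros(tuple(grid_shape), dtype=np.float32)
    i, j, k = np.asarray(coords, int).T
    vol[i, j, k] = values
    nib.save(nib.Nifti1Image(vol, affine), str(path))


# ---------------------------------------------------------------------------
# TSV
# ---------------------------------------------------------------------------


def connectivity_to_tsv(conn: ConnectivityMatrix, path: str | Path,
                        roi_names: list[str] | None = None) -> None:
    n, R = conn.z.shape
    cols = roi_names or [f"roi{r:03d}" for r in range(R)]
    df = pd.DataFrame(conn.z, columns=cols)
    if conn.voxel_coords is not None:
        for ax, name in enumerate(("i", "j", "k")):
            df.insert(ax, name, conn.voxel_coords[:, ax])
    df.to_csv(path, sep="\t", index=False)


def connectivity_from_tsv(path: str | Path) -> ConnectivityMatrix:
    df = pd.read_csv(path, sep="\t")
    coords = None
    if {"i", "j", "k"}.issubset(df.columns):
        coords = df[["i", "j", "k"]].to_numpy(int)
        df = df.drop(columns=["i", "j", "k"])
    return ConnectivityMatrix(df.to_numpy(float), voxel_coords=coords)


def roi_ts_to_tsv(rts: ROITimeSeries, path: str | Path) -> None:
    names = rts.roi_names or [f"roi{i:03d}" for i in range(rts.n_rois)]
    nets = rts.network_of_roi or [""] * rts.n_rois
    df = pd.DataFrame(rts.data)
    df.insert(0, "roi_name", names)
    df.insert(1, "network", nets)
    df.to_csv(path, sep="\t", index=False)


def roi_ts_from_tsv(path: str | Path) -> ROITimeSeries:
    df = pd.read_csv(path, sep="\t")
    names = list(df.pop("roi_name").astype(str))
    nets = list(df.pop("network").astype(str))
    return ROITimeSeries(df.to_numpy(float), names, nets if any(nets) else None)


# ---------------------------------------------------------------------------
# config / logging
# ---------------------------------------------------------------------------


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    return cfg


def dump_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def write_run_log(out_dir: str | Path, command: str, resolved_config: dict, seed: int | None) -> None:
    """Record the resolved configuration, seed and versions for a run."""
    import decparc

    log = {
        "command": command,
        "seed": seed,
        "config": resolved_config,
        "versions": {
            "decparc": decparc.__version__,
            "numpy": np.__version__,
            "python": platform.python_version(),
        },
    }
    Path(out_dir).mkdir(parents=True, exist_ok=True)
    with open(Path(out_dir) / "run_log.yaml", "w") as fh:
        yaml.safe_dump(log, fh, sort_keys=True)
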