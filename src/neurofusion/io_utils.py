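"""Readers and writers for the standard formats touched by the pipeline:
NIfTI volumes + integer ROI masks, PNG images, and HDF5 feature/latent
sidecars.

Volumes are used in stored index order; no reorientation is applied.  Voxels
are serialized ascending by (z, y, x); a voxel's coordinates are its (x, y, z)
indices into the volume.  Background voxels carry mask label 0 and are
excluded; stored labels ``1..n_roi`` map to internal labels ``0..n_roi-1``.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
from PIL import Image

from .synthetic_data import SyntheticPairSet
from .voxel_embedding import VoxelGrid

__all__ = [
    "read_fmri",
    "write_fmri",
    "write_pair_set",
    "read_pair_images",
    "content_hash",
]


class InputError(ValueError):
    """Malformed input volume or mask."""


def read_fmri(volume_path, roi_mask_path) -> VoxelGrid:
    """Load a 4D signal volume plus 3D integer ROI mask into a VoxelGrid."""
    vol = nib.load(str(volume_path))
    mask_img = nib.load(str(roi_mask_path))
    data = np.asarray(vol.dataobj)
    mask = np.asarray(mask_img.dataobj)
    if data.ndim == 3:
        data = data[..., None]
    if data.ndim != 4:
        raise InputError(f"signal volume must be 4D, got shape {data.shape}")
    if mask.ndim != 3:
        raise InputError(f"ROI mask must be 3D, got shape {mask.shape}")
    if data.shape[:3] != mask.shape:
        raise InputError(
            f"spatial shape mismatch: volume {data.shape[:3]} vs mask {mask.shape}")
    if not np.allclose(mask, np.round(mask)):
        raise InputError("ROI mask must be integer-valued")
    mask = mask.astype(np.int64)
    xs, ys, zs = np.nonzero(mask > 0)
    if xs.size == 0:
        raise InputError("no ROI voxels: mask has no labels > 0")
    # serialize ascending (z, y, x)
    order = np.lexsort((xs, ys, zs))
    xs, ys, zs = xs[order], ys[order], zs[order]
    coords = np.stack([xs, ys, zs], axis=1)
    labels = mask[xs, ys, zs] - 1
    signal = data[xs, ys, zs, :].T.astype(np.float64)   # (T, N_vox)
    return VoxelGrid(coords=coords, signal=signal, roi_labels=labels)


def write_fmri(grid: VoxelGrid, volume_path, roi_mask_path) -> None:
    """Write a VoxelGrid as a 4D NIfTI volume + 3D integer ROI mask.

    Round trip through :func:`read_fmri` is bit-exact (float64 volume).
    """
    shape = tuple(int(grid.coords[:, a].max()) + 1 for a in range(3))
    vol = np.zeros(shape + (grid.n_timesteps,), dtype=np.float64)
    mask = np.zeros(shape, dtype=np.int16)
    xs, ys, zs = grid.coords.T
    vol[xs, ys, zs, :] = grid.signal.T
    mask[xs, ys, zs] = grid.roi_labels + 1
    affine = np.eye(4)
    nib.save(nib.Nifti1Image(vol, affine), str(volume_path))
    nib.save(nib.Nifti1Image(mask, affine), str(roi_mask_path))


def write_pair_set(pairs: SyntheticPairSet, out_dir) -> dict:
    """Write a synthetic pair set to disk; returns the manifest.

    Layout: ``signal.nii.gz`` + ``roi_mask.nii.gz`` (grid and responses),
    ``images/sample_{i:05d}.png``, ``latents.h5`` (latents, loadings,
    responses), ``manifest.json``.
    """
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    grid = VoxelGrid(coords=pairs.grid.coords, signal=pairs.responses,
                     roi_labels=pairs.grid.roi_labels)
    write_fmri(grid, out / "signal.nii.gz", out / "roi_mask.nii.gz")
    for i, img in enumerate(pairs.images):
        arr = np.clip(np.round(img * 255), 0, 255).astype(np.uint8)
        Image.fromarray(arr).save(out / "images" / f"sample_{i:05d}.png")
    with h5py.File(out / "latents.h5", "w") as fh:
        fh.create_dataset("latents", data=pairs.latents)
        fh.create_dataset("responses", data=pairs.responses)
        if pairs.voxel_loadings is not None:
            fh.create_dataset("voxel_loadings", data=pairs.voxel_loadings)
    manifest = {
        "n_samples": int(pairs.n_samples),
        "n_vox": int(pairs.grid.n_vox),
        "n_roi": int(pairs.grid.n_roi),
        "img_size": int(pairs.images.shape[1]),
        "config": vars(pairs.config),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def read_pair_images(data_dir, n_samples: int, img_size: int) -> np.ndarray:
    """Load PNG samples back into a (n, img_size, img_size, 3) float array."""
    out = np.empty((n_samples, img_size, img_size, 3))
    for i in range(n_samples):
        path = Path(data_dir) / "images" / f"sample_{i:05d}.png"
        img = Image.open(path).convert("RGB")
        if img.size != (img_size, img_size):
            img = img.resize((img_size, img_size), Image.BILINEAR)
        out[i] = np.asarray(img, dtype=np.float64) / 255.0
    return out


def load_pair_set(data_dir) -> SyntheticPairSet:
    """Read back a directory written by :func:`write_pair_set`."""
    from .synthetic_data import SyntheticConfig
    out = Path(data_dir)
    manifest = json.loads((out / "manifest.json").read_text())
    grid = read_fmri(out / "signal.nii.gz", out / "roi_mask.nii.gz")
    with h5py.File(out / "latents.h5", "r") as fh:
        latents = fh["latents"][:]
        responses = fh["responses"][:]
        loadings = fh["voxel_loadings"][:] if "voxel_loadings" in fh else None
    images = read_pair_images(out, manifest["n_samples"], manifest["img_size"])
    cfg = SyntheticConfig(**manifest["config"])
    return SyntheticPairSet(images=images, grid=grid, responses=responses,
                            latents=latents, config=cfg,
                            voxel_loadings=loadings)


def write_features_h5(path, features: dict[str, np.ndarray]) -> None:
    with h5py.File(path, "w") as fh:
        for name, arr in features.items():
            fh.create_dataset(name, data=np.asarray(arr))


def content_hash(*arrays) -> str:
    """Deterministic SHA-256 over the byte content of the given arrays."""
    digest = hashlib.sha256()
    for arr in arrays:
        arr = np.ascontiguousarray(arr)
        digest.update(str(arr.dtype).encode())
        digest.update(str(arr.shape).encode())
        digest.update(arr.tobytes())
    return digest.hexdigest()
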