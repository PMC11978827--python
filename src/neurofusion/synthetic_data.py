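"""Synthetic paired (image, voxel-response) data with a known latent coupling.

The generator stands in for a natural-scenes fMRI corpus so the whole
pipeline is testable offline.  One shared voxel grid partitions ``n_vox``
lattice voxels into ``n_roi`` spatially contiguous ROIs.  Each sample draws
one latent code per ROI; the image is rendered procedurally from the codes —
the image is divided into one sector per ROI and each sector shows a colored
disk whose color and radius are functions of that ROI's code (mimicking
category-selective regions) — while each voxel's response is its ROI's code
projected through a fixed per-grid loading, scaled by ``alignment_strength``,
plus Gaussian noise.  Ground-truth latents are returned so recovery tests can
measure how much of the coupling a model finds.

Everything is driven by ``numpy.random.default_rng(seed)``: equal seeds give
bit-identical datasets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .voxel_embedding import VoxelGrid, serialization_order

__all__ = [
    "SyntheticConfig",
    "SyntheticPairSet",
    "generate_pairs",
    "make_voxel_grid",
    "roi_image_sectors",
]


class ConfigurationError(ValueError):
    """Invalid generator configuration; the message names the field."""


@dataclass
class SyntheticConfig:
    n_samples: int = 64
    n_vox: int = 60
    n_roi: int = 6
    img_size: int = 224
    d_latent: int = 4
    alignment_strength: float = 0.9
    noise_sd: float = 0.1
    seed: int = 0
    # temporal emulation: repeat each response T times with AR(1) noise
    n_timesteps: int = 1
    ar_coef: float = 0.5

    def validate(self) -> None:
        if self.n_samples < 1:
            raise ConfigurationError(f"n_samples must be >= 1, got {self.n_samples}")
        if self.n_roi < 1:
            raise ConfigurationError(f"n_roi must be >= 1, got {self.n_roi}")
        if self.n_vox < self.n_roi:
            raise ConfigurationError(
                f"n_vox ({self.n_vox}) must be >= n_roi ({self.n_roi}) so "
                "every ROI receives at least one voxel")
        if self.img_size < 8:
            raise ConfigurationError(f"img_size must be >= 8, got {self.img_size}")
        if self.d_latent < 1:
            raise ConfigurationError(f"d_latent must be >= 1, got {self.d_latent}")
        if not 0.0 <= self.alignment_strength <= 1.0:
            raise ConfigurationError(
                f"alignment_strength must be in [0, 1], got {self.alignment_strength}")
        if self.noise_sd < 0:
            raise ConfigurationError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.n_timesteps < 1:
            raise ConfigurationError(
                f"n_timesteps must be >= 1, got {self.n_timesteps}")


@dataclass
class SyntheticPairSet:
    """Paired raster images and voxel responses with known latents."""

    images: np.ndarray      # (n_samples, img_size, img_size, 3) in [0, 1]
    grid: VoxelGrid         # shared across samples
    responses: np.ndarray   # (n_samples, n_vox)
    latents: np.ndarray     # (n_samples, n_roi, d_latent)
    config: SyntheticConfig
    voxel_loadings: np.ndarray = field(repr=False, default=None)  # (n_vox, d_latent)
    timeseries: np.ndarray | None = None  # (n_samples, T, n_vox) when T > 1

    @property
    def n_samples(self) -> int:
        return self.images.shape[0]

    def subset(self, idx) -> "SyntheticPairSet":
        idx = np.asarray(idx)
        return SyntheticPairSet(
            images=self.images[idx], grid=self.grid,
            responses=self.responses[idx], latents=self.latents[idx],
            config=self.config, voxel_loadings=self.voxel_loadings,
            timeseries=None if self.timeseries is None else self.timeseries[idx])


def _lattice_extent(n_vox: int) -> int:
    # room for ~4x the voxel count so blobs have space to separate
    return max(4, math.ceil((4 * n_vox) ** (1 / 3)))


def make_voxel_grid(n_vox: int, n_roi: int, seed: int) -> VoxelGrid:
    """Unique lattice voxels split into spatially contiguous, balanced ROIs.

    ROI centers are sampled well-separated on the lattice; lattice points are
    then assigned greedily in order of distance to their nearest center, each
    ROI holding a fixed quota, which yields compact blobs of near-equal size.
    """
    if n_roi < 1:
        raise ConfigurationError(f"n_roi must be >= 1, got {n_roi}")
    if n_vox < n_roi:
        raise ConfigurationError(
            f"n_vox ({n_vox}) must be >= n_roi ({n_roi})")
    rng = np.random.default_rng(seed)
    extent = _lattice_extent(n_vox)
    points = np.stack(np.meshgrid(*([np.arange(extent)] * 3),
                                  indexing="ij"), axis=-1).reshape(-1, 3)
    # sample well-separated centers, relaxing the spacing if needed
    min_sep = extent / 2.0
    while True:
        centers = points[rng.choice(len(points), size=n_roi, replace=False)]
        if n_roi == 1:
            break
        dists = np.linalg.norm(centers[:, None] - centers[None, :], axis=-1)
        np.fill_diagonal(dists, np.inf)
        if dists.min() >= min_sep:
            break
        min_sep *= 0.95
    # balanced quotas
    quotas = np.full(n_roi, n_vox // n_roi)
    quotas[: n_vox % n_roi] += 1
    d2 = ((points[:, None, :] - centers[None, :, :]) ** 2).sum(axis=-1)
    nearest = d2.min(axis=1)
    chosen_coords = []
    chosen_labels = []
    remaining = quotas.copy()
    for p in np.argsort(nearest, kind="stable"):
        order = np.argsort(d2[p], kind="stable")
        for r in order:
            if remaining[r] > 0:
                remaining[r] -= 1
                chosen_coords.append(points[p])
                chosen_labels.append(r)
                break
        if not remaining.any():
            break
    coords = np.array(chosen_coords)
    labels = np.array(chosen_labels)
    order = serialization_order(coords)
    coords, labels = coords[order], labels[order]
    # coords are stored (x, y, z); meshgrid ij gives axis order directly
    return VoxelGrid(coords=coords, signal=np.zeros((1, n_vox)),
                     roi_labels=labels)


def roi_image_sectors(img_size: int, n_roi: int) -> list[tuple[int, int, int, int]]:
    """Fixed half-open pixel boxes (r0, r1, c0, c1), one per ROI.

    Sectors tile the image in a near-square grid (2 x 3 for six ROIs).
    """
    n_cols = math.ceil(math.sqrt(n_roi))
    n_rows = math.ceil(n_roi / n_cols)
    boxes = []
    for k in range(n_roi):
        i, j = divmod(k, n_cols)
        r0 = i * img_size // n_rows
        r1 = (i + 1) * img_size // n_rows
        c0 = j * img_size // n_cols
        c1 = (j + 1) * img_size // n_cols
        boxes.append((r0, r1, c0, c1))
    return boxes


def _render_images(latents: np.ndarray, img_size: int,
                   color_maps: np.ndarray, radius_maps: np.ndarray
                   ) -> np.ndarray:
    """Vectorized glyph renderer: one colored disk per ROI sector.

    ``color_maps`` is (n_roi, 3, d_latent); ``radius_maps`` is (n_roi, d_latent).
    Disk color = 0.5 + 0.45 tanh(C_k z), radius fraction = 0.55 + 0.3 tanh(a_k z).
    """
    n_samples, n_roi, _ = latents.shape
    images = np.full((n_samples, img_size, img_size, 3), 0.5)
    sectors = roi_image_sectors(img_size, n_roi)
    for k, (r0, r1, c0, c1) in enumerate(sectors):
        z = latents[:, k, :]                               # (n, d_latent)
        color = 0.5 + 0.45 * np.tanh(z @ color_maps[k].T)  # (n, 3)
        frac = 0.55 + 0.3 * np.tanh(z @ radius_maps[k])    # (n,)
        h, w = r1 - r0, c1 - c0
        radius = frac * (min(h, w) / 2.0 - 1.0)
        rr = np.arange(h) - (h - 1) / 2.0
        cc = np.arange(w) - (w - 1) / 2.0
        dist2 = rr[:, None] ** 2 + cc[None, :] ** 2
        inside = dist2[None] <= (radius[:, None, None] ** 2)  # (n, h, w)
        sector = images[:, r0:r1, c0:c1, :]
        images[:, r0:r1, c0:c1, :] = np.where(
            inside[..., None], color[:, None, None, :], sector)
    return np.clip(images, 0.0, 1.0)


def generate_pairs(cfg: SyntheticConfig) -> SyntheticPairSet:
    """Generate a :class:`SyntheticPairSet` per the configured coupling."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    grid = make_voxel_grid(cfg.n_vox, cfg.n_roi, cfg.seed)

    # fixed per-grid structures
    loadings = rng.normal(size=(cfg.n_vox, cfg.d_latent))
    loadings /= np.linalg.norm(loadings, axis=1, keepdims=True)
    color_maps = rng.normal(size=(cfg.n_roi, 3, cfg.d_latent))
    radius_maps = rng.normal(size=(cfg.n_roi, cfg.d_latent))

    latents = rng.normal(size=(cfg.n_samples, cfg.n_roi, cfg.d_latent))
    noise = rng.normal(size=(cfg.n_samples, cfg.n_vox))

    roi_of_voxel = grid.roi_labels
    # response[n, v] = a * loadings[v] . latents[n, roi(v)] + noise_sd * eps
    signal_part = np.einsum("vd,nvd->nv", loadings,
                            latents[:, roi_of_voxel, :])
    responses = cfg.alignment_strength * signal_part + cfg.noise_sd * noise

    images = _render_images(latents, cfg.img_size, color_maps, radius_maps)

    timeseries = None
    if cfg.n_timesteps > 1:
        eps = rng.normal(size=(cfg.n_samples, cfg.n_timesteps, cfg.n_vox))
        ar = np.zeros_like(eps)
        ar[:, 0] = eps[:, 0]
        for t in range(1, cfg.n_timesteps):
            ar[:, t] = cfg.ar_coef * ar[:, t - 1] + eps[:, t]
        timeseries = responses[:, None, :] + cfg.noise_sd * ar

    grid = VoxelGrid(coords=grid.coords, signal=responses.copy(),
                     roi_labels=grid.roi_labels)
    return SyntheticPairSet(images=images, grid=grid, responses=responses,
                            latents=latents, config=cfg,
                            voxel_loadings=loadings, timeseries=timeseries)
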