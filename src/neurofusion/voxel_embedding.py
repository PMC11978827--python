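"""Voxel-grid representation and the coordinate-aware signal tokenizer.

A brain volume is serialized to a 1D voxel sequence in a fixed order
(ascending ``(z, y, x)`` lexicographic on coordinates).  Each voxel's 3D
coordinate is lifted to a ``d``-dimensional feature by an affine map; the raw
amplitude sequence at one timestep is tokenized by a strided 1D convolution,
and each token is fused (elementwise addition) with the mean coordinate
embedding over its receptive field.  The same index arithmetic backs both the
plain-numpy reference operations here and the trainable model in
:mod:`neurofusion.model`.

Conventions (shared with the I/O layer): 0-based voxel indices, half-open
receptive-field ranges ``[start, stop)``, ``(z, y, x)`` serialization order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "VoxelGrid",
    "VoxelEmbedding",
    "TokenizedSignal",
    "Conv1dParams",
    "CoordEmbedParams",
    "embed_coords",
    "concat_voxels",
    "tokenize_and_fuse",
    "roi_pool",
    "conv_token_layout",
    "token_roi_weights",
    "normalize_coords",
    "serialization_order",
]

DEFAULT_KERNEL = 32
DEFAULT_STRIDE = 16


def serialization_order(coords: np.ndarray) -> np.ndarray:
    """Indices sorting coordinate triples ascending by (z, y, x)."""
    coords = np.asarray(coords)
    return np.lexsort((coords[:, 0], coords[:, 1], coords[:, 2]))


@dataclass
class VoxelGrid:
    """Voxel coordinates, per-timestep signals, and ROI labels for one brain.

    ``coords`` is ``(N_vox, 3)`` integer ``(x, y, z)`` triples in grid units,
    ``signal`` is ``(T, N_vox)``, ``roi_labels`` is ``(N_vox,)`` with values in
    ``[0, n_roi)``.  Rows follow the fixed (z, y, x) serialization order.
    """

    coords: np.ndarray
    signal: np.ndarray
    roi_labels: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.int64)
        self.signal = np.asarray(self.signal, dtype=np.float64)
        self.roi_labels = np.asarray(self.roi_labels, dtype=np.int64)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (N_vox, 3)")
        n = self.coords.shape[0]
        if self.signal.ndim != 2 or self.signal.shape[1] != n:
            raise ValueError(
                f"signal must be (T, {n}), got {self.signal.shape}")
        if self.roi_labels.shape != (n,):
            raise ValueError(f"roi_labels must have length {n}")
        uniq = np.unique(self.coords, axis=0)
        if uniq.shape[0] != n:
            raise ValueError("duplicate voxel coordinates")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal contains non-finite values")

    @property
    def n_vox(self) -> int:
        return self.coords.shape[0]

    @property
    def n_roi(self) -> int:
        return int(self.roi_labels.max()) + 1

    @property
    def n_timesteps(self) -> int:
        return self.signal.shape[0]

    def roi_sizes(self) -> np.ndarray:
        return np.bincount(self.roi_labels, minlength=self.n_roi)


@dataclass
class VoxelEmbedding:
    """Per-voxel features and their ordered concatenation."""

    per_voxel: np.ndarray       # (N_vox, d)
    concatenated: np.ndarray    # (N_vox * d,)


@dataclass
class TokenizedSignal:
    """Token features for one timestep plus receptive-field bookkeeping.

    ``receptive_map[j] = (start, stop)`` is the half-open range of true
    (unpadded) voxel indices covered by token ``j``.
    """

    tokens: np.ndarray                        # (N_tok, d)
    receptive_map: list[tuple[int, int]] = field(default_factory=list)

    @property
    def n_tokens(self) -> int:
        return self.tokens.shape[0]


@dataclass
class CoordEmbedParams:
    """Affine map 3 -> d applied to (optionally normalized) coordinates."""

    weight: np.ndarray                        # (3, d)
    bias: np.ndarray | None = None            # (d,)
    normalize: bool = True

    def __post_init__(self) -> None:
        self.weight = np.asarray(self.weight, dtype=np.float64)
        if self.weight.ndim != 2 or self.weight.shape[0] != 3:
            raise ValueError(f"weight must be (3, d), got {self.weight.shape}")
        if self.bias is not None:
            self.bias = np.asarray(self.bias, dtype=np.float64)
            if self.bias.shape != (self.weight.shape[1],):
                raise ValueError("bias shape does not match weight columns")

    @property
    def d(self) -> int:
        return self.weight.shape[1]


@dataclass
class Conv1dParams:
    """Single-input-channel strided 1D convolution producing d channels."""

    weight: np.ndarray                        # (kernel, d)
    bias: np.ndarray | None = None            # (d,)
    stride: int = DEFAULT_STRIDE

    def __post_init__(self) -> None:
        self.weight = np.asarray(self.weight, dtype=np.float64)
        if self.weight.ndim != 2:
            raise ValueError("conv weight must be (kernel, d)")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        if self.bias is not None:
            self.bias = np.asarray(self.bias, dtype=np.float64)
            if self.bias.shape != (self.weight.shape[1],):
                raise ValueError("conv bias shape mismatch")

    @property
    def kernel(self) -> int:
        return self.weight.shape[0]

    @property
    def d(self) -> int:
        return self.weight.shape[1]


def normalize_coords(coords: np.ndarray) -> np.ndarray:
    """Scale each coordinate axis to [0, 1]; constant axes map to 0."""
    coords = np.asarray(coords, dtype=np.float64)
    lo = coords.min(axis=0)
    span = coords.max(axis=0) - lo
    span = np.where(span == 0, 1.0, span)
    return (coords - lo) / span


def embed_coords(coords: np.ndarray, params: CoordEmbedParams) -> np.ndarray:
    """Affine image of each voxel's coordinate triple; (N_vox, d)."""
    coords = np.asarray(coords, dtype=np.float64)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError(f"coords must be (N_vox, 3), got {coords.shape}")
    x = normalize_coords(coords) if params.normalize else coords
    out = x @ params.weight
    if params.bias is not None:
        out = out + params.bias
    return out


def concat_voxels(per_voxel: np.ndarray) -> np.ndarray:
    """Ordered concatenation of per-voxel features into one long vector."""
    per_voxel = np.asarray(per_voxel, dtype=np.float64)
    if per_voxel.ndim != 2:
        raise ValueError("per_voxel must be a (N_vox, d) matrix")
    if per_voxel.shape[0] == 0:
        raise ValueError("cannot concatenate an empty feature list")
    return per_voxel.reshape(-1)


def conv_token_layout(n_vox: int, kernel: int, stride: int
                      ) -> list[tuple[int, int]]:
    """Half-open true receptive ranges for each token of a strided conv.

    Emits ``floor((n_vox - kernel) / stride) + 1`` full windows; if they do
    not reach index ``n_vox - 1`` (or if ``n_vox < kernel``), one extra
    zero-padded remainder window is appended so no voxel is discarded.
    """
    if n_vox < 1:
        raise ValueError("empty voxel sequence")
    if kernel < 1 or stride < 1:
        raise ValueError("kernel and stride must be positive")
    ranges: list[tuple[int, int]] = []
    if n_vox >= kernel:
        n_full = (n_vox - kernel) // stride + 1
        for j in range(n_full):
            ranges.append((j * stride, j * stride + kernel))
        covered = (n_full - 1) * stride + kernel
        if covered < n_vox:
            ranges.append((n_full * stride, n_vox))
    else:
        ranges.append((0, n_vox))
    return ranges


def tokenize_and_fuse(grid: VoxelGrid, timestep: int, conv: Conv1dParams,
                      coord_params: CoordEmbedParams) -> TokenizedSignal:
    """Strided-conv tokens of the amplitude sequence fused with pooled
    coordinate embeddings (elementwise residual addition).

    The raw signal at ``timestep`` is right-padded with zeros to complete the
    final window; each token's coordinate embedding is the mean of
    ``embed_coords`` over the true voxels in its receptive field.
    """
    if conv.d != coord_params.d:
        raise ValueError(
            f"conv output channels ({conv.d}) != coordinate embedding "
            f"dimension ({coord_params.d})")
    x = grid.signal[timestep]
    ranges = conv_token_layout(grid.n_vox, conv.kernel, conv.stride)
    emb = embed_coords(grid.coords, coord_params)
    tokens = np.empty((len(ranges), conv.d))
    padded = np.zeros(max(grid.n_vox, ranges[-1][0] + conv.kernel))
    padded[:grid.n_vox] = x
    for j, (start, stop) in enumerate(ranges):
        window = padded[start:start + conv.kernel]
        conv_out = window @ conv.weight
        if conv.bias is not None:
            conv_out = conv_out + conv.bias
        tokens[j] = conv_out + emb[start:stop].mean(axis=0)
    return TokenizedSignal(tokens=tokens, receptive_map=ranges)


def token_roi_weights(receptive_map: list[tuple[int, int]],
                      roi_labels: np.ndarray, n_roi: int | None = None
                      ) -> np.ndarray:
    """Row-normalized (N_roi, N_tok) pooling weights.

    Raw weight of token j for ROI r is the fraction of token j's true
    receptive field whose voxels carry label r; rows are normalized to sum
    to 1 so pooling is a weighted mean.
    """
    roi_labels = np.asarray(roi_labels)
    if n_roi is None:
        n_roi = int(roi_labels.max()) + 1
    n_tok = len(receptive_map)
    raw = np.zeros((n_roi, n_tok))
    for j, (start, stop) in enumerate(receptive_map):
        labels = roi_labels[start:stop]
        counts = np.bincount(labels, minlength=n_roi)
        raw[:, j] = counts / (stop - start)
    row_sums = raw.sum(axis=1)
    empty = np.nonzero(row_sums == 0)[0]
    if empty.size:
        raise ValueError(
            f"ROI {int(empty[0])} overlaps no token receptive field")
    return raw / row_sums[:, None]


def roi_pool(tokens: TokenizedSignal, grid: VoxelGrid) -> np.ndarray:
    """Receptive-field-weighted mean of tokens per ROI; (N_roi, d)."""
    weights = token_roi_weights(tokens.receptive_map, grid.roi_labels,
                                grid.n_roi)
    return weights @ tokens.tokens
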