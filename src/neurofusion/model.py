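"""Joint cross-modal model: signal branch, vision branch, fusion, and the
voxel-response prediction head.

The signal branch reproduces, in differentiable form, the reference pipeline
of :mod:`neurofusion.voxel_embedding` and :mod:`neurofusion.timeformer`:
affine coordinate embedding, strided 1D conv tokenization with residual
fusion, then the sliced-window transformer.  The vision branch is
:class:`~neurofusion.vision_encoder.VisionEncoder`.  Pooled fused features
feed a linear head predicting per-voxel responses (used for the encoding
metric); the alignment losses operate on the pre-fusion features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor
from .fusion_losses import FusionBlock
from .nn import Linear, Module
from .timeformer import Timeformer, TimeformerConfig
from .vision_encoder import BackboneSpec, VisionEncoder
from .voxel_embedding import (DEFAULT_KERNEL, DEFAULT_STRIDE, VoxelGrid,
                              conv_token_layout, normalize_coords,
                              token_roi_weights)

__all__ = ["ModelConfig", "CrossModalModel", "ModelOutput"]


@dataclass
class ModelConfig:
    d: int = 32
    conv_kernel: int = DEFAULT_KERNEL
    conv_stride: int = DEFAULT_STRIDE
    timeformer: TimeformerConfig = field(default_factory=TimeformerConfig)
    backbone: BackboneSpec = field(default_factory=BackboneSpec)
    img_size: int = 224

    def __post_init__(self) -> None:
        # one shared feature dimension across both modalities
        self.timeformer.d = self.d
        self.backbone.d = self.d


class SignalBranch(Module):
    """Coordinate embedding + conv tokenizer + timeformer, end to end."""

    def __init__(self, cfg: ModelConfig, grid: VoxelGrid, n_roi: int,
                 rng: np.random.Generator):
        d = cfg.d
        kernel, stride = cfg.conv_kernel, cfg.conv_stride
        self.coord_weight = Tensor(
            rng.uniform(-1, 1, size=(3, d)) / np.sqrt(3), requires_grad=True)
        self.coord_bias = Tensor(np.zeros(d), requires_grad=True)
        self.conv_weight = Tensor(
            rng.normal(0, np.sqrt(2.0 / kernel), size=(kernel, d)),
            requires_grad=True)
        self.conv_bias = Tensor(np.zeros(d), requires_grad=True)
        self.kernel = kernel
        self.stride = stride
        self.coords_norm = normalize_coords(grid.coords)
        layout = conv_token_layout(grid.n_vox, kernel, stride)
        self.receptive_map = layout
        self.n_vox = grid.n_vox
        # gather indices into the zero-padded amplitude sequence
        pad_len = max(grid.n_vox, layout[-1][0] + kernel)
        self.pad_len = pad_len
        self.window_idx = np.stack(
            [np.arange(start, start + kernel) for start, _ in layout])
        # (N_tok, N_vox) mean-pooling matrix over true receptive fields
        pool = np.zeros((len(layout), grid.n_vox))
        for j, (start, stop) in enumerate(layout):
            pool[j, start:stop] = 1.0 / (stop - start)
        self.coord_pool = pool
        self.roi_weights = token_roi_weights(layout, grid.roi_labels, n_roi)
        self.timeformer = Timeformer(cfg.timeformer, n_roi, rng)

    def tokenize(self, signal: Tensor) -> Tensor:
        """(batch, N_vox) amplitudes -> (batch, N_tok, d) fused tokens."""
        b = signal.shape[0]
        if self.pad_len > self.n_vox:
            from .autodiff import concat
            pad = Tensor(np.zeros((b, self.pad_len - self.n_vox)))
            signal = concat([signal, pad], axis=1)
        windows = signal[:, self.window_idx.reshape(-1)]
        windows = windows.reshape(b, len(self.receptive_map), self.kernel)
        conv = windows @ self.conv_weight + self.conv_bias
        emb = Tensor(self.coords_norm) @ self.coord_weight + self.coord_bias
        pooled_emb = Tensor(self.coord_pool) @ emb       # (N_tok, d)
        return conv + pooled_emb

    def __call__(self, signal: Tensor) -> tuple[Tensor, Tensor]:
        tokens = self.tokenize(signal)
        return self.timeformer(tokens, self.roi_weights)


@dataclass
class ModelOutput:
    vis_global: Tensor
    sig_global: Tensor
    vis_local: Tensor
    sig_roi: Tensor
    fused_pooled: Tensor
    pred_responses: Tensor


class CrossModalModel(Module):
    """Both branches, the fusion block, and the voxel-prediction head."""

    def __init__(self, cfg: ModelConfig, grid: VoxelGrid, n_roi: int,
                 seed: int = 0):
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        self.n_roi = n_roi
        self.signal_branch = SignalBranch(cfg, grid, n_roi, rng)
        self.vision = VisionEncoder(
            BackboneSpec(name=cfg.backbone.name, d=cfg.d,
                         seed=int(rng.integers(2 ** 31))),
            n_roi=n_roi, img_size=cfg.img_size)
        self.fusion = FusionBlock(cfg.d, n_roi, rng)
        self.encoding_head = Linear(cfg.d, grid.n_vox, rng)

    def __call__(self, images: Tensor, signal: Tensor) -> ModelOutput:
        vis_global, vis_local = self.vision(images)
        sig_global, sig_roi = self.signal_branch(signal)
        _, pooled = self.fusion(vis_global, sig_global, vis_local, sig_roi)
        pred = self.encoding_head(pooled)
        return ModelOutput(vis_global=vis_global, sig_global=sig_global,
                           vis_local=vis_local, sig_roi=sig_roi,
                           fused_pooled=pooled, pred_responses=pred)

    def predict_responses_from_images(self, images: np.ndarray,
                                      signal_placeholder: np.ndarray | None = None
                                      ) -> np.ndarray:
        """Encoding-model prediction: voxel responses for held-out images.

        The fusion block needs signal-side tokens; at prediction time the
        signal branch is fed zeros so predictions depend on the image alone.
        """
        images = np.asarray(images, dtype=np.float64)
        n = images.shape[0]
        if signal_placeholder is None:
            signal_placeholder = np.zeros((n, self.signal_branch.n_vox))
        out = self(Tensor(images), Tensor(signal_placeholder))
        return out.pred_responses.data
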