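"""Sliced-window transformer over the tokenized signal sequence.

Long token sequences are cut into overlapping windows of width ``w`` sliding
with stride ``s``; each window is processed by a standard pre-norm
transformer block with padded positions masked out of attention, and
overlapping window outputs are reassembled into a token sequence by
position-wise averaging.  Stacking ``h`` such layers and mean-pooling the
final sequence yields the global signal feature; ROI features are pooled with
receptive-field weights and projected by a linear head.

Attention cost per layer is ``n_windows * w**2`` query-key pairs — strictly
below the ``L**2`` of full attention once ``L > w``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor
from .nn import Linear, Module, TransformerLayer

__all__ = [
    "TimeformerConfig",
    "WindowSlice",
    "FMRIFeature",
    "Timeformer",
    "slice_windows",
    "window_layout",
    "trans_block",
    "timeformer_forward",
    "attention_pair_count",
]

logger = logging.getLogger(__name__)

PAD_POLICIES = ("pad_last", "drop_last")


@dataclass
class TimeformerConfig:
    """Window width / stride / depth configuration (defaults per the method:
    w=64, s=32, h=2)."""

    w: int = 64
    s: int = 32
    h: int = 2
    d: int = 32
    n_heads: int = 4
    pad_policy: str = "pad_last"
    # optional per-layer (w, s) override; None = constant schedule
    per_layer: list[tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        if not (1 <= self.s <= self.w):
            raise ValueError(f"stride s={self.s} must satisfy 1 <= s <= w={self.w}")
        if self.h < 1:
            raise ValueError("h must be >= 1")
        if self.d % self.n_heads:
            raise ValueError(f"d={self.d} not divisible by n_heads={self.n_heads}")
        if self.pad_policy not in PAD_POLICIES:
            raise ValueError(f"pad_policy must be one of {PAD_POLICIES}")
        if self.per_layer is not None and len(self.per_layer) != self.h:
            raise ValueError("per_layer schedule length must equal h")

    def layer_ws(self) -> list[tuple[int, int]]:
        if self.per_layer is not None:
            return [tuple(p) for p in self.per_layer]
        return [(self.w, self.s)] * self.h


@dataclass
class WindowSlice:
    """One contiguous window of the token sequence, zero-padded to width w."""

    content: np.ndarray       # (w, d)
    start: int
    true_len: int

    @property
    def width(self) -> int:
        return self.content.shape[0]


@dataclass
class FMRIFeature:
    """Global pooled signal feature plus per-ROI features."""

    global_feat: np.ndarray   # (d,) or (batch, d)
    per_roi: np.ndarray       # (N_roi, d) or (batch, N_roi, d)


def window_layout(length: int, w: int, s: int, pad_policy: str = "pad_last"
                  ) -> list[tuple[int, int]]:
    """(start, true_len) for each window over a length-``length`` sequence.

    ``floor((L - w) / s) + 1`` full windows; ``pad_last`` appends one
    right-padded window whenever the full windows leave a tail uncovered
    (including the L < w case).  ``drop_last`` logs how many trailing
    positions go uncovered.
    """
    if length < 1:
        raise ValueError("cannot slice an empty sequence")
    out: list[tuple[int, int]] = []
    if length >= w:
        n_full = (length - w) // s + 1
        for i in range(n_full):
            out.append((i * s, w))
        covered = (n_full - 1) * s + w
    else:
        n_full = 0
        covered = 0
    if covered < length:
        if pad_policy == "pad_last":
            start = n_full * s
            out.append((start, length - start))
        else:
            logger.warning("drop_last leaves %d trailing positions uncovered",
                           length - covered)
            if not out:
                raise ValueError(
                    f"sequence of length {length} shorter than window {w} "
                    "with drop_last: nothing to process")
    return out


def slice_windows(tokens: np.ndarray, cfg: TimeformerConfig
                  ) -> list[WindowSlice]:
    """Cut a (L, d) token sequence into overlapping zero-padded windows."""
    tokens = np.asarray(tokens, dtype=np.float64)
    if tokens.ndim != 2 or tokens.shape[0] == 0:
        raise ValueError("tokens must be a nonempty (L, d) sequence")
    slices = []
    for start, true_len in window_layout(tokens.shape[0], cfg.w, cfg.s,
                                         cfg.pad_policy):
        content = np.zeros((cfg.w, tokens.shape[1]))
        content[:true_len] = tokens[start:start + true_len]
        slices.append(WindowSlice(content=content, start=start,
                                  true_len=true_len))
    return slices


def _mask_bias(w: int, true_len: int) -> np.ndarray:
    """Additive attention bias: -inf-like on padded key positions."""
    bias = np.zeros((w, w))
    bias[:, true_len:] = -1e9
    return bias


def trans_block(sl: WindowSlice, layer: TransformerLayer) -> WindowSlice:
    """Apply a pre-norm transformer block to one window, masking padding."""
    if sl.content.ndim != 2:
        raise ValueError("window content must be (w, d)")
    w = sl.width
    out = layer(Tensor(sl.content), mask_bias=_mask_bias(w, sl.true_len))
    return WindowSlice(content=out.data, start=sl.start, true_len=sl.true_len)


def attention_pair_count(length: int, cfg: TimeformerConfig) -> int:
    """Query-key pair count for one layer: n_windows * w**2."""
    n_windows = len(window_layout(length, cfg.w, cfg.s, cfg.pad_policy))
    return n_windows * cfg.w ** 2


class Timeformer(Module):
    """Stack of h sliced-window transformer layers plus pooling heads."""

    def __init__(self, cfg: TimeformerConfig, n_roi: int,
                 rng: np.random.Generator):
        self.cfg = cfg
        self.n_roi = n_roi
        self.layers = [TransformerLayer(cfg.d, cfg.n_heads, rng)
                       for _ in range(cfg.h)]
        self.roi_head = Linear(cfg.d, cfg.d, rng)

    def encode(self, tokens: Tensor) -> Tensor:
        """(batch, L, d) -> (batch, L, d) after h sliced-window layers."""
        b, length, d = tokens.shape
        for layer, (w, s) in zip(self.layers, self.cfg.layer_ws()):
            layout = window_layout(length, w, s, self.cfg.pad_policy)
            n_win = len(layout)
            # positions beyond every window's true length are masked in all
            # windows and discarded at reassembly; clipping them is exact
            w = min(w, max(true_len for _, true_len in layout))
            # gather windows: (batch, n_win, w, d), zero-padded tails
            idx = np.zeros((n_win, w), dtype=np.int64)
            valid = np.zeros((n_win, w), dtype=bool)
            for i, (start, true_len) in enumerate(layout):
                idx[i, :true_len] = np.arange(start, start + true_len)
                valid[i, :true_len] = True
            gathered = tokens[:, idx.reshape(-1), :]
            gathered = gathered.reshape(b, n_win, w, d) * valid[None, :, :, None]
            bias = np.where(valid, 0.0, -1e9)[None, :, None, None, :]
            out = layer(gathered, mask_bias=bias)
            # position-wise average of overlapping window outputs
            flat_idx = idx[valid]                       # true positions
            counts = np.bincount(flat_idx, minlength=length).astype(float)
            scatter = np.zeros((n_win * w, length))
            scatter[np.nonzero(valid.reshape(-1))[0], flat_idx] = 1.0
            scatter /= counts[None, :]
            tokens = (out.reshape(b, n_win * w, d).swapaxes(-1, -2)
                      @ Tensor(scatter)).swapaxes(-1, -2)
        return tokens

    def __call__(self, tokens: Tensor, roi_weights: np.ndarray) -> tuple[Tensor, Tensor]:
        """Returns (global (b, d), per_roi (b, N_roi, d))."""
        seq = self.encode(tokens)
        global_feat = seq.mean(axis=1)
        pooled = Tensor(roi_weights) @ seq            # (b, N_roi, d)
        return global_feat, self.roi_head(pooled)


def timeformer_forward(tokens: np.ndarray, cfg: TimeformerConfig,
                       model: Timeformer, roi_weights: np.ndarray
                       ) -> FMRIFeature:
    """Single-sequence (L, d) convenience wrapper around :class:`Timeformer`.

    ``roi_weights`` is the (N_roi, L) row-normalized token pooling matrix
    from :func:`neurofusion.voxel_embedding.token_roi_weights`.
    """
    if model.cfg is not cfg and model.cfg != cfg:
        raise ValueError("config does not match the model it was built with")
    tokens = np.asarray(tokens, dtype=np.float64)
    g, r = model(Tensor(tokens[None]), roi_weights)
    return FMRIFeature(global_feat=g.data[0], per_roi=r.data[0])
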