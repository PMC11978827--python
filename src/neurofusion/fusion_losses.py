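"""Cross-modal fusion block and the training objectives.

Two losses drive alignment:

* a symmetric temperature-scaled contrastive loss over global features —
  mean over samples of the cross-entropy of matching each visual feature to
  its paired signal feature among the batch, plus the same in the opposite
  direction;
* an ROI-guided local loss — for every sample and ROI, the cross-entropy of
  matching the image's k-th local feature to the k-th ROI feature against the
  other ROIs of the same sample, summed and divided by the ROI count (the
  printed normalization; ``bfg_batch_norm`` additionally divides by the batch
  size, since the printed form grows linearly with it).

Both are implemented once over autodiff tensors (vectorized, log-sum-exp
stabilized) and exposed as plain-numpy scalar functions; tests check them
against naive loop oracles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat, logsumexp
from .nn import Module, TransformerLayer

__all__ = [
    "LossConfig",
    "FusedRepresentation",
    "FusionBlock",
    "contrastive_loss",
    "contrastive_loss_t",
    "fmri_guided_loss",
    "fmri_guided_loss_t",
    "total_loss",
    "normalize_rows",
    "fuse",
]


@dataclass
class LossConfig:
    """Temperature, loss weights, and normalization toggles."""

    sigma: float = 0.07
    lambda_con: float = 1.0
    lambda_bfg: float = 1.0
    normalize_features: bool = True
    bfg_batch_norm: bool = False

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        if self.lambda_con < 0 or self.lambda_bfg < 0:
            raise ValueError("loss weights must be nonnegative")


@dataclass
class FusedRepresentation:
    """Token sequence and pooled feature after cross-modal fusion."""

    tokens: np.ndarray   # (2 + 2*N_roi, d) or batched
    pooled: np.ndarray   # (d,) or (batch, d)


def normalize_rows(x: Tensor, eps: float = 1e-12) -> Tensor:
    norm = ((x * x).sum(axis=-1, keepdims=True) + eps).pow(0.5)
    return x / norm


def contrastive_loss_t(p: Tensor, q: Tensor, sigma: float,
                       normalize: bool = True) -> Tensor:
    """Differentiable symmetric contrastive loss over (n, d) feature batches."""
    n = p.shape[0]
    if n < 1:
        raise ValueError("contrastive loss needs at least one sample")
    if p.shape != q.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {q.shape}")
    if normalize:
        p = normalize_rows(p)
        q = normalize_rows(q)
    sim = (p @ q.swapaxes(-1, -2)) * (1.0 / sigma)     # (n, n)
    diag = np.arange(n)
    # -log softmax along rows (p_i against all q_j) and columns (q_i vs p_j)
    row_ce = logsumexp(sim, axis=1) - sim[diag, diag]
    col_ce = logsumexp(sim, axis=0) - sim[diag, diag]
    return (row_ce.mean() + col_ce.mean())


def contrastive_loss(p: np.ndarray, q: np.ndarray, sigma: float,
                     normalize: bool = True) -> float:
    """Symmetric temperature-scaled contrastive loss (scalar)."""
    p = np.asarray(p, dtype=np.float64)
    q = np.asarray(q, dtype=np.float64)
    if p.ndim != 2 or q.ndim != 2:
        raise ValueError("expected (n, d) feature matrices")
    if p.shape[0] == 0:
        raise ValueError("contrastive loss needs at least one sample")
    if not (np.all(np.isfinite(p)) and np.all(np.isfinite(q))):
        raise ValueError("non-finite features")
    return contrastive_loss_t(Tensor(p), Tensor(q), sigma, normalize).item()


def fmri_guided_loss_t(p_local: Tensor, q_roi: Tensor,
                       normalize: bool = True,
                       batch_norm: bool = False) -> Tensor:
    """Differentiable ROI-guided loss over (n, N_roi, d) feature batches."""
    if p_local.shape != q_roi.shape:
        raise ValueError(f"shape mismatch: {p_local.shape} vs {q_roi.shape}")
    n, n_roi, _ = p_local.shape
    if normalize:
        p_local = normalize_rows(p_local)
        q_roi = normalize_rows(q_roi)
    # sim[i, k, g] = p_local[i, k] . q_roi[i, g]
    sim = p_local @ q_roi.swapaxes(-1, -2)
    diag = np.arange(n_roi)
    ce = logsumexp(sim, axis=2) - sim[:, diag, diag]   # (n, N_roi)
    loss = ce.sum() * (1.0 / n_roi)
    if batch_norm:
        loss = loss * (1.0 / n)
    return loss


def fmri_guided_loss(p_local: np.ndarray, q_roi: np.ndarray,
                     normalize: bool = True,
                     batch_norm: bool = False) -> float:
    """ROI-guided local alignment loss (scalar)."""
    p_local = np.asarray(p_local, dtype=np.float64)
    q_roi = np.asarray(q_roi, dtype=np.float64)
    if p_local.ndim != 3 or q_roi.ndim != 3:
        raise ValueError("expected (n, N_roi, d) feature arrays")
    if p_local.shape[1] < 1:
        raise ValueError("need at least one ROI")
    return fmri_guided_loss_t(Tensor(p_local), Tensor(q_roi),
                              normalize, batch_norm).item()


def total_loss(lcon: float, lbfg: float, cfg: LossConfig) -> float:
    """Weighted sum of the two alignment losses."""
    if not (np.isfinite(lcon) and np.isfinite(lbfg)):
        raise ValueError("non-finite loss inputs")
    return cfg.lambda_con * lcon + cfg.lambda_bfg * lbfg


class FusionBlock(Module):
    """One transformer encoder layer over the joint cross-modal token set.

    Token order: [global-visual, global-signal, N_roi local-visual,
    N_roi ROI-signal].  A learned type embedding (4 types: global/local x
    modality) is added per token before the encoder layer; the pooled output
    is the mean over tokens.
    """

    N_TYPES = 4

    def __init__(self, d: int, n_roi: int, rng: np.random.Generator):
        self.d = d
        self.n_roi = n_roi
        self.type_embed = Tensor(rng.normal(0.0, 0.02, size=(self.N_TYPES, d)),
                                 requires_grad=True)
        self.layer = TransformerLayer(d, n_heads=4, rng=rng)

    def token_types(self) -> np.ndarray:
        """Type index per token position."""
        return np.array([0, 1] + [2] * self.n_roi + [3] * self.n_roi)

    def assemble(self, vis_global: Tensor, sig_global: Tensor,
                 vis_local: Tensor, sig_roi: Tensor) -> Tensor:
        """(b, d), (b, d), (b, N_roi, d), (b, N_roi, d) -> (b, 2+2N_roi, d)."""
        b, d = vis_global.shape
        if sig_roi.shape[1] != self.n_roi or vis_local.shape[1] != self.n_roi:
            raise ValueError(
                f"expected {self.n_roi} local/ROI features, got "
                f"{vis_local.shape[1]}/{sig_roi.shape[1]}")
        if d != self.d or sig_global.shape[1] != self.d:
            raise ValueError("feature dimension mismatch in fusion block")
        toks = concat([vis_global.reshape(b, 1, d),
                       sig_global.reshape(b, 1, d),
                       vis_local, sig_roi], axis=1)
        return toks + self.type_embed[self.token_types()]

    def __call__(self, vis_global: Tensor, sig_global: Tensor,
                 vis_local: Tensor, sig_roi: Tensor) -> tuple[Tensor, Tensor]:
        tokens = self.layer(self.assemble(vis_global, sig_global,
                                          vis_local, sig_roi))
        return tokens, tokens.mean(axis=1)


def fuse(visual, fmri, block: FusionBlock) -> FusedRepresentation:
    """Fuse one sample's VisualFeature and FMRIFeature (numpy in/out)."""
    vg = np.asarray(visual.global_feat, dtype=np.float64)
    qg = np.asarray(fmri.global_feat, dtype=np.float64)
    vl = np.asarray(visual.local, dtype=np.float64)
    qr = np.asarray(fmri.per_roi, dtype=np.float64)
    single = vg.ndim == 1
    if single:
        vg, qg, vl, qr = vg[None], qg[None], vl[None], qr[None]
    tokens, pooled = block(Tensor(vg), Tensor(qg), Tensor(vl), Tensor(qr))
    if single:
        return FusedRepresentation(tokens=tokens.data[0], pooled=pooled.data[0])
    return FusedRepresentation(tokens=tokens.data, pooled=pooled.data)
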