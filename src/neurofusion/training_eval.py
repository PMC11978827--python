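"""Training loop and evaluation: joint contrastive optimization, cross-modal
retrieval, voxel-encoding correlation, and standalone detection/segmentation
metric primitives (IoU, mean IoU, average precision from precision/recall
points).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor
from .fusion_losses import (LossConfig, contrastive_loss_t, fmri_guided_loss_t,
                            normalize_rows)
from .model import CrossModalModel
from .nn import Adam
from .synthetic_data import SyntheticPairSet

__all__ = [
    "TrainConfig",
    "EvalReport",
    "train",
    "evaluate",
    "retrieval_accuracy",
    "pcc",
    "iou",
    "mean_iou",
    "average_precision",
    "encode_dataset",
    "roi_alignment_gap",
    "train_test_split",
]

logger = logging.getLogger(__name__)

MSE_WEIGHT = 0.1  # auxiliary response-prediction term alongside the alignment losses


@dataclass
class TrainConfig:
    lr: float = 1e-4
    epochs: int = 30
    batch_size: int = 32
    seed: int = 0
    loss: LossConfig = field(default_factory=LossConfig)
    mse_weight: float = MSE_WEIGHT

    def __post_init__(self) -> None:
        if self.lr < 0:
            raise ValueError(f"lr must be >= 0, got {self.lr}")
        if self.epochs < 0:
            raise ValueError(f"epochs must be >= 0, got {self.epochs}")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class EvalReport:
    retrieval_top1: float
    retrieval_top5: float
    mean_pcc: float
    n_test: int
    loss_history: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "retrieval_top1": self.retrieval_top1,
            "retrieval_top5": self.retrieval_top5,
            "mean_pcc": self.mean_pcc,
            "n_test": self.n_test,
            "loss_history": self.loss_history,
        }


def train(pairs: SyntheticPairSet, model: CrossModalModel, cfg: TrainConfig
          ) -> list[dict]:
    """Minibatch Adam on the weighted alignment objective.

    Returns the per-epoch loss history (mean total, contrastive, and
    ROI-guided components).  Deterministic given ``cfg.seed``.
    """
    n = pairs.n_samples
    if n == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.lr)
    history: list[dict] = []
    lcfg = cfg.loss
    # one fixed shuffle for the whole run: batch composition then stays
    # constant across epochs, so a frozen optimizer yields a flat history
    order = rng.permutation(n)
    for epoch in range(cfg.epochs):
        totals = np.zeros(3)
        n_batches = 0
        for lo in range(0, n, cfg.batch_size):
            idx = order[lo:lo + cfg.batch_size]
            out = model(Tensor(pairs.images[idx]),
                        Tensor(pairs.responses[idx]))
            lcon = contrastive_loss_t(out.vis_global, out.sig_global,
                                      lcfg.sigma, lcfg.normalize_features)
            lbfg = fmri_guided_loss_t(out.vis_local, out.sig_roi,
                                      lcfg.normalize_features,
                                      lcfg.bfg_batch_norm)
            diff = out.pred_responses - Tensor(pairs.responses[idx])
            mse = (diff * diff).mean()
            loss = (lcfg.lambda_con * lcon + lcfg.lambda_bfg * lbfg
                    + cfg.mse_weight * mse)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss in epoch {epoch}, batch starting at "
                    f"sample {lo} (indices {idx[:4].tolist()}...)")
            opt.zero_grad()
            loss.backward()
            opt.step()
            totals += (loss.item(), lcon.item(), lbfg.item())
            n_batches += 1
        mean = totals / n_batches
        history.append({"epoch": epoch, "total": mean[0],
                        "contrastive": mean[1], "roi_guided": mean[2]})
        logger.debug("epoch %d: total=%.4f con=%.4f bfg=%.4f",
                     epoch, *mean)
    return history


def encode_dataset(model: CrossModalModel, pairs: SyntheticPairSet,
                   batch_size: int = 64) -> dict[str, np.ndarray]:
    """Forward pass over a dataset; returns stacked numpy features."""
    outs = {"vis_global": [], "sig_global": [], "vis_local": [],
            "sig_roi": [], "pred": []}
    for lo in range(0, pairs.n_samples, batch_size):
        sl = slice(lo, lo + batch_size)
        out = model(Tensor(pairs.images[sl]), Tensor(pairs.responses[sl]))
        outs["vis_global"].append(out.vis_global.data)
        outs["sig_global"].append(out.sig_global.data)
        outs["vis_local"].append(out.vis_local.data)
        outs["sig_roi"].append(out.sig_roi.data)
        outs["pred"].append(out.pred_responses.data)
    return {k: np.concatenate(v) for k, v in outs.items()}


def retrieval_accuracy(p: np.ndarray, q: np.ndarray, k: int) -> float:
    """Fraction of rows of ``p`` whose true partner row of ``q`` ranks in the
    top ``k`` by cosine similarity (ties broken toward lower index)."""
    p = np.asarray(p, dtype=np.float64)
    q = np.asarray(q, dtype=np.float64)
    if p.shape != q.shape or p.ndim != 2:
        raise ValueError("p and q must be matching (n, d) matrices")
    n = p.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} must satisfy 1 <= k <= n={n}")
    p = p / np.maximum(np.linalg.norm(p, axis=1, keepdims=True), 1e-12)
    q = q / np.maximum(np.linalg.norm(q, axis=1, keepdims=True), 1e-12)
    sim = p @ q.T
    hits = 0
    for i in range(n):
        # stable sort on -sim keeps lower indices first among ties
        ranked = np.argsort(-sim[i], kind="stable")[:k]
        hits += int(i in ranked)
    return hits / n


def pcc(predicted: np.ndarray, observed: np.ndarray) -> float:
    """Per-voxel Pearson correlation across samples, averaged over voxels.

    Inputs are (n_samples, n_vox).  Voxels with zero variance in either
    array are excluded (and logged); if all are excluded, raises.
    """
    predicted = np.asarray(predicted, dtype=np.float64)
    observed = np.asarray(observed, dtype=np.float64)
    if predicted.shape != observed.shape or predicted.ndim != 2:
        raise ValueError("predicted and observed must match as (n_samples, n_vox)")
    if predicted.shape[0] < 2:
        raise ValueError("need at least two samples per voxel")
    pc = predicted - predicted.mean(axis=0)
    oc = observed - observed.mean(axis=0)
    p_sd = np.sqrt((pc ** 2).sum(axis=0))
    o_sd = np.sqrt((oc ** 2).sum(axis=0))
    valid = (p_sd > 0) & (o_sd > 0)
    n_excluded = int((~valid).sum())
    if n_excluded == predicted.shape[1]:
        raise ValueError("all voxels have zero variance")
    if n_excluded:
        logger.info("pcc: excluded %d zero-variance voxels", n_excluded)
    r = (pc[:, valid] * oc[:, valid]).sum(axis=0) / (p_sd[valid] * o_sd[valid])
    return float(r.mean())


def iou(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Intersection over union of two same-shape binary masks."""
    mask_a = np.asarray(mask_a, dtype=bool)
    mask_b = np.asarray(mask_b, dtype=bool)
    if mask_a.shape != mask_b.shape:
        raise ValueError(f"mask shapes differ: {mask_a.shape} vs {mask_b.shape}")
    union = np.logical_or(mask_a, mask_b).sum()
    if union == 0:
        logger.info("iou: both masks empty, returning 0.0")
        return 0.0
    return float(np.logical_and(mask_a, mask_b).sum() / union)


def mean_iou(per_class_ious) -> float:
    """Unweighted mean of per-class IoU values."""
    vals = list(per_class_ious)
    if not vals:
        raise ValueError("mean_iou of an empty class list")
    return float(np.mean(vals))


def average_precision(points) -> float:
    """Discrete AP: sum of precision_i times the recall increment from the
    previous point (first increment measured from recall 0).

    ``points`` is an ordered sequence of (precision, recall) pairs with
    nondecreasing recall in [0, 1].
    """
    pts = [(float(p), float(r)) for p, r in points]
    prev_recall = 0.0
    ap = 0.0
    for precision, recall in pts:
        if recall < prev_recall - 1e-12 or not 0.0 <= recall <= 1.0:
            raise ValueError(
                f"recall values must be nondecreasing in [0, 1]; got {recall} "
                f"after {prev_recall}")
        ap += precision * (recall - prev_recall)
        prev_recall = recall
    return ap


def roi_alignment_gap(vis_local: np.ndarray, sig_roi: np.ndarray) -> float:
    """Mean matched-ROI cosine similarity minus mean mismatched, per sample.

    The desk-scale readout of whether the ROI-guided loss actually pulls each
    image-local feature toward its own ROI's signal feature.
    """
    p = normalize_rows(Tensor(np.asarray(vis_local, dtype=np.float64))).data
    q = normalize_rows(Tensor(np.asarray(sig_roi, dtype=np.float64))).data
    sim = np.einsum("nkd,ngd->nkg", p, q)
    n_roi = sim.shape[1]
    diag = np.arange(n_roi)
    matched = sim[:, diag, diag].mean()
    off_mask = ~np.eye(n_roi, dtype=bool)
    mismatched = sim[:, off_mask].mean()
    return float(matched - mismatched)


def train_test_split(pairs: SyntheticPairSet, test_fraction: float = 0.2,
                     seed: int = 0) -> tuple[SyntheticPairSet, SyntheticPairSet]:
    """Shuffled holdout split at the sample level."""
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    n = pairs.n_samples
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_test = max(1, int(round(n * test_fraction)))
    return pairs.subset(order[n_test:]), pairs.subset(order[:n_test])


def evaluate(model: CrossModalModel, test_pairs: SyntheticPairSet,
             loss_history: list[dict] | None = None) -> EvalReport:
    """Retrieval and encoding quality on held-out pairs."""
    feats = encode_dataset(model, test_pairs)
    p, q = feats["vis_global"], feats["sig_global"]
    n = p.shape[0]
    top1 = retrieval_accuracy(p, q, 1)
    top5 = retrieval_accuracy(p, q, min(5, n))
    predicted = model.predict_responses_from_images(test_pairs.images)
    mean_pcc = pcc(predicted, test_pairs.responses)
    return EvalReport(retrieval_top1=top1, retrieval_top5=top5,
                      mean_pcc=mean_pcc, n_test=n,
                      loss_history=loss_history or [])
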