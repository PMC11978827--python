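import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neurofusion.autodiff import Tensor
from neurofusion.fusion_losses import (FusionBlock, LossConfig,
                                       contrastive_loss, contrastive_loss_t,
                                       fmri_guided_loss, fuse, total_loss)


# -- independent loop oracles (printed formulas, computed naively) -----------

def unit_rows(x):
    return x / np.linalg.norm(x, axis=-1, keepdims=True)


def loop_contrastive(p, q, sigma):
    n = p.shape[0]
    total = 0.0
    for i in range(n):
        num = math.exp(np.dot(p[i], q[i]) / sigma)
        den = sum(math.exp(np.dot(p[i], q[j]) / sigma) for j in range(n))
        total -= math.log(num / den) / n
    for i in range(n):
        num = math.exp(np.dot(q[i], p[i]) / sigma)
        den = sum(math.exp(np.dot(q[i], p[j]) / sigma) for j in range(n))
        total -= math.log(num / den) / n
    return total


def loop_fmri_guided(p_local, q_roi):
    n, n_roi, _ = p_local.shape
    total = 0.0
    for i in range(n):
        for k in range(n_roi):
            num = math.exp(np.dot(p_local[i, k], q_roi[i, k]))
            den = sum(math.exp(np.dot(p_local[i, k], q_roi[i, g]))
                      for g in range(n_roi))
            total -= math.log(num / den)
    return total / n_roi


# -- contrastive loss --------------------------------------------------------

def test_single_sample_zero():
    p = np.array([[1.0, 2.0]])
    assert contrastive_loss(p, p, sigma=0.07) == pytest.approx(0.0, abs=1e-12)


def test_uniform_similarity_gives_2_ln_n(rng):
    # identical rows make every pairwise dot product equal
    row = rng.normal(size=8)
    p = np.tile(row, (4, 1))
    q = np.tile(rng.normal(size=8), (4, 1))
    assert contrastive_loss(p, q, sigma=0.07) == pytest.approx(2 * math.log(4),
                                                               abs=1e-9)


def test_matches_loop_oracle(rng):
    for _ in range(20):
        p = rng.normal(size=(3, 8))
        q = rng.normal(size=(3, 8))
        got = contrastive_loss(p, q, sigma=0.07, normalize=True)
        want = loop_contrastive(unit_rows(p), unit_rows(q), 0.07)
        assert got == pytest.approx(want, abs=1e-6)
        # un-normalized route against the raw printed formula
        got_raw = contrastive_loss(p, q, sigma=2.0, normalize=False)
        assert got_raw == pytest.approx(loop_contrastive(p, q, 2.0), abs=1e-6)


def test_symmetry_under_modality_swap(rng):
    p, q = rng.normal(size=(5, 6)), rng.normal(size=(5, 6))
    assert contrastive_loss(p, q, 0.1) == pytest.approx(
        contrastive_loss(q, p, 0.1), abs=1e-12)


@given(seed=st.integers(0, 10_000))
@settings(max_examples=30, deadline=None)
def test_permutation_invariance(seed):
    r = np.random.default_rng(seed)
    p, q = r.normal(size=(6, 4)), r.normal(size=(6, 4))
    perm = r.permutation(6)
    assert contrastive_loss(p, q, 0.07) == pytest.approx(
        contrastive_loss(p[perm], q[perm], 0.07), abs=1e-10)


def test_temperature_limit(rng):
    p, q = rng.normal(size=(5, 8)), rng.normal(size=(5, 8))
    assert contrastive_loss(p, q, sigma=1e6) == pytest.approx(
        2 * math.log(5), abs=1e-3)


def test_nonnegative_and_near_zero_at_one_hot(rng):
    p = np.eye(4)
    assert contrastive_loss(p, p, sigma=0.01) >= 0.0
    # matched pairs hold essentially all softmax mass at low temperature
    assert contrastive_loss(p, p, sigma=0.01) == pytest.approx(0.0, abs=1e-10)
    q = rng.normal(size=(6, 4))
    assert contrastive_loss(rng.normal(size=(6, 4)), q, 0.07) >= 0.0


def test_degenerate_inputs_raise():
    with pytest.raises(ValueError):
        contrastive_loss(np.empty((0, 4)), np.empty((0, 4)), 0.07)
    with pytest.raises(ValueError):
        contrastive_loss(np.array([[np.inf, 0.0]]), np.ones((1, 2)), 0.07)
    with pytest.raises(ValueError):
        contrastive_loss(np.ones((2, 3)), np.ones((3, 3)), 0.07)


def test_gradient_step_increases_matched_similarity(rng):
    """One gradient step pulls matched pairs together relative to mismatched."""
    from neurofusion.nn import Adam
    p = Tensor(rng.normal(size=(8, 6)), requires_grad=True)
    q = Tensor(rng.normal(size=(8, 6)), requires_grad=True)

    def gap(pd, qd):
        s = unit_rows(pd) @ unit_rows(qd).T
        return np.mean(np.diag(s)) - np.mean(s[~np.eye(8, dtype=bool)])

    before = gap(p.data, q.data)
    opt = Adam([p, q], lr=0.05)
    loss = contrastive_loss_t(p, q, sigma=0.5)
    loss.backward()
    opt.step()
    assert gap(p.data, q.data) > before


# -- fMRI-guided loss --------------------------------------------------------

def test_bfg_single_roi_zero():
    x = np.ones((1, 1, 4))
    assert fmri_guided_loss(x, x) == pytest.approx(0.0, abs=1e-12)


def test_bfg_uniform_similarity():
    # identical local features across ROIs -> uniform softmax
    p = np.tile(np.array([1.0, 0.0]), (2, 6, 1))
    q = np.tile(np.array([0.0, 1.0]), (2, 6, 1))
    assert fmri_guided_loss(p, q) == pytest.approx(2 * math.log(6), abs=1e-9)
    assert fmri_guided_loss(p, q, batch_norm=True) == pytest.approx(
        math.log(6), abs=1e-9)


def test_bfg_matches_triple_loop_oracle(rng):
    for _ in range(20):
        p = rng.normal(size=(2, 3, 5))
        q = rng.normal(size=(2, 3, 5))
        got = fmri_guided_loss(p, q, normalize=True)
        want = loop_fmri_guided(unit_rows(p), unit_rows(q))
        assert got == pytest.approx(want, abs=1e-6)
        got_raw = fmri_guided_loss(p, q, normalize=False)
        assert got_raw == pytest.approx(loop_fmri_guided(p, q), abs=1e-6)


def test_bfg_shape_mismatch_raises(rng):
    with pytest.raises(ValueError):
        fmri_guided_loss(rng.normal(size=(2, 3, 4)), rng.normal(size=(2, 4, 4)))


# -- total loss --------------------------------------------------------------

def test_total_loss_cases():
    assert total_loss(1.5, 0.4, LossConfig(lambda_con=0, lambda_bfg=0)) == 0.0
    assert total_loss(1.5, 0.4, LossConfig(lambda_con=1, lambda_bfg=0)) == 1.5
    # hand arithmetic: 0.7 * 1.5 + 2.0 * 0.4 = 1.05 + 0.8
    assert total_loss(1.5, 0.4, LossConfig(lambda_con=0.7, lambda_bfg=2.0)) \
        == pytest.approx(1.85, abs=1e-12)


def test_negative_weights_rejected():
    with pytest.raises(ValueError):
        LossConfig(lambda_con=-1.0)
    with pytest.raises(ValueError):
        LossConfig(sigma=0.0)


def test_total_loss_nonfinite_rejected():
    with pytest.raises(ValueError):
        total_loss(float("nan"), 0.0, LossConfig())


# -- fusion block ------------------------------------------------------------

class F:
    def __init__(self, g, l):
        self.global_feat = g
        self.local = l
        self.per_roi = l


def test_token_count(rng):
    block = FusionBlock(d=8, n_roi=6, rng=rng)
    vis = F(rng.normal(size=8), rng.normal(size=(6, 8)))
    sig = F(rng.normal(size=8), rng.normal(size=(6, 8)))
    out = fuse(vis, sig, block)
    assert out.tokens.shape == (14, 8)
    assert out.pooled.shape == (8,)


def test_identity_limit(rng):
    block = FusionBlock(d=8, n_roi=2, rng=rng)
    block.layer.attn.out_proj.weight.data[:] = 0
    block.layer.attn.out_proj.bias.data[:] = 0
    block.layer.ff2.weight.data[:] = 0
    block.layer.ff2.bias.data[:] = 0
    vis = F(rng.normal(size=8), rng.normal(size=(2, 8)))
    sig = F(rng.normal(size=8), rng.normal(size=(2, 8)))
    out = fuse(vis, sig, block)
    raw = np.concatenate([vis.global_feat[None], sig.global_feat[None],
                          vis.local, sig.per_roi])
    expected = (raw + block.type_embed.data[block.token_types()]).mean(axis=0)
    np.testing.assert_allclose(out.pooled, expected, atol=1e-12)


def test_modality_swap_permutes_tokens(rng):
    """With symmetric type embeddings, swapping modality inputs permutes the
    assembled token sequence accordingly."""
    block = FusionBlock(d=8, n_roi=3, rng=rng)
    # make global-visual/global-signal and local/ROI types indistinguishable
    block.type_embed.data[1] = block.type_embed.data[0]
    block.type_embed.data[3] = block.type_embed.data[2]
    vis = F(rng.normal(size=(1, 8)), rng.normal(size=(1, 3, 8)))
    sig = F(rng.normal(size=(1, 8)), rng.normal(size=(1, 3, 8)))
    a = block.assemble(Tensor(vis.global_feat), Tensor(sig.global_feat),
                       Tensor(vis.local), Tensor(sig.per_roi)).data
    b = block.assemble(Tensor(sig.global_feat), Tensor(vis.global_feat),
                       Tensor(sig.per_roi), Tensor(vis.local)).data
    perm = [1, 0, 5, 6, 7, 2, 3, 4]
    np.testing.assert_allclose(b[0], a[0][perm], atol=1e-12)


def test_fusion_dim_mismatch(rng):
    block = FusionBlock(d=8, n_roi=3, rng=rng)
    with pytest.raises(ValueError):
        block.assemble(Tensor(rng.normal(size=(1, 8))),
                       Tensor(rng.normal(size=(1, 8))),
                       Tensor(rng.normal(size=(1, 2, 8))),
                       Tensor(rng.normal(size=(1, 3, 8))))
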