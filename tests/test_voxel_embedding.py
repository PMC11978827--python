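import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neurofusion.synthetic_data import make_voxel_grid
from neurofusion.voxel_embedding import (Conv1dParams, CoordEmbedParams,
                                         TokenizedSignal, VoxelGrid,
                                         concat_voxels, conv_token_layout,
                                         embed_coords, roi_pool,
                                         token_roi_weights, tokenize_and_fuse)


def grid_of(n_vox, n_roi=2, seed=0, signal=None):
    g = make_voxel_grid(n_vox, n_roi, seed)
    if signal is None:
        signal = np.random.default_rng(seed).normal(size=(1, n_vox))
    return VoxelGrid(coords=g.coords, signal=signal, roi_labels=g.roi_labels)


# -- embed_coords ------------------------------------------------------------

def test_embed_zero_map_annihilates(rng):
    coords = rng.integers(0, 10, size=(7, 3))
    params = CoordEmbedParams(weight=np.zeros((3, 4)), bias=np.zeros(4))
    np.testing.assert_array_equal(embed_coords(coords, params),
                                  np.zeros((7, 4)))


def test_embed_identity_recovers_coords(rng):
    coords = rng.integers(0, 10, size=(6, 3))
    params = CoordEmbedParams(weight=np.eye(3), bias=None, normalize=False)
    np.testing.assert_array_equal(embed_coords(coords, params),
                                  coords.astype(float))


def test_embed_matches_per_voxel_matvec(rng):
    """Brute-force oracle: explicit per-voxel matrix-vector products."""
    coords = np.array([[0, 1, 2], [3, 4, 5], [9, 0, 1], [2, 2, 2], [7, 7, 0]])
    W = rng.normal(size=(3, 8))
    b = rng.normal(size=8)
    params = CoordEmbedParams(weight=W, bias=b, normalize=False)
    got = embed_coords(coords, params)
    for i in range(5):
        expected = np.array([sum(coords[i, a] * W[a, j] for a in range(3)) + b[j]
                             for j in range(8)])
        np.testing.assert_allclose(got[i], expected, atol=1e-6)


@given(t=st.tuples(st.integers(-20, 20), st.integers(-20, 20),
                   st.integers(-20, 20)))
@settings(max_examples=25, deadline=None)
def test_embed_translation_covariance(t):
    rng = np.random.default_rng(0)
    coords = rng.integers(0, 12, size=(9, 3))
    W = rng.normal(size=(3, 5))
    params = CoordEmbedParams(weight=W, bias=rng.normal(size=5),
                              normalize=False)
    shift = np.array(t)
    base = embed_coords(coords, params)
    moved = embed_coords(coords + shift, params)
    np.testing.assert_allclose(moved - base,
                               np.broadcast_to(shift.astype(float) @ W, base.shape),
                               atol=1e-9)


def test_embed_shape_errors():
    with pytest.raises(ValueError):
        CoordEmbedParams(weight=np.zeros((4, 5)))
    with pytest.raises(ValueError):
        embed_coords(np.zeros((3, 2)), CoordEmbedParams(weight=np.zeros((3, 4))))


# -- concat_voxels -----------------------------------------------------------

def test_concat_single_voxel_identity(rng):
    f = rng.normal(size=(1, 5))
    np.testing.assert_array_equal(concat_voxels(f), f[0])


def test_concat_ordering_contract(rng):
    a, b = rng.normal(size=4), rng.normal(size=4)
    fwd = concat_voxels(np.stack([a, b]))
    rev = concat_voxels(np.stack([b, a]))
    np.testing.assert_array_equal(fwd, np.concatenate([a, b]))
    np.testing.assert_array_equal(rev, np.concatenate([b, a]))


def test_concat_index_arithmetic(rng):
    per_voxel = rng.normal(size=(7, 4))
    out = concat_voxels(per_voxel)
    assert out.shape == (28,)
    for i in range(7):
        for j in range(4):
            assert out[4 * i + j] == per_voxel[i, j]


def test_concat_rejects_empty_and_ragged():
    with pytest.raises(ValueError):
        concat_voxels(np.empty((0, 4)))
    with pytest.raises(ValueError):
        concat_voxels(np.array([[1.0, 2.0], [3.0]], dtype=object))


# -- tokenizer ---------------------------------------------------------------

def test_token_layout_default_params():
    assert conv_token_layout(64, 32, 16) == [(0, 32), (16, 48), (32, 64)]


def test_token_layout_remainder_padding():
    # 60 voxels: two full windows then a padded remainder token
    assert conv_token_layout(60, 32, 16) == [(0, 32), (16, 48), (32, 60)]


def test_token_layout_short_sequence():
    assert conv_token_layout(10, 32, 16) == [(0, 10)]


def test_tokenize_residual_only_limit(rng):
    """Zero conv weights: tokens equal the pooled coordinate embeddings."""
    grid = grid_of(64, seed=1)
    conv = Conv1dParams(weight=np.zeros((32, 6)), bias=np.zeros(6), stride=16)
    cp = CoordEmbedParams(weight=rng.normal(size=(3, 6)))
    out = tokenize_and_fuse(grid, 0, conv, cp)
    emb = embed_coords(grid.coords, cp)
    for j, (start, stop) in enumerate(out.receptive_map):
        np.testing.assert_allclose(out.tokens[j], emb[start:stop].mean(axis=0),
                                   atol=1e-12)


def test_tokenize_conv_only_limit_matches_sliding_oracle(rng):
    """Zero coordinate map: tokens equal a brute-force strided convolution."""
    grid = grid_of(64, seed=2)
    W = rng.normal(size=(32, 6))
    b = rng.normal(size=6)
    conv = Conv1dParams(weight=W, bias=b, stride=16)
    cp = CoordEmbedParams(weight=np.zeros((3, 6)), bias=np.zeros(6))
    out = tokenize_and_fuse(grid, 0, conv, cp)
    x = grid.signal[0]
    assert out.n_tokens == 3
    for j in range(3):
        start = j * 16
        expected = np.array([sum(x[start + t] * W[t, c] for t in range(32)) + b[c]
                             for c in range(6)])
        np.testing.assert_allclose(out.tokens[j], expected, atol=1e-9)


def test_tokenize_degenerate_identity_equivalence(rng):
    """kernel=1, stride=1, all-ones conv row: token j = x_j * 1 + v_j."""
    grid = grid_of(12, seed=3)
    d = 4
    conv = Conv1dParams(weight=np.ones((1, d)), bias=None, stride=1)
    cp = CoordEmbedParams(weight=rng.normal(size=(3, d)))
    out = tokenize_and_fuse(grid, 0, conv, cp)
    emb = embed_coords(grid.coords, cp)
    np.testing.assert_allclose(out.tokens, grid.signal[0][:, None] + emb,
                               atol=1e-12)


def test_tokenize_dim_mismatch_raises(rng):
    grid = grid_of(40, seed=4)
    conv = Conv1dParams(weight=np.zeros((32, 6)), stride=16)
    cp = CoordEmbedParams(weight=np.zeros((3, 5)))
    with pytest.raises(ValueError, match="dimension"):
        tokenize_and_fuse(grid, 0, conv, cp)


# -- roi_pool ----------------------------------------------------------------

def test_roi_pool_single_roi_is_token_mean(rng):
    grid = grid_of(64, n_roi=1, seed=5)
    tokens = TokenizedSignal(tokens=rng.normal(size=(3, 4)),
                             receptive_map=conv_token_layout(64, 32, 16))
    np.testing.assert_allclose(roi_pool(tokens, grid)[0],
                               tokens.tokens.mean(axis=0), atol=1e-12)


def test_roi_pool_constant_tokens(rng):
    grid = grid_of(64, n_roi=3, seed=6)
    c = rng.normal(size=4)
    tokens = TokenizedSignal(tokens=np.tile(c, (3, 1)),
                             receptive_map=conv_token_layout(64, 32, 16))
    out = roi_pool(tokens, grid)
    np.testing.assert_allclose(out, np.tile(c, (3, 1)), atol=1e-12)


def test_roi_pool_hand_computed_weighted_mean():
    """3 tokens, 2 ROIs with printed overlap fractions."""
    # 8 voxels: labels 0 0 0 1 1 1 1 1; tokens cover [0,4), [2,6), [4,8)
    coords = np.array([[i, 0, 0] for i in range(8)])
    grid = VoxelGrid(coords=coords, signal=np.zeros((1, 8)),
                     roi_labels=np.array([0, 0, 0, 1, 1, 1, 1, 1]))
    rmap = [(0, 4), (2, 6), (4, 8)]
    tokens = TokenizedSignal(tokens=np.array([[1.0], [2.0], [4.0]]),
                             receptive_map=rmap)
    # fractions in ROI0: 3/4, 1/4, 0 ; ROI1: 1/4, 3/4, 1
    w0 = np.array([0.75, 0.25, 0.0])
    w1 = np.array([0.25, 0.75, 1.0])
    expected0 = (w0 @ tokens.tokens[:, 0]) / w0.sum()
    expected1 = (w1 @ tokens.tokens[:, 0]) / w1.sum()
    out = roi_pool(tokens, grid)
    np.testing.assert_allclose(out[:, 0], [expected0, expected1], atol=1e-6)


def test_roi_pool_empty_roi_raises():
    labels = np.array([0, 0, 2, 2])  # ROI 1 empty
    with pytest.raises(ValueError, match="ROI 1"):
        token_roi_weights([(0, 4)], labels, n_roi=3)


# -- VoxelGrid invariants ----------------------------------------------------

def test_grid_rejects_duplicates_and_mismatches():
    coords = np.array([[0, 0, 0], [0, 0, 0]])
    with pytest.raises(ValueError, match="duplicate"):
        VoxelGrid(coords=coords, signal=np.zeros((1, 2)),
                  roi_labels=np.zeros(2, dtype=int))
    with pytest.raises(ValueError):
        VoxelGrid(coords=np.array([[0, 0, 0]]), signal=np.zeros((1, 2)),
                  roi_labels=np.zeros(1, dtype=int))
    with pytest.raises(ValueError, match="finite"):
        VoxelGrid(coords=np.array([[0, 0, 0]]),
                  signal=np.array([[np.nan]]), roi_labels=np.zeros(1, dtype=int))
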