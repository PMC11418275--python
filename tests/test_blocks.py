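"""Building blocks: patch unfold/fold, channel shuffle, GSConv, LSK, MobileViT."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import signal

from mlgyolo.blocks import (GSConv, GSConvConfig, LSKBlock, LSKConfig,
                            MobileViTBlock, MobileViTConfig, channel_shuffle,
                            mobilevit_fold, mobilevit_unfold)
from mlgyolo.layers import set_seed
from mlgyolo.tensor import Tensor


# ---------------------------------------------------------------------------
# unfold / fold
# ---------------------------------------------------------------------------
def test_unfold_shapes():
    x = Tensor(np.arange(16, dtype=np.float32).reshape(1, 1, 4, 4))
    u = mobilevit_unfold(x, 2, 2)
    assert u.shape == (1, 4, 4, 1)          # P = wh = 4, N = HW/P = 4
    # unit patches reduce to a pure reshape with N = H*W
    u1 = mobilevit_unfold(x, 1, 1)
    assert u1.shape == (1, 1, 16, 1)
    np.testing.assert_array_equal(u1.data.ravel(), x.data.ravel())


def test_unfold_partition():
    """Every input element appears exactly once in the unfolded tensor."""
    x = Tensor(np.arange(2 * 3 * 8 * 6, dtype=np.float32).reshape(2, 3, 8, 6))
    u = mobilevit_unfold(x, 2, 3)
    assert sorted(u.data.ravel().tolist()) == sorted(x.data.ravel().tolist())


def test_unfold_rejects_non_divisible():
    x = Tensor(np.zeros((1, 1, 5, 4), dtype=np.float32))
    with pytest.raises(ValueError):
        mobilevit_unfold(x, 2, 2)


@settings(derandomize=True, max_examples=25)
@given(nh=st.integers(1, 4), nw=st.integers(1, 4), ph=st.integers(1, 3),
       pw=st.integers(1, 3), d=st.integers(1, 4), seed=st.integers(0, 2 ** 16))
def test_fold_unfold_identity(nh, nw, ph, pw, d, seed):
    h, w = nh * ph, nw * pw
    x = np.random.default_rng(seed).standard_normal((1, d, h, w)).astype(np.float32)
    u = mobilevit_unfold(Tensor(x), ph, pw)
    back = mobilevit_fold(u, ph, pw, h, w)
    np.testing.assert_array_equal(back.data, x)


def test_fold_zero_and_shape_errors():
    z = Tensor(np.zeros((1, 4, 4, 2), dtype=np.float32))
    out = mobilevit_fold(z, 2, 2, 4, 4)
    assert not out.data.any()
    with pytest.raises(ValueError):
        mobilevit_fold(z, 2, 2, 4, 8)


def test_patch_permutation_is_not_identity(rng):
    """Swapping two patches before folding must move pixels (order bugs)."""
    x = rng.standard_normal((1, 1, 4, 4)).astype(np.float32)
    u = mobilevit_unfold(Tensor(x), 2, 2).data.copy()
    u[:, :, [0, 1]] = u[:, :, [1, 0]]
    back = mobilevit_fold(Tensor(u), 2, 2, 4, 4)
    assert not np.array_equal(back.data, x)


def test_unfold_gradient_is_permutation(rng):
    x = Tensor(rng.standard_normal((1, 2, 4, 4)), requires_grad=True)
    mobilevit_unfold(x, 2, 2).sum().backward()
    np.testing.assert_allclose(x.grad, 1.0)


# ---------------------------------------------------------------------------
# channel shuffle
# ---------------------------------------------------------------------------
def test_channel_shuffle_interleave_definition():
    x = Tensor(np.arange(4, dtype=np.float32).reshape(1, 4, 1, 1))  # [a,b,c,d]
    out = channel_shuffle(x, 2).data.ravel()
    np.testing.assert_array_equal(out, [0, 2, 1, 3])                # [a,c,b,d]


def test_channel_shuffle_groups1_identity(rng):
    x = Tensor(rng.standard_normal((2, 6, 3, 3)))
    np.testing.assert_array_equal(channel_shuffle(x, 1).data, x.data)


def test_channel_shuffle_twice_groups2_c4_identity(rng):
    # enumeration: perm [0,2,1,3] has order 2
    x = Tensor(rng.standard_normal((1, 4, 2, 2)))
    twice = channel_shuffle(channel_shuffle(x, 2), 2)
    np.testing.assert_array_equal(twice.data, x.data)


@settings(derandomize=True, max_examples=20)
@given(groups=st.integers(1, 4), per=st.integers(1, 4), seed=st.integers(0, 999))
def test_channel_shuffle_bijection(groups, per, seed):
    c = groups * per
    x = np.random.default_rng(seed).standard_normal((1, c, 2, 2)).astype(np.float32)
    out = channel_shuffle(Tensor(x), groups).data
    # per-pixel multiset of channel values is conserved
    np.testing.assert_array_equal(np.sort(out, axis=1), np.sort(x, axis=1))


def test_channel_shuffle_rejects_non_divisible(rng):
    with pytest.raises(ValueError):
        channel_shuffle(Tensor(rng.standard_normal((1, 5, 2, 2))), 2)


# ---------------------------------------------------------------------------
# GSConv
# ---------------------------------------------------------------------------
def test_gsconv_output_channels(rng):
    set_seed(0)
    gs = GSConv(GSConvConfig(64, 128, 3, stride=2))
    y = gs(Tensor(rng.standard_normal((1, 64, 16, 16))))
    assert y.shape == (1, 128, 8, 8)


def test_gsconv_rejects_odd_output():
    with pytest.raises(ValueError):
        GSConvConfig(16, 15)


def test_gsconv_cheaper_than_dense_conv():
    gs = GSConv(GSConvConfig(64, 128, 3))
    dense = 3 * 3 * 64 * 128 + 2 * 128      # conv + BN, closed form
    assert gs.num_params() < dense
    # closed form: dense half + depthwise half
    expected = (3 * 3 * 64 * 64 + 2 * 64) + (5 * 5 * 64 + 2 * 64)
    assert gs.num_params() == expected


# ---------------------------------------------------------------------------
# LSK
# ---------------------------------------------------------------------------
def test_lsk_zero_input_gives_zero_output(rng):
    set_seed(1)
    lsk = LSKBlock(LSKConfig(16)).eval()
    y = lsk(Tensor(np.zeros((1, 16, 8, 8), dtype=np.float32)))
    np.testing.assert_array_equal(y.data, 0.0)


def test_lsk_masks_in_unit_interval_and_shape(rng):
    set_seed(2)
    lsk = LSKBlock(LSKConfig(8)).eval()
    x = Tensor(3 * rng.standard_normal((2, 8, 10, 10)))
    masks = lsk.masks(x)
    assert masks.shape == (2, 2, 10, 10)
    assert masks.min() >= 0.0 and masks.max() <= 1.0
    assert lsk(x).shape == x.shape


def test_lsk_parameter_closed_form():
    for c in (16, 40, 64):
        assert LSKBlock(LSKConfig(c)).num_params() == 1.5 * c * c + 78 * c + 198


def test_lsk_requires_growing_receptive_field():
    with pytest.raises(ValueError):
        LSKConfig(16, decomposition=((7, 3), (5, 1), (5, 1)))


# ---------------------------------------------------------------------------
# MobileViT block
# ---------------------------------------------------------------------------
def test_mobilevit_block_shape_contract(rng):
    set_seed(3)
    blk = MobileViTBlock(48, MobileViTConfig(dim=64, depth=2)).eval()
    y = blk(Tensor(rng.standard_normal((1, 48, 32, 32))))
    assert y.shape == (1, 48, 32, 32)


def test_mobilevit_rejects_dim_not_above_channels():
    with pytest.raises(ValueError):
        MobileViTBlock(64, MobileViTConfig(dim=64, depth=1))


def test_mobilevit_rejects_patch_larger_than_kernel():
    with pytest.raises(ValueError):
        MobileViTConfig(dim=32, depth=1, local_kernel=3, patch_h=4, patch_w=4)


def test_mobilevit_parameter_closed_form():
    c, d, L, m = 36, 64, 2, 2
    blk = MobileViTBlock(c, MobileViTConfig(dim=d, depth=L, mlp_ratio=m))
    expected = (9 * c * c + 2 * c) + c * d \
        + L * ((4 + 2 * m) * d * d + (9 + m) * d) + 2 * d \
        + (d * c + 2 * c) + (18 * c * c + 2 * c)
    assert blk.num_params() == expected


def test_mobilevit_zeroed_global_branch_reduces_to_local_path(rng):
    """With the projection back from the transformer forced to zero, the block
    output must equal the fusion conv applied to (x, 0) — computed here with
    an independent scipy convolution."""
    set_seed(4)
    c = 6
    blk = MobileViTBlock(c, MobileViTConfig(dim=8, depth=1)).eval()
    blk.conv_project.conv.weight.data[:] = 0.0
    blk.conv_project.bn.weight.data[:] = 0.0
    blk.conv_project.bn.bias.data[:] = 0.0
    x = rng.standard_normal((1, c, 8, 8)).astype(np.float32)
    out = blk(Tensor(x)).data

    cat = np.concatenate([x, np.zeros_like(x)], axis=1)
    w = blk.conv_fuse.conv.weight.data
    ref = np.stack([
        sum(signal.correlate2d(cat[0, ci], w[co, ci], mode="same")
            for ci in range(2 * c))
        for co in range(c)])[None]
    bn = blk.conv_fuse.bn
    ref = (ref - bn.running_mean.reshape(1, -1, 1, 1)) / \
        np.sqrt(bn.running_var + bn.eps).reshape(1, -1, 1, 1)
    ref = ref * bn.weight.data.reshape(1, -1, 1, 1) + bn.bias.data.reshape(1, -1, 1, 1)
    ref = ref * (1.0 / (1.0 + np.exp(-ref)))  # silu
    np.testing.assert_allclose(out, ref, rtol=1e-3, atol=1e-4)


def test_block_parameter_counts_deterministic():
    a = MobileViTBlock(36, MobileViTConfig(dim=64, depth=2)).num_params()
    b = MobileViTBlock(36, MobileViTConfig(dim=64, depth=2)).num_params()
    assert a == b
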