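"""Architecture contracts: ECA, pooling, residual blocks, branches, fusion."""

import numpy as np
import pytest

from emgfuse import nn
from emgfuse.model import (
    ResidualBlockSpec,
    branch_spec,
    build_branch,
    build_two_stream,
    eca_attend,
    eca_kernel_size,
    eca_spec,
    forward,
    global_average_pool,
    init_residual_params,
    residual_block_forward,
    two_stream_spec,
)

# ---------------------------------------------------------------------------
# independent loop oracles
# ---------------------------------------------------------------------------

def eca_loop_oracle(pooled, w):
    """Sliding dot product with symmetric zero padding + sigmoid."""
    C, k = len(pooled), len(w)
    p = (k - 1) // 2
    padded = np.concatenate([np.zeros(p), pooled, np.zeros(p)])
    z = np.array([sum(w[j] * padded[c + j] for j in range(k)) for c in range(C)])
    return 1.0 / (1.0 + np.exp(-z))


def same_pad_1side(size, k, s):
    out = -(-size // s)
    total = max((out - 1) * s + k - size, 0)
    return total // 2, total - total // 2


def conv2d_loop_oracle(x, w, stride):
    """Direct per-element 2-D convolution, 'same' asymmetric padding.

    x: (H, W, Cin); w: (Cout, Cin, kh, kw); returns (OH, OW, Cout).
    """
    h, wd, cin = x.shape
    cout, _, kh, kw = w.shape
    sh, sw = stride
    pt, pb = same_pad_1side(h, kh, sh)
    pl, pr = same_pad_1side(wd, kw, sw)
    xp = np.zeros((h + pt + pb, wd + pl + pr, cin))
    xp[pt : pt + h, pl : pl + wd] = x
    oh = (xp.shape[0] - kh) // sh + 1
    ow = (xp.shape[1] - kw) // sw + 1
    y = np.zeros((oh, ow, cout))
    for o in range(cout):
        for i in range(oh):
            for j in range(ow):
                for c in range(cin):
                    for a in range(kh):
                        for b in range(kw):
                            y[i, j, o] += w[o, c, a, b] * xp[sh * i + a, sw * j + b, c]
    return y


def residual_loop_oracle(x, spec, params):
    """conv-bn(identity)-relu-conv-bn + shortcut, then relu — all via loops."""
    stride = (spec.stride, spec.stride)
    f = conv2d_loop_oracle(x, params["conv1_w"], stride)
    f = f / np.sqrt(1.0 + 1e-5)  # identity batch norm at running stats (0, 1)
    f = np.maximum(f, 0.0)
    f = conv2d_loop_oracle(f, params["conv2_w"], (1, 1))
    f = f / np.sqrt(1.0 + 1e-5)
    if spec.projection:
        s = conv2d_loop_oracle(x, params["proj_w"], stride) / np.sqrt(1.0 + 1e-5)
    else:
        s = x
    return np.maximum(f + s, 0.0)


# ---------------------------------------------------------------------------
# ECA
# ---------------------------------------------------------------------------

class TestEcaKernelSize:
    @pytest.mark.parametrize("C,expected", [(512, 5), (1, 1), (64, 3), (32, 3), (256, 5)])
    def test_reference_values(self, C, expected):
        assert eca_kernel_size(C) == expected

    def test_always_odd_and_positive(self):
        for C in range(1, 1025):
            k = eca_kernel_size(C)
            assert k >= 1 and k % 2 == 1

    def test_invalid_channel_count(self):
        with pytest.raises(ValueError):
            eca_kernel_size(0)


class TestGlobalAveragePool:
    def test_constant_map(self):
        np.testing.assert_array_equal(
            global_average_pool(np.full((3, 4, 2), 3.0)), [3.0, 3.0]
        )

    def test_small_example(self):
        fm = np.array([[1.0, 2.0], [3.0, 4.0]])[:, :, None]
        assert global_average_pool(fm)[0] == 2.5

    def test_matches_triple_loop_oracle(self, rng):
        fm = rng.normal(size=(7, 5, 16))
        expected = np.zeros(16)
        for c in range(16):
            for i in range(7):
                for j in range(5):
                    expected[c] += fm[i, j, c]
        expected /= 35
        np.testing.assert_allclose(global_average_pool(fm), expected, atol=1e-12)

    def test_empty_spatial_extent_rejected(self):
        with pytest.raises(ValueError):
            global_average_pool(np.empty((0, 3, 2)))


class TestEcaAttend:
    def test_zero_kernel_halves_input(self):
        spec = eca_spec(8, conv_weights=np.zeros(eca_kernel_size(8)))
        pooled = np.arange(8.0)
        w, a = eca_attend(pooled, spec)
        np.testing.assert_allclose(w, 0.5)
        np.testing.assert_allclose(a, pooled / 2)

    def test_weights_strictly_in_unit_interval(self, rng):
        for C in (8, 32, 128, 512):
            spec = eca_spec(C, seed=C)
            w, a = eca_attend(rng.normal(scale=5.0, size=C), spec)
            assert (w > 0).all() and (w < 1).all()
            # attention attenuates: |attended| <= |pooled|
            pooled = rng.normal(size=C)
            w2, a2 = eca_attend(pooled, spec)
            assert (np.abs(a2) <= np.abs(pooled) + 1e-15).all()

    def test_matches_loop_oracle(self, rng):
        spec = eca_spec(32, seed=3)
        pooled = rng.normal(size=32)
        w, a = eca_attend(pooled, spec)
        expected_w = eca_loop_oracle(pooled, spec.conv_weights)
        np.testing.assert_allclose(w, expected_w, atol=1e-6)
        np.testing.assert_allclose(a, expected_w * pooled, atol=1e-6)


# ---------------------------------------------------------------------------
# residual blocks and branches
# ---------------------------------------------------------------------------

class TestResidualBlock:
    def test_zero_residual_path_is_identity_on_nonnegative(self, rng):
        spec = ResidualBlockSpec(4, 4, 1)
        params = init_residual_params(spec, 0)
        params["conv1_w"][...] = 0.0
        params["conv2_w"][...] = 0.0
        x = np.abs(rng.normal(size=(1, 8, 8, 4)))
        np.testing.assert_array_equal(residual_block_forward(x, spec, params), x)

    def test_stride_two_downsamples_and_widens(self, rng):
        spec = ResidualBlockSpec(64, 128, 2)
        params = init_residual_params(spec, 1)
        y = residual_block_forward(rng.normal(size=(1, 56, 56, 64)), spec, params)
        assert y.shape == (1, 28, 28, 128)

    @pytest.mark.parametrize("stride,cin,cout", [(1, 4, 4), (2, 4, 6)])
    def test_matches_naive_convolution_oracle(self, rng, stride, cin, cout):
        spec = ResidualBlockSpec(cin, cout, stride)
        params = init_residual_params(spec, 42)
        x = rng.normal(size=(8, 8, cin))
        got = residual_block_forward(x, spec, params)
        expected = residual_loop_oracle(x, spec, params)
        np.testing.assert_allclose(got, expected, atol=1e-5)

    def test_gradient_passes_unchanged_through_zero_residual_path(self, rng):
        # the additive shortcut keeps d(out)/d(in) = dF/dx + I; with F == 0
        # the block's backward pass returns the upstream gradient untouched
        block = nn.ResidualBlock(3, 3, 1, np.random.default_rng(0))
        block.conv1.params["w"][...] = 0.0
        block.conv2.params["w"][...] = 0.0
        x = np.abs(rng.normal(size=(2, 3, 6, 6))) + 0.1
        block.forward(x, train=False)
        dy = rng.normal(size=(2, 3, 6, 6))
        np.testing.assert_allclose(block.backward(dy), dy, atol=1e-12)

    def test_channel_mismatch_rejected(self, rng):
        spec = ResidualBlockSpec(4, 4, 1)
        with pytest.raises(ValueError, match="input must be"):
            residual_block_forward(rng.normal(size=(1, 8, 8, 3)), spec,
                                   init_residual_params(spec))


class TestBranch:
    def test_full_preset_stage_sizes_on_square_probe(self, rng):
        br = build_branch(branch_spec("full", (224, 224)), 0)
        v = br.forward(rng.normal(size=(1, 1, 224, 224)))
        assert v.shape == (1, 512)
        assert br.stage_output_sizes == [(56, 56), (28, 28), (14, 14), (7, 7)]

    def test_full_preset_on_emg_window(self, rng):
        br = build_branch(branch_spec("full", (12, 400)), 0)
        v = br.forward(rng.normal(size=(1, 1, 12, 400)))
        assert v.shape == (1, 512)

    def test_small_preset_vector_length(self, rng):
        br = build_branch(branch_spec("small", (36, 100)), 0)
        v = br.forward(rng.normal(size=(3, 1, 36, 100)))
        assert v.shape == (3, 32)

    def test_window_thinner_than_stem_rejected(self):
        with pytest.raises(ValueError, match="stem"):
            branch_spec("full", (12, 4))


@pytest.fixture(scope="module")
def small_model():
    return build_two_stream(two_stream_spec(64, n_classes=5, preset="small", seed=0))


class TestTwoStream:
    def test_full_preset_fused_length(self):
        spec = two_stream_spec(400, n_classes=49, preset="full")
        assert spec.fused_length == 1024

    def test_probabilities_sum_to_one(self, small_model, rng):
        p = forward(small_model, rng.normal(size=(12, 64)), rng.normal(size=(36, 64)))
        assert p.shape == (5,)
        assert (p >= 0).all()
        assert abs(p.sum() - 1.0) < 1e-6

    def test_inference_is_deterministic_despite_dropout(self, small_model, rng):
        emg, acc = rng.normal(size=(4, 12, 64)), rng.normal(size=(4, 36, 64))
        p1 = small_model.predict_proba(emg, acc)
        p2 = small_model.predict_proba(emg, acc)
        np.testing.assert_array_equal(p1, p2)

    def test_permuting_batch_permutes_outputs(self, small_model, rng):
        emg, acc = rng.normal(size=(6, 12, 64)), rng.normal(size=(6, 36, 64))
        perm = np.array([3, 0, 5, 1, 4, 2])
        p = small_model.predict_proba(emg, acc)
        pp = small_model.predict_proba(emg[perm], acc[perm])
        np.testing.assert_allclose(pp, p[perm], atol=1e-6)

    def test_zero_init_head_gives_uniform_probabilities(self, rng):
        model = build_two_stream(two_stream_spec(64, n_classes=5, preset="small", seed=1))
        model.head.fc2.params["w"][...] = 0.0
        model.head.fc2.params["b"][...] = 0.0
        p = forward(model, rng.normal(size=(12, 64)), rng.normal(size=(36, 64)))
        np.testing.assert_allclose(p, 0.2, atol=1e-7)

    def test_mismatched_pair_counts_rejected(self, small_model, rng):
        with pytest.raises(ValueError, match="paired"):
            small_model.forward_logits(
                rng.normal(size=(3, 12, 64)), rng.normal(size=(4, 36, 64))
            )

    def test_invalid_class_count_rejected(self):
        with pytest.raises(ValueError, match="n_classes"):
            two_stream_spec(64, n_classes=1, preset="small")
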