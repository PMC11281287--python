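"""Band-attention block and residual backbone: pooling oracles, the shared
MLP, the identity at zero initialisation, and structural properties."""

import numpy as np
import pytest

from specband.model import (AttentionParams, WaterDeficitClassifier,
                            attention_forward, bottleneck_width, classify,
                            load_checkpoint, model_forward, save_checkpoint,
                            shared_mlp, spectral_pool_avg, spectral_pool_max)

rng = np.random.default_rng(42)


class TestSpectralPooling:
    def test_constant_cube(self):
        h = np.full((3, 4, 4), 0.3)
        np.testing.assert_allclose(spectral_pool_avg(h), 0.3)
        np.testing.assert_allclose(spectral_pool_max(h), 0.3)

    def test_single_channel_arithmetic(self):
        h = np.array([[[1.0, 2.0], [3.0, 4.0]]])
        assert spectral_pool_avg(h)[0] == pytest.approx(2.5)
        assert spectral_pool_max(h)[0] == 4.0

    def test_matches_loop_oracle_on_random_cubes(self):
        for _ in range(20):
            h = rng.normal(size=(5, 4, 4))
            avg = np.array([sum(h[c, i, j] for i in range(4) for j in range(4)) / 16
                            for c in range(5)])
            mx = np.array([max(h[c, i, j] for i in range(4) for j in range(4))
                           for c in range(5)])
            np.testing.assert_allclose(spectral_pool_avg(h), avg, rtol=1e-6)
            np.testing.assert_allclose(spectral_pool_max(h), mx, rtol=1e-6)

    def test_empty_spatial_extent_rejected(self):
        with pytest.raises(ValueError, match="empty spatial"):
            spectral_pool_avg(np.zeros((3, 0, 4)))


class TestSharedMLP:
    def test_zero_parameters_give_one_half(self):
        params = AttentionParams.zeros(6)
        np.testing.assert_allclose(shared_mlp(np.ones(6), params), 0.5)

    def test_bottleneck_is_half_the_channel_count(self):
        assert bottleneck_width(428) == 214
        assert AttentionParams.zeros(428).w1.shape == (214, 428)
        assert bottleneck_width(7) == 3  # floor for odd C

    def test_two_channel_hand_computed_forward_pass(self):
        params = AttentionParams(
            w1=np.array([[1.0, -1.0]]), b1=np.array([0.5]),
            w2=np.array([[2.0], [-1.0]]), b2=np.array([0.0, 1.0]))
        z = np.array([0.8, 0.2])
        # hidden = relu(0.8 - 0.2 + 0.5) = 1.1; s = sigmoid([2.2, -0.1])
        expected = 1 / (1 + np.exp(-np.array([2.2, -1.1 + 1.0])))
        np.testing.assert_allclose(shared_mlp(z, params), expected, rtol=1e-12)

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError, match="expected 4"):
            shared_mlp(np.ones(3), AttentionParams.zeros(4))


class TestAttentionForward:
    def test_zero_parameters_make_attention_the_identity(self):
        h = rng.uniform(0, 1, size=(6, 5, 5)).astype(np.float32)
        maps = attention_forward(h, AttentionParams.zeros(6))
        np.testing.assert_array_equal(maps.m, 1.0)
        np.testing.assert_array_equal(maps.h_l, h)
        np.testing.assert_array_equal(maps.s_avg, 0.5)
        np.testing.assert_array_equal(maps.s_max, 0.5)

    def test_m_strictly_inside_zero_two(self):
        params = AttentionParams(
            w1=rng.normal(size=(3, 6)), b1=rng.normal(size=3),
            w2=rng.normal(size=(6, 3)) * 5, b2=rng.normal(size=6) * 5)
        h = rng.uniform(0, 1, size=(6, 4, 4))
        maps = attention_forward(h, params)
        assert np.all(maps.m > 0) and np.all(maps.m < 2)
        np.testing.assert_allclose(maps.m, maps.s_avg + maps.s_max)
        np.testing.assert_allclose(maps.h_l, maps.m[:, None, None] * h, rtol=1e-6)

    def test_doubling_one_channel_only_moves_its_own_z(self):
        h = rng.uniform(0.1, 0.9, size=(5, 4, 4))
        h2 = h.copy()
        h2[3] *= 2
        params = AttentionParams.zeros(5)
        a, b = attention_forward(h, params), attention_forward(h2, params)
        changed = np.flatnonzero(a.z_avg != b.z_avg)
        np.testing.assert_array_equal(changed, [3])
        np.testing.assert_array_equal(np.flatnonzero(a.z_max != b.z_max), [3])

    def test_channel_permutation_equivariance(self):
        c, hid = 8, 4
        params = AttentionParams(
            w1=rng.normal(size=(hid, c)), b1=rng.normal(size=hid),
            w2=rng.normal(size=(c, hid)), b2=rng.normal(size=c))
        h = rng.uniform(0, 1, size=(c, 3, 3))
        perm = rng.permutation(c)
        permuted = AttentionParams(w1=params.w1[:, perm], b1=params.b1,
                                   w2=params.w2[perm], b2=params.b2[perm])
        m_perm = attention_forward(h[perm], permuted).m
        m_base = attention_forward(h, params).m
        np.testing.assert_allclose(m_perm, m_base[perm], rtol=1e-10)


class TestBackbone:
    def test_parameter_count_matches_closed_form(self):
        c, w = 12, (8, 16, 32, 64)
        model = WaterDeficitClassifier(c, widths=w, seed=0)
        n_attn = (c // 2) * c + c // 2 + c * (c // 2) + c
        expected = n_attn + _resnet18_param_count(c, w)
        assert sum(p.data.size for p in model.parameters()) == expected

    def test_probability_range_and_inference_determinism(self):
        model = WaterDeficitClassifier(6, widths=(4, 8, 8, 8), seed=1)
        h = rng.uniform(0, 1, size=(6, 50, 50)).astype(np.float32)
        p1, p2 = model_forward(h, model), model_forward(h, model)
        assert 0 < p1 < 1
        assert p1 == p2

    def test_wrong_spatial_size_reports_shapes(self):
        model = WaterDeficitClassifier(6, widths=(4, 8, 8, 8), seed=1)
        with pytest.raises(ValueError, match=r"\(6, 50, 50\)"):
            model_forward(np.zeros((6, 64, 64), np.float32), model)

    def test_residual_block_with_zero_branch_is_identity(self):
        from specband.model import BasicBlock
        from specband.nn import Tensor
        block = BasicBlock(8, 8, 1, np.random.default_rng(0))
        block.conv2.weight.data[...] = 0.0  # forces f(x) = 0 after bn2(0)=0
        x = np.abs(rng.normal(size=(2, 8, 7, 7))).astype(np.float32)
        out = block(Tensor(x), train=False)
        np.testing.assert_allclose(out.data, x, atol=1e-6)

    def test_checkpoint_round_trip(self, tmp_path):
        model = WaterDeficitClassifier(6, widths=(4, 8, 8, 8), seed=3)
        h = rng.uniform(0, 1, size=(6, 50, 50)).astype(np.float32)
        p_before = model_forward(h, model)
        path = tmp_path / "model.npz"
        save_checkpoint(model, path)
        back = load_checkpoint(path)
        assert back.n_channels == 6 and back.widths == (4, 8, 8, 8)
        assert model_forward(h, back) == p_before


def _resnet18_param_count(c_in, w):
    """Closed-form parameter count of the 18-layer design (convs without
    bias, BN gamma+beta, 1-logit FC head)."""
    n = c_in * w[0] * 49 + 2 * w[0]  # stem conv + BN
    prev = w[0]
    for i, width in enumerate(w):
        stride = 1 if i == 0 else 2
        # first block (possibly projecting), then an identity block
        n += prev * width * 9 + 2 * width + width * width * 9 + 2 * width
        if stride != 1 or prev != width:
            n += prev * width + 2 * width
        n += 2 * (width * width * 9 + 2 * width)
        prev = width
    return n + w[-1] + 1  # FC head


@pytest.mark.parametrize("p, expected", [(0.74, 1), (0.26, 0), (0.5, 1)])
def test_classify_threshold_boundary(p, expected):
    assert classify(p) == expected


def test_classify_rejects_invalid_probability():
    with pytest.raises(ValueError):
        classify(1.3)
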