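"""Network shape algebra, parameter counting and layer numerics.

Numerical layers are checked against independent brute-force oracles
(triple-loop convolution, explicit window maxima, layer-by-layer forward).
"""

import numpy as np
import pytest

from shocknet.model import (HPConfig, conv1d_block, count_params, forward,
                            init_params, layer_shapes, load_model, maxpool,
                            save_model)

TABLE_CONFIGS = {
    # depth-indexed optima (single sigmoid head)
    1: ((113,), (50,), (), 5877),
    2: ((10, 15), (60, 25), (), 4391),
    3: ((5, 10, 20), (10, 30, 50), (), 11606),
    4: ((15, 15, 15, 10), (20, 25, 30, 40), (), 18741),
    5: ((20, 15, 15, 10, 5), (10, 10, 10, 10, 10), (), 7521),
    6: ((30, 30, 15, 15, 10, 5), (15, 10, 10, 10, 10, 10), (), 18311),
    7: ((40, 30, 25, 15, 10, 5, 5), (15, 5, 5, 5, 5, 5, 5), (), 13486),
}
COMPARATIVE_CONFIGS = [
    ((8, 8, 8, 8), (7, 7, 7, 7), (), 1441),
    ((32, 16, 8), (5, 5, 5), (), 3425),
    ((32, 16), (15, 15), (10,), 8389),
]


def brute_conv(x, w, b):
    """Triple-loop valid cross-correlation + ReLU; x (L, C), w (F, C, K)."""
    length, c = x.shape
    f, _, k = w.shape
    out = np.zeros((length - k + 1, f))
    for j in range(length - k + 1):
        for fi in range(f):
            acc = b[fi]
            for ci in range(c):
                for ki in range(k):
                    acc += w[fi, ci, ki] * x[j + ki, ci]
            out[j, fi] = max(acc, 0.0)
    return out


def brute_pool(v, mp):
    """Explicit window maxima; trailing short window pooled on its own."""
    return np.array([max(v[i:i + mp]) for i in range(0, len(v), mp)])


class TestCountParams:
    @pytest.mark.parametrize("n", sorted(TABLE_CONFIGS))
    def test_depth_optima(self, n):
        f, k, dh, expected = TABLE_CONFIGS[n]
        cfg = HPConfig(n_blocks=n, filters=f, kernels=k, dense_hidden=dh)
        assert count_params(cfg) == expected

    @pytest.mark.parametrize("f,k,dh,expected", COMPARATIVE_CONFIGS)
    def test_comparative_architectures(self, f, k, dh, expected):
        cfg = HPConfig(n_blocks=len(f), filters=f, kernels=k, dense_hidden=dh)
        assert count_params(cfg) == expected

    def test_minimal_network_hand_count(self):
        # 1 kernel weight + 1 conv bias + 1 dense weight + 1 dense bias
        assert count_params(HPConfig(1, (1,), (1,))) == 4

    def test_count_equals_instantiated_scalars(self, rng):
        for _ in range(20):
            n = int(rng.integers(1, 5))
            f = tuple(int(v) for v in rng.integers(1, 30, size=n))
            k = tuple(int(v) for v in rng.integers(1, 20, size=n))
            dh = tuple(int(v) for v in rng.integers(1, 10, size=int(rng.integers(0, 3))))
            cfg = HPConfig(n, f, k, dense_hidden=dh)
            assert count_params(cfg) == init_params(cfg, seed=0).n_scalars()

    def test_independent_of_input_length(self):
        a = HPConfig(2, (4, 3), (5, 5), input_len=250)
        b = HPConfig(2, (4, 3), (5, 5), input_len=1250)
        assert count_params(a) == count_params(b)


class TestLayerShapes:
    def test_best_model_recurrence(self):
        cfg = HPConfig(5, (20, 15, 15, 10, 5), (10,) * 5, input_len=625)
        s = layer_shapes(cfg)
        assert s.pooled_len == (308, 150, 71, 31, 11)
        assert s.feasible

    def test_all_depth_optima_feasible_at_625(self):
        for n, (f, k, dh, _) in TABLE_CONFIGS.items():
            cfg = HPConfig(n, f, k, dense_hidden=dh, input_len=625)
            assert layer_shapes(cfg).feasible, f"depth {n} infeasible"

    def test_oversized_kernels_infeasible_at_block3(self):
        cfg = HPConfig(7, (5,) * 7, (100,) * 7, input_len=625)
        s = layer_shapes(cfg)
        assert not s.feasible
        assert s.pooled_len[1] == 82  # 82 < 100: block 3 cannot convolve
        assert s.conv_len[2] < 1

    def test_kernel_equal_to_input(self):
        # length-1 conv output pools to a single value: still feasible
        s = layer_shapes(HPConfig(1, (3,), (20,), input_len=20))
        assert s.conv_len == (1,) and s.pooled_len == (1,) and s.feasible


class TestConvBlock:
    def test_hand_example(self):
        x = np.array([[1.0], [2.0], [3.0], [4.0]])
        w = np.array([[[1.0, 0.0, -1.0]]])
        out = conv1d_block(x[None], w, np.zeros(1))[0]
        # pre-activation [-2, -2] clips to zero under ReLU
        assert np.array_equal(out, [[0.0], [0.0]])

    def test_zero_weights_zero_output(self, rng):
        x = rng.normal(size=(2, 30, 3))
        out = conv1d_block(x, np.zeros((4, 3, 5)), np.zeros(4))
        assert np.all(out == 0.0)

    def test_matches_brute_force(self, rng):
        for _ in range(5):
            length, c, f, k = 40, 3, 4, 7
            x = rng.normal(size=(2, length, c))
            w = rng.normal(size=(f, c, k))
            b = rng.normal(size=f)
            got = conv1d_block(x, w, b)
            for bi in range(2):
                want = brute_conv(x[bi], w, b)
                np.testing.assert_allclose(got[bi], want, rtol=1e-6, atol=1e-12)

    def test_short_input_rejected(self, rng):
        with pytest.raises(ValueError):
            conv1d_block(rng.normal(size=(1, 3, 1)), np.zeros((1, 1, 5)), np.zeros(1))


class TestMaxPool:
    @pytest.mark.parametrize("v,mp,expected", [
        ([1, 3, 2, 5], 2, [3, 5]),
        ([1, 3, 2, 5, 9], 2, [3, 5, 9]),   # trailing window pooled on its own
        ([4, 4, 4, 4, 4, 4], 2, [4, 4, 4]),
    ])
    def test_examples(self, v, mp, expected):
        assert maxpool(np.array(v, dtype=float), mp).tolist() == expected

    def test_matches_brute_force(self, rng):
        for n in (6, 7, 9, 10):
            v = rng.normal(size=n)
            np.testing.assert_array_equal(maxpool(v, 2), brute_pool(v, 2))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            maxpool(np.array([]), 2)


class TestForward:
    def test_zero_params_give_half(self):
        cfg = HPConfig(1, (2,), (3,), input_len=10)
        p = init_params(cfg, seed=0)
        for arr in p.flat():
            arr[:] = 0.0
        out = forward(cfg, p, np.ones((3, 10)))
        assert np.allclose(out, 0.5)

    def test_probability_range(self, rng):
        cfg = HPConfig(2, (4, 3), (5, 3), input_len=50)
        p = init_params(cfg, seed=1)
        out = forward(cfg, p, rng.normal(scale=100, size=(20, 50)))
        assert np.all((out > 0) & (out < 1))

    def test_matches_layerwise_oracle(self, rng):
        cfg = HPConfig(2, (3, 2), (4, 3), input_len=30)
        p = init_params(cfg, seed=5)
        x = rng.normal(size=30)
        a = x[:, None]
        for w, b in zip(p.conv_w, p.conv_b):
            conv = brute_conv(a, w, b)
            a = np.stack([brute_pool(conv[:, fi], 2) for fi in range(conv.shape[1])], axis=1)
        g = a.max(axis=0)
        z = float((p.dense_w[-1] @ g + p.dense_b[-1])[0])
        want = 1.0 / (1.0 + np.exp(-z))
        got = forward(cfg, p, x)[0]
        np.testing.assert_allclose(got, want, rtol=1e-6)

    def test_same_params_serve_any_window_length(self, rng):
        cfg_a = HPConfig(2, (4, 3), (5, 3), input_len=250)
        cfg_b = HPConfig(2, (4, 3), (5, 3), input_len=1250)
        p = init_params(cfg_a, seed=2)
        forward(cfg_a, p, rng.normal(size=(2, 250)))
        forward(cfg_b, p, rng.normal(size=(2, 1250)))  # no shape error

    def test_relu_maps_nonnegative(self, rng):
        x = rng.normal(size=(2, 20, 2))
        out = conv1d_block(x, rng.normal(size=(3, 2, 4)), rng.normal(size=3))
        assert np.all(out >= 0.0)

    def test_wrong_window_length_rejected(self, rng):
        cfg = HPConfig(1, (2,), (3,), input_len=10)
        with pytest.raises(ValueError):
            forward(cfg, init_params(cfg), rng.normal(size=(1, 11)))


class TestModelStore:
    def test_hdf5_round_trip_bit_exact(self, tmp_path, rng):
        cfg = HPConfig(3, (4, 3, 2), (5, 3, 3), input_len=100, dense_hidden=(6,))
        p = init_params(cfg, seed=9)
        path = tmp_path / "model.h5"
        save_model(path, cfg, p, meta={"note": "test"})
        cfg2, p2, meta = load_model(path)
        assert cfg2 == cfg and meta == {"note": "test"}
        for a, b in zip(p.flat(), p2.flat()):
            assert np.array_equal(a, b)
        x = rng.normal(size=(4, 100))
        assert np.array_equal(forward(cfg, p, x), forward(cfg2, p2, x))
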