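"""Deformable convolution/pooling, heads, training and hyperparameter tuning."""

import numpy as np
import pytest

from ocuclean import dcn, dsefo, metrics


class TestInterpolation:
    @pytest.mark.parametrize(
        "v,it,expected", [(3, 3, 1.0), (3, 4.2, 0.0), (0, 0.25, 0.75)]
    )
    def test_triangular_kernel_values(self, v, it, expected):
        assert dcn.interp_kernel(v, it) == pytest.approx(expected)

    def test_integer_position_returns_exact_sample(self, rng):
        f = rng.standard_normal(10)
        for i in range(10):
            assert dcn.sample_fractional(f, float(i)) == pytest.approx(f[i])

    def test_halfway_position_returns_mean(self, rng):
        f = rng.standard_normal(10)
        assert dcn.sample_fractional(f, 3.5) == pytest.approx((f[3] + f[4]) / 2)

    def test_matches_full_kernel_summation(self, rng):
        f = rng.standard_normal(16)
        for _ in range(20):
            it = rng.uniform(-2, 18)
            brute = sum(dcn.interp_kernel(v, it) * f[v] for v in range(16))
            assert dcn.sample_fractional(f, it) == pytest.approx(brute, abs=1e-12)

    def test_out_of_range_contributes_zero(self):
        f = np.ones(5)
        assert dcn.sample_fractional(f, -2.0) == 0.0
        assert dcn.sample_fractional(f, 7.0) == 0.0


def _brute_deformable_conv(x, layer):
    B, C, T = x.shape
    delta = dcn._conv_same(x, layer.Wo, layer.bo)
    y = np.zeros((B, layer.out_ch, T))
    for b in range(B):
        for o in range(layer.out_ch):
            for t in range(T):
                acc = 0.0
                for c in range(C):
                    for n in range(layer.k):
                        it = t + n - layer.k // 2 + delta[b, n, t]
                        acc += layer.W[o, c, n] * dcn.sample_fractional(x[b, c], it)
                y[b, o, t] = acc
    return y


def _brute_deformable_pool(x, layer):
    B, C, T = x.shape
    t_out = layer.out_length(T)
    delta = dcn._conv_strided(x, layer.Wo, layer.bo, layer.stride, t_out)
    y = np.zeros((B, C, t_out))
    for b in range(B):
        for c in range(C):
            for t0 in range(t_out):
                acc = 0.0
                for n in range(layer.window):
                    it = t0 * layer.stride + n + delta[b, n, t0]
                    acc += dcn.sample_fractional(x[b, c], it)
                y[b, c, t0] = acc / layer.window
    return y


class TestDeformableForward:
    def test_conv_matches_bruteforce_on_random_cases(self, rng):
        for _ in range(10):
            c_in = int(rng.integers(1, 4))
            layer = dcn.DeformableConv1d(c_in, int(rng.integers(1, 4)), 3, rng)
            layer.Wo = rng.normal(0, 0.3, layer.Wo.shape)
            layer.bo = rng.normal(0, 0.3, layer.bo.shape)
            x = rng.standard_normal((2, c_in, int(rng.integers(8, 20))))
            np.testing.assert_allclose(
                layer.forward(x), _brute_deformable_conv(x, layer), atol=1e-6
            )

    def test_pool_matches_bruteforce_on_random_cases(self, rng):
        for _ in range(10):
            c_in = int(rng.integers(1, 4))
            layer = dcn.DeformablePool1d(c_in, 2, rng)
            layer.Wo = rng.normal(0, 0.3, layer.Wo.shape)
            layer.bo = rng.normal(0, 0.3, layer.bo.shape)
            x = rng.standard_normal((2, c_in, int(rng.integers(8, 20)) // 2 * 2))
            np.testing.assert_allclose(
                layer.forward(x), _brute_deformable_pool(x, layer), atol=1e-6
            )

    def test_zero_offsets_reduce_to_standard_convolution(self, rng):
        layer = dcn.DeformableConv1d(2, 3, 3, rng)  # offsets zero-initialized
        x = rng.standard_normal((2, 2, 16))
        expected = dcn._conv_same(x, layer.W, np.zeros(3))
        np.testing.assert_allclose(layer.forward(x), expected, atol=1e-12)

    def test_zero_offsets_pool_is_plain_average(self, rng):
        layer = dcn.DeformablePool1d(1, 2, rng)
        x = rng.standard_normal((1, 1, 10))
        expected = x.reshape(1, 1, 5, 2).mean(axis=3)
        np.testing.assert_allclose(layer.forward(x), expected, atol=1e-12)

    def test_zero_input_gives_zero_output(self, rng):
        layer = dcn.DeformableConv1d(1, 2, 3, rng)
        assert np.all(layer.forward(np.zeros((1, 1, 12))) == 0)

    def test_constant_input_constant_pool(self, rng):
        layer = dcn.DeformablePool1d(1, 2, rng)
        out = layer.forward(np.full((1, 1, 8), 2.5))
        np.testing.assert_allclose(out, 2.5)


class TestGradients:
    def test_backward_matches_finite_differences(self, rng):
        layer = dcn.DeformableConv1d(2, 2, 3, rng)
        layer.Wo = rng.normal(0, 0.1, layer.Wo.shape)
        x = rng.standard_normal((2, 2, 10))
        R = rng.standard_normal((2, 2, 10))
        layer.forward(x, train=True)
        _, grads = layer.backward(R)
        for name in ("W", "Wo", "bo"):
            P = layer.params()[name]
            for _ in range(3):
                ix = tuple(rng.integers(0, s) for s in P.shape)
                eps = 1e-6
                old = P[ix]
                P[ix] = old + eps
                lp = float((layer.forward(x) * R).sum())
                P[ix] = old - eps
                lm = float((layer.forward(x) * R).sum())
                P[ix] = old
                num = (lp - lm) / (2 * eps)
                assert num == pytest.approx(grads[name][ix], rel=1e-4, abs=1e-7)


class TestHeads:
    def test_zero_weight_detector_outputs_half_and_negative_label(self, rng):
        model = dcn.build_model((("flatten",), ("dense", 1)), 1, 4, "detector", seed=0)
        dense = model.layers[-1]
        dense.W[:] = 0
        dense.b[:] = 0
        x = rng.standard_normal((3, 1, 4))
        np.testing.assert_allclose(model.forward(x), 0.5)
        assert np.all(model.predict(x) == 0)  # tie 0.5 -> negative class

    def test_denoiser_affine_head_matches_manual_matmul(self, rng):
        model = dcn.build_model((("conv", 1, 1),), 1, 3, "denoiser", seed=1)
        conv = model.layers[0]
        x = rng.standard_normal((2, 1, 3))
        expected = x * conv.W[0, 0, 0] + conv.b[0]
        np.testing.assert_allclose(model.forward(x), expected, atol=1e-12)


class TestTraining:
    def test_separable_gaussians_reach_high_accuracy(self, rng):
        n = 200
        y = (np.arange(n) % 2).astype(float)
        X = rng.normal(0, 1, (n, 1, 2))
        X[y == 1] += 6.0  # 6 sigma separation
        model = dcn.build_model((("flatten",), ("dense", 1)), 1, 2, "detector", seed=0)
        dcn.train(model, X, y, dcn.NetworkConfig(epochs=20, learning_rate=0.3, seed=0))
        assert (model.predict(X) == y).mean() >= 0.95

    def test_identity_denoising_converges(self, rng):
        X = rng.standard_normal((64, 1, 40))
        spec = (("dconv", 4, 3), ("conv", 1, 1))
        model = dcn.build_model(spec, 1, 40, "denoiser", seed=0)
        # 200 epochs total with an annealed rate (MAE floor scales with lr)
        for rep, lr in enumerate([0.5, 0.3, 0.2, 0.1, 0.05, 0.05, 0.02, 0.02, 0.01, 0.01]):
            dcn.train(model, X, X, dcn.NetworkConfig(epochs=20, learning_rate=lr, seed=rep))
        mae = np.mean(np.abs(model.forward(X) - X))
        assert mae <= 0.05 * X.std()

    def test_training_loss_decreases_on_identity_task(self, rng):
        X = rng.standard_normal((64, 1, 30))
        model = dcn.build_model((("dconv", 4, 3), ("conv", 1, 1)), 1, 30, "denoiser", seed=0)
        dcn.train(model, X, X, dcn.NetworkConfig(epochs=20, learning_rate=0.2, seed=0))
        curve = np.array(model.loss_curve)
        smooth = np.convolve(curve, np.ones(5) / 5, mode="valid")
        assert smooth[-1] < smooth[0]

    def test_seeded_training_is_deterministic(self, rng):
        X = rng.standard_normal((40, 1, 16))
        y = (rng.uniform(size=40) > 0.5).astype(float)
        weights = []
        for _ in range(2):
            m = dcn.build_model(dcn.DETECTOR_SPEC, 1, 16, "detector", seed=5)
            dcn.train(m, X, y, dcn.NetworkConfig(epochs=10, learning_rate=0.2, seed=5))
            weights.append(
                [p.copy() for layer in m.layers for p in layer.params().values()]
            )
        for a, b in zip(*weights):
            np.testing.assert_array_equal(a, b)

    def test_divergent_loss_aborts_with_diagnostic(self, rng):
        X = rng.standard_normal((16, 1, 8)) * 1e200
        model = dcn.build_model((("flatten",), ("dense", 1)), 1, 8, "denoiser", seed=0)
        model.layers[-1].W[:] = 1e200  # overflow -> non-finite loss
        targets = np.zeros((16, 1))
        with pytest.raises(dcn.TrainingDivergedError):
            dcn.train(
                model, X, targets, dcn.NetworkConfig(epochs=2, learning_rate=0.9, seed=0)
            )


class TestTuning:
    def test_returns_integer_epochs_within_box(self, rng):
        n = 60
        y = (np.arange(n) % 2).astype(float)
        X = rng.normal(0, 1, (n, 1, 4))
        X[y == 1, 0, :2] += 4.0
        params = dsefo.EFOParams(
            bounds=np.array([dcn.EPOCH_RANGE, dcn.LR_RANGE], dtype=float),
            pop_size=4,
            iterations=3,
            seed=0,
        )
        cfg = dcn.tune_hyperparams(
            (("flatten",), ("dense", 1)),
            "detector",
            X[:40],
            y[:40],
            X[40:],
            y[40:],
            dsefo_params=params,
        )
        assert isinstance(cfg.epochs, int)
        assert dcn.EPOCH_RANGE[0] <= cfg.epochs <= dcn.EPOCH_RANGE[1]
        assert dcn.LR_RANGE[0] <= cfg.learning_rate <= dcn.LR_RANGE[1]

    def test_fitness_of_perfect_classifier_is_half(self):
        assert metrics.fitness_detection(1.0, 1.0) == 0.5

    def test_fitness_at_reported_operating_point(self):
        assert metrics.fitness_detection(0.944, 0.701) == pytest.approx(0.6079, abs=2e-4)
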