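import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from szcast import network as nn
from szcast import preprocess as pp

from conftest import mean_score_auc


def tiny_dense_spec(shape=(1, 4, 4)):
    """Smallest spec producing a 2-vector output (flatten -> dense)."""
    return nn.NetworkSpec(
        shape[0],
        [nn.FlattenSpec(), nn.DenseSpec(2)],
        input_shape=shape[1:],
    )


# ---------------------------------------------------------------------------
# KL divergence


class TestKLGaussian:
    def test_identical_distributions_zero(self):
        assert nn.kl_gaussian(np.zeros(5), np.ones(5)) == pytest.approx(0.0)

    def test_unit_mean_shift_half(self):
        assert nn.kl_gaussian(np.array(1.0), np.array(1.0)) == pytest.approx(0.5)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            nn.kl_gaussian(np.zeros(2), np.array([1.0, 0.0]))

    def test_monte_carlo_oracle(self):
        # oracle: E_q[log q - log p] estimated from 1e6 draws
        rng = np.random.default_rng(0)
        mu, sigma = 0.3, 0.7
        closed = nn.kl_gaussian(np.array(mu), np.array(sigma))
        z = rng.normal(mu, sigma, 1_000_000)
        log_q = -0.5 * np.log(2 * np.pi * sigma**2) - (z - mu) ** 2 / (2 * sigma**2)
        log_p = -0.5 * np.log(2 * np.pi) - z**2 / 2
        diffs = log_q - log_p
        mc = diffs.mean()
        se = diffs.std(ddof=1) / np.sqrt(len(diffs))
        assert abs(closed - mc) < 3 * se

    def test_zero_iff_posterior_equals_prior(self):
        assert nn.kl_gaussian(np.zeros(3), np.ones(3), 0.0, 1.0) == 0.0
        assert nn.kl_gaussian(np.full(3, 0.01), np.ones(3)) > 0
        assert nn.kl_gaussian(np.zeros(3), np.full(3, 1.01)) > 0


# ---------------------------------------------------------------------------
# weight sampling


class TestSampleWeights:
    def test_sigma_zero_limit_equals_mu(self):
        spec = tiny_dense_spec()
        layers = nn.init_layers(spec, 0, sigma_init=1e-12)
        real = nn.sample_weights(spec, layers, 1)
        np.testing.assert_allclose(real[0]["w"], layers[0].mu_w, atol=1e-9)

    def test_same_seed_identical(self):
        spec = tiny_dense_spec()
        layers = nn.init_layers(spec, 0)
        a = nn.sample_weights(spec, layers, 7)
        b = nn.sample_weights(spec, layers, 7)
        np.testing.assert_array_equal(a[0]["w"], b[0]["w"])

    def test_sampling_oracle_mean_sd(self):
        # 1e4 realizations of one weight match (mu, sigma) within 3 se
        spec = tiny_dense_spec((1, 2, 2))
        layers = nn.init_layers(spec, 3, sigma_init=0.2)
        mu = layers[0].mu_w[0, 0]
        sigma = layers[0].sigma_w[0, 0]
        rng = np.random.default_rng(11)
        draws = np.array(
            [nn.sample_weights(spec, layers, rng)[0]["w"][0, 0] for _ in range(10_000)]
        )
        assert abs(draws.mean() - mu) < 3 * sigma / np.sqrt(len(draws))
        sd_se = sigma / np.sqrt(2 * (len(draws) - 1))
        assert abs(draws.std(ddof=1) - sigma) < 3 * sd_se

    def test_shape_mismatch_rejected(self):
        spec = tiny_dense_spec()
        layers = nn.init_layers(tiny_dense_spec((1, 3, 3)), 0)
        with pytest.raises(ValueError):
            nn.sample_weights(spec, layers, 0)


# ---------------------------------------------------------------------------
# forward pass


class TestForward:
    def test_all_zero_weights_zero_outputs(self):
        spec = tiny_dense_spec()
        real = [
            {"w": np.zeros((16, 2)), "b": np.zeros(2)},
        ]
        out, _ = nn.forward(spec, real, np.random.default_rng(0).standard_normal((1, 4, 4)))
        np.testing.assert_array_equal(out, [0.0, 0.0])

    def test_toy_conv_hand_computed(self):
        # 1 channel, one 2x2 kernel on a 2x2 input: single dot product
        spec = nn.NetworkSpec(1, [nn.ConvSpec(1, (2, 2))], input_shape=(2, 2))
        x = np.array([[[1.0, 2.0], [3.0, 4.0]]])
        w = np.array([[[[1.0, 0.0], [0.0, 1.0]]]])
        real = [{"w": w, "b": np.array([0.5])}]
        out, fm = nn.forward(spec, real, x)
        assert out[0, 0, 0] == pytest.approx(1.0 + 4.0 + 0.5)
        assert fm[0, 0, 0] == pytest.approx(5.5)

    def test_conv_matches_brute_force_oracle(self):
        # triple-loop valid strided convolution, written independently
        rng = np.random.default_rng(5)
        x = rng.standard_normal((2, 3, 9, 11))
        w = rng.standard_normal((4, 3, 3, 5))
        b = rng.standard_normal(4)
        y, _ = nn.conv2d_forward(x, w, b, (2, 3))
        oh = (9 - 3) // 2 + 1
        ow = (11 - 5) // 3 + 1
        oracle = np.zeros((2, 4, oh, ow))
        for bi in range(2):
            for o in range(4):
                for i in range(oh):
                    for j in range(ow):
                        patch = x[bi, :, 2 * i : 2 * i + 3, 3 * j : 3 * j + 5]
                        oracle[bi, o, i, j] = (patch * w[o]).sum() + b[o]
        np.testing.assert_allclose(y, oracle, atol=1e-10)

    def test_linearity_of_conv_feature_map(self):
        spec = nn.NetworkSpec(1, [nn.ConvSpec(2, (2, 2))], input_shape=(4, 4))
        rng = np.random.default_rng(2)
        real = [{"w": rng.standard_normal((2, 1, 2, 2)), "b": np.zeros(2)}]
        x = np.abs(rng.standard_normal((1, 4, 4)))
        _, fm1 = nn.forward(spec, real, x)
        _, fm2 = nn.forward(spec, real, 2 * x)
        np.testing.assert_allclose(fm2, 2 * fm1, atol=1e-10)

    def test_shape_mismatch_rejected(self):
        spec = tiny_dense_spec()
        layers = nn.init_layers(spec, 0)
        real = nn.sample_weights(spec, layers, 0)
        with pytest.raises(ValueError, match="shape"):
            nn.forward(spec, real, np.zeros((1, 5, 5)))

    def test_reference_architecture_shapes(self):
        spec = nn.default_spec(19)
        shapes = spec.feature_shapes()
        assert shapes[0] == (16, 26, 62)   # conv1: stride-2 valid 5x5
        assert shapes[-2] == (256,)
        assert shapes[-1] == (2,)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_softmax_sums_to_one(self, seed):
        z = np.random.default_rng(seed).standard_normal((3, 2)) * 10
        p = nn.softmax(z)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(p >= 0)


# ---------------------------------------------------------------------------
# ELBO loss


class TestElboLoss:
    def test_confident_correct_near_zero(self):
        outputs = np.array([[10.0, -10.0], [-10.0, 10.0]])
        obj = nn.elbo_loss(outputs, [0, 1], kl_total=5.0, kl_weight=0.0)
        assert obj.total == pytest.approx(0.0, abs=1e-6)

    def test_uniform_outputs_log2(self):
        obj = nn.elbo_loss(np.zeros((4, 2)), [0, 1, 0, 1], 0.0, 0.0)
        assert obj.nll == pytest.approx(np.log(2))

    def test_total_decomposition(self):
        obj = nn.elbo_loss(np.zeros((1, 2)), [0], kl_total=10.0, kl_weight=0.5)
        assert obj.total == pytest.approx(obj.nll + 0.5 * 10.0)

    def test_matches_independent_cross_entropy(self):
        # oracle: scipy-based cross-entropy re-implementation
        from scipy.special import softmax as sp_softmax

        rng = np.random.default_rng(8)
        outputs = rng.standard_normal((10, 2)) * 3
        labels = rng.integers(0, 2, 10)
        p = sp_softmax(outputs, axis=1)
        oracle = -np.log(p[np.arange(10), labels]).mean() + 0.3 * 12.5
        obj = nn.elbo_loss(outputs, labels, 12.5, 0.3)
        assert obj.total == pytest.approx(oracle, rel=1e-10)

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            nn.elbo_loss(np.zeros((0, 2)), [], 0.0, 0.0)


# ---------------------------------------------------------------------------
# training


class _FakeSegment:
    """Minimal stand-in for STFTSegment when shapes are deliberately tiny."""

    def __init__(self, values, label, start_s=0.0, clock_hour=0.0):
        self.values = values
        self.label = label
        self.start_s = start_s
        self.clock_hour = clock_hour


def _random_segments(n, rng, label_fn, shape=(1, 56, 128)):
    cls = pp.STFTSegment if shape[1:] == (56, 128) else _FakeSegment
    return [
        cls(rng.standard_normal(shape), label_fn(i), float(i * 15))
        for i in range(n)
    ]


class TestTrain:
    def test_loss_decreases_on_separable_data(self, trained_model):
        trace = trained_model["trace"]
        assert trace[-1].total < trace[0].total

    def test_single_class_rejected(self):
        rng = np.random.default_rng(0)
        segs = _random_segments(8, rng, lambda i: "interictal", (1, 4, 4))
        with pytest.raises(ValueError, match="both classes"):
            nn.train(tiny_dense_spec(), segs, nn.TrainConfig(epochs=1))

    def test_large_kl_weight_pins_posterior_to_prior(self):
        rng = np.random.default_rng(1)
        segs = _random_segments(
            40, rng, lambda i: "preictal" if i % 2 else "interictal", (1, 4, 4)
        )
        spec = tiny_dense_spec()
        init = nn.init_layers(spec, seed=0)
        init_mu = np.abs(init[0].mu_w).mean()
        layers, _ = nn.train(
            spec,
            segs,
            nn.TrainConfig(epochs=30, kl_weight=50.0, seed=0, normalize_input=False),
        )
        assert np.abs(layers[0].mu_w).mean() < init_mu
        ps = nn.mc_predict(spec, layers, segs[0], S=100, seed=2)
        assert abs(ps.scores.mean() - 0.5) < 0.15

    def test_held_out_auc_above_09(self, separable_data, trained_model):
        auc = mean_score_auc(
            trained_model["spec"], trained_model["layers"], separable_data["test"]
        )
        assert auc > 0.9

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        segs = _random_segments(
            20, rng, lambda i: "preictal" if i % 2 else "interictal", (1, 4, 4)
        )
        spec = tiny_dense_spec()
        l1, t1 = nn.train(spec, segs, nn.TrainConfig(epochs=2, seed=5))
        l2, t2 = nn.train(spec, segs, nn.TrainConfig(epochs=2, seed=5))
        np.testing.assert_array_equal(l1[0].mu_w, l2[0].mu_w)
        assert t1[-1].total == t2[-1].total


# ---------------------------------------------------------------------------
# Monte-Carlo prediction


class TestMCPredict:
    def test_default_sample_count_is_500(self):
        import inspect

        assert inspect.signature(nn.mc_predict).parameters["S"].default == 500

    def test_degenerate_posterior_identical_scores(self):
        spec = tiny_dense_spec((1, 56, 128))
        layers = nn.init_layers(spec, 0, sigma_init=1e-12)
        x = pp.STFTSegment(
            np.random.default_rng(0).standard_normal((1, 56, 128)), "interictal", 0.0
        )
        ps = nn.mc_predict(spec, layers, x, S=10, seed=3)
        assert np.ptp(ps.scores) < 1e-9

    def test_s_below_two_rejected(self):
        spec = tiny_dense_spec()
        layers = nn.init_layers(spec, 0)
        with pytest.raises(ValueError):
            nn.mc_predict(spec, layers, np.zeros((1, 4, 4)), S=1)

    def test_monte_carlo_convergence(self):
        # |mean of 2000 draws - mean of first 500| < 3 sd / sqrt(500)
        spec = tiny_dense_spec((1, 2, 2))
        layers = nn.init_layers(spec, 1, sigma_init=0.3)
        x = np.random.default_rng(4).standard_normal((1, 2, 2))
        ps = nn.mc_predict(spec, layers, x, S=2000, seed=9)
        m500 = ps.scores[:500].mean()
        m2000 = ps.scores.mean()
        assert abs(m2000 - m500) < 3 * ps.scores.std(ddof=1) / np.sqrt(500)

    def test_deterministic_cnn_correspondence(self):
        # kl_weight 0 and sigma ~ 0 reduces to a deterministic CNN
        spec = tiny_dense_spec((1, 2, 2))
        layers = nn.init_layers(spec, 2, sigma_init=1e-12)
        x = np.random.default_rng(6).standard_normal((1, 2, 2))
        ps = nn.mc_predict(spec, layers, x, S=5, seed=1)
        det_out, _ = nn.forward(spec, nn.mean_weights(spec, layers), x)
        det_score = nn.softmax(det_out)[1]
        np.testing.assert_allclose(ps.scores, det_score, atol=1e-9)

    def test_batch_agrees_with_scalar_path(self):
        spec = tiny_dense_spec((1, 56, 128))
        layers = nn.init_layers(spec, 3, sigma_init=0.2)
        v = np.random.default_rng(7).standard_normal((1, 56, 128))
        seg = pp.STFTSegment(v, "interictal", 0.0)
        a = nn.mc_predict(spec, layers, v, S=300, seed=2)
        b = nn.mc_predict_batch(spec, layers, [seg], S=300, seed=2)[0]
        # identical seed stream draws the same weights in both paths
        np.testing.assert_allclose(a.scores, b.scores, atol=1e-12)


# ---------------------------------------------------------------------------
# checkpoints


class TestCheckpoint:
    def test_round_trip(self, tmp_path):
        spec = nn.default_spec(2, width_scale=0.1)
        spec.input_center, spec.input_scale = 1.5, 2.5
        layers = nn.init_layers(spec, 4)
        path = nn.save_checkpoint(tmp_path / "m.h5", spec, layers)
        spec2, layers2 = nn.load_checkpoint(path)
        assert spec2.input_center == 1.5
        assert spec2.n_channels == 2
        assert len(layers2) == len(layers)
        np.testing.assert_array_equal(layers2[0].mu_w, layers[0].mu_w)
        np.testing.assert_array_equal(layers2[-1].rho_b, layers[-1].rho_b)
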