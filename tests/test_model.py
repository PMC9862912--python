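"""Deterministic architecture, variational lifting, MOPED prior, ELBO."""

import numpy as np
import pytest

import bayesmi as bm
from bayesmi.nn import ArchitectureSpec, ShallowNet, cross_entropy, softmax, softmax_ce_grad


class TestShapeChain:
    @pytest.mark.parametrize("c", [3, 22])
    def test_printed_shape_chain(self, c):
        """Temporal conv length 478 and dense width 2160 for any channel
        count: the spatial convolution collapses the electrode axis."""
        spec = ArchitectureSpec(n_channels=c, n_classes=4)
        chain = spec.shape_chain()
        assert chain["temporal_out_len"] == 478
        assert chain["avg_pool_out_len"] == 434
        assert chain["max_pool_out_len"] == 54
        assert chain["dense_in"] == 2160

    def test_forward_shapes_and_simplex(self, rng):
        spec = ArchitectureSpec(n_channels=3, n_classes=2)
        net = bm.build_deterministic(spec, seed=0)
        x = rng.standard_normal((4, 1000, 3))
        p = softmax(net.forward(x, train=True))
        assert p.shape == (4, 2)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)

    def test_wrong_input_length_rejected(self, rng):
        net = bm.build_deterministic(ArchitectureSpec(n_channels=3,
                                                      n_classes=2), seed=0)
        with pytest.raises(ValueError, match="expected input"):
            net.forward(rng.standard_normal((2, 900, 3)))


class TestGradients:
    def test_backprop_matches_finite_differences(self, tiny_arch, rng):
        net = ShallowNet(tiny_arch, rng)
        net.bn_momentum = 0.0
        x = rng.standard_normal((3, tiny_arch.input_len, tiny_arch.n_channels))
        y = np.array([0, 2, 1])
        loss, dlog = softmax_ce_grad(net.forward(x, train=True), y)
        g = net.backward(dlog)
        h = 1e-6
        for k, gk in g.items():
            flat = net.weights[k].ravel()
            for i in rng.choice(flat.size, size=min(5, flat.size),
                                replace=False):
                old = flat[i]
                flat[i] = old + h
                lp = cross_entropy(softmax(net.forward(x, train=True)), y)
                flat[i] = old - h
                lm = cross_entropy(softmax(net.forward(x, train=True)), y)
                flat[i] = old
                num = (lp - lm) / (2 * h)
                assert gk.ravel()[i] == pytest.approx(num, abs=1e-6, rel=1e-4)


class TestVariational:
    def test_stochastic_forward_passes_differ(self, tiny_arch, rng):
        net = bm.to_bayesian(ShallowNet(tiny_arch, rng),
                             bm.PriorSpec(kind="standard"))
        x = rng.standard_normal((2, tiny_arch.input_len, tiny_arch.n_channels))
        a = net.forward(x, rng=rng)
        b = net.forward(x, rng=rng)
        assert not np.allclose(a, b)

    def test_parameter_count_doubles(self, tiny_arch, rng):
        base = ShallowNet(tiny_arch, rng)
        n_det = sum(base.weights[k].size for k in ShallowNet.WEIGHT_KEYS)
        net = bm.to_bayesian(base, bm.PriorSpec(kind="standard"))
        assert net.n_variational_parameters() == 2 * n_det

    def test_collapse_to_deterministic(self, tiny_arch, rng):
        """Posterior scales ~0 with means at the deterministic weights
        reproduce the deterministic output."""
        det = ShallowNet(tiny_arch, rng)
        prior = bm.moped_prior(det.copy_weights())
        net = bm.to_bayesian(ShallowNet(tiny_arch, rng), prior)
        for k in net.rho:
            net.rho[k] = np.full_like(net.rho[k], -50.0)  # sigma ~ 2e-22
        net.base.set_bn_state(det.bn_state())
        x = rng.standard_normal((3, tiny_arch.input_len, tiny_arch.n_channels))
        ref = det.forward(x, train=False)
        out = net.forward(x, rng=rng, train=False)
        np.testing.assert_allclose(out, ref, atol=1e-5)

    def test_moped_without_weights_rejected(self):
        with pytest.raises(ValueError, match="pretrained"):
            bm.PriorSpec(kind="moped").validate()


class TestMopedPrior:
    def test_scale_rule(self):
        prior = bm.moped_prior({"w": np.array([0.5, 0.0, -2.0])}, delta=0.1,
                               scale_floor=1e-6)
        net_sigma = np.maximum(0.1 * np.abs([0.5, 0.0, -2.0]), 1e-6)
        np.testing.assert_allclose(net_sigma, [0.05, 1e-6, 0.2])
        np.testing.assert_allclose(prior.pretrained_weights["w"],
                                   [0.5, 0.0, -2.0])

    def test_prior_and_posterior_init(self, tiny_arch, rng):
        det = ShallowNet(tiny_arch, rng)
        net = bm.to_bayesian(ShallowNet(tiny_arch, rng),
                             bm.moped_prior(det.copy_weights(), delta=0.1))
        for k in net.mu:
            wd = det.weights[k]
            np.testing.assert_array_equal(net.mu[k], wd)
            np.testing.assert_array_equal(net.prior_mu[k], wd)
            np.testing.assert_allclose(net.prior_sigma[k],
                                       np.maximum(0.1 * np.abs(wd), 1e-6))
            np.testing.assert_allclose(net.sigma()[k], net.prior_sigma[k],
                                       rtol=1e-9)

    def test_invalid_delta_rejected(self):
        with pytest.raises(ValueError):
            bm.moped_prior({"w": np.ones(2)}, delta=-0.1)


class TestElbo:
    def test_kl_zero_for_identical_gaussians(self, rng):
        mu = rng.standard_normal(10)
        sig = rng.uniform(0.1, 2.0, 10)
        np.testing.assert_allclose(bm.gaussian_kl(mu, sig, mu, sig), 0.0,
                                   atol=1e-14)

    def test_kl_closed_form_value(self):
        # KL(N(1, 0.5^2) || N(0, 1)) = ln 2 + (0.25 + 1)/2 - 0.5
        val = bm.gaussian_kl(np.array(1.0), np.array(0.5),
                             np.array(0.0), np.array(1.0))
        assert val == pytest.approx(np.log(2) + 1.25 / 2 - 0.5, abs=1e-12)
        assert val == pytest.approx(0.81814718, abs=1e-7)

    def test_kl_zero_when_posterior_equals_prior(self, tiny_arch, rng):
        det = ShallowNet(tiny_arch, rng)
        net = bm.to_bayesian(ShallowNet(tiny_arch, rng),
                             bm.moped_prior(det.copy_weights()))
        assert net.kl() == pytest.approx(0.0, abs=1e-6)

    def test_elbo_loss_components(self, tiny_arch, rng):
        net = bm.to_bayesian(ShallowNet(tiny_arch, rng),
                             bm.PriorSpec(kind="standard"))
        x = rng.standard_normal((4, tiny_arch.input_len, tiny_arch.n_channels))
        y = np.array([0, 1, 2, 0])
        logits = net.forward(x, rng=rng)
        loss = bm.elbo_loss(logits, y, net, kl_weight=0.01)
        ce = cross_entropy(softmax(logits), y)
        assert loss == pytest.approx(ce + 0.01 * net.kl(), rel=1e-12)
        assert net.kl() >= 0.0
        with pytest.raises(ValueError):
            bm.elbo_loss(logits, y[:2], net, kl_weight=0.01)


class TestMcPredict:
    def test_rows_on_simplex_and_draw_mean(self, tiny_arch, rng):
        net = bm.to_bayesian(ShallowNet(tiny_arch, rng),
                             bm.PriorSpec(kind="standard"))
        x = rng.standard_normal((tiny_arch.input_len, tiny_arch.n_channels))
        stack = bm.mc_predict(net, x, T=10, seed=4)
        assert stack.shape == (10, tiny_arch.n_classes)
        np.testing.assert_allclose(stack.sum(axis=1), 1.0, atol=1e-9)
        y_star, _ = bm.mean_prediction(stack)
        np.testing.assert_allclose(y_star, stack.mean(axis=0), atol=1e-12)

    def test_deterministic_model_gives_identical_rows(self, tiny_arch, rng):
        det = ShallowNet(tiny_arch, rng)
        x = rng.standard_normal((tiny_arch.input_len, tiny_arch.n_channels))
        stack = bm.mc_predict(det, x, T=5, seed=0)
        assert np.all(stack == stack[0])

    def test_t_below_two_rejected(self, tiny_arch, rng):
        det = ShallowNet(tiny_arch, rng)
        x = rng.standard_normal((tiny_arch.input_len, tiny_arch.n_channels))
        with pytest.raises(ValueError):
            bm.mc_predict(det, x, T=1)

    def test_default_passes_is_fifty(self):
        assert bm.TrainingConfig().t_predict == 50


class TestTrainingSmoke:
    def test_deterministic_training_reduces_loss(self, tiny_arch, rng):
        """A few epochs on linearly separable toy crops lowers the loss."""
        n = 60
        x = rng.standard_normal((n, 2, tiny_arch.input_len)) * 0.3
        y = rng.integers(0, 3, n)
        for i in range(n):  # class-dependent oscillation amplitude
            x[i] += (0.4 + 0.4 * y[i]) * np.sin(
                2 * np.pi * 10 * np.arange(tiny_arch.input_len) / 250.0)
        crops = bm.CropSet(crops=x, trial_index=np.arange(n),
                           crop_position=np.zeros(n, dtype=int),
                           start_time_s=np.zeros(n), labels=y, fs=250.0)
        tr = crops.subset(np.arange(n) < 40)
        va = crops.subset(np.arange(n) >= 40)
        net = ShallowNet(tiny_arch, rng)
        hist = bm.train(net, tr, va, bm.TrainingConfig(max_epochs=8,
                                                       batch_size=16, seed=0))
        assert hist.train_loss[-1] < hist.train_loss[0]
        assert hist.best_val_loss < np.log(3)  # better than chance

    def test_empty_sets_rejected(self, tiny_arch, rng):
        net = ShallowNet(tiny_arch, rng)
        empty = bm.CropSet(crops=np.zeros((0, 2, 120)),
                           trial_index=np.zeros(0, dtype=int),
                           crop_position=np.zeros(0, dtype=int),
                           start_time_s=np.zeros(0),
                           labels=np.zeros(0, dtype=int), fs=250.0)
        with pytest.raises(ValueError):
            bm.train(net, empty, empty, bm.TrainingConfig())
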