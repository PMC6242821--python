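import numpy as np
import pytest

from spikeglm.data import SpikeCountMatrix
from spikeglm.distributions import count_logpmf
from spikeglm.dynamics import current_series
from spikeglm.distributions import transfer
from spikeglm.inference import (FitConfig, ParamPacker, count_parameters,
                                default_trainable, grad_log_likelihood,
                                initial_params, irprop_fit, log_likelihood)
from spikeglm.params import ModelParams, default_params

from conftest import random_counts, random_params


class TestCountParameters:
    def test_printed_formulas_at_sixty_neurons(self):
        assert count_parameters("exp_poisson", 60) == 14520
        assert count_parameters("sig_negbin", 60) == 14172
        assert count_parameters("exp_poisson", 60) - count_parameters("sig_negbin", 60) == 348

    def test_general_formulas(self):
        for n in (2, 5, 17):
            assert count_parameters("exp_poisson", n) == 4 * n * (n - 1) + 6 * n
            assert count_parameters("sig_negbin", n) == 4 * n * (n - 1) + 12

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            count_parameters("nope", 10)
        with pytest.raises(ValueError):
            count_parameters("sig_negbin", 1)


class TestLogLikelihood:
    def test_single_poisson_bin(self):
        # 16 bins of silence: one evaluable bin with lambda = exp(0) = 1
        data = SpikeCountMatrix(np.zeros((1, 16), int), dt=0.01)
        p = default_params("exp_poisson", 2, dt=0.01)
        p1 = default_params("exp_poisson", 2, dt=0.01)
        del p1
        one = ModelParams("exp_poisson", np.zeros((1, 1, 4)), np.zeros(1),
                          np.zeros(5), p.tau_sfa, dt=0.01,
                          diag_weights=np.zeros((1, 6)))
        assert log_likelihood(data, one) == pytest.approx(-1.0)

    def test_additivity_over_decoupled_subnetworks(self, rng):
        p = random_params("sig_negbin", 4, rng)
        p.weights[:2, 2:, :] = 0.0
        p.weights[2:, :2, :] = 0.0
        data = random_counts(4, 80, rng)
        sub_a = SpikeCountMatrix(data.counts[:2], data.dt)
        sub_b = SpikeCountMatrix(data.counts[2:], data.dt)
        pa = ModelParams("sig_negbin", p.weights[:2, :2], p.h[:2], p.g_sfa,
                         p.tau_sfa, p.lambda_inf, p.gamma, p.r_nb, p.dt)
        pb = ModelParams("sig_negbin", p.weights[2:, 2:], p.h[2:], p.g_sfa,
                         p.tau_sfa, p.lambda_inf, p.gamma, p.r_nb, p.dt)
        assert log_likelihood(data, p) == pytest.approx(
            log_likelihood(sub_a, pa) + log_likelihood(sub_b, pb))

    @pytest.mark.parametrize("variant", ["sig_negbin", "exp_poisson"])
    def test_matches_direct_pmf_summation(self, variant, rng):
        p = random_params(variant, 3, rng)
        data = random_counts(3, 60, rng)
        H = current_series(data.counts.astype(float), p)
        lam = transfer(H, variant, p.lambda_inf, p.gamma)
        direct = count_logpmf(data.counts[:, 15:], lam[:, 15:], variant,
                              p.r_nb).sum()
        assert log_likelihood(data, p) == pytest.approx(direct)

    def test_requires_enough_bins(self, rng):
        p = random_params("sig_negbin", 2, rng)
        with pytest.raises(ValueError):
            log_likelihood(random_counts(2, 15, rng), p)


class TestGradients:
    @pytest.mark.parametrize("variant", ["sig_negbin", "exp_poisson",
                                         "sig_poisson", "exp_negbin"])
    def test_analytic_gradient_matches_finite_differences(self, variant, rng):
        p = random_params(variant, 3, rng)
        data = random_counts(3, 60, rng)
        trainable = default_trainable(variant)
        packer = ParamPacker(p, trainable)
        _, grads = grad_log_likelihood(data, p, trainable)
        ga = packer.pack_grads(grads)
        theta = packer.pack(p)
        eps = 1e-5
        gfd = np.empty_like(theta)
        for k in range(len(theta)):
            tp, tm = theta.copy(), theta.copy()
            tp[k] += eps
            tm[k] -= eps
            gfd[k] = (log_likelihood(data, packer.unpack(tp))
                      - log_likelihood(data, packer.unpack(tm))) / (2 * eps)
        rel = np.abs(ga - gfd) / np.maximum(np.abs(gfd), 1.0)
        assert rel.max() < 1e-4

    def test_poisson_intercept_stationarity(self, rng):
        # dLL/dh = 0 exactly where exp(h) equals the mean observed count
        data = random_counts(2, 500, rng, rate=0.4)
        mean = data.counts[:, 15:].mean(axis=1)
        p = default_params("exp_poisson", 2)
        p.h = np.log(mean)
        _, grads = grad_log_likelihood(data, p, ("h",))
        np.testing.assert_allclose(grads["h"], 0.0, atol=1e-8)

    def test_zero_data_pushes_intercept_down(self):
        data = SpikeCountMatrix(np.zeros((2, 100), int), dt=0.01)
        p = default_params("exp_poisson", 2)
        p.h = np.array([-3.0, 1.0])
        _, grads = grad_log_likelihood(data, p, ("h",))
        assert np.all(grads["h"] < 0.0)


class TestPacker:
    def test_round_trip_preserves_parameters(self, rng):
        p = random_params("sig_negbin", 4, rng)
        packer = ParamPacker(p, default_trainable("sig_negbin"))
        q = packer.unpack(packer.pack(p))
        np.testing.assert_allclose(q.weights, p.weights)
        np.testing.assert_allclose(q.h, p.h)
        np.testing.assert_allclose(q.tau_sfa, p.tau_sfa)
        assert q.lambda_inf == pytest.approx(p.lambda_inf)

    def test_diagonal_structural_zeros_survive(self, rng):
        p = random_params("sig_negbin", 4, rng)
        packer = ParamPacker(p, default_trainable("sig_negbin"))
        v = packer.pack(p) + 10.0   # arbitrary update
        q = packer.unpack(v)
        idx = np.arange(4)
        assert np.all(q.weights[idx, idx, :] == 0.0)
        assert np.all(q.diag_weights == 0.0)


class TestIrprop:
    def test_recovers_homogeneous_poisson_rate(self, rng):
        rate = 0.6
        data = SpikeCountMatrix(rng.poisson(rate, (3, 4000)), dt=0.01)
        cfg = FitConfig(variant="exp_poisson", trainable=("h",), max_epochs=200)
        res = irprop_fit(data, cfg)
        emp = data.counts[:, 15:].mean(axis=1)
        np.testing.assert_allclose(np.exp(res.params.h), emp, rtol=0.02)

    def test_best_ll_non_decreasing_and_constraints_kept(self, rng):
        data = random_counts(3, 300, rng)
        cfg = FitConfig(variant="sig_negbin", max_epochs=40)
        res = irprop_fit(data, cfg)
        best = np.maximum.accumulate(res.ll_trace)
        assert np.all(np.diff(best) >= 0)
        idx = np.arange(3)
        assert np.all(res.params.weights[idx, idx, :] == 0.0)
        assert np.all(res.params.diag_weights == 0.0)
        assert res.params.r_nb == 0.22  # never inferred

    def test_frozen_blocks_untouched(self, rng):
        data = random_counts(3, 300, rng)
        init = initial_params(data, "sig_negbin")
        g0 = init.g_sfa.copy()
        tau0 = init.tau_sfa.copy()
        cfg = FitConfig(variant="sig_negbin", trainable=("weights", "h"),
                        max_epochs=30)
        res = irprop_fit(data, cfg, init=init)
        np.testing.assert_array_equal(res.params.g_sfa, g0)
        np.testing.assert_array_equal(res.params.tau_sfa, tau0)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            FitConfig(eta_plus=0.9)
        with pytest.raises(ValueError):
            FitConfig(step_init=2.0, step_max=1.0)
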