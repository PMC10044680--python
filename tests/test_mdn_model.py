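"""Mixture math, network contracts, training behavior, linear baseline."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from tmbcal import (
    InputConfig,
    LinearBaseline,
    MixtureDensityNetwork,
    MixtureParams,
    ModelConfig,
    TrainConfig,
    lognormal_mixture_nll,
    mixture_cdf,
    mixture_pdf,
    mixture_quantile,
    prob_above,
)
from tmbcal.mdn_model import design_matrix, train


def random_mixture(rng, k=3):
    w = rng.dirichlet(np.ones(k))
    mu = rng.normal(0, 1.5, size=k)
    sigma = rng.uniform(0.2, 1.5, size=k)
    return MixtureParams(weights=w, mu=mu, sigma=sigma)


def nll_oracle(params, y):
    """Direct two-route evaluation: sum of scipy lognorm densities."""
    dens = sum(
        w * stats.lognorm.pdf(y, s=sig, scale=np.exp(mu))
        for w, mu, sig in zip(params.weights, params.mu, params.sigma)
    )
    return -np.log(dens)


class TestMixtureMath:
    def test_standard_lognormal_nll_at_median(self):
        params = MixtureParams([1.0], [0.0], [1.0])
        assert lognormal_mixture_nll(params, 1.0) == pytest.approx(
            np.log(np.sqrt(2 * np.pi)), abs=1e-12)

    def test_degenerate_two_component_equals_single(self):
        single = MixtureParams([1.0], [0.3], [0.7])
        double = MixtureParams([0.5, 0.5], [0.3, 0.3], [0.7, 0.7])
        for y in (0.1, 1.0, 5.0):
            assert lognormal_mixture_nll(double, y) == pytest.approx(
                lognormal_mixture_nll(single, y), rel=1e-12)

    def test_two_component_against_independent_oracle(self):
        params = MixtureParams([0.3, 0.7], [0.0, 1.0], [0.5, 1.0])
        assert lognormal_mixture_nll(params, 2.0) == pytest.approx(
            nll_oracle(params, 2.0), rel=1e-10)

    def test_nonpositive_y_rejected(self):
        with pytest.raises(ValueError):
            lognormal_mixture_nll(MixtureParams([1.0], [0.0], [1.0]), 0.0)

    def test_density_integrates_to_one(self, rng):
        for _ in range(5):
            params = random_mixture(rng)
            total, _ = integrate.quad(
                lambda y: mixture_pdf(params, y), 0, np.inf, limit=200)
            assert total == pytest.approx(1.0, abs=1e-4)

    def test_cdf_at_single_component_median(self):
        assert mixture_cdf(MixtureParams([1.0], [0.0], [1.0]), 1.0) == \
            pytest.approx(0.5)

    def test_cdf_limits(self):
        params = MixtureParams([0.4, 0.6], [0.0, 2.0], [0.5, 1.0])
        assert mixture_cdf(params, 1e12) == pytest.approx(1.0, abs=1e-9)
        assert mixture_cdf(params, 1e-12) == pytest.approx(0.0, abs=1e-9)
        assert mixture_cdf(params, -1.0) == 0.0

    def test_degenerate_weight_median(self):
        params = MixtureParams([1.0, 0.0], [0.7, 3.0], [0.5, 0.5])
        # zero-weight component is inert: CDF at exp(mu_1) is 1/2
        assert mixture_cdf(params, np.exp(0.7)) == pytest.approx(0.5)

    def test_quantile_of_single_lognormal(self):
        params = MixtureParams([1.0], [np.log(3.0)], [0.5])
        assert mixture_quantile(params, 0.5) == pytest.approx(3.0, rel=1e-7)

    def test_quantile_cdf_roundtrip_on_random_mixtures(self, rng):
        for _ in range(25):
            params = random_mixture(rng)
            for q in (0.025, 0.5, 0.975):
                t = mixture_quantile(params, q)
                assert mixture_cdf(params, t) == pytest.approx(q, abs=1e-6)

    def test_quantiles_monotone(self, rng):
        params = random_mixture(rng)
        qs = [mixture_quantile(params, q) for q in (0.25, 0.5, 0.75)]
        assert qs[0] <= qs[1] <= qs[2]

    def test_quantile_domain(self):
        params = MixtureParams([1.0], [0.0], [1.0])
        for q in (0.0, 1.0, -0.1):
            with pytest.raises(ValueError):
                mixture_quantile(params, q)

    def test_prob_above_complement_and_monotone(self, rng):
        params = random_mixture(rng)
        for t in (0.1, 1.0, 10.0):
            assert prob_above(params, t) + mixture_cdf(params, t) == \
                pytest.approx(1.0, abs=1e-9)
        ts = np.linspace(0.1, 20, 50)
        ps = [prob_above(params, t) for t in ts]
        assert all(a >= b - 1e-12 for a, b in zip(ps, ps[1:]))

    def test_mixture_mean_closed_form(self):
        params = MixtureParams([0.25, 0.75], [0.0, 1.0], [0.5, 0.3])
        expected = 0.25 * np.exp(0.125) + 0.75 * np.exp(1.0 + 0.045)
        assert params.mean == pytest.approx(expected)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            MixtureParams([0.5, 0.6], [0, 0], [1, 1])
        with pytest.raises(ValueError):
            MixtureParams([1.0], [0.0], [0.0])


class TestForward:
    def _model(self, n_features=2, k=3, seed=0):
        model = MixtureDensityNetwork(
            n_features, ModelConfig(hidden_sizes=(16, 8), n_components=k))
        model._init_params(np.random.default_rng(seed))
        return model

    def test_weights_normalized_and_sigma_floored(self, rng):
        model = self._model()
        X = rng.normal(size=(50, 2))
        W, MU, SIG = model.predict_params(X)
        assert np.allclose(W.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(SIG >= model.config.sigma_floor)

    def test_deterministic_forward(self, rng):
        model = self._model()
        x = rng.normal(size=(1, 2))
        W1, MU1, SIG1 = model.predict_params(x)
        W2, MU2, SIG2 = model.predict_params(x.copy())
        assert np.array_equal(W1, W2) and np.array_equal(MU1, MU2)

    def test_dimension_mismatch_rejected(self, rng):
        model = self._model(n_features=2)
        with pytest.raises(ValueError):
            model.predict_params(rng.normal(size=(5, 3)))

    def test_gradient_matches_finite_differences(self, rng):
        """Analytic backprop against central finite differences."""
        model = self._model(n_features=2, k=2, seed=3)
        X = rng.normal(size=(8, 2))
        z = rng.normal(size=8)
        grads, loss = model._backward(X, z)
        params = model.weights_ + model.biases_
        eps = 1e-6
        for p_idx in (0, len(model.weights_), len(params) - 1):
            p = params[p_idx]
            flat_idx = (0,) if p.ndim == 1 else (0, 0)
            orig = p[flat_idx]
            p[flat_idx] = orig + eps
            up = float(np.mean(model._nll_z(X, z)))
            p[flat_idx] = orig - eps
            down = float(np.mean(model._nll_z(X, z)))
            p[flat_idx] = orig
            fd = (up - down) / (2 * eps)
            assert grads[p_idx][flat_idx] == pytest.approx(fd, rel=1e-4,
                                                           abs=1e-8)


def _constant_input_table(y):
    return pd.DataFrame({
        "sample_id": [f"S{i}" for i in range(len(y))],
        "nonsyn_per_mb": np.ones(len(y)),
        "all_per_mb": np.ones(len(y)),
        "hotspot_per_mb": np.zeros(len(y)),
        "ancestry": ["EUR"] * len(y),
        "exomic_tmb": y,
    })


# constant-input fits plateau slowly at the default learning rate; a larger
# step with longer patience reaches the optimum in under a second
FAST = TrainConfig(seed=1, max_epochs=400, patience=50, batch_size=256,
                   learning_rate=3e-3)


class TestTraining:
    def test_k1_constant_input_recovers_closed_form_mle(self, rng):
        """Homoscedastic single-log-normal data: the fitted component must sit
        at the closed-form MLE (mean and SD of the log labels)."""
        y = rng.lognormal(mean=1.0, sigma=0.6, size=2500)
        mc = ModelConfig(hidden_sizes=(16, 8), n_components=1,
                         label_offset=0.0)
        model = train(_constant_input_table(y), mc, FAST)
        W, MU, SIG = model.predict_params(
            design_matrix(_constant_input_table(y[:1]), mc.input_config))
        logy = np.log(y)
        assert MU[0, 0] == pytest.approx(logy.mean(), abs=0.02)
        assert SIG[0, 0] == pytest.approx(logy.std(), abs=0.02)

    def test_same_seed_is_bit_identical(self, rng):
        y = rng.lognormal(mean=0.5, sigma=0.5, size=400)
        table = _constant_input_table(y)
        mc = ModelConfig(hidden_sizes=(8,), n_components=2)
        tc = TrainConfig(seed=7, max_epochs=15, patience=15)
        m1 = train(table, mc, tc)
        m2 = train(table, mc, tc)
        assert [l["val_nll"] for l in m1.training_log_] == \
            [l["val_nll"] for l in m2.training_log_]
        assert all(np.array_equal(a, b)
                   for a, b in zip(m1.weights_, m2.weights_))

    def test_log_label_shift_shifts_mu(self, rng):
        """Multiplying labels by e^c (a shift of ln y) shifts the fitted mu by
        c at K=1 with constant input (checked with no label offset)."""
        y = rng.lognormal(mean=0.8, sigma=0.4, size=1500)
        c = 1.0
        mc = ModelConfig(hidden_sizes=(16, 8), n_components=1,
                         label_offset=0.0)
        m1 = train(_constant_input_table(y), mc, FAST)
        m2 = train(_constant_input_table(y * np.exp(c)), mc, FAST)
        X = design_matrix(_constant_input_table(y[:1]), mc.input_config)
        mu1 = m1.predict_params(X)[1][0, 0]
        mu2 = m2.predict_params(X)[1][0, 0]
        assert mu2 - mu1 == pytest.approx(c, abs=0.03)

    def test_nll_requires_offsettable_labels(self):
        table = _constant_input_table(np.array([-1.0, 1.0, 2.0]))
        mc = ModelConfig(hidden_sizes=(8,), n_components=1)
        with pytest.raises(ValueError):
            train(table, mc, TrainConfig(max_epochs=2))

    def test_save_load_roundtrip(self, tmp_path, rng):
        y = rng.lognormal(mean=0.5, sigma=0.5, size=300)
        table = _constant_input_table(y)
        mc = ModelConfig(hidden_sizes=(8,), n_components=2)
        model = train(table, mc, TrainConfig(seed=2, max_epochs=5, patience=5))
        prefix = str(tmp_path / "ckpt")
        model.save(prefix)
        loaded = MixtureDensityNetwork.load(prefix)
        X = design_matrix(table, mc.input_config)
        assert np.array_equal(model.predict_median(X),
                              loaded.predict_median(X))


class TestLinearBaseline:
    def test_noiseless_line_recovered(self):
        X = np.linspace(0, 10, 50)[:, None]
        y = 2 * X[:, 0] + 1
        bl = LinearBaseline().fit(X, y)
        assert bl.coef_ == pytest.approx([1.0, 2.0], abs=1e-8)
        assert bl.sigma_ == pytest.approx(0.0, abs=1e-8)

    def test_median_equals_mean(self, rng):
        X = rng.normal(size=(100, 2))
        y = X @ np.array([1.0, -2.0]) + rng.normal(size=100)
        bl = LinearBaseline().fit(X, y)
        assert np.array_equal(bl.predict_median(X), bl.predict_mean(X))

    def test_rank_deficient_design_rejected(self, rng):
        X = np.repeat(rng.normal(size=(30, 1)), 2, axis=1)  # duplicate column
        y = rng.normal(size=30)
        with pytest.raises(ValueError, match="rank"):
            LinearBaseline().fit(X, y)

    def test_prob_above_consistent_with_quantile(self, rng):
        X = rng.normal(size=(40, 1))
        y = 3 * X[:, 0] + rng.normal(size=40)
        bl = LinearBaseline().fit(X, y)
        q90 = bl.predict_quantile(X, 0.9)
        p = 1.0 - bl.predict_prob_above(X[:1], float(q90[0]))
        assert p == pytest.approx(0.9, abs=1e-9)
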