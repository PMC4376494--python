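import logging

import numpy as np
import pytest

from vesselem import (InvalidInputError, MixtureParameters, PixelDataset,
                      ResponsibilityMatrix, classify, e_step, fit_em,
                      log_likelihood, m_step)


def make_params(means, variances, mixing):
    means = np.asarray(means, dtype=float)[:, None]
    covs = np.asarray(variances, dtype=float)[:, None, None]
    return MixtureParameters(means=means, covariances=covs, mixing=np.asarray(mixing, float))


def gauss_pdf(x, mu, var):
    return np.exp(-0.5 * (x - mu) ** 2 / var) / np.sqrt(2 * np.pi * var)


class TestLogLikelihood:
    def test_single_component_closed_form(self, rng):
        x = rng.normal(2.0, 1.5, size=200)
        mu, var = 1.8, 2.2
        params = make_params([mu], [var], [1.0])
        ll = log_likelihood(PixelDataset(x), params)
        closed = (-0.5 * len(x) * np.log(2 * np.pi * var)
                  - np.sum((x - mu) ** 2) / (2 * var))
        assert ll == pytest.approx(closed, rel=1e-12)

    def test_duplicated_component_invariance(self, rng):
        x = rng.normal(size=100)
        single = log_likelihood(PixelDataset(x), make_params([0.3], [1.1], [1.0]))
        double = log_likelihood(PixelDataset(x),
                                make_params([0.3, 0.3], [1.1, 1.1], [0.5, 0.5]))
        assert double == pytest.approx(single, rel=1e-12)

    def test_hand_listed_points_oracle(self):
        x = np.array([-1.0, 0.0, 0.5, 2.0, 3.5])
        params = make_params([0.0, 3.0], [1.0, 0.5], [0.6, 0.4])
        expected = sum(
            np.log(0.6 * gauss_pdf(xi, 0.0, 1.0) + 0.4 * gauss_pdf(xi, 3.0, 0.5))
            for xi in x)
        assert log_likelihood(PixelDataset(x), params) == pytest.approx(expected, abs=1e-10)


class TestEStep:
    def test_identical_components_give_half(self, rng):
        x = rng.normal(size=50)
        params = make_params([1.0, 1.0], [2.0, 2.0], [0.5, 0.5])
        resp = e_step(PixelDataset(x), params)
        np.testing.assert_allclose(resp.gamma, 0.5)

    def test_dominant_likelihood_limit(self):
        params = make_params([0.0, 50.0], [1.0, 1.0], [0.5, 0.5])
        resp = e_step(PixelDataset(np.array([0.0])), params)
        assert resp.gamma[0, 0] == pytest.approx(1.0, abs=1e-6)

    def test_four_point_bayes_oracle(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        mus, vars_, pis = [0.5, 2.5], [0.25, 0.25], [0.4, 0.6]
        params = make_params(mus, vars_, pis)
        resp = e_step(PixelDataset(x), params)
        for i, xi in enumerate(x):
            num = np.array([p * gauss_pdf(xi, m, v)
                            for p, m, v in zip(pis, mus, vars_)])
            np.testing.assert_allclose(resp.gamma[i], num / num.sum(), atol=1e-12)

    def test_rows_sum_to_one_far_in_tails(self):
        # far-tail points underflow linear-space densities; log space must not NaN
        x = np.array([1e5, -1e5])
        params = make_params([0.0, 1.0], [1.0, 1.0], [0.5, 0.5])
        resp = e_step(PixelDataset(x), params)
        assert np.all(np.isfinite(resp.gamma))
        np.testing.assert_allclose(resp.gamma.sum(axis=1), 1.0, atol=1e-12)


class TestMStep:
    def test_all_mass_on_first_component(self, rng, caplog):
        x = rng.normal(3.0, 2.0, size=30)
        gamma = np.column_stack([np.ones(30), np.zeros(30)])
        with caplog.at_level(logging.WARNING):
            params = m_step(PixelDataset(x), ResponsibilityMatrix(gamma))
        assert params.means[0, 0] == pytest.approx(x.mean(), rel=1e-12)
        assert params.covariances[0, 0, 0] == pytest.approx(np.var(x), rel=1e-12)
        np.testing.assert_allclose(params.mixing, [1.0, 0.0])
        assert "no responsibility" in caplog.text

    def test_uniform_responsibilities(self, rng):
        x = rng.normal(size=40)
        gamma = np.full((40, 2), 0.5)
        params = m_step(PixelDataset(x), ResponsibilityMatrix(gamma))
        np.testing.assert_allclose(params.means[:, 0], x.mean(), rtol=1e-12)
        np.testing.assert_allclose(params.mixing, [0.5, 0.5])

    def test_random_responsibilities_match_weighted_formulas(self, rng):
        x = rng.normal(size=20)
        raw = rng.random((20, 2))
        gamma = raw / raw.sum(axis=1, keepdims=True)
        params = m_step(PixelDataset(x), ResponsibilityMatrix(gamma))
        for k in range(2):
            nk = gamma[:, k].sum()
            mu = np.sum(gamma[:, k] * x) / nk
            var = np.sum(gamma[:, k] * (x - mu) ** 2) / nk
            assert params.means[k, 0] == pytest.approx(mu, abs=1e-12)
            assert params.covariances[k, 0, 0] == pytest.approx(var, abs=1e-12)
            assert params.mixing[k] == pytest.approx(nk / 20, abs=1e-12)

    def test_m_step_is_the_maximizer(self, rng):
        # perturbing a recovered mean must not increase the expected
        # complete-data log-likelihood at fixed responsibilities
        x = rng.normal(size=50)
        raw = rng.random((50, 2))
        gamma = raw / raw.sum(axis=1, keepdims=True)
        params = m_step(PixelDataset(x), ResponsibilityMatrix(gamma))

        def q_value(p):
            total = 0.0
            for k in range(2):
                logpdf = (np.log(gauss_pdf(x, p.means[k, 0], p.covariances[k, 0, 0])))
                total += np.sum(gamma[:, k] * (np.log(p.mixing[k]) + logpdf))
            return total

        base = q_value(params)
        for k in range(2):
            sigma = np.sqrt(params.covariances[k, 0, 0])
            for delta in (+0.01 * sigma, -0.01 * sigma):
                perturbed = MixtureParameters(
                    means=params.means + np.eye(2)[k][:, None] * delta,
                    covariances=params.covariances.copy(),
                    mixing=params.mixing.copy())
                assert q_value(perturbed) <= base + 1e-10


class TestFitEM:
    def test_single_gaussian_recovers_sample_moments(self, rng):
        x = rng.normal(1.0, 0.7, size=500)
        fit = fit_em(PixelDataset(x), k=1, max_iter=1)
        assert fit.params.means[0, 0] == pytest.approx(x.mean(), rel=1e-10)
        assert fit.params.covariances[0, 0, 0] == pytest.approx(np.var(x), rel=1e-10)

    def test_two_component_parameter_recovery(self):
        rng = np.random.default_rng(1)
        n = 10_000
        comp = rng.random(n) < 0.7
        x = np.where(comp, rng.normal(0.5, 0.4, n), rng.normal(4.0, 0.8, n))
        fit = fit_em(PixelDataset(x), k=2)
        order = np.argsort(fit.params.means[:, 0])
        mus = fit.params.means[order, 0]
        sds = np.sqrt(fit.params.covariances[order, 0, 0])
        pis = fit.params.mixing[order]
        for est, true in [(mus[0], 0.5), (mus[1], 4.0), (sds[0], 0.4),
                          (sds[1], 0.8), (pis[0], 0.7), (pis[1], 0.3)]:
            assert abs(est - true) / true < 0.05

    def test_trace_non_decreasing(self, rng):
        x = np.concatenate([rng.normal(0, 1, 300), rng.normal(5, 0.5, 200)])
        fit = fit_em(PixelDataset(x), k=2)
        trace = np.asarray(fit.log_likelihood_trace)
        assert np.all(np.diff(trace) >= -1e-8)

    def test_too_few_points_rejected(self):
        with pytest.raises(InvalidInputError):
            fit_em(PixelDataset(np.array([1.0])), k=2)

    def test_deterministic_given_seed(self, rng):
        x = rng.normal(size=(200,))
        a = fit_em(PixelDataset(x), k=2, init="kmeans", seed=7)
        b = fit_em(PixelDataset(x), k=2, init="kmeans", seed=7)
        np.testing.assert_array_equal(a.params.means, b.params.means)
        np.testing.assert_array_equal(a.responsibilities.gamma, b.responsibilities.gamma)

    def test_permutation_invariance(self, rng):
        x = np.concatenate([rng.normal(0, 1, 100), rng.normal(4, 1, 100)])
        perm = rng.permutation(200)
        a = fit_em(PixelDataset(x), k=2)
        b = fit_em(PixelDataset(x[perm]), k=2)
        np.testing.assert_allclose(a.params.means, b.params.means, atol=1e-9)
        np.testing.assert_allclose(a.responsibilities.gamma[perm],
                                   b.responsibilities.gamma, atol=1e-9)

    def test_row_stochastic_and_simplex_every_iteration(self, rng):
        x = np.concatenate([np.zeros(200), rng.normal(3, 0.5, 60)])
        data = PixelDataset(x)
        fit = fit_em(data, k=2, max_iter=25)
        np.testing.assert_allclose(fit.responsibilities.gamma.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(fit.responsibilities.gamma >= 0)
        assert np.all(fit.responsibilities.gamma <= 1)
        assert fit.params.mixing.sum() == pytest.approx(1.0, abs=1e-12)


class TestClassify:
    def test_argmax_toward_higher_mean(self):
        params = make_params([0.0, 2.0], [1.0, 1.0], [0.5, 0.5])
        resp = ResponsibilityMatrix(np.array([[0.1, 0.9]]))
        assert classify(resp, params, shape=(1,))[0]

    def test_tie_goes_to_vessel(self):
        params = make_params([0.0, 2.0], [1.0, 1.0], [0.5, 0.5])
        resp = ResponsibilityMatrix(np.array([[0.5, 0.5]]))
        assert classify(resp, params, shape=(1,))[0]

    def test_k3_unsupported(self):
        params = make_params([0.0, 1.0, 2.0], [1.0, 1.0, 1.0], [0.3, 0.3, 0.4])
        resp = ResponsibilityMatrix(np.full((1, 3), 1 / 3))
        with pytest.raises(InvalidInputError):
            classify(resp, params, shape=(1,))

    def test_band_distance_map_recovered(self):
        from vesselem import distance_map
        mask = np.zeros((40, 40), bool)
        mask[15:25, :] = True
        dm = distance_map(mask)
        data = PixelDataset(dm.values.ravel())
        fit = fit_em(data, k=2)
        pred = classify(fit.responsibilities, fit.params, shape=mask.shape)
        disagree = np.mean(pred != mask)
        assert disagree <= 0.02
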