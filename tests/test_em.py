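"""EM machinery: E-step, penalized M-step updates, stopping, full fits."""

import numpy as np
import pytest
from scipy import linalg
from scipy.stats import multivariate_normal

from pmnmix.em import (
    MixtureModel,
    PenaltyConfig,
    aitken_should_stop,
    e_step,
    fit_pmnmm,
    init_kmeans,
    kkt_residual,
    penalized_loglik,
    predict_labels,
    solve_penalized_precision,
    update_means_penalized,
    update_precisions,
    update_weights,
    weighted_scatter_U,
    weighted_scatter_V,
)
from pmnmix.exceptions import SingularityError
from pmnmix.matnorm import (
    MatrixNormalParams,
    MatrixSampleSet,
    fit_matnorm_mle,
    sample_matnorm,
)

from conftest import random_params, random_spd, vec


def two_component_model(rng, p=3, q=3, penalties=None, separation=0.0):
    comps = [random_params(rng, p, q) for _ in range(2)]
    comps[1].M = comps[1].M + separation
    return MixtureModel(
        weights=np.array([0.4, 0.6]),
        components=comps,
        penalties=penalties or PenaltyConfig(),
    )


class TestEStep:
    def test_single_component_all_ones(self, rng):
        model = MixtureModel(
            weights=np.array([1.0]),
            components=[random_params(rng, 2, 3)],
        )
        tau = e_step(rng.normal(size=(5, 2, 3)), model)
        np.testing.assert_allclose(tau, 1.0)

    def test_identical_components_half_half(self, rng):
        comp = random_params(rng, 2, 2)
        model = MixtureModel(
            weights=np.array([0.5, 0.5]),
            components=[comp, MatrixNormalParams(comp.M, comp.U, comp.V)],
        )
        tau = e_step(rng.normal(size=(6, 2, 2)), model)
        np.testing.assert_allclose(tau, 0.5, atol=1e-12)

    def test_matches_vec_normal_density_ratio(self, rng):
        model = two_component_model(rng)
        X = rng.normal(size=(5, 3, 3))
        tau = e_step(X, model)
        for i in range(5):
            dens = np.array([
                w * multivariate_normal(
                    vec(c.M), np.kron(c.V, c.U)
                ).pdf(vec(X[i]))
                for w, c in zip(model.weights, model.components)
            ])
            np.testing.assert_allclose(tau[i], dens / dens.sum(), atol=1e-10)

    def test_rows_sum_to_one(self, rng):
        model = two_component_model(rng)
        tau = e_step(rng.normal(size=(20, 3, 3)), model)
        np.testing.assert_allclose(tau.sum(axis=1), 1.0, atol=1e-12)


class TestWeights:
    @pytest.mark.parametrize(
        "tau, expected",
        [
            (np.full((10, 2), 0.5), [0.5, 0.5]),
            (np.repeat([[1.0, 0.0], [0.0, 1.0]], [30, 70], axis=0), [0.3, 0.7]),
        ],
    )
    def test_column_means(self, tau, expected):
        np.testing.assert_allclose(update_weights(tau), expected)

    def test_sums_to_one(self, rng):
        tau = rng.dirichlet(np.ones(3), size=50)
        assert update_weights(tau).sum() == pytest.approx(1.0, abs=1e-12)


class TestMeanUpdate:
    def test_zero_penalty_gives_weighted_mean(self, rng):
        model = two_component_model(rng)
        X = rng.normal(size=(12, 3, 3))
        tau = e_step(X, model)
        means = update_means_penalized(X, tau, model, 0.0)
        for j in range(2):
            w = tau[:, j]
            np.testing.assert_allclose(
                means[j], np.einsum("i,ipq->pq", w, X) / w.sum()
            )

    def test_identity_covariances_scalar_threshold(self, rng):
        """With U=V=I the threshold collapses to lambda1 / sum(tau) per entry;
        each entry must match an independent scalar soft-threshold."""
        comps = [
            MatrixNormalParams(M=np.zeros((3, 4)), U=np.eye(3), V=np.eye(4))
        ]
        model = MixtureModel(weights=np.array([1.0]), components=comps)
        X = rng.normal(size=(10, 3, 4))
        tau = np.ones((10, 1))
        lam = 2.5
        (out,) = update_means_penalized(X, tau, model, lam)
        Mhat = X.mean(axis=0)
        t = lam / 10.0
        expected = np.where(np.abs(Mhat) > t, np.sign(Mhat) * (np.abs(Mhat) - t), 0.0)
        np.testing.assert_allclose(out, expected, atol=1e-14)

    def test_huge_penalty_zeroes_everything(self, rng):
        model = two_component_model(rng)
        X = rng.normal(size=(8, 3, 3))
        tau = e_step(X, model)
        for M in update_means_penalized(X, tau, model, 1e12):
            np.testing.assert_array_equal(M, 0.0)

    def test_negative_threshold_entries_are_clamped(self, rng):
        """A row/column-sum product can be negative for covariances with
        strong negative off-diagonals; those entries get no shrinkage."""
        U = np.array([[1.0, -0.6, 0.0], [-0.6, 1.0, -0.6], [0.0, -0.6, 1.0]])
        comps = [MatrixNormalParams(M=np.zeros((3, 3)), U=U, V=np.eye(3))]
        model = MixtureModel(weights=np.array([1.0]), components=comps)
        assert U.sum(axis=1)[1] < 0  # middle row sum is negative
        X = rng.normal(size=(6, 3, 3)) + 5.0
        tau = np.ones((6, 1))
        (out,) = update_means_penalized(X, tau, model, 1.0)
        Mhat = X.mean(axis=0)
        np.testing.assert_allclose(out[1], Mhat[1])  # untouched row
        assert np.all(np.abs(out[0]) < np.abs(Mhat[0]))  # shrunk rows

    def test_sparsity_monotone_in_lambda1(self, rng):
        """Holding tau, U, V fixed, the zero count of the thresholded mean is
        non-decreasing in lambda1 (elementwise soft-threshold property)."""
        model = two_component_model(rng)
        X = rng.normal(size=(15, 3, 3))
        tau = e_step(X, model)
        zeros = [
            sum(int((M == 0).sum()) for M in update_means_penalized(X, tau, model, lam))
            for lam in (0.0, 0.5, 2.0, 10.0, 100.0)
        ]
        assert zeros == sorted(zeros)


class TestScatters:
    def test_single_sample_centered_is_zero(self, rng):
        X = rng.normal(size=(1, 3, 4))
        S = weighted_scatter_U(X, [1.0], X[0], random_spd(rng, 4))
        np.testing.assert_allclose(S, 0.0, atol=1e-12)
        S = weighted_scatter_V(X, [1.0], X[0], random_spd(rng, 3))
        np.testing.assert_allclose(S, 0.0, atol=1e-12)

    def test_direct_summation_oracle(self, rng):
        X = rng.normal(size=(7, 3, 4))
        M = rng.normal(size=(3, 4))
        w = np.ones(7)
        S = weighted_scatter_U(X, w, M, np.eye(4))
        expected = sum((x - M) @ (x - M).T for x in X) / (7 * 4)
        np.testing.assert_allclose(S, expected, atol=1e-12)
        S = weighted_scatter_V(X, w, M, np.eye(3))
        expected = sum((x - M).T @ (x - M) for x in X) / (7 * 3)
        np.testing.assert_allclose(S, expected, atol=1e-12)

    def test_symmetric_output(self, rng):
        X = rng.normal(size=(9, 3, 4))
        S = weighted_scatter_U(X, rng.uniform(0.1, 1, 9), rng.normal(size=(3, 4)),
                               random_spd(rng, 4))
        np.testing.assert_allclose(S, S.T, atol=1e-12)

    def test_transpose_duality(self, rng):
        """The V-scatter on samples equals the U-scatter on transposed samples."""
        X = rng.normal(size=(6, 3, 4))
        M = rng.normal(size=(3, 4))
        w = rng.uniform(0.1, 1, 6)
        W = random_spd(rng, 3)
        a = weighted_scatter_V(X, w, M, W)
        b = weighted_scatter_U(X.transpose(0, 2, 1), w, M.T, W)
        np.testing.assert_allclose(a, b, atol=1e-12)


class TestPenalizedPrecision:
    def test_zero_penalty_inverts(self, rng):
        S = random_spd(rng, 4)
        np.testing.assert_allclose(
            solve_penalized_precision(S, 0.0), np.linalg.inv(S), atol=1e-8
        )

    def test_zero_penalty_singular_raises(self):
        with pytest.raises(SingularityError):
            solve_penalized_precision(np.ones((3, 3)), 0.0)

    def test_diagonal_scatter_analytic(self):
        """For diagonal S the fully penalized solution is
        diag(1/(s_i + rho)) by the stationarity condition."""
        S = np.diag([1.0, 2.0, 3.0, 0.5])
        rho = 0.2
        theta = solve_penalized_precision(S, rho)
        np.testing.assert_allclose(theta, np.diag(1.0 / (np.diag(S) + rho)), atol=1e-6)

    def test_kkt_conditions_random(self, rng):
        for rho in (0.01, 0.1, 0.5):
            S = random_spd(rng, 5, jitter=1.0)
            theta = solve_penalized_precision(S, rho)
            assert kkt_residual(theta, S, rho) <= 1e-4
            np.testing.assert_allclose(theta, theta.T)
            assert np.all(np.linalg.eigvalsh(theta) > 0)

    def test_large_penalty_diagonalizes(self, rng):
        S = random_spd(rng, 4, jitter=1.0)
        theta = solve_penalized_precision(S, 100.0)
        np.testing.assert_allclose(theta - np.diag(np.diag(theta)), 0.0, atol=1e-10)


class TestUpdatePrecisions:
    def test_zero_penalty_matches_flip_flop_round(self, rng):
        """With no penalty, one precision update equals one alternation of
        the flip-flop covariance recursion (then scale-normalized)."""
        comp = random_params(rng, 3, 4)
        model = MixtureModel(weights=np.array([1.0]), components=[comp])
        X = sample_matnorm(comp, 50, seed=8).data
        tau = np.ones((50, 1))
        (new,) = update_precisions(X, tau, model, 0.0, 0.0)
        # manual flip-flop round at these means
        D = X - comp.M
        Vinv = np.linalg.inv(comp.V)
        U_ff = sum(d @ Vinv @ d.T for d in D) / (50 * 4)
        V_ff = sum(d.T @ np.linalg.inv(U_ff) @ d for d in D) / (50 * 3)
        c = 3 / np.trace(U_ff)
        np.testing.assert_allclose(new.U, c * U_ff, atol=1e-8)
        np.testing.assert_allclose(new.V, V_ff / c, atol=1e-8)

    def test_mean_only_reduction_keeps_dense_precisions(self, rng):
        """lambda2 = lambda3 = 0 reduces to the mean-penalized model: the
        precisions are exact (dense) inverses of the covariance factors."""
        comp = random_params(rng, 3, 3)
        model = MixtureModel(weights=np.array([1.0]), components=[comp])
        X = sample_matnorm(comp, 60, seed=9).data
        (new,) = update_precisions(X, np.ones((60, 1)), model, 0.0, 0.0)
        np.testing.assert_allclose(new.U_inv @ new.U, np.eye(3), atol=1e-8)
        assert np.count_nonzero(new.U_inv) == 9

    def test_output_normalized_and_pd(self, rng):
        model = two_component_model(rng)
        X = rng.normal(size=(40, 3, 3))
        tau = e_step(X, model)
        for comp in update_precisions(X, tau, model, 0.05, 0.05):
            assert np.trace(comp.U) == pytest.approx(3.0)
            assert np.all(np.linalg.eigvalsh(comp.U) > 0)
            assert np.all(np.linalg.eigvalsh(comp.V) > 0)


class TestPenalizedLoglik:
    def test_zero_penalty_matches_mixture_oracle(self, rng):
        model = two_component_model(rng)
        X = rng.normal(size=(5, 3, 3))
        expected = sum(
            np.log(sum(
                w * multivariate_normal(vec(c.M), np.kron(c.V, c.U)).pdf(vec(x))
                for w, c in zip(model.weights, model.components)
            ))
            for x in X
        )
        assert penalized_loglik(X, model) == pytest.approx(expected, abs=1e-8)

    def test_identity_precision_penalty_arithmetic(self, rng):
        comps = [MatrixNormalParams(M=np.zeros((3, 4)), U=np.eye(3), V=np.eye(4))]
        base = MixtureModel(weights=np.array([1.0]), components=comps)
        pen = MixtureModel(
            weights=np.array([1.0]),
            components=[MatrixNormalParams(M=np.zeros((3, 4)), U=np.eye(3), V=np.eye(4))],
            penalties=PenaltyConfig(1.0, 1.0, 1.0),
        )
        X = rng.normal(size=(4, 3, 4))
        # |M|=0, |U^-1|_1 = p, |V^-1|_1 = q
        assert penalized_loglik(X, pen) == pytest.approx(
            penalized_loglik(X, base) - (3 + 4)
        )

    def test_adding_back_penalty_recovers_unpenalized(self, rng):
        model = two_component_model(rng, penalties=PenaltyConfig(0.7, 0.2, 0.3))
        X = rng.normal(size=(6, 3, 3))
        penalty = sum(
            0.7 * np.abs(c.M).sum()
            + 0.2 * np.abs(c.precision_U()).sum()
            + 0.3 * np.abs(c.precision_V()).sum()
            for c in model.components
        )
        bare = MixtureModel(weights=model.weights, components=model.components)
        assert penalized_loglik(X, model) + penalty == pytest.approx(
            penalized_loglik(X, bare)
        )


class TestAitken:
    def test_simple_history_continues(self):
        stop, l_hat = aitken_should_stop([1.0, 2.0, 2.5], 1e-3)
        assert not stop
        assert l_hat == pytest.approx(3.0)

    def test_geometric_sequence_extrapolates_limit(self):
        L, c, r = 10.0, 4.0, 0.6
        h = [L - c * r**t for t in range(1, 6)]
        stop, l_hat = aitken_should_stop(h, 1e-3)
        assert l_hat == pytest.approx(L, abs=1e-10)
        # stops exactly when the remaining gap L - l(t) drops below epsilon
        assert stop == (L - h[-1] <= 1e-3)
        h_long = [L - c * r**t for t in range(1, 30)]
        stop, _ = aitken_should_stop(h_long, 1e-3)
        assert stop

    def test_constant_history_stops(self):
        stop, _ = aitken_should_stop([5.0, 5.0, 5.0], 1e-3)
        assert stop

    def test_short_history_continues(self):
        assert aitken_should_stop([1.0, 2.0], 1e-3) == (False, None)

    def test_non_contracting_continues(self):
        stop, _ = aitken_should_stop([1.0, 2.0, 3.5], 1e-3)  # a = 1.5
        assert not stop


class TestInitAndFit:
    def make_separated(self, rng, n=40, sep=30.0):
        a = rng.normal(size=(n // 2, 3, 3))
        b = rng.normal(size=(n // 2, 3, 3)) + sep
        labels = np.repeat([0, 1], n // 2)
        return MatrixSampleSet(np.concatenate([a, b])), labels

    def test_init_separated_clusters_recovered(self, rng):
        samples, labels = self.make_separated(rng)
        model = init_kmeans(samples, 2, seed=0)
        tau = e_step(samples, model)
        pred = tau.argmax(axis=1)
        agreement = max((pred == labels).mean(), (pred != labels).mean())
        assert agreement == 1.0

    def test_init_deterministic(self, rng):
        samples, _ = self.make_separated(rng)
        a = init_kmeans(samples, 2, seed=3)
        b = init_kmeans(samples, 2, seed=3)
        for ca, cb in zip(a.components, b.components):
            np.testing.assert_array_equal(ca.M, cb.M)
            np.testing.assert_array_equal(ca.U, cb.U)

    def test_init_single_component_is_global_mle(self, rng):
        params = random_params(rng, 3, 3)
        samples = sample_matnorm(params, 100, seed=11)
        model = init_kmeans(samples, 1, seed=0)
        ref = fit_matnorm_mle(samples)
        np.testing.assert_allclose(model.components[0].M, ref.M)
        np.testing.assert_allclose(model.components[0].U, ref.U)

    def test_unpenalized_single_component_recovers_mle(self, rng):
        """lambda = (0,0,0) with G=1 must reproduce the flip-flop MLE."""
        params = random_params(rng, 3, 3)
        samples = sample_matnorm(params, 80, seed=12)
        model = fit_pmnmm(samples, 1, (0.0, 0.0, 0.0), n_restarts=1, seed=0)
        ref = fit_matnorm_mle(samples, tol=1e-4, max_iter=500)
        np.testing.assert_allclose(model.weights, [1.0])
        np.testing.assert_allclose(model.components[0].M, ref.M, atol=1e-8)
        np.testing.assert_allclose(
            np.kron(model.components[0].V, model.components[0].U),
            np.kron(ref.V, ref.U),
            rtol=0.02,
        )

    def test_fit_separates_well_separated_clusters(self, rng):
        samples, labels = self.make_separated(rng, n=60, sep=25.0)
        model = fit_pmnmm(samples, 2, (0.1, 0.01, 0.01), n_restarts=2, seed=0)
        pred, tau = predict_labels(samples, model)
        agreement = max((pred == labels).mean(), (pred != labels).mean())
        assert agreement == 1.0
        h = np.array(model.trace.loglik_history)
        assert np.all(np.diff(h) >= -1e-6 * np.abs(h[1:]))

    def test_fit_permutation_stable(self, rng):
        """On well-separated data the fitted model is the same (up to
        component relabeling) whatever the sample order."""
        samples, _ = self.make_separated(rng, n=40, sep=25.0)
        perm = rng.permutation(40)
        a = fit_pmnmm(samples, 2, (0.1, 0.0, 0.0), n_restarts=1, seed=5)
        b = fit_pmnmm(samples.data[perm], 2, (0.1, 0.0, 0.0), n_restarts=1, seed=5)
        means_a = sorted(np.sum(c.M) for c in a.components)
        means_b = sorted(np.sum(c.M) for c in b.components)
        np.testing.assert_allclose(means_a, means_b, rtol=1e-6)


class TestPredict:
    def test_map_labels_and_tie_rule(self, rng):
        model = two_component_model(rng, separation=20.0)
        X = np.stack([model.components[0].M, model.components[1].M])
        labels, tau = predict_labels(X, model)
        np.testing.assert_array_equal(labels, [0, 1])
        # tie broken toward the lower index
        assert np.array([[0.5, 0.5]]).argmax(axis=1)[0] == 0
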