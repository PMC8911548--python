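"""Gaussian-mixture EM on phasor clouds: density, fit, ordering, summaries."""

import math

import numpy as np
import pytest

from phasorseg import (
    AcquisitionConfig,
    cluster_summary,
    compute_phasor_cloud,
    fit_gmm,
    gmm_density,
    hard_assign,
    mono_exponential_phasor,
    order_clusters,
    tau_phase,
)
from phasorseg.gmm import FitResult, GMMParams
from phasorseg.errors import (
    DegenerateDataError,
    DomainError,
    InsufficientDataError,
)


def scalar_bivariate_normal(x, mean, cov):
    """From-scratch scalar evaluation of the bivariate normal density."""
    det = cov[0][0] * cov[1][1] - cov[0][1] * cov[1][0]
    dx, dy = x[0] - mean[0], x[1] - mean[1]
    inv = [
        [cov[1][1] / det, -cov[0][1] / det],
        [-cov[1][0] / det, cov[0][0] / det],
    ]
    maha = dx * (inv[0][0] * dx + inv[0][1] * dy) + dy * (
        inv[1][0] * dx + inv[1][1] * dy
    )
    return math.exp(-0.5 * maha) / (2 * math.pi * math.sqrt(det))


def random_spd(rng):
    a = rng.normal(size=(2, 2))
    return a @ a.T + 0.05 * np.eye(2)


def two_cluster_params(sep=1.0, var=0.01):
    return GMMParams(
        fractions=np.array([0.5, 0.5]),
        means=np.array([[-sep / 2, 0.0], [sep / 2, 0.0]]),
        covariances=np.tile(var * np.eye(2), (2, 1, 1)),
    )


class TestGMMDensity:
    def test_standard_normal_peak(self):
        params = GMMParams(
            fractions=np.array([1.0]),
            means=np.array([[0.3, 0.2]]),
            covariances=np.eye(2)[None],
        )
        assert gmm_density(np.array([0.3, 0.2]), params) == pytest.approx(
            1 / (2 * math.pi), rel=1e-12
        )

    def test_matches_scalar_formula_on_random_spd(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            cov = random_spd(rng)
            mean = rng.normal(size=2)
            fracs = rng.dirichlet([2.0, 2.0])
            params = GMMParams(
                fractions=fracs,
                means=np.stack([mean, mean + 1]),
                covariances=np.stack([cov, random_spd(rng)]),
            )
            x = rng.normal(size=2)
            expected = sum(
                f * scalar_bivariate_normal(x, m, c)
                for f, m, c in zip(
                    params.fractions, params.means, params.covariances
                )
            )
            assert gmm_density(x, params) == pytest.approx(expected, rel=1e-12)

    def test_integrates_to_one(self):
        """Numerical quadrature over +/- 8 SD recovers unit mass."""
        params = two_cluster_params(sep=0.6, var=0.02)
        lim = 0.3 + 8 * math.sqrt(0.02)
        xs = np.linspace(-lim, lim, 601)
        ys = np.linspace(-lim, lim, 601)
        gx, gy = np.meshgrid(xs, ys, indexing="ij")
        pts = np.column_stack([gx.ravel(), gy.ravel()])
        dens = gmm_density(pts, params).reshape(gx.shape)
        mass = np.trapezoid(np.trapezoid(dens, ys, axis=1), xs)
        assert mass == pytest.approx(1.0, abs=1e-3)

    def test_symmetric_midpoint(self):
        params = two_cluster_params(sep=0.4, var=0.01)
        mid = np.array([0.0, 0.0])
        single = scalar_bivariate_normal(mid, params.means[0], params.covariances[0])
        assert gmm_density(mid, params) == pytest.approx(single, rel=1e-12)

    def test_non_spd_covariance_rejected(self):
        with pytest.raises(DomainError):
            GMMParams(
                fractions=np.array([1.0]),
                means=np.array([[0.0, 0.0]]),
                covariances=np.array([[[1.0, 2.0], [2.0, 1.0]]]),
            )


def jittered_two_population_cloud(n_per=50, sigma=1e-3, seed=0):
    """Points at the closed-form phasors of tau = 3.7 and 1.7 ns with tiny
    seeded jitter."""
    config = AcquisitionConfig()
    centers = np.array(
        [mono_exponential_phasor(3.7, config), mono_exponential_phasor(1.7, config)]
    )
    rng = np.random.default_rng(seed)
    pts = np.vstack(
        [c + sigma * rng.standard_normal((n_per, 2)) for c in centers]
    )
    truth = np.repeat([0, 1], n_per)
    return pts, centers, truth


class TestFitGMM:
    def test_recovers_two_tight_populations(self):
        pts, centers, _ = jittered_two_population_cloud()
        result = fit_gmm(pts, k=2, seed=1)
        fitted = result.params.means
        # match fitted components to truth by nearest center
        order = np.argsort(-fitted[:, 0])  # 3.7 ns center has larger g
        truth_order = np.argsort(-centers[:, 0])
        np.testing.assert_allclose(
            fitted[order], centers[truth_order], atol=1e-3
        )
        np.testing.assert_allclose(result.params.fractions, [0.5, 0.5], atol=0.01)

    def test_k1_fit_equals_sample_moments(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(200, 2)) * [0.1, 0.05] + [0.6, 0.3]
        result = fit_gmm(pts, k=1, seed=0, n_starts=1)
        np.testing.assert_allclose(result.params.means[0], pts.mean(axis=0), atol=1e-9)
        np.testing.assert_allclose(
            result.params.covariances[0], np.cov(pts.T, bias=True), atol=1e-9
        )
        assert result.params.fractions[0] == pytest.approx(1.0, abs=1e-12)

    def test_log_likelihood_trace_non_decreasing(self):
        rng = np.random.default_rng(9)
        pts = rng.normal(size=(300, 2))
        result = fit_gmm(pts, k=2, seed=2)
        diffs = np.diff(result.log_likelihood_trace)
        assert np.all(diffs >= -1e-9)

    def test_responsibility_rows_sum_to_one(self):
        pts, _, _ = jittered_two_population_cloud(seed=3)
        result = fit_gmm(pts, k=2, seed=3)
        np.testing.assert_allclose(
            result.responsibilities.sum(axis=1), 1.0, atol=1e-10
        )

    def test_insufficient_data_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_gmm(np.zeros((5, 2)) + np.arange(5)[:, None], k=2, seed=0)

    def test_degenerate_identical_points_rejected(self):
        with pytest.raises(DegenerateDataError):
            fit_gmm(np.full((50, 2), 0.5), k=2, seed=0)

    def test_seeded_determinism(self):
        pts, _, _ = jittered_two_population_cloud(seed=8)
        a = fit_gmm(pts, k=2, seed=4)
        b = fit_gmm(pts, k=2, seed=4)
        np.testing.assert_array_equal(a.params.means, b.params.means)
        np.testing.assert_array_equal(a.responsibilities, b.responsibilities)

    def test_parameter_recovery_well_separated(self):
        """Two seeded Gaussian clouds >= 5 SD apart: means recovered within
        3 SE, label accuracy >= 0.99."""
        rng = np.random.default_rng(21)
        n = 400
        sd = 0.02
        mu_a, mu_b = np.array([0.3, 0.2]), np.array([0.5, 0.35])  # ~12 SD apart
        pts = np.vstack(
            [
                mu_a + sd * rng.standard_normal((n, 2)),
                mu_b + sd * rng.standard_normal((n, 2)),
            ]
        )
        truth = np.repeat([1, 2], n)
        result = fit_gmm(pts, k=2, seed=0)
        labels = hard_assign(result)
        se = sd / math.sqrt(n)
        means = result.params.means
        order = np.argsort(means[:, 0])
        assert np.all(np.abs(means[order[0]] - mu_a) < 3 * se)
        assert np.all(np.abs(means[order[1]] - mu_b) < 3 * se)
        # labels may be permuted relative to truth
        acc = max(
            (labels == truth).mean(), (3 - labels == truth).mean()
        )
        assert acc >= 0.99

    def test_permutation_invariance_of_canonical_fit(self):
        pts, _, _ = jittered_two_population_cloud(n_per=80, seed=12)
        config = AcquisitionConfig()

        class _Cloud:
            def __init__(self, coords):
                self.coords = coords
                self.config = config

        rng = np.random.default_rng(0)
        perm = rng.permutation(len(pts))
        a = order_clusters(fit_gmm(pts, k=2, seed=5), _Cloud(pts))
        b = order_clusters(fit_gmm(pts[perm], k=2, seed=5), _Cloud(pts[perm]))
        np.testing.assert_allclose(a.params.means, b.params.means, atol=1e-9)
        np.testing.assert_allclose(a.params.fractions, b.params.fractions, atol=1e-9)
        np.testing.assert_allclose(
            a.params.covariances, b.params.covariances, atol=1e-9
        )

    def test_agrees_with_sklearn_reference(self):
        """Independent cross-check against scikit-learn's EM on the same
        well-separated cloud: both reach the same optimum."""
        from sklearn.mixture import GaussianMixture

        pts, _, _ = jittered_two_population_cloud(n_per=100, sigma=5e-3, seed=17)
        ours = fit_gmm(pts, k=2, seed=0)
        ref = GaussianMixture(
            n_components=2, covariance_type="full", n_init=3, random_state=0,
            tol=1e-8,
        ).fit(pts)
        order_ours = np.argsort(ours.params.means[:, 0])
        order_ref = np.argsort(ref.means_[:, 0])
        np.testing.assert_allclose(
            ours.params.means[order_ours], ref.means_[order_ref], atol=1e-4
        )
        np.testing.assert_allclose(
            ours.params.fractions[order_ours], ref.weights_[order_ref], atol=1e-4
        )


class TestHardAssignAndOrdering:
    def _result_with_resp(self, resp):
        k = resp.shape[1]
        params = GMMParams(
            fractions=np.full(k, 1.0 / k),
            means=np.arange(2 * k, dtype=float).reshape(k, 2) / 10 + 0.1,
            covariances=np.tile(0.01 * np.eye(2), (k, 1, 1)),
        )
        return FitResult(
            params=params,
            responsibilities=resp,
            log_likelihood_trace=np.array([0.0]),
            n_iter=1,
            converged=True,
        )

    def test_argmax_assignment(self):
        result = self._result_with_resp(np.array([[0.7, 0.3], [0.2, 0.8]]))
        assert hard_assign(result).tolist() == [1, 2]

    def test_tie_breaks_to_lower_index(self):
        result = self._result_with_resp(np.array([[0.5, 0.5]]))
        assert hard_assign(result).tolist() == [1]

    def test_every_phasor_labelled(self):
        rng = np.random.default_rng(2)
        resp = rng.dirichlet([1, 1], size=50)
        labels = hard_assign(self._result_with_resp(resp))
        assert set(labels.tolist()) <= {1, 2}
        assert len(labels) == 50

    def test_longer_lifetime_becomes_cluster_one(self, noiseless_interface_map):
        cloud, tau_map = compute_phasor_cloud(noiseless_interface_map)
        fit = order_clusters(fit_gmm(cloud, k=2, seed=0), cloud)
        labels = hard_assign(fit)
        summaries = cluster_summary(cloud, tau_map, labels)
        assert summaries[0].cluster_id == 1
        assert summaries[0].mean_tau_ns > summaries[1].mean_tau_ns
        assert summaries[0].mean_tau_ns == pytest.approx(3.7, abs=0.02)

    def test_single_cluster_unchanged(self):
        params = GMMParams(
            fractions=np.array([1.0]),
            means=np.array([[0.8, 0.3]]),
            covariances=0.01 * np.eye(2)[None],
        )
        result = FitResult(
            params=params,
            responsibilities=np.ones((10, 1)),
            log_likelihood_trace=np.array([1.0]),
            n_iter=1,
            converged=True,
        )

        class _Cloud:
            coords = np.zeros((10, 2))
            config = AcquisitionConfig()

        ordered = order_clusters(result, _Cloud())
        np.testing.assert_array_equal(ordered.params.means, params.means)

    def test_equal_lifetime_ties_break_by_fraction(self):
        # both means on the same ray from origin -> identical tau-phase
        params = GMMParams(
            fractions=np.array([0.3, 0.7]),
            means=np.array([[0.4, 0.2], [0.8, 0.4]]),
            covariances=np.tile(0.01 * np.eye(2), (2, 1, 1)),
        )
        result = FitResult(
            params=params,
            responsibilities=np.ones((6, 2)) / 2,
            log_likelihood_trace=np.array([0.0]),
            n_iter=1,
            converged=True,
        )

        class _Cloud:
            coords = np.zeros((6, 2))
            config = AcquisitionConfig()

        ordered = order_clusters(result, _Cloud())
        assert ordered.params.fractions.tolist() == [0.7, 0.3]


class TestClusterSummary:
    def test_two_population_summary(self, poisson_interface_map):
        cloud, tau_map = compute_phasor_cloud(poisson_interface_map)
        fit = order_clusters(fit_gmm(cloud, k=2, seed=0), cloud)
        labels = hard_assign(fit)
        summaries = cluster_summary(cloud, tau_map, labels)
        assert sum(s.n_points for s in summaries) == len(cloud)
        assert summaries[0].mean_tau_ns == pytest.approx(3.7, abs=0.1)
        assert summaries[1].mean_tau_ns == pytest.approx(1.7, abs=0.1)
        assert all(s.sd_tau_ns >= 0 for s in summaries)

    def test_noiseless_population_sd_is_discretization_only(
        self, noiseless_interface_map
    ):
        cloud, tau_map = compute_phasor_cloud(noiseless_interface_map)
        fit = order_clusters(fit_gmm(cloud, k=2, seed=0), cloud)
        summaries = cluster_summary(cloud, tau_map, hard_assign(fit))
        assert all(s.sd_tau_ns <= 0.02 for s in summaries)

    def test_single_cluster_covers_cloud(self, noiseless_interface_map):
        cloud, tau_map = compute_phasor_cloud(noiseless_interface_map)
        labels = np.ones(len(cloud), dtype=int)
        (summary,) = cluster_summary(cloud, tau_map, labels)
        assert summary.fraction == 1.0
        assert summary.n_points == len(cloud)

    def test_population_sd_uses_n_denominator(self, noiseless_interface_map):
        cloud, tau_map = compute_phasor_cloud(noiseless_interface_map)
        labels = np.ones(len(cloud), dtype=int)
        (summary,) = cluster_summary(cloud, tau_map, labels)
        taus = tau_map.finite_values()
        assert summary.sd_tau_ns == pytest.approx(taus.std(ddof=0), rel=1e-12)
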