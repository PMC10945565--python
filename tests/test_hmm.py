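"""HMM inference and training, checked against independent oracles.

The forward-backward and Viterbi implementations are verified against
brute-force enumeration over all K^T state paths on small instances, and
cross-checked against hmmlearn on a shared parameter set.
"""

import itertools

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from statedyn.data import TimeSeriesSet
from statedyn.hmm import (
    GaussianHMM,
    HMMParams,
    dual_estimate,
    forward_backward,
    free_energy,
    viterbi,
)
from statedyn.simulate import (
    HMMSimSpec,
    distinct_covariances,
    random_covariances,
    sample_hmm,
)

# ---------------------------------------------------------------------------
# brute-force oracle


def enumerate_paths(params: HMMParams, x: np.ndarray):
    """Exact marginals / evidence / MAP path by summing over all paths."""
    K = params.n_states
    T = len(x)
    emis = np.stack(
        [
            multivariate_normal.pdf(
                x, mean=params.means[k], cov=params.covariances[k]
            ).reshape(T)
            for k in range(K)
        ],
        axis=1,
    )
    evidence = 0.0
    gamma = np.zeros((T, K))
    best_prob, best_path = -1.0, None
    for path in itertools.product(range(K), repeat=T):
        p = params.initial_distribution[path[0]] * emis[0, path[0]]
        for t in range(1, T):
            p *= params.transition_matrix[path[t - 1], path[t]] * emis[t, path[t]]
        evidence += p
        for t in range(T):
            gamma[t, path[t]] += p
        if p > best_prob:
            best_prob, best_path = p, path
    return gamma / evidence, np.log(evidence), np.array(best_path)


def random_instance(K, T, C, rng):
    A = rng.dirichlet(np.ones(K) * 2, size=K)
    pi = rng.dirichlet(np.ones(K))
    means = rng.normal(size=(K, C))
    covs = random_covariances(K, C, rng)
    params = HMMParams(means, covs, A, pi)
    x = rng.normal(size=(T, C))
    return params, x


class TestExactInferenceOracle:
    @pytest.mark.parametrize("K,T", [(2, 4), (2, 7), (3, 4), (3, 6)])
    def test_marginals_and_evidence_match_enumeration(self, K, T, rng):
        for _ in range(5):
            params, x = random_instance(K, T, 2, rng)
            g_oracle, loge_oracle, _ = enumerate_paths(params, x)
            post = forward_backward(params, x)
            assert np.abs(post.gamma - g_oracle).max() < 1e-10
            assert post.log_evidence == pytest.approx(loge_oracle, abs=1e-10)

    @pytest.mark.parametrize("K,T", [(2, 5), (3, 5)])
    def test_viterbi_matches_enumeration(self, K, T, rng):
        for _ in range(5):
            params, x = random_instance(K, T, 2, rng)
            _, _, path_oracle = enumerate_paths(params, x)
            assert np.array_equal(viterbi(params, x)[0], path_oracle)

    def test_xi_consistent_with_gamma_margins(self, rng):
        params, x = random_instance(3, 12, 2, rng)
        post = forward_backward(params, x)
        assert np.allclose(post.xi.sum(axis=2), post.gamma[:-1], atol=1e-10)
        assert np.allclose(post.xi.sum(axis=1), post.gamma[1:], atol=1e-10)

    def test_cross_check_against_hmmlearn(self, rng):
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        params, x = random_instance(3, 400, 4, rng)
        ref = hmmlearn.GaussianHMM(n_components=3, covariance_type="full")
        ref.startprob_ = params.initial_distribution
        ref.transmat_ = params.transition_matrix
        ref.means_ = params.means
        ref.covars_ = params.covariances
        loge_ref, gamma_ref = ref.score_samples(x)
        post = forward_backward(params, x)
        assert post.log_evidence == pytest.approx(loge_ref, abs=1e-6)
        assert np.abs(post.gamma - gamma_ref).max() < 1e-8
        assert np.array_equal(viterbi(params, x)[0], ref.predict(x))


class TestForwardBackwardProperties:
    def test_single_state_gives_iid_gaussian_evidence(self, rng):
        x = rng.normal(size=(200, 3))
        cov = np.eye(3) * 2.0
        params = HMMParams(np.zeros((1, 3)), cov[None], np.ones((1, 1)), np.ones(1))
        post = forward_backward(params, x)
        expected = multivariate_normal.logpdf(x, mean=np.zeros(3), cov=cov).sum()
        assert post.log_evidence == pytest.approx(expected, abs=1e-8)
        assert np.allclose(post.gamma, 1.0)

    def test_state_swap_symmetry(self, rng):
        # identical states: posterior cannot prefer either
        cov = np.eye(2)
        params = HMMParams(
            np.zeros((2, 2)), np.stack([cov, cov]), np.full((2, 2), 0.5),
            np.array([0.5, 0.5]),
        )
        post = forward_backward(params, rng.normal(size=(50, 2)))
        assert np.allclose(post.gamma, 0.5, atol=1e-12)

    def test_gamma_rows_sum_to_one_long_series(self, rng):
        params, _ = random_instance(3, 2, 3, rng)
        x = rng.normal(size=(100_000, 3))
        post = forward_backward(params, x)
        assert np.abs(post.gamma.sum(axis=1) - 1).max() < 1e-10
        assert np.isfinite(post.log_evidence)

    def test_subject_boundaries_restart_chains(self, rng):
        params, _ = random_instance(2, 2, 2, rng)
        xa, xb = rng.normal(size=(60, 2)), rng.normal(size=(40, 2))
        joint = forward_backward(params, [xa, xb])
        sep_a = forward_backward(params, xa)
        sep_b = forward_backward(params, xb)
        assert joint.log_evidence == pytest.approx(
            sep_a.log_evidence + sep_b.log_evidence, abs=1e-8
        )
        assert np.allclose(joint.gamma[:60], sep_a.gamma, atol=1e-12)
        assert np.allclose(joint.gamma[60:], sep_b.gamma, atol=1e-12)

    def test_singular_covariance_raises_helpful_error(self):
        cov = np.zeros((2, 2))
        with pytest.raises(np.linalg.LinAlgError, match="regulariz"):
            params = HMMParams(
                np.zeros((1, 2)), cov[None], np.ones((1, 1)), np.ones(1)
            )
            forward_backward(params, np.zeros((10, 2)))


class TestViterbiProperties:
    def test_likelihood_dominated_limit_is_nearest_mean(self, rng):
        means = np.array([[0.0, 0.0], [10.0, 10.0]])
        covs = np.stack([np.eye(2) * 1e-4] * 2)
        params = HMMParams(means, covs, np.full((2, 2), 0.5), np.array([0.5, 0.5]))
        x = np.vstack([means[rng.integers(2)] for _ in range(100)])
        x = x + 1e-3 * rng.normal(size=x.shape)
        path = viterbi(params, x)[0]
        nearest = np.argmin(
            ((x[:, None, :] - means[None]) ** 2).sum(axis=2), axis=1
        )
        assert np.array_equal(path, nearest)

    def test_single_state_constant_path(self, rng):
        params = HMMParams(
            np.zeros((1, 2)), np.eye(2)[None], np.ones((1, 1)), np.ones(1)
        )
        assert np.all(viterbi(params, rng.normal(size=(30, 2)))[0] == 0)


class TestFreeEnergy:
    def test_unused_extra_state_cannot_raise_exact_evidence(self, rng):
        # evidence is monotone under nesting: adding a state with zero
        # initial mass and unreachable transitions leaves it unchanged;
        # giving it mass can only average in more path probability
        params, x = random_instance(2, 30, 2, rng)
        K = 2
        A3 = np.zeros((3, 3))
        A3[:2, :2] = params.transition_matrix
        A3[2, 2] = 1.0
        pi3 = np.concatenate([params.initial_distribution, [0.0]])
        params3 = HMMParams(
            np.vstack([params.means, np.zeros(2)]),
            np.concatenate([params.covariances, np.eye(2)[None]]),
            A3,
            pi3,
        )
        assert free_energy(params3, x) == pytest.approx(
            free_energy(params, x), abs=1e-8
        )


class TestFit:
    def test_em_objective_non_increasing(self, rng):
        spec = HMMSimSpec(
            n_samples=3000,
            n_channels=3,
            state_means=2 * np.eye(3),
            state_covariances=distinct_covariances(3, 3, rng),
            transition_matrix=0.9,
            seed=0,
        )
        ts, _ = sample_hmm(spec)
        res = GaussianHMM(ts, 3).fit(n_iter=40, seed=1)
        diffs = np.diff(res.free_energy_trace)
        assert (diffs <= 1e-8 * np.abs(res.free_energy_trace[:-1]) + 1e-8).all()

    def test_same_seed_bit_identical(self, rng):
        x = rng.normal(size=(800, 2))
        r1 = GaussianHMM(x, 2).fit(n_iter=10, seed=7)
        r2 = GaussianHMM(x, 2).fit(n_iter=10, seed=7)
        assert np.array_equal(r1.params.covariances, r2.params.covariances)
        assert np.array_equal(r1.params.transition_matrix, r2.params.transition_matrix)
        assert r1.free_energy == r2.free_energy

    def test_transition_rows_sum_to_one_after_fit(self, rng):
        x = rng.normal(size=(1000, 2))
        res = GaussianHMM(x, 3).fit(n_iter=15, seed=0)
        assert np.allclose(res.params.transition_matrix.sum(axis=1), 1.0, atol=1e-10)
        assert np.abs(res.posterior.gamma.sum(axis=1) - 1).max() < 1e-10

    def test_mean_pinning_resolved_from_preparation_record(self, rng):
        from statedyn.prepare import prepare_tde_pipeline

        ts = TimeSeriesSet([rng.normal(size=(600, 1))], sampling_frequency=100.0)
        pd = prepare_tde_pipeline(ts, n_embeddings=5)
        model = GaussianHMM(pd, 2)
        assert model.pin_means
        res = model.fit(n_iter=5, seed=0)
        assert np.allclose(res.params.means, 0.0)

    def test_vb_mode_runs_and_reports_negative_elbo(self, rng):
        spec = HMMSimSpec(
            n_samples=2000,
            n_channels=2,
            state_means=np.array([[2.0, 0.0], [-2.0, 0.0]]),
            state_covariances=np.stack([np.eye(2)] * 2),
            transition_matrix=0.9,
            seed=3,
        )
        ts, _ = sample_hmm(spec)
        res = GaussianHMM(ts, 2).fit(n_iter=30, seed=0, algorithm="vb")
        assert res.algorithm == "vb"
        assert np.isfinite(res.free_energy)
        # negative ELBO must upper-bound the negative exact log evidence
        assert res.free_energy >= free_energy(res.params, ts.arrays) - 1e-6
        # the trend decreases
        assert res.free_energy_trace[-1] < res.free_energy_trace[0]


class TestDualEstimation:
    def test_one_hot_constant_gamma_equals_sample_moments(self, rng):
        x = rng.normal(size=(500, 3)) + 1.0
        ts = TimeSeriesSet([x], sampling_frequency=100.0)
        gamma = np.zeros((500, 2))
        gamma[:, 1] = 1.0
        est = dual_estimate([gamma], ts)
        assert est["missing"][0, 0]
        assert np.allclose(est["means"][0, 1], x.mean(axis=0), atol=1e-12)
        assert np.allclose(est["covariances"][0, 1], np.cov(x.T, bias=True), atol=1e-10)

    def test_uniform_gamma_gives_global_statistics(self, rng):
        x = rng.normal(size=(400, 2))
        ts = TimeSeriesSet([x], sampling_frequency=100.0)
        gamma = np.full((400, 3), 1 / 3)
        est = dual_estimate([gamma], ts)
        for k in range(3):
            assert np.allclose(est["means"][0, k], x.mean(axis=0), atol=1e-12)

    def test_recovers_subject_specific_means(self):
        spec = HMMSimSpec(
            n_samples=20_000,
            n_channels=3,
            n_subjects=2,
            state_means=3 * np.eye(3),
            state_covariances=np.stack([np.eye(3)] * 3),
            transition_matrix=0.9,
            subject_jitter=0.5,
            seed=21,
        )
        ts, paths = sample_hmm(spec)
        est = dual_estimate(paths, ts, n_states=3)
        # per-subject means must match that subject's own empirical means
        for s in range(2):
            for k in range(3):
                sel = paths[s] == k
                assert np.allclose(
                    est["means"][s, k], ts.arrays[s][sel].mean(axis=0), atol=1e-10
                )
        # jittered subjects differ
        assert np.abs(est["means"][0] - est["means"][1]).max() > 0.1
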