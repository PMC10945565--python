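"""Soft-mixture model: mixing arithmetic and small-scale inference checks."""

import numpy as np
import pytest

from statedyn.dynemo import (
    DyNeMo,
    DyNeMoParams,
    binarize_mixing,
    mix_parameters,
    renormalize_mixing,
    softmax_mixing,
)
from statedyn.pipeline import align_states
from statedyn.simulate import (
    HMMSimSpec,
    MixtureSimSpec,
    distinct_covariances,
    sample_hmm,
    sample_soft_mixture,
)


class TestSoftmaxMixing:
    def test_zero_logits_uniform(self):
        alpha = softmax_mixing(np.zeros((10, 4)))
        assert np.allclose(alpha, 0.25, atol=1e-12)

    def test_dominant_logit_one_hot_limit(self):
        alpha = softmax_mixing(np.array([[50.0, 0.0, 0.0]]))
        assert alpha[0, 0] > 1 - 1e-12

    def test_shift_invariance(self, rng):
        theta = rng.normal(size=(100, 3))
        assert np.allclose(
            softmax_mixing(theta), softmax_mixing(theta + 5.0), atol=1e-12
        )

    def test_rows_on_simplex(self, rng):
        alpha = softmax_mixing(rng.normal(size=(1000, 5)) * 10)
        assert np.allclose(alpha.sum(axis=1), 1.0, atol=1e-10)
        assert (alpha >= 0).all()


class TestMixParameters:
    def test_one_hot_selects_mode(self, spd_covs):
        means = np.arange(15).reshape(3, 5).astype(float)
        alpha = np.array([[0.0, 1.0, 0.0]])
        m, C = mix_parameters(alpha, means, spd_covs)
        assert np.array_equal(m[0], means[1])
        assert np.array_equal(C[0], spd_covs[1])

    def test_identical_modes_alpha_independent(self, rng):
        cov = np.eye(2)
        covs = np.stack([cov] * 3)
        means = np.tile([1.0, 2.0], (3, 1))
        for alpha in (np.array([[1, 0, 0.0]]), np.array([[0.2, 0.3, 0.5]])):
            m, C = mix_parameters(alpha, means, covs)
            assert np.allclose(m[0], [1, 2])
            assert np.allclose(C[0], cov)

    def test_matches_direct_weighted_sum(self, rng, spd_covs):
        means = rng.normal(size=(3, 5))
        alpha = rng.dirichlet(np.ones(3), size=7)
        m, C = mix_parameters(alpha, means, spd_covs)
        for t in range(7):
            assert np.allclose(m[t], sum(alpha[t, j] * means[j] for j in range(3)),
                               atol=1e-12)
            assert np.allclose(C[t], sum(alpha[t, j] * spd_covs[j] for j in range(3)),
                               atol=1e-12)

    def test_mixed_covariance_eigenvalue_bound(self, rng, spd_covs):
        # convexity: smallest eigenvalue of the mix >= min over modes
        alpha = rng.dirichlet(np.ones(3), size=20)
        _, C = mix_parameters(alpha, np.zeros((3, 5)), spd_covs)
        floor = min(np.linalg.eigvalsh(c).min() for c in spd_covs)
        assert np.linalg.eigvalsh(C).min() >= floor - 1e-10


class TestRenormalizeMixing:
    def test_hand_computed_two_mode_case(self):
        covs = np.stack([2 * np.eye(1), np.eye(1)])  # traces 2 and 1
        out = renormalize_mixing(np.array([[0.5, 0.5]]), covs)
        assert np.allclose(out, [[2 / 3, 1 / 3]], atol=1e-12)

    def test_equal_traces_identity(self, rng):
        covs = np.stack([np.eye(3), np.diag([2.0, 0.5, 0.5])])
        alpha = rng.dirichlet(np.ones(2), size=50)
        assert np.allclose(renormalize_mixing(alpha, covs), alpha, atol=1e-12)

    def test_one_hot_stays_one_hot(self):
        covs = np.stack([np.eye(2) * 5, np.eye(2)])
        out = renormalize_mixing(np.array([[1.0, 0.0], [0.0, 1.0]]), covs)
        assert np.allclose(out, np.eye(2), atol=1e-12)

    def test_rows_sum_to_one(self, rng, spd_covs):
        alpha = rng.dirichlet(np.ones(3), size=200)
        out = renormalize_mixing(alpha, spd_covs)
        assert np.allclose(out.sum(axis=1), 1.0, atol=1e-10)


class TestBinarizeMixing:
    def test_separable_mixture_recovered(self, rng):
        lo = rng.normal(0.1, 0.01, size=2000)
        hi = rng.normal(0.6, 0.01, size=2000)
        values = np.concatenate([lo, hi])
        truth = np.concatenate([np.zeros(2000, bool), np.ones(2000, bool)])
        on, threshold = binarize_mixing(values, seed=0)
        assert 0.2 < threshold < 0.5
        assert (on == truth).mean() > 0.99

    def test_constant_series_warns_all_off(self):
        with pytest.warns(UserWarning, match="constant"):
            on, threshold = binarize_mixing(np.full(100, 0.3))
        assert not on.any()

    def test_two_level_switcher_jaccard(self, rng):
        truth = rng.random(5000) < 0.3
        values = np.where(truth, 0.7, 0.2) + 0.02 * rng.normal(size=5000)
        on, _ = binarize_mixing(values, seed=0)
        jac = (on & truth).sum() / (on | truth).sum()
        assert jac > 0.95


class TestFit:
    def test_single_mode_reduces_to_gaussian(self, rng):
        x = rng.normal(size=(2000, 3))
        res = DyNeMo(x, 1, pin_means=True).fit(n_iter=100, seed=0)
        assert np.allclose(res.alpha, 1.0)
        # the single mode covariance approaches the sample covariance
        assert np.allclose(
            res.params.mode_covariances[0], np.cov(x.T, bias=True), atol=0.15
        )

    def test_seeded_runs_reproducible(self, rng):
        x = rng.normal(size=(1500, 3))
        r1 = DyNeMo(x, 2, pin_means=True).fit(n_iter=30, seed=3)
        r2 = DyNeMo(x, 2, pin_means=True).fit(n_iter=30, seed=3)
        assert np.array_equal(r1.alpha, r2.alpha)
        assert r1.free_energy == r2.free_energy

    def test_loss_trend_decreases(self, rng):
        covs = distinct_covariances(2, 3, rng)
        spec = MixtureSimSpec(
            n_samples=5000, n_channels=3, mode_means=np.zeros((2, 3)),
            mode_covariances=covs, seed=0,
        )
        ts, _ = sample_soft_mixture(spec)
        res = DyNeMo(ts, 2, pin_means=True).fit(n_iter=200, seed=0)
        assert np.mean(res.loss_trace[-20:]) < np.mean(res.loss_trace[:20])

    def test_recovers_mixing_small_scale(self, rng):
        covs = distinct_covariances(3, 5, np.random.default_rng(5))
        spec = MixtureSimSpec(
            n_samples=10_000, n_channels=5, mode_means=np.zeros((3, 5)),
            mode_covariances=covs, seed=2,
        )
        ts, alpha = sample_soft_mixture(spec)
        res = DyNeMo(ts, 3, pin_means=True).fit(n_iter=400, seed=0)
        perm = align_states(DyNeMoParams(np.zeros((3, 5)), covs), res)
        ra_true = renormalize_mixing(alpha, covs)
        for j in range(3):
            r = np.corrcoef(ra_true[:, j], res.renormalized_alpha[:, perm[j]])[0, 1]
            assert r > 0.75

    def test_hard_mixing_likelihood_matches_hmm_observation_model(self, rng):
        # with one-hot alpha the mixture likelihood equals the HMM's
        # per-state observation likelihood for the same path
        from scipy.stats import multivariate_normal

        covs = distinct_covariances(2, 3, rng)
        means = rng.normal(size=(2, 3))
        path = rng.integers(2, size=50)
        alpha = np.eye(2)[path]
        x = rng.normal(size=(50, 3))
        m, C = mix_parameters(alpha, means, covs)
        ll_mix = sum(
            multivariate_normal.logpdf(x[t], m[t], C[t]) for t in range(50)
        )
        ll_hmm = sum(
            multivariate_normal.logpdf(x[t], means[path[t]], covs[path[t]])
            for t in range(50)
        )
        assert ll_mix == pytest.approx(ll_hmm, abs=1e-8)

    def test_alpha_rows_sum_to_one_after_fit(self, rng):
        x = rng.normal(size=(1200, 2))
        res = DyNeMo(x, 2, pin_means=True).fit(n_iter=40, seed=1)
        assert np.allclose(res.alpha.sum(axis=1), 1.0, atol=1e-10)
        assert np.allclose(res.renormalized_alpha.sum(axis=1), 1.0, atol=1e-10)
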