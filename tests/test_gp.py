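"""GP regression: kernel, posterior algebra, MLL fitting, acquisition."""

import math

import numpy as np
import pytest

from cdrgen.encoders import onehot_encoder
from cdrgen.gp import (
    GPModel,
    KernelParams,
    fit_gp_on_sequences,
    fit_mll,
    kd_to_affinity,
    rbf_kernel,
)
from cdrgen.seqspace import ALPHABET


def dense_posterior_oracle(p, X, Y, z):
    """Brute-force dense-inverse posterior for cross-checking."""
    n = X.shape[0]
    K = np.array([[rbf_kernel(a, b, p) for b in X] for a in X]) + p.sigma_n**2 * np.eye(n)
    k = np.array([rbf_kernel(z, a, p) for a in X])
    Kinv = np.linalg.inv(K)
    mu = p.C + k @ Kinv @ (Y - p.C)
    var = p.delta - k @ Kinv @ k
    return mu, var


class TestAffinityScale:
    @pytest.mark.parametrize("kd,faff", [(1.0, 0.0), (0.04, 1.398), (100.0, -2.0)])
    def test_log_affinity(self, kd, faff):
        assert kd_to_affinity(kd) == pytest.approx(faff, abs=1e-3)

    def test_monotone_decreasing_and_positive_domain(self):
        assert kd_to_affinity(0.1) > kd_to_affinity(1.0) > kd_to_affinity(10.0)
        with pytest.raises(ValueError):
            kd_to_affinity(0.0)


class TestKernel:
    def test_self_kernel_is_delta(self):
        p = KernelParams(delta=2.5, lam=3.0)
        u = np.array([1.0, 2.0])
        assert rbf_kernel(u, u, p) == pytest.approx(2.5)

    def test_hand_evaluation(self):
        p = KernelParams(delta=2.0, lam=1.0)
        u, v = np.array([0.0, 0.0]), np.array([1.0, 1.0])  # ||u-v||^2 = 2
        assert rbf_kernel(u, v, p) == pytest.approx(2.0 * math.exp(-1.0))

    def test_vanishes_at_infinity_and_symmetric(self):
        p = KernelParams(delta=1.0, lam=0.5)
        u, v = np.zeros(3), np.full(3, 50.0)
        assert rbf_kernel(u, v, p) < 1e-300 or rbf_kernel(u, v, p) == 0.0
        a, b = np.array([0.3, -1.0]), np.array([2.0, 0.1])
        assert rbf_kernel(a, b, p) == rbf_kernel(b, a, p)


class TestPosterior:
    def test_prior_reduction_with_no_data(self):
        p = KernelParams(delta=1.7, lam=2.0, sigma_n=0.3, C=0.9)
        mu, var = GPModel(p).posterior(np.array([[1.0, 2.0]]))
        assert mu[0] == pytest.approx(0.9)
        assert var[0] == pytest.approx(1.7)

    def test_single_point_closed_form(self):
        p = KernelParams(delta=2.0, lam=1.0, sigma_n=0.5, C=0.3)
        x1, y1 = np.array([[0.0, 0.0]]), np.array([1.5])
        mu, var = GPModel(p, x1, y1).posterior(x1)
        d, sn2 = 2.0, 0.25
        assert mu[0] == pytest.approx(0.3 + d / (d + sn2) * (1.5 - 0.3))
        assert var[0] == pytest.approx(d - d**2 / (d + sn2))

    def test_matches_dense_oracle(self, rng):
        p = KernelParams(delta=1.3, lam=2.2, sigma_n=0.4, C=-0.2)
        X = rng.normal(size=(30, 5))
        Y = rng.normal(size=30)
        model = GPModel(p, X, Y)
        for _ in range(5):
            z = rng.normal(size=5)
            mu, var = model.posterior(z)
            mu0, var0 = dense_posterior_oracle(p, X, Y, z)
            assert mu[0] == pytest.approx(mu0, rel=1e-8, abs=1e-10)
            assert var[0] == pytest.approx(var0, rel=1e-8, abs=1e-10)

    def test_variance_bounded_by_prior_and_nonnegative(self, rng):
        p = KernelParams(delta=2.0, lam=1.0, sigma_n=0.1)
        X = rng.normal(size=(40, 3))
        model = GPModel(p, X, rng.normal(size=40))
        _, var = model.posterior(rng.normal(size=(20, 3)))
        assert np.all(var >= 0.0)
        assert np.all(var <= 2.0 + 1e-9)

    def test_noisy_variant_adds_observation_noise(self, rng):
        p = KernelParams(sigma_n=0.7)
        X = rng.normal(size=(5, 2))
        model = GPModel(p, X, rng.normal(size=5))
        z = rng.normal(size=(1, 2))
        _, lat = model.posterior(z)
        _, noisy = model.posterior(z, noisy=True)
        assert noisy[0] == pytest.approx(lat[0] + 0.49)

    def test_interpolates_as_noise_vanishes(self, rng):
        X = rng.normal(size=(10, 4))
        Y = rng.normal(size=10)
        p = KernelParams(delta=1.0, lam=2.0, sigma_n=1e-6)
        mu, _ = GPModel(p, X, Y).posterior(X)
        np.testing.assert_allclose(mu, Y, atol=1e-4)

    def test_invariant_under_training_permutation(self, rng):
        p = KernelParams(delta=1.1, lam=1.5, sigma_n=0.3, C=0.2)
        X = rng.normal(size=(25, 3))
        Y = rng.normal(size=25)
        perm = rng.permutation(25)
        z = rng.normal(size=(4, 3))
        mu1, var1 = GPModel(p, X, Y).posterior(z)
        mu2, var2 = GPModel(p, X[perm], Y[perm]).posterior(z)
        np.testing.assert_allclose(mu1, mu2, atol=1e-9)
        np.testing.assert_allclose(var1, var2, atol=1e-9)


class TestAcquisition:
    def test_beta_zero_is_posterior_mean(self, rng):
        p = KernelParams()
        X, Y = rng.normal(size=(8, 2)), rng.normal(size=8)
        model = GPModel(p, X, Y)
        z = rng.normal(size=(3, 2))
        np.testing.assert_allclose(model.acquisition(z, 0.0), model.posterior(z)[0])

    def test_strictly_increasing_in_beta(self, rng):
        p = KernelParams()
        model = GPModel(p, rng.normal(size=(8, 2)), rng.normal(size=8))
        z = rng.normal(size=(1, 2)) + 10.0  # far from data: sigma > 0
        vals = [model.acquisition(z, b)[0] for b in (-1.0, 0.0, 1.0, 2.0)]
        assert np.all(np.diff(vals) > 0)

    def test_zero_variance_removes_beta_dependence(self):
        p = KernelParams(delta=1.0, lam=1.0, sigma_n=0.0)
        X = np.array([[0.0]])
        model = GPModel(p, X, np.array([2.0]))
        vals = {round(float(model.acquisition(X, b)[0]), 9) for b in (-1, 0, 1, 2)}
        assert len(vals) == 1


class TestFitting:
    def test_mll_matches_dense_oracle_at_fixed_params(self, rng):
        p = KernelParams(delta=1.5, lam=2.0, sigma_n=0.3, C=0.1)
        X, Y = rng.normal(size=(15, 3)), rng.normal(size=15)
        model = GPModel(p, X, Y)
        n = 15
        K = np.array([[rbf_kernel(a, b, p) for b in X] for a in X]) + 0.09 * np.eye(n)
        r = Y - 0.1
        direct = (
            -0.5 * r @ np.linalg.inv(K) @ r
            - 0.5 * np.log(np.linalg.det(K))
            - 0.5 * n * np.log(2 * np.pi)
        )
        assert model.log_marginal_likelihood() == pytest.approx(direct, rel=1e-8)

    def test_fit_improves_mll_and_trace_trends_up(self, rng):
        X = rng.normal(size=(40, 3))
        Y = np.sin(X[:, 0]) + 0.1 * rng.normal(size=40)
        model = GPModel(KernelParams(delta=0.5, lam=5.0, sigma_n=0.5), X, Y)
        before = model.log_marginal_likelihood()
        fitted, trace = fit_mll(model, steps=300, return_trace=True)
        assert fitted.log_marginal_likelihood() >= before - 1e-9
        smoothed = np.convolve(trace, np.ones(10) / 10, mode="valid")
        assert smoothed[-1] >= smoothed[0]

    def test_parameter_recovery_from_known_gp(self, rng):
        # draw data from a GP with known hyperparameters; recover lambda +-50%
        true = KernelParams(delta=1.5, lam=2.0, sigma_n=0.2, C=0.5)
        X = rng.normal(size=(200, 2))
        K = np.array([[rbf_kernel(a, b, true) for b in X] for a in X])
        f = rng.multivariate_normal(np.full(200, true.C), K)
        Y = f + true.sigma_n * rng.normal(size=200)
        model = GPModel(KernelParams(delta=1.0, lam=1.0, sigma_n=0.5, C=0.0), X, Y)
        fitted = fit_mll(model, steps=600)
        assert 0.5 * true.lam <= fitted.params.lam <= 1.5 * true.lam

    def test_requires_two_points(self):
        model = GPModel(KernelParams(), np.zeros((1, 2)), np.zeros(1))
        with pytest.raises(ValueError):
            fit_mll(model)


class TestSequencePipeline:
    def test_fit_on_sequences_predicts_heldout_ranks(self, rng):
        # additive ground truth is exactly the GP's easy case; check rank skill
        from scipy.stats import spearmanr

        L = 8
        letters = list(ALPHABET)
        effects = {(i, a): rng.normal() for i in range(L) for a in letters}
        seqs = list({"".join(rng.choice(letters, L)) for _ in range(120)})
        truth = np.array([sum(effects[(i, a)] for i, a in enumerate(s)) for s in seqs])
        obs = truth + 0.1 * rng.normal(size=len(seqs))
        model, enc = fit_gp_on_sequences(seqs[:80], obs[:80], steps=150)
        pred = model.posterior(enc.encode_many(seqs[80:]))[0]
        assert spearmanr(pred, truth[80:]).statistic > 0.5
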