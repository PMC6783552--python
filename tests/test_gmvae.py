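import numpy as np
import pytest
from scipy.special import expit

from atacmix import cluster as cl
from atacmix import preprocess as pp
from atacmix.gmvae import (GMMPrior, GMVAE, EncoderPosterior, DecoderOutput,
                           TrainConfig, elbo, extract_features, impute,
                           init_gmm, responsibilities, _kl_terms)
from atacmix.simulate import SimConfig, simulate

TINY = TrainConfig(k=2, latent_dim=3, encoder_dims=(8, 5), batch_size=4,
                   seed=1, warmup_epochs=1, max_epochs=2)


def _tiny_model(seed=1):
    m = GMVAE(7, TINY)
    rng = np.random.default_rng(seed)
    m.params["mu_c"] = rng.normal(0, 1, (2, 3))
    m.params["lv_c"] = rng.normal(0, 0.3, (2, 3))
    m.params["rho"] = np.array([0.3, -0.2])
    return m


def _random_prior(rng, k=3, d=4):
    pi = rng.dirichlet(np.ones(k))
    return GMMPrior(pi, rng.normal(0, 2, (k, d)), rng.uniform(0.3, 2.5, (k, d)))


class TestResponsibilities:
    def test_single_component_is_one(self, rng):
        prior = GMMPrior([1.0], rng.normal(0, 1, (1, 4)), np.ones((1, 4)))
        g = responsibilities(rng.normal(0, 1, 4), prior).gamma
        np.testing.assert_allclose(g, [1.0])

    def test_dominance_at_component_mean(self):
        mu = np.array([[-20.0, 0.0], [20.0, 0.0]])
        prior = GMMPrior([0.5, 0.5], mu, np.ones((2, 2)))
        g = responsibilities(mu[0], prior).gamma
        assert g[0] > 1 - 1e-12

    def test_matches_naive_density_ratio(self, rng):
        """Log-space computation agrees with direct Gaussian densities."""
        prior = _random_prior(rng)
        for _ in range(20):
            z = rng.normal(0, 3, 4)
            dens = prior.pi * np.exp(
                -0.5 * np.sum((z - prior.mu) ** 2 / prior.sigma2
                              + np.log(2 * np.pi * prior.sigma2), axis=1))
            expected = dens / dens.sum()
            np.testing.assert_allclose(
                responsibilities(z, prior).gamma, expected, atol=1e-10)

    def test_extreme_z_no_nan_and_sums_to_one(self, rng):
        prior = _random_prior(rng)
        z = np.full(4, 1e3)  # all densities underflow without log-sum-exp
        g = responsibilities(z, prior).gamma
        assert np.all(np.isfinite(g))
        assert abs(g.sum() - 1) < 1e-8


class TestEncodeDecode:
    def test_latent_dimension_default_ten(self):
        m = GMVAE(50, TrainConfig(encoder_dims=(16, 8)))
        post = m.encode(np.zeros(50))
        assert post.mu_z.shape == (10,)

    def test_encode_deterministic_given_eps(self):
        m = _tiny_model()
        x = np.array([1, 0, 1, 1, 0, 0, 1], dtype=float)
        eps = np.zeros(3)
        a = m.encode(x, eps=eps)
        b = m.encode(x, eps=eps)
        np.testing.assert_array_equal(a.z, b.z)
        assert np.all(a.sigma2_z > 0)

    def test_shape_mismatch_raises(self):
        m = _tiny_model()
        with pytest.raises(ValueError, match="expected 7 peaks"):
            m.encode(np.zeros(9))
        with pytest.raises(ValueError, match="latent dim"):
            m.decode(np.zeros(5))

    def test_decode_zero_latent_gives_sigmoid_bias(self):
        m = _tiny_model()
        m.params["bd"] = np.linspace(-2, 2, 7)
        np.testing.assert_allclose(m.decode(np.zeros(3)).mu_x,
                                   expit(m.params["bd"]), atol=1e-12)

    def test_decode_monotone_in_positive_weight(self):
        m = _tiny_model()
        m.params["Wd"][0, 0] = 1.5  # feature 0 -> peak 0, positive weight
        lo = m.decode(np.array([0.0, 0.0, 0.0])).mu_x[0]
        hi = m.decode(np.array([2.0, 0.0, 0.0])).mu_x[0]
        assert hi > lo

    def test_mu_x_strictly_inside_unit_interval(self, rng):
        m = _tiny_model()
        z = rng.normal(0, 50, (30, 3))
        mu_x = m.decode(z).mu_x
        assert np.all(mu_x > 0) and np.all(mu_x < 1)


class TestElbo:
    def test_k1_reduces_to_standard_vae_kl(self, rng):
        """With a single component the KL term must equal the textbook
        Gaussian-prior VAE divergence, computed here independently."""
        d = 5
        mu1 = rng.normal(0, 1, d)
        s21 = rng.uniform(0.3, 2, d)
        prior = GMMPrior([1.0], mu1[None], s21[None])
        mu_z = rng.normal(0, 1, d)
        s2_z = rng.uniform(0.2, 1.5, d)
        kl = _kl_terms(mu_z, s2_z, np.array([1.0]), prior)[0]
        kl_vae = 0.5 * np.sum(np.log(s21 / s2_z)
                              + (s2_z + (mu_z - mu1) ** 2) / s21 - 1)
        assert abs(kl - kl_vae) < 1e-6

    def test_kl_nonnegative_over_random_inputs(self, rng):
        for _ in range(200):
            prior = _random_prior(rng)
            mu_z = rng.normal(0, 3, 4)
            s2_z = rng.uniform(0.05, 4, 4)
            gamma = responsibilities(rng.normal(0, 3, 4), prior).gamma
            assert _kl_terms(mu_z, s2_z, gamma, prior)[0] >= -1e-9

    def test_rejects_non_binary_input(self, rng):
        m = _tiny_model()
        post = m.encode(np.ones(7), eps=np.zeros(3))
        out = m.decode(post.z)
        gam = responsibilities(post.z, m.prior)
        with pytest.raises(ValueError, match="binary"):
            elbo(np.array([0, 1, 2, 0, 1, 0, 1]), post, out, gam, m.prior)

    def test_matches_monte_carlo_estimate(self, rng):
        """Closed-form ELBO equals the sampled estimate of
        E[log p(x,z,c) - log q(z,c|x)] with q(c|x) held at gamma."""
        d, k, n_peaks = 3, 2, 8
        prior = _random_prior(rng, k, d)
        m = GMVAE(n_peaks, TrainConfig(k=k, latent_dim=d, encoder_dims=(6, 4)))
        mu = rng.normal(0, 1, d)
        s2 = rng.uniform(0.2, 1.5, d)
        x = (rng.random(n_peaks) < 0.5).astype(float)
        gamma = responsibilities(mu, prior).gamma

        n = 100_000
        eps = rng.standard_normal((n, d))
        z = mu + np.sqrt(s2) * eps
        out = m.decode(z)
        post = EncoderPosterior(np.tile(mu, (n, 1)), np.tile(s2, (n, 1)), z)
        closed = elbo(np.tile(x, (n, 1)), post, out,
                      np.tile(gamma, (n, 1)), prior).mean()

        c = rng.choice(k, n, p=gamma)
        mu_x = out.mu_x
        recon = np.sum(x * np.log(mu_x) + (1 - x) * np.log(1 - mu_x), axis=1)
        lpz = -0.5 * np.sum(np.log(2 * np.pi * prior.sigma2[c])
                            + (z - prior.mu[c]) ** 2 / prior.sigma2[c], axis=1)
        lqz = -0.5 * np.sum(np.log(2 * np.pi * s2) + (z - mu) ** 2 / s2, axis=1)
        mc = np.mean(recon + lpz + np.log(prior.pi[c]) - lqz - np.log(gamma[c]))
        assert abs(closed - mc) < 0.05


class TestGradients:
    def test_analytic_gradients_match_finite_differences(self, rng):
        """Every parameter gradient of the batch loss agrees with central
        differences when the responsibilities are pinned."""
        m = _tiny_model()
        X = (rng.random((4, 7)) < 0.4).astype(float)
        eps = rng.standard_normal((4, 3))
        post = m.encode(X, eps=eps)
        gamma = responsibilities(post.z, m.prior).gamma
        _, _, _, grads = m._loss_and_grads(X, eps, gamma=gamma)
        h = 1e-6
        for name, p in m.params.items():
            num = np.zeros_like(p)
            it = np.nditer(p, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                orig = p[idx]
                p[idx] = orig + h
                lp = m._loss_and_grads(X, eps, gamma=gamma)[0]
                p[idx] = orig - h
                lm = m._loss_and_grads(X, eps, gamma=gamma)[0]
                p[idx] = orig
                num[idx] = (lp - lm) / (2 * h)
            ana = grads.get(name, np.zeros_like(p))
            scale = np.max(np.abs(num)) + 1e-8
            assert np.max(np.abs(ana - num)) / scale < 1e-5, name


class TestInitGmm:
    def test_separated_blobs_recover_centroids(self, rng):
        a = rng.normal(0, 0.2, (40, 3)) + np.array([5, 0, 0])
        b = rng.normal(0, 0.2, (40, 3)) - np.array([5, 0, 0])
        prior = init_gmm(np.vstack([a, b]), 2, seed=0)
        centers = prior.mu[np.argsort(prior.mu[:, 0])]
        np.testing.assert_allclose(centers[0], b.mean(0), atol=0.2)
        np.testing.assert_allclose(centers[1], a.mean(0), atol=0.2)
        assert abs(prior.pi.sum() - 1) < 1e-12

    def test_single_component_moments(self, rng):
        x = rng.normal(2, 1.5, (200, 2))
        prior = init_gmm(x, 1, seed=0)
        np.testing.assert_allclose(prior.mu[0], x.mean(0), atol=1e-6)
        np.testing.assert_allclose(prior.sigma2[0], x.var(0), rtol=0.02)

    def test_fewer_cells_than_components(self, rng):
        with pytest.raises(ValueError):
            init_gmm(rng.normal(0, 1, (2, 3)), 5)


class TestPriorValidation:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            GMMPrior([0.5, 0.6], np.zeros((2, 2)), np.ones((2, 2)))
        with pytest.raises(ValueError):
            GMMPrior([0.5, 0.5], np.zeros((2, 2)), np.zeros((2, 2)))

    def test_softmax_parameterization_keeps_pi_on_simplex(self, rng):
        m = _tiny_model()
        X = (rng.random((8, 7)) < 0.3).astype(float)
        adam = m._adam_init()
        for _ in range(5):
            _, _, _, g = m._loss_and_grads(X, rng.standard_normal((8, 3)))
            m._adam_step(g, adam)
            pi = m.prior.pi
            assert abs(pi.sum() - 1) < 1e-12 and np.all(pi >= 0)
            assert np.all(m.prior.sigma2 > 0)


@pytest.fixture(scope="module")
def fitted(trained_models):
    return trained_models.get(0.4, 0)


class TestTraining:
    def test_elbo_trend_nondecreasing(self, fitted):
        """Moving average of the per-epoch ELBO rises over joint training."""
        _, _, model = fitted
        elbos = [h["elbo"] for h in model.history if h["phase"] == "joint"]
        w = 10
        smooth = np.convolve(elbos, np.ones(w) / w, mode="valid")
        assert smooth[-1] > smooth[0]
        # late training does not regress below the early phase
        assert np.min(smooth[-5:]) > np.max(smooth[:3]) - 5

    def test_latent_features_shape_and_identical_cells(self, fitted):
        bundle, binarized, model = fitted
        feats = extract_features(binarized, model)
        assert feats.shape == (300, 10)
        x = binarized.dense()[:, 0]
        dup = np.vstack([x, x])
        post = model.encode(dup, eps=np.zeros((2, 10)))
        np.testing.assert_array_equal(post.mu_z[0], post.mu_z[1])

    def test_impute_shape_and_range(self, fitted):
        bundle, binarized, model = fitted
        imputed = impute(binarized, model)
        assert imputed.shape == binarized.shape
        assert np.all((imputed > 0) & (imputed < 1))

    def test_untrained_model_refuses_feature_extraction(self):
        m = _tiny_model()
        from atacmix.matrix_io import Peak, PeakByCellMatrix
        mat = PeakByCellMatrix(np.zeros((7, 2), dtype=int),
                               [Peak("c", i, i + 1) for i in range(7)],
                               ["a", "b"])
        with pytest.raises(RuntimeError):
            extract_features(mat, m)

    def test_fit_requires_binary_input(self):
        m = _tiny_model()
        with pytest.raises(ValueError, match="binary"):
            m.fit(np.full((6, 7), 2.0))

    def test_seed_reproducibility_small(self):
        rng = np.random.default_rng(0)
        X = (rng.random((20, 7)) < 0.3).astype(float)
        losses = []
        for _ in range(2):
            m = _tiny_model()
            m.fit(X)
            losses.append(m.history[-1]["elbo"])
        assert losses[0] == losses[1]

    def test_save_load_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        X = (rng.random((10, 7)) < 0.3).astype(float)
        m = _tiny_model()
        m.fit(X)
        m.save(tmp_path / "model")
        back = GMVAE.load(tmp_path / "model")
        np.testing.assert_array_equal(
            back.encode(X, eps=np.zeros((10, 3))).mu_z,
            m.encode(X, eps=np.zeros((10, 3))).mu_z)
        assert (tmp_path / "model" / "training_log.tsv").exists()


def test_quick_mode_encoder_shape():
    cfg = TrainConfig(quick=True)
    assert cfg.effective_encoder_dims == (1024, 128)
    assert cfg.effective_patience == 10
    m = GMVAE(500, cfg)
    assert m.params["enc_W0"].shape == (500, 1024)
    assert m.params["enc_W1"].shape == (1024, 128)
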