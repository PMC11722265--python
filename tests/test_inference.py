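import numpy as np
import pytest

from ephyslink.features import FeatureStandardizer
from ephyslink.inference import (
    PosteriorModel,
    TrainingConfig,
    build_training_set,
    map_estimate,
    posterior_entropy,
    train_npe,
)
from ephyslink.library import SimulationLibrary
from ephyslink.mdn import ConditionalMDN, MDNConfig
from ephyslink.params import DEFAULT_PRIOR, PriorBox

TOY_PRIOR_1D = PriorBox(lower=np.array([-20.0]), upper=np.array([20.0]), names=("theta",))


def _toy_library(n=300, seed=0):
    rng = np.random.default_rng(seed)
    theta = rng.uniform(DEFAULT_PRIOR.lower, DEFAULT_PRIOR.upper, size=(n, 13))
    x = rng.normal(size=(n, 23))
    return SimulationLibrary(
        theta=theta,
        x_raw=x.copy(),
        x_transformed=x,
        defined=np.ones(n, bool),
        standardizer=FeatureStandardizer(mean=np.zeros(23), sd=np.ones(23)),
    )


def _toy_posterior(noise_sd=0.3, seed=0, n=4000, epochs=60):
    """1-D linear-Gaussian toy wrapped in the posterior-model interface."""
    rng = np.random.default_rng(seed)
    th = rng.normal(size=(n, 1))
    x = th + noise_sd * rng.normal(size=(n, 1))
    mdn = ConditionalMDN(1, 1, MDNConfig(n_components=3, hidden=(24,), max_epochs=epochs, seed=seed))
    mdn.fit(x, th)
    return PosteriorModel(
        mdn=mdn,
        theta_mean=np.zeros(1),
        theta_sd=np.ones(1),
        prior=TOY_PRIOR_1D,
        standardizer=FeatureStandardizer(mean=np.zeros(23), sd=np.ones(23)),
        config=TrainingConfig(scheme="standard"),
    )


class TestBuildTrainingSet:
    def setup_method(self):
        self.lib = _toy_library()
        self.obs = self.lib.x_transformed[:5] + 0.05

    def test_standard_uses_all_defined_pairs(self):
        cfg = TrainingConfig(scheme="standard")
        theta, x = build_training_set(self.lib, None, cfg)
        assert theta.shape[0] == len(self.lib)

    def test_nonstandard_without_observations_raises(self):
        cfg = TrainingConfig(scheme="best_euclidean")
        with pytest.raises(ValueError):
            build_training_set(self.lib, None, cfg)

    def test_zero_noise_equals_best_euclidean(self):
        cfg_be = TrainingConfig(scheme="best_euclidean", n_close=40)
        cfg_n0 = TrainingConfig(scheme="noise_ephys", sigma=0.0, n_close=40)
        t1, x1 = build_training_set(self.lib, self.obs, cfg_be)
        t2, x2 = build_training_set(self.lib, self.obs, cfg_n0)
        assert np.array_equal(t1, t2) and np.array_equal(x1, x2)

    def test_noise_amplitude_matches_sigma(self):
        cfg_be = TrainingConfig(scheme="best_euclidean", n_close=150)
        cfg_n = TrainingConfig(scheme="noise_ephys", sigma=0.1, n_close=150, seed=1)
        _, x_clean = build_training_set(self.lib, self.obs, cfg_be)
        _, x_noisy = build_training_set(self.lib, self.obs, cfg_n)
        diff = x_noisy - x_clean
        assert diff.std() == pytest.approx(0.1, rel=0.05)
        assert np.abs(diff.mean()) < 0.01

    def test_augmentation_doubles_the_subset(self):
        cfg_be = TrainingConfig(scheme="best_euclidean", n_close=40)
        cfg_aug = TrainingConfig(scheme="augmentation", sigma=0.1, n_close=40)
        t1, _ = build_training_set(self.lib, self.obs, cfg_be)
        t2, x2 = build_training_set(self.lib, self.obs, cfg_aug)
        assert t2.shape[0] == 2 * t1.shape[0]
        assert np.array_equal(t2[: t1.shape[0]], t1)

    def test_param_noise_stays_inside_prior_box(self):
        cfg = TrainingConfig(scheme="noise_ephys_params", sigma=0.5, n_close=100, seed=2)
        theta, _ = build_training_set(self.lib, self.obs, cfg)
        assert DEFAULT_PRIOR.contains(theta).all()


class TestPosteriorOperations:
    def test_map_with_one_sample_is_that_draw(self):
        model = _toy_posterior()
        x0 = np.array([0.4])
        draw = model.sample(1, x0, seed=5)[0]
        mp = map_estimate(model, x0, n_samples=1, seed=np.random.default_rng(
            np.random.SeedSequence((5,))
        ))
        # same rng construction is not guaranteed; check determinism instead
        a = map_estimate(model, x0, n_samples=200, seed=11)
        b = map_estimate(model, x0, n_samples=200, seed=11)
        assert np.array_equal(a, b)
        assert np.isfinite(draw).all() and np.isfinite(mp).all()

    def test_map_tracks_conditional_mean_in_linear_toy(self):
        model = _toy_posterior(noise_sd=0.3, seed=1)
        # analytic posterior mean for x0: x0 / (1 + sd^2)
        x0 = np.array([0.8])
        mp = map_estimate(model, x0, n_samples=4000, seed=0)
        assert mp[0] == pytest.approx(0.8 / 1.09, abs=0.15)

    def test_entropy_orders_posterior_widths(self):
        wide = _toy_posterior(noise_sd=1.0, seed=2)
        narrow = _toy_posterior(noise_sd=0.1, seed=2)
        x0 = np.array([0.0])
        assert posterior_entropy(narrow, x0, K=500, seed=0) < posterior_entropy(
            wide, x0, K=500, seed=0
        )

    def test_entropy_with_single_draw(self):
        model = _toy_posterior(seed=3)
        x0 = np.array([0.2])
        rng_draw = model.sample(1, x0, seed=4)
        e = posterior_entropy(model, x0, K=1, seed=4)
        assert e == pytest.approx(-float(model.log_density(rng_draw, x0[None, :])[0]))

    def test_entropy_seed_reproducible(self):
        model = _toy_posterior(seed=4)
        x0 = np.array([-0.3])
        assert posterior_entropy(model, x0, seed=8) == posterior_entropy(model, x0, seed=8)

    def test_posterior_concentrates_on_generating_parameter(self):
        model = _toy_posterior(noise_sd=0.2, seed=5)
        rng = np.random.default_rng(6)
        wins = 0
        for _ in range(50):
            th_star = rng.normal()
            x_obs = np.array([th_star + 0.2 * rng.normal()])
            lp_star = float(model.log_density(np.array([[th_star]]), x_obs[None, :])[0])
            lp_rand = float(
                model.log_density(np.array([[rng.normal() * 3]]), x_obs[None, :])[0]
            )
            wins += lp_star > lp_rand
        assert wins >= 45


class TestTrainNPE:
    def test_minimum_pair_count_enforced(self):
        lib = _toy_library(n=30)
        cfg = TrainingConfig(scheme="standard", min_pairs=100)
        pairs = build_training_set(lib, None, cfg)
        with pytest.raises(ValueError):
            train_npe(pairs, cfg, lib)

    def test_training_is_seed_deterministic(self):
        lib = _toy_library(n=400, seed=9)
        cfg = TrainingConfig(
            scheme="standard", seed=13, mdn=MDNConfig(max_epochs=10, hidden=(16,))
        )
        pairs = build_training_set(lib, None, cfg)
        m1 = train_npe(pairs, cfg, lib)
        m2 = train_npe(pairs, cfg, lib)
        x0 = np.zeros(23)
        assert np.array_equal(m1.sample(20, x0, seed=1), m2.sample(20, x0, seed=1))
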