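"""Posterior estimation of biophysical parameters from summary features.

Standard neural posterior estimation (NPE) trains a conditional density
estimator q(theta | x) on (parameter, feature) pairs simulated from the
prior. Under model-data mismatch -- observations lying in a region of
feature space the simulator barely reaches -- standard NPE extrapolates
poorly. The noise-robust variant (NPE-N) restricts training to simulations
near the observations in standardized feature space and smooths that
neighborhood by adding isotropic Gaussian noise (default amplitude 0.1
z-units) to their standardized features.

Training schedules
------------------
``standard``            all defined library pairs.
``best_euclidean``      union of the ``n_close`` nearest defined pairs per
                        observation.
``noise_ephys``         the same subset with N(0, sigma^2) added to every
                        standardized feature (NPE-N).
``noise_ephys_params``  additionally N(0, sigma^2) on standardized
                        parameters, mapped back and clipped to the prior box.
``augmentation``        clean subset plus its noisy copy.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .features import FeatureStandardizer
from .library import SimulationLibrary, nearest
from .mdn import ConditionalMDN, MDNConfig
from .params import PriorBox
from .simulator import StimulusProtocol, simulate_batch
from .features import extract_features_batch, transform_matrix

__all__ = [
    "TrainingConfig",
    "PosteriorModel",
    "FitReport",
    "build_training_set",
    "train_npe",
    "map_estimate",
    "posterior_entropy",
    "evaluate_fit",
]

SCHEMES = ("standard", "best_euclidean", "noise_ephys", "noise_ephys_params", "augmentation")


@dataclass
class TrainingConfig:
    """How to assemble training pairs and fit the density estimator."""

    scheme: str = "noise_ephys"
    sigma: float = 0.1            # noise amplitude in z-units
    n_close: int = 1000           # nearest simulations kept per observation
    mdn: MDNConfig = field(default_factory=MDNConfig)
    min_pairs: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"scheme must be one of {SCHEMES}")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


@dataclass
class PosteriorModel:
    """Trained conditional density q(theta | x) over original parameter units.

    The estimator works on standardized parameters internally; log-densities
    are reported in original units through the constant change of variables.
    Conditioning vectors x are in the library's z-scored feature space.
    """

    mdn: ConditionalMDN
    theta_mean: np.ndarray
    theta_sd: np.ndarray
    prior: PriorBox
    standardizer: FeatureStandardizer
    config: TrainingConfig

    @property
    def _log_jacobian(self) -> float:
        return -float(np.sum(np.log(self.theta_sd)))

    def log_density(self, theta: np.ndarray, x: np.ndarray) -> np.ndarray:
        theta_s = (np.atleast_2d(theta) - self.theta_mean) / self.theta_sd
        return self.mdn.log_prob(theta_s, x) + self._log_jacobian

    def sample(self, n: int, x: np.ndarray, seed: int | np.random.Generator = 0) -> np.ndarray:
        """Posterior draws truncated to the prior support (rejection).

        The estimated density outside the prior box is an artifact of the
        unconstrained mixture parameterization; draws there are rejected.
        If the acceptance rate is extremely low the remainder is filled
        with clipped draws so the call always returns ``n`` samples.
        """
        rng = np.random.default_rng(seed)
        out = np.empty((0, self.theta_mean.size))
        for _ in range(50):
            need = n - out.shape[0]
            if need <= 0:
                break
            s = self.mdn.sample(max(need, 64), x, seed=rng)
            theta = s * self.theta_sd + self.theta_mean
            ok = self.prior.contains(theta)
            out = np.vstack([out, theta[ok][:need]])
        if out.shape[0] < n:
            s = self.mdn.sample(n - out.shape[0], x, seed=rng)
            out = np.vstack([out, self.prior.clip(s * self.theta_sd + self.theta_mean)])
        return out


def build_training_set(
    lib: SimulationLibrary,
    observations: Optional[np.ndarray],
    config: TrainingConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Assemble (theta, x_z) training pairs under the configured schedule.

    ``observations`` is an (m, 23) matrix in the library's z space (ignored
    by the ``standard`` scheme). Returns parameters in original units and
    features in z space.
    """
    z_all_idx = lib.defined_indices
    theta_all = lib.theta[z_all_idx]
    x_all = lib.standardizer.apply(lib.x_transformed[z_all_idx])

    if config.scheme == "standard":
        return theta_all, x_all

    if observations is None or len(observations) == 0:
        raise ValueError(f"scheme '{config.scheme}' requires observations")
    observations = np.atleast_2d(np.asarray(observations, dtype=float))

    n_close = min(config.n_close, z_all_idx.size)
    sel: set[int] = set()
    for obs in observations:
        idx, _ = nearest(obs, lib, k=n_close)
        sel.update(idx.tolist())
    sel_idx = np.array(sorted(sel))
    pos = np.searchsorted(z_all_idx, sel_idx)
    theta = theta_all[pos]
    x = x_all[pos]

    if config.scheme == "best_euclidean" or config.sigma == 0:
        if config.scheme == "augmentation":
            return np.concatenate([theta, theta]), np.concatenate([x, x])
        return theta, x

    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 7)))
    x_noisy = x + config.sigma * rng.standard_normal(x.shape)
    if config.scheme == "noise_ephys":
        return theta, x_noisy
    if config.scheme == "noise_ephys_params":
        t_mean = theta_all.mean(axis=0)
        t_sd = theta_all.std(axis=0)
        theta_s = (theta - t_mean) / t_sd
        theta_noisy = (theta_s + config.sigma * rng.standard_normal(theta_s.shape)) * t_sd + t_mean
        return lib.prior.clip(theta_noisy), x_noisy
    # augmentation
    return np.concatenate([theta, theta]), np.concatenate([x, x_noisy])


def train_npe(
    pairs: tuple[np.ndarray, np.ndarray],
    config: TrainingConfig,
    lib: SimulationLibrary,
) -> PosteriorModel:
    """Fit the conditional density estimator on (theta, x_z) pairs."""
    theta, x = pairs
    if theta.shape[0] < config.min_pairs:
        raise ValueError(f"need at least {config.min_pairs} training pairs, got {theta.shape[0]}")
    t_mean = theta.mean(axis=0)
    t_sd = theta.std(axis=0)
    t_sd[t_sd == 0] = 1.0
    theta_s = (theta - t_mean) / t_sd
    mdn_cfg = replace(config.mdn, seed=config.seed)
    mdn = ConditionalMDN(x.shape[1], theta.shape[1], mdn_cfg)
    mdn.fit(x, theta_s)
    return PosteriorModel(
        mdn=mdn,
        theta_mean=t_mean,
        theta_sd=t_sd,
        prior=lib.prior,
        standardizer=lib.standardizer,
        config=config,
    )


def map_estimate(
    model: PosteriorModel,
    x: np.ndarray,
    n_samples: int = 10000,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Posterior draw with the highest estimated density (sample-argmax MAP)."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    draws = model.sample(n_samples, x, seed=seed)
    if n_samples == 1:
        return draws[0]
    logq = model.log_density(draws, np.atleast_2d(x))
    return draws[int(np.argmax(logq))]


def posterior_entropy(
    model: PosteriorModel,
    x: np.ndarray,
    K: int = 1000,
    seed: int | np.random.Generator = 0,
) -> float:
    """Monte-Carlo differential-entropy score -mean_k log q(theta_k | x).

    Lower scores mean a tighter (better constrained) posterior.
    """
    draws = model.sample(K, x, seed=seed)
    return float(-np.mean(model.log_density(draws, np.atleast_2d(x))))


@dataclass
class FitReport:
    """Per-observation and aggregate fit quality, in the style of a
    training-schedule comparison table."""

    map_theta: np.ndarray          # (m, 13)
    map_distance: np.ndarray       # (m,) z-space distance, NaN if MAP sim failed
    map_failed: np.ndarray         # (m,) bool
    post_fail_rate: np.ndarray     # (m,) fraction of failed posterior draws
    post_distance: np.ndarray      # (m,) mean distance of defined posterior draws
    entropy: Optional[np.ndarray] = None

    @property
    def map_fail_pct(self) -> float:
        return float(100.0 * self.map_failed.mean())

    @property
    def post_fail_pct(self) -> float:
        return float(100.0 * np.nanmean(self.post_fail_rate))

    def summary(self) -> dict:
        return {
            "map_fail_pct": self.map_fail_pct,
            "map_distance_mean": float(np.nanmean(self.map_distance)),
            "map_distance_sd": float(np.nanstd(self.map_distance)),
            "post_fail_pct": self.post_fail_pct,
            "post_distance_mean": float(np.nanmean(self.post_distance)),
            "post_distance_sd": float(np.nanstd(self.post_distance)),
        }


def evaluate_fit(
    model: PosteriorModel,
    observations: np.ndarray,
    protocol: StimulusProtocol,
    n_map_samples: int = 10000,
    n_post: int = 10,
    seed: int = 0,
    compute_entropy: bool = False,
) -> FitReport:
    """Simulate MAP and posterior-draw parameter sets for each observation.

    Observations are rows in the model's z space. MAP and posterior draws
    are clipped to the prior box before simulation. Simulations with any
    undefined feature count as fails and are excluded from distance means.
    """
    observations = np.atleast_2d(np.asarray(observations, dtype=float))
    m = observations.shape[0]
    ss = np.random.SeedSequence((seed, 21))
    rng = np.random.default_rng(ss)
    maps = np.empty((m, model.theta_mean.size))
    post_thetas = []
    for i, obs in enumerate(observations):
        maps[i] = map_estimate(model, obs, n_samples=n_map_samples, seed=rng)
        if n_post > 0:
            post_thetas.append(model.sample(n_post, obs, seed=rng))
    maps_c = model.prior.clip(maps)

    # simulate all MAPs in one batch, then compare each to its own observation
    vm, failed = simulate_batch(maps_c, protocol, seed=rng, record_dtype=np.float32)
    vals, defs = extract_features_batch(vm, protocol, failed)
    tvals, tdefs = transform_matrix(vals, defs)
    ok = tdefs.all(axis=1)
    map_failed = ~ok
    map_dist = np.full(m, np.nan)
    if ok.any():
        z = model.standardizer.apply(tvals[ok])
        map_dist[ok] = np.sqrt(((z - observations[ok]) ** 2).sum(axis=1))

    post_fail = np.full(m, np.nan)
    post_dist = np.full(m, np.nan)
    if n_post > 0:
        all_post = model.prior.clip(np.concatenate(post_thetas))
        vm, failed = simulate_batch(all_post, protocol, seed=rng, record_dtype=np.float32)
        vals, defs = extract_features_batch(vm, protocol, failed)
        tvals, tdefs = transform_matrix(vals, defs)
        ok = tdefs.all(axis=1)
        z_all = np.full((all_post.shape[0], 23), np.nan)
        if ok.any():
            z_all[ok] = model.standardizer.apply(tvals[ok])
        for i in range(m):
            sl = slice(i * n_post, (i + 1) * n_post)
            ok_i = ok[sl]
            post_fail[i] = 1.0 - ok_i.mean()
            if ok_i.any():
                di = np.sqrt(((z_all[sl][ok_i] - observations[i]) ** 2).sum(axis=1))
                post_dist[i] = di.mean()

    entropy = None
    if compute_entropy:
        entropy = np.array(
            [posterior_entropy(model, obs, seed=rng) for obs in observations]
        )
    return FitReport(
        map_theta=maps_c,
        map_distance=map_dist,
        map_failed=map_failed,
        post_fail_rate=post_fail,
        post_distance=post_dist,
        entropy=entropy,
    )
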