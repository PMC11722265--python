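"""Prior simulation libraries and the nearest-simulation baseline.

A library is a row-aligned set of (parameter vector, transformed feature
vector) pairs simulated from the prior, together with per-row defined flags
and the feature standardizer fitted on the library's own defined rows. The
"best Euclidean" baseline fits a cell by returning the defined simulation
closest to it in standardized feature space.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import h5py
import numpy as np

from .features import (
    FeatureStandardizer,
    extract_features_batch,
    fit_standardizer,
    transform_matrix,
)
from .params import DEFAULT_PRIOR, PriorBox, sample_prior
from .simulator import StimulusProtocol, simulate_batch

__all__ = ["SimulationLibrary", "build_library", "nearest", "mismatch_profile"]


@dataclass
class SimulationLibrary:
    """Row-aligned prior draws, their transformed features, and flags."""

    theta: np.ndarray            # (n, 13)
    x_raw: np.ndarray            # (n, 23) raw-space features (NaN if undefined)
    x_transformed: np.ndarray    # (n, 23) transformed space (NaN if undefined)
    defined: np.ndarray          # (n,) all-23-defined flag
    standardizer: FeatureStandardizer
    prior: PriorBox = DEFAULT_PRIOR
    protocol: StimulusProtocol = field(default_factory=StimulusProtocol)
    seed: int = 0

    def __len__(self) -> int:
        return self.theta.shape[0]

    @property
    def defined_fraction(self) -> float:
        return float(self.defined.mean())

    @property
    def z(self) -> np.ndarray:
        """Standardized features of the defined rows only."""
        return self.standardizer.apply(self.x_transformed[self.defined])

    @property
    def defined_indices(self) -> np.ndarray:
        return np.flatnonzero(self.defined)

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("theta", data=self.theta)
            f.create_dataset("x_raw", data=self.x_raw)
            f.create_dataset("x_transformed", data=self.x_transformed)
            f.create_dataset("defined", data=self.defined)
            f.create_dataset("std_mean", data=self.standardizer.mean)
            f.create_dataset("std_sd", data=self.standardizer.sd)
            f.create_dataset("prior_lower", data=self.prior.lower)
            f.create_dataset("prior_upper", data=self.prior.upper)
            f.attrs["seed"] = self.seed
            f.attrs["protocol"] = json.dumps(self.protocol.to_dict())

    @classmethod
    def load(cls, path) -> "SimulationLibrary":
        with h5py.File(path, "r") as f:
            std = FeatureStandardizer(mean=f["std_mean"][:], sd=f["std_sd"][:])
            return cls(
                theta=f["theta"][:],
                x_raw=f["x_raw"][:],
                x_transformed=f["x_transformed"][:],
                defined=f["defined"][:].astype(bool),
                standardizer=std,
                prior=PriorBox(lower=f["prior_lower"][:], upper=f["prior_upper"][:]),
                protocol=StimulusProtocol(**json.loads(f.attrs["protocol"])),
                seed=int(f.attrs["seed"]),
            )


def build_library(
    prior: PriorBox = DEFAULT_PRIOR,
    protocol: StimulusProtocol = StimulusProtocol(),
    n: int = 1000,
    seed: int = 0,
    batch: int = 2048,
    progress: bool = False,
) -> SimulationLibrary:
    """Simulate and featurize ``n`` prior draws in memory-bounded batches.

    Failed simulations (voltage guard or non-finite) and simulations with
    any undefined transformed feature are kept as undefined rows; the
    standardizer is fitted on the defined rows. Deterministic given ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    theta = sample_prior(prior, n, seed=seed)
    x_raw = np.full((n, 23), np.nan)
    x_tr = np.full((n, 23), np.nan)
    defined = np.zeros(n, dtype=bool)
    sim_seed = np.random.SeedSequence(seed).spawn(1)[0]
    rng = np.random.default_rng(sim_seed)
    for start in range(0, n, batch):
        stop = min(start + batch, n)
        vm, failed = simulate_batch(
            theta[start:stop], protocol, seed=rng, record_dtype=np.float32
        )
        vals, defs = extract_features_batch(vm, protocol, failed)
        tvals, tdefs = transform_matrix(vals, defs)
        ok = tdefs.all(axis=1)
        x_raw[start:stop] = vals
        x_tr[start:stop] = tvals
        defined[start:stop] = ok
        if progress:
            print(f"  simulated {stop}/{n} (defined so far: {defined[:stop].mean():.3f})")
    if defined.any():
        std = fit_standardizer(x_tr[defined])
    else:
        # degenerate library (e.g. a passive-only prior): keep the rows,
        # fall back to an identity standardizer
        std = FeatureStandardizer(mean=np.zeros(23), sd=np.ones(23))
    return SimulationLibrary(
        theta=theta,
        x_raw=x_raw,
        x_transformed=x_tr,
        defined=defined,
        standardizer=std,
        prior=prior,
        protocol=protocol,
        seed=seed,
    )


def nearest(
    obs_z: np.ndarray, lib: SimulationLibrary, k: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    """Indices and distances of the k defined rows nearest to ``obs_z``.

    ``obs_z`` is a fully defined feature vector in the library's z space.
    Returned indices are global library row indices, distances ascending;
    ties are broken by row index (stable sort).
    """
    obs_z = np.asarray(obs_z, dtype=float)
    if obs_z.shape != (23,):
        raise ValueError("obs_z must be a 23-vector")
    if not np.isfinite(obs_z).all():
        raise ValueError("observation must be fully defined")
    idx = lib.defined_indices
    if k < 1 or k > idx.size:
        raise ValueError(f"k must be in [1, {idx.size}]")
    z = lib.standardizer.apply(lib.x_transformed[idx])
    d = np.sqrt(((z - obs_z) ** 2).sum(axis=1))
    order = np.argsort(d, kind="stable")[:k]
    return idx[order], d[order]


def mismatch_profile(
    obs_z: np.ndarray, lib: SimulationLibrary, n_sim: Optional[int] = None, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Distance-to-nearest distributions diagnosing model-data mismatch.

    Returns ``(d_obs, d_sim)``: for each observation its distance to the
    nearest defined simulation, and for ``n_sim`` defined simulations (all
    by default) the distance to the nearest *other* defined simulation. A
    systematically larger ``d_obs`` indicates that observations occupy a
    region of feature space the simulator does not reach.
    """
    obs_z = np.atleast_2d(np.asarray(obs_z, dtype=float))
    if obs_z.shape[0] and obs_z.shape[1] != 23:
        raise ValueError("observations must have 23 columns")
    idx = lib.defined_indices
    z = lib.standardizer.apply(lib.x_transformed[idx])
    if obs_z.shape[0] == 0:
        return np.empty(0), np.empty(0)
    d_obs = np.empty(obs_z.shape[0])
    for i, o in enumerate(obs_z):
        d_obs[i] = np.sqrt(((z - o) ** 2).sum(axis=1)).min()
    rows = np.arange(z.shape[0])
    if n_sim is not None and n_sim < z.shape[0]:
        rows = np.random.default_rng(seed).choice(z.shape[0], n_sim, replace=False)
    d_sim = np.empty(rows.size)
    for j, i in enumerate(rows):
        d = np.sqrt(((z - z[i]) ** 2).sum(axis=1))
        d[i] = np.inf
        d_sim[j] = d.min()
    return d_obs, d_sim
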