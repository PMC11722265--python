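"""Biophysical parameters of the single-compartment conductance-based neuron.

The model has 13 free parameters: three passive ones (membrane capacitance,
input resistance and membrane time constant), six maximal conductances
(transient Na+, Na+, delayed-rectifier K+, muscarinic K+, Kv3.1 K+ and
high-threshold Ca2+), the leak reversal potential, the muscarinic
time-constant scale, a spike-threshold adjustment and a dimensionless
rate-to-steady-state scale ``rss`` that speeds up or slows down how fast the
Na+ and delayed-rectifier K+ gates approach their steady states.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np

__all__ = [
    "PARAM_NAMES",
    "BiophysParams",
    "PriorBox",
    "DEFAULT_PRIOR",
    "sample_prior",
    "membrane_area",
]

#: Canonical parameter order used by every matrix in the package.
PARAM_NAMES = (
    "C",        # membrane capacitance, uF/cm^2
    "Rinput",   # input resistance, MOhm
    "tau",      # membrane time constant, ms
    "gNat",     # transient Na+ maximal conductance, mS/cm^2
    "gNa",      # Na+ maximal conductance, mS/cm^2
    "gKd",      # delayed-rectifier K+ maximal conductance, mS/cm^2
    "gM",       # muscarinic K+ maximal conductance, mS/cm^2
    "gKv31",    # Kv3.1 K+ maximal conductance, mS/cm^2
    "gL",       # high-threshold Ca2+ maximal conductance, mS/cm^2
    "Eleak",    # leak reversal potential, mV
    "tau_max",  # muscarinic time-constant scale, ms
    "VT",       # spike-threshold adjustment, mV
    "rss",      # rate-to-steady-state scale, dimensionless
)

_POSITIVE = ("C", "Rinput", "tau", "tau_max", "rss")
_NONNEGATIVE = ("gNat", "gNa", "gKd", "gM", "gKv31", "gL")


@dataclass(frozen=True)
class BiophysParams:
    """One parameter vector theta of the conductance-based model.

    Conductances are per membrane area (mS/cm^2); the passive triplet
    (C, Rinput, tau) fixes the effective membrane area, see
    :func:`membrane_area`.
    """

    C: float
    Rinput: float
    tau: float
    gNat: float
    gNa: float
    gKd: float
    gM: float
    gKv31: float
    gL: float
    Eleak: float
    tau_max: float
    VT: float
    rss: float

    def __post_init__(self) -> None:
        for name in _POSITIVE:
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        for name in _NONNEGATIVE:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, theta: np.ndarray) -> "BiophysParams":
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (len(PARAM_NAMES),):
            raise ValueError(f"expected shape (13,), got {theta.shape}")
        return cls(**dict(zip(PARAM_NAMES, theta)))

    def replace(self, **kwargs: float) -> "BiophysParams":
        values = {n: getattr(self, n) for n in PARAM_NAMES}
        values.update(kwargs)
        return BiophysParams(**values)


@dataclass(frozen=True)
class PriorBox:
    """Axis-aligned box of the uniform prior over the 13 parameters."""

    lower: np.ndarray
    upper: np.ndarray
    names: tuple = PARAM_NAMES

    def __post_init__(self) -> None:
        lo = np.asarray(self.lower, dtype=float)
        hi = np.asarray(self.upper, dtype=float)
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", hi)
        if lo.shape != hi.shape or lo.shape != (len(self.names),):
            raise ValueError("bound shapes do not match parameter names")
        if not np.all(lo < hi):
            bad = [self.names[i] for i in np.nonzero(~(lo < hi))[0]]
            raise ValueError(f"lower >= upper for parameters {bad}")

    def contains(self, theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(np.asarray(theta, dtype=float))
        return np.all((theta >= self.lower) & (theta <= self.upper), axis=1)

    def clip(self, theta: np.ndarray) -> np.ndarray:
        return np.clip(np.asarray(theta, dtype=float), self.lower, self.upper)

    @property
    def midpoint(self) -> np.ndarray:
        return 0.5 * (self.lower + self.upper)

    @property
    def width(self) -> np.ndarray:
        return self.upper - self.lower

    def __iter__(self) -> Iterator[tuple]:
        return iter(zip(self.names, self.lower, self.upper))


def _default_prior() -> PriorBox:
    bounds = {
        "C": (0.1, 15.0),
        "Rinput": (20.0, 1000.0),
        "tau": (0.1, 70.0),
        "gNat": (0.0, 250.0),
        "gNa": (0.0, 100.0),
        "gKd": (0.0, 30.0),
        "gM": (0.0, 3.0),
        "gKv31": (0.0, 250.0),
        "gL": (0.0, 3.0),
        "Eleak": (-130.0, -50.0),
        "tau_max": (50.0, 4000.0),
        "VT": (-90.0, -35.0),
        "rss": (0.1, 3.0),
    }
    lo = np.array([bounds[n][0] for n in PARAM_NAMES])
    hi = np.array([bounds[n][1] for n in PARAM_NAMES])
    return PriorBox(lower=lo, upper=hi)


#: The biologically plausible prior box used throughout.
DEFAULT_PRIOR: PriorBox = _default_prior()


def sample_prior(
    prior: PriorBox = DEFAULT_PRIOR, n: int = 1, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Draw ``n`` parameter vectors uniformly from the prior box.

    Returns an ``(n, 13)`` array in the :data:`PARAM_NAMES` order.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    u = rng.random((n, len(prior.names)))
    return prior.lower + u * prior.width


def membrane_area(params: BiophysParams | np.ndarray) -> float | np.ndarray:
    """Effective membrane area in cm^2 implied by the passive triplet.

    Per-area conductances (mS/cm^2) and capacitance (uF/cm^2) are converted
    to absolute values through A = tau / (C * Rinput); with this convention
    the passive time constant of the compartment equals ``tau`` and the total
    leak conductance equals 1/Rinput exactly.
    """
    if isinstance(params, BiophysParams):
        C, R, tau = params.C, params.Rinput, params.tau
    else:
        arr = np.atleast_2d(np.asarray(params, dtype=float))
        C, R, tau = arr[:, 0], arr[:, 1], arr[:, 2]
        if np.asarray(params).ndim == 1:
            C, R, tau = C[0], R[0], tau[0]
    # uF/cm^2 * MOhm = ms/cm^2 * 1000
    return tau / (C * R * 1000.0)
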