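"""Single-compartment conductance-based neuron simulator.

The membrane equation couples seven currents -- transient Na+, Na+,
delayed-rectifier K+, muscarinic K+, Kv3.1 K+, high-threshold Ca2+ and
leak -- through

    C_m dV/dt = sum_x g_x * gates_x * (E_x - V) + I_inj + I_noise,

with the gates following first-order kinetics dx/dt = alpha(V)(1-x) - beta(V)x
(see :mod:`ephyslink.kinetics`). Per-area conductances are converted to
absolute ones through the effective membrane area A = tau / (C * Rinput), so
the passive response has time constant ``tau`` and steady-state deflection
``Rinput * I_inj`` exactly.

Integration is fixed-step: exponential Euler for the gates (unconditionally
stable, keeps every gate in [0, 1]) and forward Euler for the voltage, at
dt = 0.025 ms by default. The integrator is vectorized over a batch of
parameter vectors; a cell whose voltage leaves a +-1000 mV guard band or
turns non-finite is flagged failed, not raised.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np

from .kinetics import GATE_NAMES, T_REF, gate_rates
from .params import PARAM_NAMES, BiophysParams, membrane_area

__all__ = ["StimulusProtocol", "VoltageTrace", "simulate", "simulate_batch"]

#: Reversal potentials (mV); not free parameters.
E_NA = 50.0
E_K = -90.0
E_CA = 120.0

#: Voltage guard band (mV); beyond it a simulation counts as failed.
V_GUARD = 1000.0


@dataclass(frozen=True)
class StimulusProtocol:
    """Square current-step protocol with background current noise.

    The default emulates a somatic patch experiment at 25 deg C: a 300 pA
    step between 100 and 700 ms of an 800 ms sweep, with i.i.d. Gaussian
    current noise N(10 pA, (1 pA)^2) injected at every time point and gate
    kinetics scaled by Q10^((T - T_ref)/10).
    """

    amplitude: float = 300.0   # pA
    onset: float = 100.0       # ms
    offset: float = 700.0      # ms
    duration: float = 800.0    # ms
    dt: float = 0.025          # ms
    temperature: float = 25.0  # deg C
    noise_mean: float = 10.0   # pA
    noise_sd: float = 1.0      # pA
    q10: float = 2.3
    t_ref: float = T_REF       # deg C

    def __post_init__(self) -> None:
        if not (0 <= self.onset < self.offset <= self.duration):
            raise ValueError("need 0 <= onset < offset <= duration")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")

    @property
    def qt(self) -> float:
        return float(self.q10 ** ((self.temperature - self.t_ref) / 10.0))

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))

    def time_grid(self) -> np.ndarray:
        return np.arange(self.n_steps + 1) * self.dt

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class VoltageTrace:
    """A uniformly sampled membrane-voltage response to the step protocol."""

    time: np.ndarray            # ms
    vm: np.ndarray              # mV
    protocol: StimulusProtocol
    params: Optional[BiophysParams] = None
    failed: bool = False

    def __post_init__(self) -> None:
        if self.time.shape != self.vm.shape:
            raise ValueError("time and vm must have the same shape")

    @property
    def dt(self) -> float:
        return self.protocol.dt


def _absolute_conductances(theta: np.ndarray) -> dict:
    """Total conductances in uS and capacitance in nF for (n, 13) theta."""
    C, R, tau = theta[:, 0], theta[:, 1], theta[:, 2]
    area = membrane_area(theta)            # cm^2
    g_area = area * 1000.0                 # mS/cm^2 * cm^2 -> uS
    out = {
        "gNat": theta[:, 3] * g_area,
        "gNa": theta[:, 4] * g_area,
        "gKd": theta[:, 5] * g_area,
        "gM": theta[:, 6] * g_area,
        "gKv31": theta[:, 7] * g_area,
        "gL": theta[:, 8] * g_area,
        "gleak": 1.0 / R,                  # uS, exactly the inverse input resistance
        "Cm": C * area * 1000.0,           # nF
    }
    return out


def _init_gates(V: np.ndarray, VT: np.ndarray, tau_max: np.ndarray) -> dict:
    """Gates at steady state for the initial voltage."""
    raw = gate_rates(V, VT=VT, tau_max=tau_max)
    gates = {}
    for g in GATE_NAMES:
        a, b = raw[g]
        gates[g] = a if g in ("p", "v") else a / (a + b)
    return gates


def simulate_batch(
    theta: np.ndarray,
    protocol: StimulusProtocol = StimulusProtocol(),
    seed: int | np.random.Generator = 0,
    noise: bool = True,
    record_dtype=np.float64,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate the model for a batch of parameter vectors.

    Parameters
    ----------
    theta
        ``(n, 13)`` parameter matrix in :data:`~ephyslink.params.PARAM_NAMES`
        order (a single vector is promoted).
    noise
        Disable to obtain the deterministic skeleton of the model.

    Returns
    -------
    vm : (n, n_steps + 1) array of membrane voltage (mV); failed cells are
        NaN from the step where they left the guard band.
    failed : (n,) boolean array.
    """
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    if theta.shape[1] != len(PARAM_NAMES):
        raise ValueError(f"theta must have {len(PARAM_NAMES)} columns")
    n = theta.shape[0]
    rng = np.random.default_rng(seed)

    g = _absolute_conductances(theta)
    Eleak, tau_max, VT, rss = theta[:, 9], theta[:, 10], theta[:, 11], theta[:, 12]
    qt = protocol.qt
    dt = protocol.dt
    n_steps = protocol.n_steps
    i_on = protocol.onset / dt
    i_off = protocol.offset / dt
    amp_na = protocol.amplitude / 1000.0   # pA -> nA
    mu_na = protocol.noise_mean / 1000.0
    sd_na = protocol.noise_sd / 1000.0

    V = Eleak.copy()
    gates0 = _init_gates(V, VT, tau_max)
    X = np.vstack([gates0[name] for name in GATE_NAMES])   # (9, n) gate states
    inv_Cm = 1.0 / g["Cm"]
    # per-gate kinetic scale: qt everywhere, additionally rss on m, h, n
    scale = np.broadcast_to(qt * np.ones(n), (9, n)).copy()
    scale[:3] *= rss
    x_inf = np.empty((9, n))
    k_tot = np.empty((9, n))

    vm = np.empty((n, n_steps + 1), dtype=record_dtype)
    vm[:, 0] = V

    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        for k in range(n_steps):
            raw = gate_rates(V, VT=VT, tau_max=tau_max)
            for i, name in enumerate(GATE_NAMES):
                a, b = raw[name]
                if name in ("p", "v"):
                    x_inf[i] = a
                    k_tot[i] = 1.0 / b
                else:
                    tot = a + b
                    x_inf[i] = a / tot
                    k_tot[i] = tot
            X -= (x_inf - X) * np.expm1(-dt * k_tot * scale)

            m, h, nn, p, q, r, mt, ht, v = X
            i_ion = (
                g["gNa"] * (m * m * m * h) * (E_NA - V)
                + g["gNat"] * (mt * mt * mt * ht) * (E_NA - V)
                + g["gKd"] * (nn * nn * nn * nn) * (E_K - V)
                + g["gM"] * p * (E_K - V)
                + g["gKv31"] * v * (E_K - V)
                + g["gL"] * (q * q * r) * (E_CA - V)
                + g["gleak"] * (Eleak - V)
            )
            i_inj = amp_na if i_on <= k < i_off else 0.0
            if noise:
                i_noise = mu_na + sd_na * rng.standard_normal(n)
            else:
                i_noise = 0.0
            V = V + dt * inv_Cm * (i_ion + i_inj + i_noise)
            V = np.where(np.abs(V) > V_GUARD, np.nan, V)
            vm[:, k + 1] = V

    failed = ~np.isfinite(vm).all(axis=1)
    return vm, failed


def simulate(
    params: BiophysParams,
    protocol: StimulusProtocol = StimulusProtocol(),
    seed: int | np.random.Generator = 0,
    noise: bool = True,
) -> VoltageTrace:
    """Simulate one parameter vector and wrap the result in a trace."""
    vm, failed = simulate_batch(
        params.to_array()[None, :], protocol, seed=seed, noise=noise
    )
    return VoltageTrace(
        time=protocol.time_grid(),
        vm=vm[0],
        protocol=protocol,
        params=params,
        failed=bool(failed[0]),
    )
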