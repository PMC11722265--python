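"""Shared fixtures: crafted traces, a reusable simulation library and cohort.

Heavy artifacts (prior library, synthetic cohort) are session-scoped and
generated programmatically so the suite ships no data files.
"""

from __future__ import annotations

import numpy as np
import pytest

from ephyslink.params import BiophysParams
from ephyslink.simulator import StimulusProtocol, VoltageTrace

PROTOCOL = StimulusProtocol()


@pytest.fixture(scope="session")
def protocol() -> StimulusProtocol:
    return PROTOCOL


@pytest.fixture(scope="session")
def passive_params() -> BiophysParams:
    return BiophysParams(
        C=1.0, Rinput=100.0, tau=10.0, gNat=0.0, gNa=0.0, gKd=0.0, gM=0.0,
        gKv31=0.0, gL=0.0, Eleak=-70.0, tau_max=1000.0, VT=-60.0, rss=1.0,
    )


@pytest.fixture(scope="session")
def fast_spiking_params() -> BiophysParams:
    """High delayed-rectifier and Kv3.1 conductances, as fitted for
    fast-spiking interneurons."""
    return BiophysParams(
        C=1.0, Rinput=200.0, tau=10.0, gNat=50.0, gNa=50.0, gKd=20.0, gM=0.1,
        gKv31=100.0, gL=0.1, Eleak=-75.0, tau_max=1000.0, VT=-60.0, rss=1.0,
    )


def make_triangular_trace(
    spike_times_ms,
    amplitudes_mv=None,
    baseline=-70.0,
    rise_mv_per_step=2.0,
    protocol: StimulusProtocol = PROTOCOL,
) -> VoltageTrace:
    """Trace of triangular spikes with analytically known geometry.

    Each spike rises from baseline by ``rise_mv_per_step`` per grid step to
    a single peak sample at ``baseline + amplitude`` and descends
    symmetrically back to baseline. With the default 2 mV / 0.025 ms rise
    (80 mV/ms), the detected threshold is the last baseline sample before
    the upstroke (t0 - dt, voltage = baseline), the detected amplitude
    equals ``amplitude`` and the width at half height is
    ``amplitude / rise_mv_per_step * dt``.
    """
    dt = protocol.dt
    V = np.full(protocol.n_steps + 1, baseline)
    if amplitudes_mv is None:
        amplitudes_mv = [100.0] * len(spike_times_ms)
    for t0, amp in zip(spike_times_ms, amplitudes_mv):
        i = int(round(t0 / dt))
        n_up = int(round(amp / rise_mv_per_step))
        V[i : i + n_up] = baseline + rise_mv_per_step * np.arange(1, n_up + 1)
        V[i + n_up : i + 2 * n_up] = baseline + rise_mv_per_step * np.arange(n_up - 1, -1, -1)
    return VoltageTrace(time=protocol.time_grid(), vm=V, protocol=protocol)


@pytest.fixture(scope="session")
def small_library():
    """A 3000-draw prior library (well-definedness scale of the study)."""
    from ephyslink.library import build_library

    return build_library(n=3000, seed=20250922)


@pytest.fixture(scope="session")
def acceptance_library():
    """The 12000-draw prior library used for posterior-fitting checks."""
    from ephyslink.library import build_library

    return build_library(n=12000, seed=42)


@pytest.fixture(scope="session")
def small_cohort():
    """A 30-cell synthetic cohort shared by the acceptance tests."""
    from ephyslink.synthetic import make_cohort

    return make_cohort(n_cells=30, n_genes=120, n_active_genes=12, seed=7)
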