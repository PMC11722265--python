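"""Trace and table I/O helpers.

Traces travel as HDF5 (datasets ``time``, ``vm``; attrs: protocol fields and
seed) or as two-column CSV (``time_ms``, ``vm_mV``). Feature tables are CSV
with one row per cell and the 23 feature columns in canonical order plus a
``well_defined`` boolean.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .features import FEATURE_NAMES
from .simulator import StimulusProtocol, VoltageTrace

__all__ = ["save_trace", "load_trace", "features_to_frame"]


def save_trace(trace: VoltageTrace, path, seed: int | None = None) -> None:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.create_dataset("time", data=trace.time)
            f.create_dataset("vm", data=trace.vm)
            f.attrs["protocol"] = json.dumps(trace.protocol.to_dict())
            f.attrs["failed"] = trace.failed
            if seed is not None:
                f.attrs["seed"] = seed
    else:
        pd.DataFrame({"time_ms": trace.time, "vm_mV": trace.vm}).to_csv(path, index=False)


def load_trace(path, protocol: StimulusProtocol | None = None) -> VoltageTrace:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            protocol = StimulusProtocol(**json.loads(f.attrs["protocol"]))
            return VoltageTrace(
                time=f["time"][:],
                vm=f["vm"][:],
                protocol=protocol,
                failed=bool(f.attrs.get("failed", False)),
            )
    df = pd.read_csv(path)
    if protocol is None:
        dt = float(df.time_ms.iloc[1] - df.time_ms.iloc[0])
        protocol = StimulusProtocol(duration=float(df.time_ms.iloc[-1]), dt=dt)
    return VoltageTrace(
        time=df.time_ms.to_numpy(), vm=df.vm_mV.to_numpy(), protocol=protocol
    )


def features_to_frame(values: np.ndarray, defined: np.ndarray) -> pd.DataFrame:
    """One row per cell: the 23 features plus the well_defined flag."""
    values = np.atleast_2d(values)
    defined = np.atleast_2d(defined)
    df = pd.DataFrame(values, columns=FEATURE_NAMES)
    df["well_defined"] = defined.all(axis=1)
    return df
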