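"""Electrophysiological summary statistics of a step-current response.

Twenty-three features summarize each voltage trace: the shape of the first
and third action potential (threshold, amplitude, width at half height,
afterhyperpolarization depth), spike counts in the whole injection window
and in its first eighth / quarter / half and second half, amplitude- and
interval-adaptation ratios, coefficients of variation, latency to the first
spike, and moments of the membrane voltage before and during stimulation.

Each feature carries a defined flag: with no spike the shape, adaptation and
latency features are undefined; with fewer than three spikes the third-AP
features and the interval-adaptation ratio are undefined, and so on. Eleven
features are variance-stabilized before standardization: counts through
log(1 + x), strictly positive ratios and the latency through log(x), and
the average amplitude-adaptation ratio through a logistic sigmoid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .simulator import StimulusProtocol, VoltageTrace

__all__ = [
    "FEATURE_NAMES",
    "TRANSFORMS",
    "SpikeTable",
    "FeatureVector",
    "FeatureStandardizer",
    "detect_spikes",
    "extract_features",
    "extract_features_batch",
    "transform_features",
    "transform_matrix",
    "fit_standardizer",
    "is_well_defined",
]

#: Feature order used by every matrix in the package.
FEATURE_NAMES = (
    "ap_threshold",
    "ap_amplitude",
    "ap_width",
    "ahp",
    "ap3_threshold",
    "ap3_amplitude",
    "ap3_width",
    "ap3_ahp",
    "ap_count",
    "ap_count_1st_8th",
    "ap_count_1st_quarter",
    "ap_count_1st_half",
    "ap_count_2nd_half",
    "ap_amp_adapt",
    "ap_average_amp_adapt",
    "ap_cv",
    "isi_adapt",
    "isi_cv",
    "latency",
    "rest_vm_mean",
    "vm_mean",
    "vm_std",
    "vm_skewness",
)

#: Variance-stabilizing transform per feature.
TRANSFORMS = {
    "ap_count": "log1p",
    "ap_count_1st_8th": "log1p",
    "ap_count_1st_quarter": "log1p",
    "ap_count_1st_half": "log1p",
    "ap_count_2nd_half": "log1p",
    "ap_amp_adapt": "log",
    "ap_average_amp_adapt": "sigmoid",
    "ap_cv": "log",
    "isi_adapt": "log",
    "isi_cv": "log",
    "latency": "log",
}

_N = len(FEATURE_NAMES)
_IDX = {name: i for i, name in enumerate(FEATURE_NAMES)}

#: Default dV/dt threshold (mV/ms) marking the start of a spike upstroke.
DVDT_THRESHOLD = 20.0


@dataclass
class SpikeTable:
    """Per-spike geometry: threshold point, peak, width and AHP."""

    t_threshold: np.ndarray   # ms
    v_threshold: np.ndarray   # mV
    v_peak: np.ndarray        # mV
    amplitude: np.ndarray     # mV, peak - threshold
    width: np.ndarray         # ms at half height (NaN if not measurable)
    ahp: np.ndarray           # mV drop below threshold after the peak

    def __len__(self) -> int:
        return len(self.t_threshold)

    @classmethod
    def empty(cls) -> "SpikeTable":
        z = np.empty(0)
        return cls(z, z.copy(), z.copy(), z.copy(), z.copy(), z.copy())


@dataclass
class FeatureVector:
    """The 23 summary statistics with per-feature defined flags."""

    values: np.ndarray
    defined: np.ndarray
    space: str = "raw"        # "raw" | "transformed" | "z"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.defined = np.asarray(self.defined, dtype=bool)
        if self.values.shape != (_N,) or self.defined.shape != (_N,):
            raise ValueError(f"expected {_N} features")

    def __getitem__(self, name: str) -> float:
        return float(self.values[_IDX[name]])

    def is_defined(self, name: str) -> bool:
        return bool(self.defined[_IDX[name]])

    @property
    def well_defined(self) -> bool:
        return bool(self.defined.all() and np.isfinite(self.values).all())


def detect_spikes(
    trace: VoltageTrace | np.ndarray,
    dt: float | None = None,
    dvdt_threshold: float = DVDT_THRESHOLD,
) -> SpikeTable:
    """Detect action potentials through a voltage-slope criterion.

    The threshold point of a spike is the first grid point of an upstroke at
    which dV/dt reaches ``dvdt_threshold``; the peak is the first local
    voltage maximum after it. Width is measured at half height between
    threshold and peak (linear interpolation on both flanks) and the AHP is
    the post-peak minimum before the next threshold point (or trace end),
    measured as a drop from the threshold voltage. A new upstroke is only
    accepted once the voltage has fallen back below the previous spike's
    threshold voltage.
    """
    if isinstance(trace, VoltageTrace):
        V = trace.vm
        dt = trace.dt
    else:
        V = np.asarray(trace, dtype=float)
        if dt is None:
            raise ValueError("dt required when passing a bare array")
    T = len(V)
    if T < 3 or not np.isfinite(V).all():
        return SpikeTable.empty()

    dvdt = np.diff(V) / dt
    above = dvdt >= dvdt_threshold
    # first grid point of each upstroke segment
    starts = np.flatnonzero(above & ~np.concatenate(([False], above[:-1])))
    if starts.size == 0:
        return SpikeTable.empty()

    t_thr, v_thr, v_pk, widths, ahps = [], [], [], [], []
    peak_idx = []
    resume = 0
    for i in starts:
        if i < resume:
            continue
        # peak: first local maximum at or after the threshold point
        j = i
        while j < T - 1 and V[j + 1] > V[j]:
            j += 1
        if j == i and V[j] <= V[i]:
            pass
        vt, vp = V[i], V[j]
        if vp <= vt:
            continue
        t_thr.append(i * dt)
        v_thr.append(vt)
        v_pk.append(vp)
        peak_idx.append(j)
        # repolarization below the threshold voltage ends the spike
        below = np.flatnonzero(V[j:] <= vt)
        resume = (j + below[0]) if below.size else T
    if not t_thr:
        return SpikeTable.empty()

    t_thr = np.asarray(t_thr)
    v_thr = np.asarray(v_thr)
    v_pk = np.asarray(v_pk)
    amp = v_pk - v_thr
    thr_idx = np.round(t_thr / dt).astype(int)

    n_sp = len(t_thr)
    widths = np.full(n_sp, np.nan)
    ahps = np.full(n_sp, np.nan)
    for s in range(n_sp):
        i, j = thr_idx[s], peak_idx[s]
        nxt = thr_idx[s + 1] if s + 1 < n_sp else T - 1
        vh = v_thr[s] + 0.5 * amp[s]
        # rising flank crossing of the half-height level
        rise = np.flatnonzero(V[i : j + 1] >= vh)
        if rise.size:
            a = i + rise[0]
            if a == 0 or V[a] == vh or a == i:
                t_rise = a * dt
            else:
                t_rise = (a - 1 + (vh - V[a - 1]) / (V[a] - V[a - 1])) * dt
            fall = np.flatnonzero(V[j : nxt + 1] <= vh)
            if fall.size:
                b = j + fall[0]
                if V[b] == vh or b == j:
                    t_fall = b * dt
                else:
                    t_fall = (b - 1 + (vh - V[b - 1]) / (V[b] - V[b - 1])) * dt
                widths[s] = t_fall - t_rise
        seg = V[j : nxt + 1]
        if seg.size:
            ahps[s] = v_thr[s] - seg.min()
    return SpikeTable(t_thr, v_thr, v_pk, amp, widths, ahps)


def _window(V: np.ndarray, dt: float, start: float, end: float) -> np.ndarray:
    """Samples with start <= t < end (half-open on the grid)."""
    i0 = int(np.ceil(start / dt - 1e-9))
    i1 = int(np.ceil(end / dt - 1e-9))
    return V[i0:min(i1, len(V))]


def extract_features(
    trace: VoltageTrace,
    protocol: StimulusProtocol | None = None,
    dvdt_threshold: float = DVDT_THRESHOLD,
) -> FeatureVector:
    """Compute the 23 raw-space summary statistics of one trace."""
    protocol = protocol or trace.protocol
    values = np.full(_N, np.nan)
    defined = np.zeros(_N, dtype=bool)
    V, dt = trace.vm, protocol.dt
    if trace.failed or not np.isfinite(V).all():
        return FeatureVector(values, defined, space="raw")

    on, off = protocol.onset, protocol.offset
    span = off - on

    def put(name, val, ok=True):
        values[_IDX[name]] = val
        defined[_IDX[name]] = bool(ok)

    rest = _window(V, dt, 0.0, on)
    stim = _window(V, dt, on, off)
    put("rest_vm_mean", rest.mean())
    put("vm_mean", stim.mean())
    sd = stim.std()
    put("vm_std", sd)
    put("vm_skewness", stats.skew(stim) if sd > 0 else 0.0)

    table = detect_spikes(trace, dvdt_threshold=dvdt_threshold)
    in_win = (table.t_threshold >= on) & (table.t_threshold < off)
    t_thr = table.t_threshold[in_win]
    v_thr = table.v_threshold[in_win]
    amp = table.amplitude[in_win]
    width = table.width[in_win]
    ahp = table.ahp[in_win]
    n_ap = len(t_thr)

    put("ap_count", float(n_ap))
    put("ap_count_1st_8th", float(np.sum(t_thr < on + span / 8)))
    put("ap_count_1st_quarter", float(np.sum(t_thr < on + span / 4)))
    put("ap_count_1st_half", float(np.sum(t_thr < on + span / 2)))
    put("ap_count_2nd_half", float(np.sum(t_thr >= on + span / 2)))

    if n_ap >= 1:
        put("ap_threshold", v_thr[0])
        put("ap_amplitude", amp[0])
        put("ap_width", width[0], ok=np.isfinite(width[0]))
        put("ahp", ahp[0], ok=np.isfinite(ahp[0]))
        put("latency", t_thr[0] - on)
    if n_ap >= 2:
        put("ap_amp_adapt", amp[0] / amp[1])
        ratios = amp[:-1] / amp[1:]
        put("ap_average_amp_adapt", ratios.mean())
        put("ap_cv", amp.std() / np.abs(amp.mean()))
        isi = np.diff(t_thr)
        put("isi_cv", isi.std() / isi.mean())
    if n_ap >= 3:
        put("ap3_threshold", v_thr[2])
        put("ap3_amplitude", amp[2])
        put("ap3_width", width[2], ok=np.isfinite(width[2]))
        put("ap3_ahp", ahp[2], ok=np.isfinite(ahp[2]))
        isi = np.diff(t_thr)
        put("isi_adapt", isi[1] / isi[0])
    return FeatureVector(values, defined, space="raw")


def transform_features(fv: FeatureVector) -> FeatureVector:
    """Variance-stabilize the 11 flagged features; undefined stays undefined."""
    if fv.space != "raw":
        raise ValueError("transform_features expects a raw-space vector")
    values = fv.values.copy()
    defined = fv.defined.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        for name, kind in TRANSFORMS.items():
            i = _IDX[name]
            if not defined[i]:
                continue
            x = values[i]
            if kind == "log1p":
                y = np.log1p(x)
            elif kind == "log":
                y = np.log(x)
            else:  # sigmoid
                y = 1.0 / (1.0 + np.exp(-x))
            if not np.isfinite(y):
                defined[i] = False
                y = np.nan
            values[i] = y
    values[~defined] = np.nan
    return FeatureVector(values, defined, space="transformed")


def is_well_defined(fv: FeatureVector) -> bool:
    """True iff all 23 features survive the transform with finite values."""
    tfv = transform_features(fv) if fv.space == "raw" else fv
    return tfv.well_defined


def extract_features_batch(
    vm: np.ndarray,
    protocol: StimulusProtocol,
    failed: np.ndarray | None = None,
    dvdt_threshold: float = DVDT_THRESHOLD,
) -> tuple[np.ndarray, np.ndarray]:
    """Raw features and defined flags for a (n, T+1) batch of traces."""
    vm = np.atleast_2d(vm)
    n = vm.shape[0]
    failed = np.zeros(n, bool) if failed is None else np.asarray(failed, bool)
    values = np.full((n, _N), np.nan)
    defined = np.zeros((n, _N), dtype=bool)
    time = protocol.time_grid()
    for i in range(n):
        tr = VoltageTrace(
            time=time, vm=vm[i].astype(float), protocol=protocol, failed=bool(failed[i])
        )
        fv = extract_features(tr, protocol, dvdt_threshold=dvdt_threshold)
        values[i] = fv.values
        defined[i] = fv.defined
    return values, defined


def transform_matrix(values: np.ndarray, defined: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized :func:`transform_features` over an (n, 23) matrix."""
    values = np.array(values, dtype=float, copy=True)
    defined = np.array(defined, dtype=bool, copy=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        for name, kind in TRANSFORMS.items():
            i = _IDX[name]
            x = values[:, i]
            if kind == "log1p":
                y = np.log1p(x)
            elif kind == "log":
                y = np.log(x)
            else:
                y = 1.0 / (1.0 + np.exp(-x))
            values[:, i] = y
    bad = ~np.isfinite(values)
    defined &= ~bad
    values[~defined] = np.nan
    return values, defined


@dataclass
class FeatureStandardizer:
    """Per-feature z-scoring statistics fitted on a reference library."""

    mean: np.ndarray
    sd: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if np.any(self.sd <= 0):
            bad = [FEATURE_NAMES[i] for i in np.nonzero(self.sd <= 0)[0]]
            raise ValueError(f"zero or negative sd for features {bad}")

    def apply(self, x: np.ndarray | FeatureVector) -> np.ndarray | FeatureVector:
        if isinstance(x, FeatureVector):
            if x.space != "transformed":
                raise ValueError("standardize transformed-space vectors")
            z = (x.values - self.mean) / self.sd
            return FeatureVector(z, x.defined.copy(), space="z")
        return (np.asarray(x, dtype=float) - self.mean) / self.sd

    def invert(self, z: np.ndarray) -> np.ndarray:
        return np.asarray(z, dtype=float) * self.sd + self.mean


def fit_standardizer(
    vectors: Sequence[FeatureVector] | np.ndarray,
    defined: np.ndarray | None = None,
) -> FeatureStandardizer:
    """Fit per-feature mean/sd over fully defined transformed vectors."""
    if isinstance(vectors, np.ndarray):
        mat = np.asarray(vectors, dtype=float)
        if defined is not None:
            mat = mat[np.asarray(defined, bool).all(axis=1)]
    else:
        rows = []
        for fv in vectors:
            tfv = transform_features(fv) if fv.space == "raw" else fv
            if tfv.well_defined:
                rows.append(tfv.values)
        mat = np.asarray(rows, dtype=float)
    if mat.shape[0] == 0:
        raise ValueError("no fully defined vectors to fit the standardizer")
    return FeatureStandardizer(mean=mat.mean(axis=0), sd=mat.std(axis=0))
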