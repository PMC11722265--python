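"""Feature extraction against hand-computed oracles on crafted traces."""

import numpy as np
import pytest

from ephyslink.features import (
    FEATURE_NAMES,
    FeatureStandardizer,
    FeatureVector,
    detect_spikes,
    extract_features,
    fit_standardizer,
    is_well_defined,
    transform_features,
)
from ephyslink.simulator import StimulusProtocol, VoltageTrace

from conftest import PROTOCOL, make_triangular_trace

DT = PROTOCOL.dt

# heterogeneous crafted cohort trace: four triangular spikes whose geometry
# makes every one of the 23 features hand-computable
SPIKE_TIMES = (150.0, 250.0, 400.0, 560.0)
SPIKE_AMPS = (100.0, 90.0, 80.0, 72.0)


@pytest.fixture(scope="module")
def crafted():
    return make_triangular_trace(SPIKE_TIMES, SPIKE_AMPS)


def _expected_window_samples():
    """Analytic multiset of stimulation-window voltages from the geometry."""
    n = int(round((PROTOCOL.offset - PROTOCOL.onset) / DT))
    vals = np.full(n, -70.0)
    for t0, amp in zip(SPIKE_TIMES, SPIKE_AMPS):
        i = int(round(t0 / DT)) - int(round(PROTOCOL.onset / DT))
        n_up = int(round(amp / 2.0))
        vals[i : i + n_up] = -70.0 + 2.0 * np.arange(1, n_up + 1)
        vals[i + n_up : i + 2 * n_up] = -70.0 + 2.0 * np.arange(n_up - 1, -1, -1)
    return vals


class TestDetectSpikes:
    def test_flat_trace_has_no_spikes(self, protocol):
        tr = VoltageTrace(
            time=protocol.time_grid(),
            vm=np.full(protocol.n_steps + 1, -70.0),
            protocol=protocol,
        )
        assert len(detect_spikes(tr)) == 0

    def test_identical_triangles_geometry(self):
        tr = make_triangular_trace([200.0, 300.0, 400.0])
        st = detect_spikes(tr)
        assert len(st) == 3
        assert np.allclose(st.t_threshold, np.array([200.0, 300.0, 400.0]) - DT)
        assert np.allclose(st.v_threshold, -70.0)
        assert np.allclose(st.amplitude, 100.0)
        assert np.allclose(st.width, 1.25)
        assert np.allclose(st.ahp, 0.0)
        assert np.allclose(np.diff(st.t_threshold), 100.0)

    def test_upstroke_detection_is_direction_sensitive(self, protocol):
        # slow 16 mV/ms foot then fast 80 mV/ms flank up; uniform fast flank down
        V = np.full(protocol.n_steps + 1, -70.0)
        i = int(round(300.0 / DT))
        foot = -70.0 + 0.4 * np.arange(1, 26)       # to -60 in 25 steps
        fast = -60.0 + 2.0 * np.arange(1, 46)       # to +30
        down = 30.0 - 2.0 * np.arange(1, 51)        # back to -70
        V[i : i + 25] = foot
        V[i + 25 : i + 70] = fast
        V[i + 70 : i + 120] = down
        fwd = detect_spikes(VoltageTrace(time=protocol.time_grid(), vm=V, protocol=protocol))
        rev = detect_spikes(
            VoltageTrace(time=protocol.time_grid(), vm=V[::-1].copy(), protocol=protocol)
        )
        assert len(fwd) == 1 and len(rev) == 1
        # forward: threshold where the fast flank starts (-60); reversed: the
        # old falling flank is now a uniformly fast upstroke from baseline
        assert fwd.v_threshold[0] == pytest.approx(-60.0)
        assert rev.v_threshold[0] == pytest.approx(-70.0)
        assert fwd.v_threshold[0] != rev.v_threshold[0]


class TestFeatureOracle:
    """All 23 features of the crafted 4-spike trace match hand computation."""

    def test_spike_shape_features(self, crafted):
        fv = extract_features(crafted)
        assert fv["ap_threshold"] == pytest.approx(-70.0)
        assert fv["ap_amplitude"] == pytest.approx(100.0)
        assert fv["ap_width"] == pytest.approx(1.25)
        assert fv["ahp"] == pytest.approx(0.0)
        assert fv["ap3_threshold"] == pytest.approx(-70.0)
        assert fv["ap3_amplitude"] == pytest.approx(80.0)
        assert fv["ap3_width"] == pytest.approx(1.0)
        assert fv["ap3_ahp"] == pytest.approx(0.0)

    def test_counts_and_timing(self, crafted):
        fv = extract_features(crafted)
        # thresholds sit one sample before the nominal spike start
        assert fv["ap_count"] == 4
        assert fv["ap_count_1st_8th"] == 1      # [100, 175): spike at 150
        assert fv["ap_count_1st_quarter"] == 2  # threshold 249.975 < 250
        assert fv["ap_count_1st_half"] == 3
        assert fv["ap_count_2nd_half"] == 1
        assert fv["latency"] == pytest.approx(50.0 - DT)

    def test_adaptation_and_dispersion(self, crafted):
        fv = extract_features(crafted)
        amps = np.array(SPIKE_AMPS)
        assert fv["ap_amp_adapt"] == pytest.approx(100.0 / 90.0)
        assert fv["ap_average_amp_adapt"] == pytest.approx(np.mean(amps[:-1] / amps[1:]))
        assert fv["ap_cv"] == pytest.approx(amps.std() / amps.mean())
        isis = np.diff(np.array(SPIKE_TIMES))   # threshold shifts cancel
        assert fv["isi_adapt"] == pytest.approx(isis[1] / isis[0])
        assert fv["isi_cv"] == pytest.approx(isis.std() / isis.mean())

    def test_voltage_moments(self, crafted):
        from scipy import stats

        fv = extract_features(crafted)
        vals = _expected_window_samples()
        assert fv["rest_vm_mean"] == pytest.approx(-70.0)
        assert fv["vm_mean"] == pytest.approx(vals.mean())
        assert fv["vm_mean"] == pytest.approx(-70.0 + 14842.0 / 24000.0)
        assert fv["vm_std"] == pytest.approx(vals.std())
        assert fv["vm_skewness"] == pytest.approx(stats.skew(vals))

    def test_fully_well_defined(self, crafted):
        assert is_well_defined(extract_features(crafted))


class TestDegenerateTraces:
    def test_constant_trace(self, protocol):
        tr = VoltageTrace(
            time=protocol.time_grid(),
            vm=np.full(protocol.n_steps + 1, -70.0),
            protocol=protocol,
        )
        fv = extract_features(tr, protocol)
        assert fv["rest_vm_mean"] == -70.0
        assert fv["vm_mean"] == -70.0
        assert fv["vm_std"] == 0.0
        assert fv["vm_skewness"] == 0.0 and fv.is_defined("vm_skewness")
        assert fv["ap_count"] == 0
        for name in ("ap_threshold", "latency", "ap_amp_adapt", "isi_cv"):
            assert not fv.is_defined(name)
        assert not is_well_defined(fv)

    def test_two_spikes_leave_third_ap_features_undefined(self):
        tr = make_triangular_trace([200.0, 320.0], [100.0, 88.0])
        fv = extract_features(tr)
        assert fv["ap_count"] == 2
        assert fv.is_defined("ap_amp_adapt")
        for name in ("ap3_threshold", "ap3_amplitude", "ap3_width", "ap3_ahp", "isi_adapt"):
            assert not fv.is_defined(name)
        assert not is_well_defined(fv)

    def test_failed_trace_all_undefined(self, protocol):
        vm = np.full(protocol.n_steps + 1, np.nan)
        tr = VoltageTrace(time=protocol.time_grid(), vm=vm, protocol=protocol, failed=True)
        fv = extract_features(tr, protocol)
        assert not fv.defined.any()


class TestTransforms:
    def test_zero_count_stays_defined(self, crafted):
        fv = extract_features(crafted)
        tfv = transform_features(fv)
        # 2nd-half count is 1 -> log(2); a zero count maps to log(1) = 0
        assert tfv["ap_count"] == pytest.approx(np.log(5.0))
        assert tfv.is_defined("ap_count_2nd_half")

    def test_sigmoid_at_zero_is_half(self):
        vals = np.zeros(23)
        fv = FeatureVector(values=vals, defined=np.ones(23, bool), space="raw")
        tfv = transform_features(fv)
        assert tfv["ap_average_amp_adapt"] == pytest.approx(0.5)

    def test_zero_latency_becomes_undefined(self):
        vals = np.ones(23)
        vals[FEATURE_NAMES.index("latency")] = 0.0
        fv = FeatureVector(values=vals, defined=np.ones(23, bool), space="raw")
        tfv = transform_features(fv)
        assert not tfv.is_defined("latency")

    def test_undefined_propagates(self, crafted):
        fv = extract_features(crafted)
        fv.defined[FEATURE_NAMES.index("ap_cv")] = False
        tfv = transform_features(fv)
        assert not tfv.is_defined("ap_cv")


class TestInvariances:
    def test_voltage_shift_moves_only_voltage_features(self, crafted):
        fv0 = extract_features(crafted)
        shifted = VoltageTrace(
            time=crafted.time, vm=crafted.vm + 5.0, protocol=crafted.protocol
        )
        fv1 = extract_features(shifted)
        moved = {"ap_threshold", "ap3_threshold", "rest_vm_mean", "vm_mean"}
        for i, name in enumerate(FEATURE_NAMES):
            if name in moved:
                assert fv1.values[i] == pytest.approx(fv0.values[i] + 5.0), name
            else:
                assert fv1.values[i] == pytest.approx(fv0.values[i]), name

    def test_padding_after_duration_changes_nothing(self, crafted, protocol):
        pad = 2000
        vm = np.concatenate([crafted.vm, np.full(pad, crafted.vm[-1])])
        t = np.arange(len(vm)) * protocol.dt
        padded = VoltageTrace(time=t, vm=vm, protocol=protocol)
        fv0 = extract_features(crafted, protocol)
        fv1 = extract_features(padded, protocol)
        assert np.allclose(fv0.values, fv1.values, equal_nan=True)
        assert np.array_equal(fv0.defined, fv1.defined)

    def test_extraction_is_deterministic(self, crafted):
        a = extract_features(crafted)
        b = extract_features(crafted)
        assert np.allclose(a.values, b.values, equal_nan=True)


class TestStandardizer:
    def _matrix(self, rng, n=20):
        return rng.normal(size=(n, 23)) * 2.0 + 1.0

    def test_self_standardization_gives_unit_moments(self):
        rng = np.random.default_rng(0)
        mat = self._matrix(rng)
        std = fit_standardizer(mat, defined=np.ones(mat.shape, bool))
        z = std.apply(mat)
        assert np.allclose(z.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(z.std(axis=0), 1.0)

    def test_mean_vector_maps_to_zero(self):
        rng = np.random.default_rng(1)
        mat = self._matrix(rng)
        std = fit_standardizer(mat, defined=np.ones(mat.shape, bool))
        assert np.allclose(std.apply(mat.mean(axis=0)), 0.0, atol=1e-12)

    def test_two_vector_set_gives_plus_minus_one(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=23), rng.normal(size=23)
        mat = np.vstack([a, b])
        std = fit_standardizer(mat, defined=np.ones(mat.shape, bool))
        z = std.apply(mat)
        assert np.allclose(np.abs(z), 1.0)

    def test_zero_sd_rejected_with_feature_name(self):
        mat = np.ones((5, 23))
        with pytest.raises(ValueError, match="ap_threshold"):
            fit_standardizer(mat, defined=np.ones(mat.shape, bool))

    def test_roundtrip(self):
        rng = np.random.default_rng(3)
        mat = self._matrix(rng)
        std = fit_standardizer(mat, defined=np.ones(mat.shape, bool))
        assert np.allclose(std.invert(std.apply(mat)), mat)
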