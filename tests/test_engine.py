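"""Cable integrator: RC analytics, steady state, determinism, clamp."""

import math

import numpy as np
import pytest

from l5sim import engine
from l5sim.distribution import MembraneModel, N_CHANNELS
from l5sim.engine import StimulusProtocol, integrate
from l5sim.ephys_features import detect_spikes, spike_count
from l5sim.morphology import Compartment, CompartmentTree, assign_passive


def _single_compartment_model(rm=36.0, cm=1.5, diam=25.0, length=25.0):
    """Passive isopotential soma: analytic RC behaviour is known exactly."""
    tree = CompartmentTree([Compartment(id=0, parent_id=None, region="soma",
                                        length=length, diameter=diam,
                                        path_distance=0.0)])
    assign_passive(tree, cm=cm, rm_soma=rm, rm_tip=rm / 10.0)
    # soma takes rm_soma regardless of the dendritic profile
    area_cm2 = math.pi * diam * length * 1e-8
    g_leak = area_cm2 * 1e3 / rm  # µS
    c_nF = cm * area_cm2 * 1e3
    return MembraneModel(
        tree=tree, parent=np.array([-1], dtype=np.int32),
        g_ax=np.zeros(1), c=np.array([c_nF]), area=np.array([area_cm2]),
        g_leak=np.array([g_leak]), e_leak=-70.0,
        G=np.zeros((N_CHANNELS, 1)), v_shift=np.zeros(N_CHANNELS))


class TestPassiveRC:
    def test_step_response_matches_analytic_rc(self):
        """DeltaV = I*R and tau = rm*cm for an isopotential compartment."""
        m = _single_compartment_model()
        r_in = engine.passive_input_resistance(m)  # MΩ
        tau_ms = 36.0 * 1.5  # rm (kΩcm²) x cm (µF/cm²) = 54 ms
        proto = StimulusProtocol("current_clamp", ((0.0, 50.0), (-50.0, 400.0)))
        tr = integrate(m, proto, settle_ms=200.0)
        t = tr.time
        stim = t > 50.0
        dv_final = tr.values[-1] - (-70.0)
        assert dv_final == pytest.approx(-50e-3 * r_in, rel=0.01)
        # voltage at one time constant after onset: 63.2% of the step
        idx = np.searchsorted(t, 50.0 + tau_ms)
        frac = (tr.values[idx] - (-70.0)) / dv_final
        assert frac == pytest.approx(1 - math.exp(-1), rel=0.01)

    def test_zero_current_settles_at_rest(self):
        m = _single_compartment_model()
        tr = integrate(m, StimulusProtocol("current_clamp", ((0.0, 1000.0),)),
                       settle_ms=500.0)
        assert np.all(np.abs(tr.values - (-70.0)) < 0.1)


def test_active_rest_is_quiescent_and_stable(control_model):
    tr = integrate(control_model,
                   StimulusProtocol("current_clamp", ((0.0, 1000.0),)))
    assert len(detect_spikes(tr)) == 0
    assert np.ptp(tr.values) < 0.1


def test_fi_protocol_trace_count_and_amplitudes(control_sweep):
    assert len(control_sweep) == 13
    assert list(control_sweep.amplitudes) == list(np.arange(0.0, 601.0, 50.0))


def test_spike_count_non_decreasing_with_amplitude(control_counts):
    counts = [control_counts[a] for a in sorted(control_counts)]
    assert counts == sorted(counts)


def test_engine_output_bit_stable(control_model):
    proto = StimulusProtocol("current_clamp", ((0.0, 50.0), (450.0, 300.0)))
    a = integrate(control_model, proto)
    b = integrate(control_model, proto)
    assert np.array_equal(a.values, b.values)


def test_dt_guard_for_fast_sodium(control_model):
    with pytest.raises(ValueError):
        integrate(control_model,
                  StimulusProtocol("current_clamp", ((0.0, 10.0),)), dt=0.1)


def test_nonfinite_state_raises_diagnostic(control_model):
    m = control_model.copy()
    proto = StimulusProtocol("current_clamp", ((float("nan"), 100.0),))
    with pytest.raises(engine.IntegrationError, match="compartment"):
        integrate(m, proto, settle_ms=50.0)


class TestVoltageClamp:
    def test_leak_only_model_has_zero_tail(self, control_model):
        # purely ohmic membrane: once the passive tree has redistributed,
        # the clamp current carries no deactivating tail
        leak = control_model.masked(keep=[])
        _, amp = engine.run_im_tail_protocol(leak, depol_duration=800.0,
                                             tail_ms=1000.0, dt=0.05,
                                             mask_confounds=False,
                                             measure_delay_ms=300.0)
        assert abs(amp) < 1.0  # pA

    def test_km_tail_decays_monotonically(self, control_model):
        km = control_model.masked(keep=["K_M"])
        tail, amp = engine.run_im_tail_protocol(km, depol_duration=1500.0,
                                                tail_ms=1000.0, dt=0.05)
        assert amp > 0
        # after the redistribution transient the tail relaxes monotonically
        t = tail.time
        seg = tail.values[(t > 30.0) & (t < 900.0)]
        smoothed = np.convolve(seg, np.ones(50) / 50, mode="valid")
        assert np.all(np.diff(smoothed) < 1e-3)

    def test_km_tail_scales_linearly_with_density(self, control_model):
        km = control_model.masked(keep=["K_M"])
        scaled = km.copy()
        scaled.scale_channel("K_M", 0.76)
        _, a1 = engine.run_im_tail_protocol(km, depol_duration=1500.0,
                                            tail_ms=1200.0, dt=0.05)
        _, a2 = engine.run_im_tail_protocol(scaled, depol_duration=1500.0,
                                            tail_ms=1200.0, dt=0.05)
        assert a2 / a1 == pytest.approx(0.76, rel=0.02)


def test_passive_input_resistance_matches_simulation(control_model):
    """Independent steady-state cable solve vs time-stepped step response."""
    passive = control_model.masked(keep=[])
    r_analytic = engine.passive_input_resistance(passive)
    traces = []
    for amp in (-50.0, 50.0):
        proto = StimulusProtocol("current_clamp", ((0.0, 100.0), (amp, 1500.0)))
        tr = integrate(passive, proto, dt=0.05, settle_ms=500.0)
        traces.append(float(np.mean(tr.values[-2000:])))
    r_sim = (traces[1] - traces[0]) / 100.0 * 1e3  # MΩ
    assert r_sim == pytest.approx(r_analytic, rel=0.02)
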