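"""Feature extraction: spikes, F-I fit, input resistance, AHP, threshold."""

import numpy as np
import pytest

from l5sim.engine import Trace, TraceSet
from l5sim.ephys_features import (ahp_amplitude, ap_voltage_threshold,
                                  detect_spikes, fi_features, input_resistance,
                                  traceset_from_table)
from l5sim.synthetic_data import generate_trace_fixture


def _flat_trace(v=-70.0, dur=1000.0, dt=0.1):
    n = int(dur / dt)
    return Trace(values=np.full(n, v), sampling_interval=dt,
                 stimulus_amplitude=0.0, t_stim_on=0.0, t_stim_off=dur)


def _trace_with_spikes(times_ms, dur=1000.0, dt=0.1, base=-70.0):
    n = int(dur / dt)
    v = np.full(n, base)
    for t0 in times_ms:
        i0 = int(t0 / dt)
        v[i0:i0 + int(2.0 / dt)] = 10.0  # 80 mV transient
    return Trace(values=v, sampling_interval=dt, stimulus_amplitude=100.0,
                 t_stim_on=0.0, t_stim_off=dur)


class TestDetectSpikes:
    def test_flat_trace_has_no_spikes(self):
        assert len(detect_spikes(_flat_trace())) == 0

    def test_three_inserted_transients_are_counted(self):
        tr = _trace_with_spikes([100.0, 400.0, 700.0])
        assert len(detect_spikes(tr)) == 3

    def test_voltage_clamp_trace_rejected(self):
        tr = _flat_trace()
        tr.mode = "voltage_clamp"
        with pytest.raises(ValueError):
            detect_spikes(tr)

    def test_agrees_with_derivative_based_oracle(self):
        """Threshold-crossing counts match an independent dV/dt detector."""
        rng = np.random.default_rng(7)
        for k in range(100):
            ts = generate_trace_fixture(rheobase=float(rng.uniform(75, 250)),
                                        fi_slope=float(rng.uniform(40, 120)),
                                        noise_sd=0.2, seed=k)
            for tr in ts:
                dvdt = np.diff(tr.values) / tr.sampling_interval
                # oracle: upstrokes exceeding 50 mV/ms, 2 ms apart
                idx = np.flatnonzero(dvdt > 50.0)
                n_oracle = 0
                last = -10.0
                for i in idx:
                    t = i * tr.sampling_interval
                    if t - last >= 2.0:
                        n_oracle += 1
                        last = t
                assert len(detect_spikes(tr)) == n_oracle


class TestFIFeatures:
    def _set_from_counts(self, counts, dur=1000.0):
        traces = []
        for amp, n in counts.items():
            times = np.linspace(50.0, dur - 50.0, n) if n else []
            tr = _trace_with_spikes(times, dur=dur)
            tr.stimulus_amplitude = float(amp)
            traces.append(tr)
        return TraceSet(traces)

    def test_exact_line_recovers_slope_and_intercept(self):
        # rates 4, 8, 12 Hz at 150/200/250 pA lie exactly on an 80 Hz/nA line
        ts = self._set_from_counts({100: 0, 150: 4, 200: 8, 250: 12})
        fit = fi_features(ts)
        assert fit.slope == pytest.approx(80.0)
        assert fit.rheobase == pytest.approx(100.0)

    def test_saturating_point_excluded_by_selection_rule(self):
        ts = self._set_from_counts({100: 0, 150: 4, 200: 8, 250: 12, 300: 13})
        fit = fi_features(ts)
        assert 300.0 not in fit.amplitudes_used
        assert fit.slope == pytest.approx(80.0)

    def test_isolated_onset_transient_not_part_of_linear_portion(self):
        ts = self._set_from_counts({100: 1, 150: 1, 200: 4, 250: 8, 300: 12})
        fit = fi_features(ts)
        assert min(fit.amplitudes_used) == 200.0

    def test_invariant_under_trace_reordering(self):
        counts = {100: 0, 150: 4, 200: 8, 250: 12}
        ts = self._set_from_counts(counts)
        shuffled = TraceSet(list(reversed(ts.traces)))
        a, b = fi_features(ts), fi_features(shuffled)
        assert a.slope == b.slope and a.rheobase == b.rheobase

    def test_all_subthreshold_is_an_error(self):
        with pytest.raises(ValueError):
            fi_features(self._set_from_counts({100: 0, 150: 0}))


class TestInputResistance:
    def _iv_traces(self, r_mohm=100.0, rest=-70.0):
        traces = []
        for amp in (-50.0, 0.0, 50.0):
            tr = _flat_trace(v=rest + amp * r_mohm * 1e-3)
            tr.stimulus_amplitude = amp
            traces.append(tr)
        return traces

    def test_ohms_law_example(self):
        assert input_resistance(self._iv_traces(100.0)) == pytest.approx(100.0)

    def test_offset_invariance(self):
        a = input_resistance(self._iv_traces(80.0, rest=-70.0))
        b = input_resistance(self._iv_traces(80.0, rest=-60.0))
        assert a == pytest.approx(b)

    def test_spiking_trace_rejected(self):
        traces = self._iv_traces()
        traces[2] = _trace_with_spikes([500.0])
        traces[2].stimulus_amplitude = 50.0
        with pytest.raises(ValueError):
            input_resistance(traces)


class TestAHP:
    def _trace_with_undershoot(self, depth, dur=1000.0, post=1000.0, dt=0.1):
        n_stim, n_post = int(dur / dt), int(post / dt)
        v = np.concatenate([np.full(n_stim, -55.0), np.full(n_post, -70.0)])
        for t0 in (100.0, 300.0, 500.0):
            v[int(t0 / dt):int(t0 / dt) + 20] = 10.0
        if depth > 0:
            t = np.arange(n_post) * dt / 120.0
            v[n_stim:] -= depth * t * np.exp(1.0 - t)
        return Trace(values=v, sampling_interval=dt, stimulus_amplitude=300.0,
                     t_stim_on=0.0, t_stim_off=dur)

    def test_monotone_return_gives_zero(self):
        assert ahp_amplitude(self._trace_with_undershoot(0.0)) == 0.0

    def test_constructed_depth_recovered(self):
        assert ahp_amplitude(self._trace_with_undershoot(5.0)) == \
            pytest.approx(5.0, abs=0.1)

    def test_missing_stimulus_offset_is_an_error(self):
        tr = self._trace_with_undershoot(5.0)
        tr.t_stim_off = None
        with pytest.raises(ValueError):
            ahp_amplitude(tr)


class TestAPThreshold:
    def _sigmoid_spike(self, dt, onset_tau=1.5, t_mid=50.0, base=-60.0,
                       amp=80.0, dur=100.0):
        t = np.arange(1, int(dur / dt) + 1) * dt
        v = base + amp / (1.0 + np.exp(-(t - t_mid) / onset_tau))
        return Trace(values=v, sampling_interval=dt, stimulus_amplitude=200.0,
                     t_stim_on=0.0, t_stim_off=dur), t, base, amp, onset_tau, t_mid

    def test_matches_symbolic_third_derivative_oracle(self):
        """The d³V/dt³ peak of a logistic upstroke is known in closed form."""
        import sympy as sp

        tr, t, base, amp, tau, t_mid = self._sigmoid_spike(dt=0.02)
        ts = sp.symbols("t")
        expr = amp / (1 + sp.exp(-(ts - t_mid) / tau))
        d3 = sp.lambdify(ts, sp.diff(expr, ts, 3), "numpy")
        tt = np.arange(t_mid - 10.0, t_mid, 1e-3)
        y = d3(tt)
        peaks = np.flatnonzero((y[1:-1] > y[:-2]) & (y[1:-1] >= y[2:])) + 1
        t_peak = tt[peaks[0]]  # first maximum of d³V/dt³ before the upstroke
        v_expected = base + amp / (1 + np.exp(-(t_peak - t_mid) / tau))
        assert ap_voltage_threshold(tr) == pytest.approx(v_expected, abs=0.2)

    def test_stable_under_sampling_refinement(self):
        a = ap_voltage_threshold(self._sigmoid_spike(dt=0.05)[0])
        b = ap_voltage_threshold(self._sigmoid_spike(dt=0.025)[0])
        assert abs(a - b) < 0.2

    def test_coarse_sampling_rejected(self):
        tr = self._sigmoid_spike(dt=0.2)[0]
        with pytest.raises(ValueError):
            ap_voltage_threshold(tr)


def test_traceset_round_trips_through_table():
    ts = generate_trace_fixture(noise_sd=0.0, seed=0)
    df = ts.to_dataframe()
    back = traceset_from_table(df, t_stim_on=100.0, t_stim_off=1100.0)
    fit_a, fit_b = fi_features(ts), fi_features(back)
    assert fit_a.slope == pytest.approx(fit_b.slope)
    assert fit_a.rheobase == pytest.approx(fit_b.rheobase)
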