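"""Channel kinetics: bounds, monotonicity, shifts, calcium pool."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from l5sim import channels as ch

V_GRID = np.linspace(-120.0, 60.0, 73)
CA_GRID = np.logspace(-5, -1, 20)  # mM


def _gate_curves(channel, gate, v, ca=1e-3):
    if gate.calcium_dependent:
        return gate.steady_state(v, ca), gate.time_constant(v, ca)
    return gate.steady_state(v), gate.time_constant(v)


def test_every_steady_state_bounded_and_tau_positive():
    for name, channel in ch.CHANNELS.items():
        for gate in channel.gates:
            for v in V_GRID:
                inf, tau = _gate_curves(channel, gate, float(v))
                assert 0.0 <= inf <= 1.0, (name, gate.label, v)
                assert tau > 0.0, (name, gate.label, v)


def test_gate_at_steady_state_has_zero_derivative():
    na = ch.CHANNELS["Na"]
    state = {"m": ch.na_m_inf(-55.0), "h": ch.na_h_inf(-55.0)}
    deriv = ch.gate_dynamics(na, -55.0, None, state)
    assert deriv["m"] == pytest.approx(0.0, abs=1e-12)
    assert deriv["h"] == pytest.approx(0.0, abs=1e-12)


def test_boltzmann_gate_half_activates_at_its_midpoint():
    assert ch.nap_m_inf(ch.NAP_VHALF) == pytest.approx(0.5)
    assert ch.hcn1_m_inf(ch.HCN1_VHALF) == pytest.approx(0.5)


def test_relaxation_matches_analytic_exponential():
    """First-order gating under fixed voltage has a closed-form solution."""
    nap = ch.CHANNELS["Na_P"]
    v, x0 = -50.0, 0.0
    inf, tau = ch.nap_m_inf(v), ch.nap_m_tau(v)
    rate = nap.temperature_factor / tau
    dt = tau / 100.0
    x = x0
    for k in range(1, 501):
        x = x + dt * ch.gate_dynamics(nap, v, None, {"m": x})["m"]
        exact = inf + (x0 - inf) * math.exp(-rate * k * dt)
        # forward Euler at dt = tau/100 tracks the exact exponential closely
        assert abs(x - exact) < 1e-3
    # and the Rush-Larsen update used by the engine is exact per step
    x_rl = inf + (x0 - inf) * math.exp(-rate * 5 * dt)
    exact = inf + (x0 - inf) * math.exp(-rate * 5 * dt)
    assert abs(x_rl - exact) < 1e-12


def test_bk_requires_calcium():
    bk = ch.CHANNELS["K_BK"]
    with pytest.raises(ValueError):
        ch.gate_dynamics(bk, -20.0, None, {"m": 0.1})
    with pytest.raises(ValueError):
        ch.bk_open_fraction(-20.0, 0.0)


def test_bk_surface_bounded_and_jointly_monotone():
    vv, cc = np.meshgrid(np.linspace(-100, 100, 20), CA_GRID)
    surf = ch.bk_open_fraction(vv, cc)
    assert np.all((surf >= 0.0) & (surf <= 1.0))
    # non-decreasing in v at fixed ca, and in ca at fixed v (brute force)
    assert np.all(np.diff(surf, axis=1) >= -1e-12)
    assert np.all(np.diff(surf, axis=0) >= -1e-12)
    # halving calcium never increases the open fraction
    assert np.all(ch.bk_open_fraction(vv, cc / 2.0) <= surf + 1e-12)


def test_bk_saturates_at_high_voltage_and_calcium():
    assert ch.bk_open_fraction(100.0, 1e-2) > 0.95


class TestShiftHalfActivation:
    def test_zero_shift_is_identity(self):
        nap = ch.CHANNELS["Na_P"]
        shifted = ch.shift_half_activation(nap, 0.0)
        for v in V_GRID:
            assert shifted._inf(shifted.gates[0], v, None) == \
                nap._inf(nap.gates[0], v, None)

    def test_hyperpolarizing_shift_raises_activation(self):
        nap = ch.CHANNELS["Na_P"]
        shifted = ch.shift_half_activation(nap, -2.0)
        for v in V_GRID:
            assert shifted._inf(shifted.gates[0], float(v), None) >= \
                nap._inf(nap.gates[0], float(v), None)

    def test_shifts_compose_and_invert(self):
        nap = ch.CHANNELS["Na_P"]
        back = ch.shift_half_activation(ch.shift_half_activation(nap, 2.0), -2.0)
        assert back.v_half_shift == pytest.approx(nap.v_half_shift)


class TestCalciumPool:
    def test_zero_current_stays_at_rest(self):
        pool = ch.CalciumPool()
        for _ in range(100):
            pool = ch.update_calcium(pool, 0.0, 0.1)
        assert pool.concentration == pool.resting_concentration

    def test_constant_current_converges_to_closed_form(self):
        pool = ch.CalciumPool()
        i_ca = 0.01  # mA/cm²
        for _ in range(200000):
            pool = ch.update_calcium(pool, i_ca, 0.05)
        expected = (pool.resting_concentration
                    + pool.influx_scale * i_ca * pool.decay_time_constant)
        assert pool.concentration == pytest.approx(expected, rel=1e-3)

    def test_concentration_never_below_rest(self):
        pool = ch.CalciumPool(concentration=5e-4)
        for _ in range(10000):
            pool = ch.update_calcium(pool, 0.0, 1.0)
            assert pool.concentration >= pool.resting_concentration

    def test_nonpositive_dt_rejected(self):
        with pytest.raises(ValueError):
            ch.update_calcium(ch.CalciumPool(), 0.0, 0.0)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.floats(min_value=0.0, max_value=1e4, allow_nan=False))
def test_hcn_split_conserves_total(total):
    h1, h2 = ch.hcn_split(total)
    assert h1 + h2 == total  # exact by construction
    assert h1 >= h2 >= 0.0


def test_hcn_split_examples():
    h1, h2 = ch.hcn_split(0.95)
    assert h1 == pytest.approx(2.0 / 3.0 * 0.95)
    assert h2 == pytest.approx(0.95 / 3.0)
    assert ch.hcn_split(0.0) == (0.0, 0.0)
    with pytest.raises(ValueError):
        ch.hcn_split(-1.0)


def test_hcn1_less_hyperpolarized_and_faster_than_hcn2():
    assert ch.HCN1_VHALF > ch.HCN2_VHALF
    for v in (-120.0, -90.0, -70.0):
        assert ch.hcn1_m_tau(v) < ch.hcn2_m_tau(v)


def test_current_scales_linearly_with_density():
    """At fixed (v, state) the instantaneous current is proportional to g."""
    na = ch.CHANNELS["Na"]
    state = {"m": 0.3, "h": 0.6}
    v = -20.0
    open_frac = na.open_fraction(v, state=state)
    i1 = 1.0 * open_frac * (v - na.reversal_potential)
    i2 = 3.7 * open_frac * (v - na.reversal_potential)
    assert i2 == pytest.approx(3.7 * i1)


def test_shipped_channel_config_in_sync():
    import yaml
    from importlib import resources

    with resources.files("l5sim.config").joinpath("channels.yaml").open() as fh:
        shipped = yaml.safe_load(fh)
    assert shipped == yaml.safe_load(
        yaml.safe_dump(ch.export_channel_config(), sort_keys=False))
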