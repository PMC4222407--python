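"""Density rules, profiles and membrane-model assembly."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from l5sim import channels as ch
from l5sim import morphology as morph
from l5sim.distribution import (CHANNEL_INDEX, DensityRule, build_membrane_model,
                                default_model, density_at, ka_exchange_fraction,
                                rules_from_config)


class TestDensityAt:
    def test_uniform_axonal_sodium(self):
        rule = DensityRule(channel="Na_x", region="axon", start_density=3500)
        for d in (0.0, 10.0, 44.0):
            assert density_at(rule, d) == 3500

    def test_exponential_decay_at_one_length_constant(self):
        rule = DensityRule(channel="K_V", region="apical", profile="exponential",
                           start_density=20, length_constant=80)
        assert density_at(rule, 80.0) == pytest.approx(20 * math.exp(-1))

    def test_hcn_growth_capped_at_40x(self):
        rule = DensityRule(channel="HCN", region="apical", profile="exponential",
                           grow=True, start_density=0.95, length_constant=323,
                           cap_factor=40)
        assert density_at(rule, 0.0) == pytest.approx(0.95)
        d_cap = 323 * math.log(40)  # ~1191 um
        assert density_at(rule, d_cap + 1) == pytest.approx(38.0)

    def test_km_restricted_to_proximal_apical(self):
        rule = DensityRule(channel="K_M", region="apical", start_density=5,
                           extent=100)
        assert density_at(rule, 50.0) == 5
        assert density_at(rule, 150.0) == 0.0

    def test_it2_restricted_to_distal_dendrite(self):
        rule = DensityRule(channel="Ca_IT2", region="apical", start_density=0.5,
                           onset=300)
        assert density_at(rule, 300.0) == 0.0
        assert density_at(rule, 301.0) == 0.5

    def test_linear_profile_continuous_within_region(self):
        rule = DensityRule(channel="Na", region="basal", profile="linear",
                           start_density=150, end_or_factor=75,
                           region_length=200.0)
        d = np.linspace(0, 200, 101)
        vals = np.array([density_at(rule, x) for x in d])
        assert vals[0] == 150 and vals[-1] == 75
        assert np.all(np.abs(np.diff(vals)) < 1.0)  # no jumps


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.floats(min_value=0.0, max_value=2000.0, allow_nan=False))
def test_ka_exchange_fraction_clamped(d):
    f = ka_exchange_fraction(d)
    assert 0.0 <= f <= 1.0


def test_ka_exchange_examples():
    assert ka_exchange_fraction(0.0) == 0.0
    assert ka_exchange_fraction(150.0) == pytest.approx(0.5)
    assert ka_exchange_fraction(450.0) == 1.0


def test_unit_conversion_round_trip():
    # 1 pS/um2 over 1 cm2 of membrane is 1e-4 S
    area_um2 = 1e8  # 1 cm²
    g_uS = 1.0 * (area_um2 * 1e-8) * 100.0  # assembly formula
    assert g_uS * 1e-6 == pytest.approx(1e-4)  # S


@pytest.fixture(scope="module")
def model():
    return default_model()


class TestAssembly:

    def test_soma_receives_table_densities(self, model):
        assert model.channel_density("K_AP", 0) == pytest.approx(150.0)
        assert model.channel_density("K_BK", 0) == pytest.approx(0.6)
        assert model.channel_density("Na_P", 0) == pytest.approx(10.0)

    def test_soma_hcn_split_two_thirds_one_third(self, model):
        h1 = model.channel_density("HCN1", 0)
        h2 = model.channel_density("HCN2", 0)
        assert h1 + h2 == pytest.approx(0.95)
        assert h1 == pytest.approx(2 * h2)

    def test_spine_corrected_basal_doubles_density(self, model):
        comp = next(c for c in model.tree.compartments
                    if c.region == "basal" and 40 <= c.path_distance <= 60)
        rule_value = 150 + (75 - 150) * comp.path_distance / \
            model.tree.max_path_distance("basal")
        assert model.channel_density("Na", comp.id) == \
            pytest.approx(2 * rule_value, rel=1e-6)

    def test_ka_variants_sum_to_total_times_spine_factor(self, model):
        for comp in model.tree.compartments:
            if comp.region != "apical":
                continue
            total = (model.channel_density("K_AP", comp.id)
                     + model.channel_density("K_AD", comp.id))
            assert total == pytest.approx(300.0 * comp.spine_factor, rel=1e-6)

    def test_empty_rule_list_rejected(self, model):
        with pytest.raises(ValueError):
            build_membrane_model(model.tree, [])

    def test_unknown_channel_rejected(self, model):
        bad = [DensityRule(channel="K_X", region="soma", start_density=1.0)]
        with pytest.raises(ValueError):
            build_membrane_model(model.tree, bad)

    def test_calibration_touches_only_soma_and_axon(self):
        base = rules_from_config()
        scaled = rules_from_config(calibration={"Na": 1.3, "K_V": 1.3})
        for r0, r1 in zip(base, scaled):
            if r0.channel in ("Na", "K_V") and r0.region in ("soma", "axon"):
                assert r1.start_density == pytest.approx(1.3 * r0.start_density)
            else:
                assert r1.start_density == r0.start_density

    def test_modulation_helpers_scale_conductance_rows(self, model):
        m = model.copy()
        before = m.G[CHANNEL_INDEX["K_M"]].copy()
        m.scale_channel("K_M", 0.5)
        assert np.allclose(m.G[CHANNEL_INDEX["K_M"]], 0.5 * before)
        with pytest.raises(ValueError):
            m.scale_channel("nope", 0.5)
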