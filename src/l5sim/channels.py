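"""Ion-channel kinetics in Hodgkin-Huxley form.

Twelve channel models are provided: transient sodium (somatodendritic
``Na`` and the axonal low-threshold ``Na_x`` variant), persistent sodium
``Na_P``, delayed-rectifier ``K_V``, M-type ``K_M``, proximal and distal
A-type ``K_AP``/``K_AD``, the large-conductance calcium- and
voltage-gated ``K_BK``, high-voltage-activated ``Ca_HVA`` and
low-threshold ``Ca_IT2`` calcium channels, and the two
hyperpolarization-activated subunits ``HCN1``/``HCN2``.

Gating follows first-order kinetics dx/dt = (x_inf - x)/tau_x with rate
functions of voltage (and, for BK, intracellular calcium).  The sodium,
delayed-rectifier, M-type and HVA-calcium rate functions use the familiar
linoid/exponential forms of cortical pyramidal cell models; the A-type,
persistent-sodium and HCN gates use Boltzmann activation curves.  The BK
model couples voltage and calcium through a half-activation voltage that
shifts linearly with log10([Ca]) - depolarization and calcium elevation
each increase the open probability, and the two requirements interact, as
in the classic allosteric picture of BK gating.

Rates are scaled to the model's nominal temperature of 32 C with a Q10 of
2.3 relative to each parameterization's source temperature.

The numerically hot scalar rate functions are numba-compiled; the same
compiled functions back both the Python-level :class:`ChannelKinetics`
API and the cable-integration kernel in :mod:`l5sim.engine`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# global constants

TEMPERATURE_C = 32.0  #: nominal simulation temperature
Q10 = 2.3             #: gating-rate Q10

#: fixed reversal potentials, mV
E_NA = 60.0
E_K = -90.0
E_H = -45.0
E_CA = 140.0

#: HCN subunit composition of the total HCN conductance
HCN1_FRACTION = 2.0 / 3.0

#: BK model parameters (half-activation voltage at the reference calcium,
#: its shift per decade of calcium, Boltzmann slope, activation tau at 32 C)
BK_VH_REF = 20.0      # mV at ca = BK_CA_REF
BK_CA_REF = 1e-3      # mM (1 uM)
BK_SHIFT_PER_DECADE = 55.0  # mV
BK_SLOPE = 28.0       # mV
BK_TAU = 1.0          # ms

#: calcium pool defaults: sub-membrane shell with first-order extrusion
CA_RESTING = 1e-4     # mM (100 nM)
CA_DECAY_TAU = 130.0  # ms
CA_SHELL_DEPTH = 0.45  # um
FARADAY = 96485.309   # C/mol
#: mM.cm^2/(ms.mA): converts an inward calcium current density to d[Ca]/dt
CA_INFLUX_SCALE = 1e4 / (2.0 * FARADAY * CA_SHELL_DEPTH)

CHANNEL_NAMES = ("Na", "Na_x", "Na_P", "K_V", "K_M", "K_AP", "K_AD",
                 "K_BK", "Ca_HVA", "Ca_IT2", "HCN1", "HCN2")

#: Q10 rate multiplier per channel, from source temperature to 32 C
_SOURCE_TEMP = {"Na": 23.0, "Na_x": 23.0, "K_V": 23.0, "K_M": 23.0,
                "Ca_HVA": 23.0, "Ca_IT2": 24.0}


def temperature_factor(name: str, temperature: float = TEMPERATURE_C) -> float:
    """Q10 rate multiplier taking a channel's source kinetics to 32 C."""
    return Q10 ** ((temperature - _SOURCE_TEMP.get(name, TEMPERATURE_C)) / 10.0)


# ---------------------------------------------------------------------------
# scalar rate functions (numba-compiled; voltages mV, taus ms, ca mM)

@njit(cache=True)
def _trap(v: float, th: float, a: float, q: float) -> float:
    """a*(v-th)/(1-exp(-(v-th)/q)), with the v == th singularity removed."""
    x = v - th
    if abs(x) < 1e-6:
        x = 1e-6
    return a * x / (1.0 - math.exp(-x / q))


#: transient-sodium activation/inactivation midpoints; the steep
#: inactivation keeps the subthreshold window current small despite the
#: high dendritic sodium densities
NA_M_TH = -30.0
NA_H_TH = -62.0
NA_H_SLOPE = 4.0
#: rate scale of inactivation; < 1 slows h so that near-threshold recovery
#: (~10 ms) is slower than the fast voltage dynamics
NA_H_RATE = 0.4


@njit(cache=True)
def na_m_inf(v: float) -> float:
    a = _trap(v, NA_M_TH, 0.182, 9.0)
    b = _trap(-v, -NA_M_TH, 0.124, 9.0)
    return a / (a + b)


@njit(cache=True)
def na_m_tau(v: float) -> float:
    a = _trap(v, NA_M_TH, 0.182, 9.0)
    b = _trap(-v, -NA_M_TH, 0.124, 9.0)
    return 1.0 / (a + b)


@njit(cache=True)
def na_h_inf(v: float) -> float:
    return 1.0 / (1.0 + math.exp((v - NA_H_TH) / NA_H_SLOPE))


@njit(cache=True)
def na_h_tau(v: float) -> float:
    a = _trap(v, -50.0, 0.024, 5.0)
    b = _trap(-v, 75.0, 0.0091, 5.0)
    return 1.0 / (NA_H_RATE * (a + b))


#: the axonal Na_x variant activates 7 mV more hyperpolarized than Na,
#: giving the axon initial segment its lower threshold (inactivation is
#: unshifted)
NAX_SHIFT = -12.0


@njit(cache=True)
def nax_m_inf(v: float) -> float:
    return na_m_inf(v - NAX_SHIFT)


@njit(cache=True)
def nax_m_tau(v: float) -> float:
    return na_m_tau(v - NAX_SHIFT)


@njit(cache=True)
def nax_h_inf(v: float) -> float:
    return na_h_inf(v)


@njit(cache=True)
def nax_h_tau(v: float) -> float:
    return na_h_tau(v)


#: persistent-sodium activation midpoint/slope; its position relative to
#: spike threshold sets how strongly a V1/2 shift moves the rheobase
NAP_VHALF = -48.5
NAP_SLOPE = 5.0


@njit(cache=True)
def nap_m_inf(v: float) -> float:
    return 1.0 / (1.0 + math.exp(-(v - NAP_VHALF) / NAP_SLOPE))


@njit(cache=True)
def nap_m_tau(v: float) -> float:
    return 1.0


#: delayed-rectifier activation threshold (mV in the trap functions)
KV_TH = -20.0


@njit(cache=True)
def kv_n_inf(v: float) -> float:
    a = _trap(v, KV_TH, 0.02, 9.0)
    b = _trap(-v, -KV_TH, 0.002, 9.0)
    return a / (a + b)


#: overall delayed-rectifier rate scale (> 1 = faster gating, sharper
#: spike repolarization and shallower fast afterhyperpolarization)
KV_RATE = 1.5


@njit(cache=True)
def kv_n_tau(v: float) -> float:
    a = _trap(v, KV_TH, 0.02, 9.0)
    b = _trap(-v, -KV_TH, 0.002, 9.0)
    return 1.0 / (KV_RATE * (a + b))


#: M-current activation: steep Boltzmann that engages just above rest and
#: saturates below spike threshold, with the slow (~100 ms) kinetics seen
#: in Kv7 deactivation tails
KM_VHALF = -45.0
KM_SLOPE = 12.0
KM_TAU = 80.0


@njit(cache=True)
def km_n_inf(v: float) -> float:
    return 1.0 / (1.0 + math.exp(-(v - KM_VHALF) / KM_SLOPE))


@njit(cache=True)
def km_n_tau(v: float) -> float:
    return KM_TAU + 600.0 / (math.exp((v + 55.0) / 12.0)
                             + math.exp(-(v + 55.0) / 12.0))


#: A-type per-gate activation midpoints (the conductance goes as n^4, so
#: the effective half-activation sits ~10 mV above these); the distal
#: variant activates more hyperpolarized than the proximal one
KAP_VHALF = -25.0
KAD_VHALF = -35.0
KA_SLOPE = 12.0


@njit(cache=True)
def kap_n_inf(v: float) -> float:
    return 1.0 / (1.0 + math.exp(-(v - KAP_VHALF) / KA_SLOPE))


@njit(cache=True)
def kap_n_tau(v: float) -> float:
    return 1.0


@njit(cache=True)
def kad_n_inf(v: float) -> float:
    return 1.0 / (1.0 + math.exp(-(v - KAD_VHALF) / KA_SLOPE))


@njit(cache=True)
def kad_n_tau(v: float) -> float:
    return 1.0


@njit(cache=True)
def ka_l_inf(v: float) -> float:
    return 1.0 / (1.0 + math.exp((v + 56.0) / 8.0))


@njit(cache=True)
def ka_l_tau(v: float) -> float:
    t = 0.26 * (v + 50.0)
    return t if t > 2.0 else 2.0


@njit(cache=True)
def bk_vhalf(ca: float) -> float:
    return BK_VH_REF - BK_SHIFT_PER_DECADE * math.log10(ca / BK_CA_REF)


@njit(cache=True)
def bk_m_inf(v: float, ca: float) -> float:
    return 1.0 / (1.0 + math.exp(-(v - bk_vhalf(ca)) / BK_SLOPE))


@njit(cache=True)
def bk_m_tau(v: float, ca: float) -> float:
    return BK_TAU


@njit(cache=True)
def ca_m_inf(v: float) -> float:
    a = _trap(v, -27.0, 0.055, 3.8)
    b = 0.94 * math.exp(-(v + 75.0) / 17.0)
    return a / (a + b)


@njit(cache=True)
def ca_m_tau(v: float) -> float:
    a = _trap(v, -27.0, 0.055, 3.8)
    b = 0.94 * math.exp(-(v + 75.0) / 17.0)
    return 1.0 / (a + b)


@njit(cache=True)
def ca_h_inf(v: float) -> float:
    a = 4.57e-4 * math.exp(-(v + 13.0) / 50.0)
    b = 6.5e-3 / (1.0 + math.exp(-(v + 15.0) / 28.0))
    return a / (a + b)


@njit(cache=True)
def ca_h_tau(v: float) -> float:
    a = 4.57e-4 * math.exp(-(v + 13.0) / 50.0)
    b = 6.5e-3 / (1.0 + math.exp(-(v + 15.0) / 28.0))
    return 1.0 / (a + b)


@njit(cache=True)
def it2_m_inf(v: float) -> float:
    return 1.0 / (1.0 + math.exp(-(v + 57.0) / 6.2))


@njit(cache=True)
def it2_m_tau(v: float) -> float:
    return 0.612 + 1.0 / (math.exp(-(v + 132.0) / 16.7) + math.exp((v + 16.8) / 18.2))


@njit(cache=True)
def it2_h_inf(v: float) -> float:
    return 1.0 / (1.0 + math.exp((v + 81.0) / 4.0))


@njit(cache=True)
def it2_h_tau(v: float) -> float:
    if v < -80.0:
        return math.exp((v + 467.0) / 66.6)
    return 28.0 + math.exp(-(v + 22.0) / 10.5)


#: HCN1 activates faster and at less hyperpolarized potentials than HCN2
HCN1_VHALF = -90.0
HCN2_VHALF = -102.0


@njit(cache=True)
def hcn1_m_inf(v: float) -> float:
    return 1.0 / (1.0 + math.exp((v - HCN1_VHALF) / 9.0))


@njit(cache=True)
def hcn1_m_tau(v: float) -> float:
    return 15.0 + 65.0 / (math.exp((v + 85.0) / 18.0) + math.exp(-(v + 85.0) / 18.0))


@njit(cache=True)
def hcn2_m_inf(v: float) -> float:
    return 1.0 / (1.0 + math.exp((v - HCN2_VHALF) / 9.0))


@njit(cache=True)
def hcn2_m_tau(v: float) -> float:
    return 80.0 + 400.0 / (math.exp((v + 95.0) / 20.0) + math.exp(-(v + 95.0) / 20.0))


# ---------------------------------------------------------------------------
# Python-level channel API


@dataclass(frozen=True)
class Gate:
    """One first-order gating variable with its exponent in the conductance."""

    label: str
    exponent: int
    steady_state: Callable  # (v[, ca]) -> [0, 1]
    time_constant: Callable  # (v[, ca]) -> ms (> 0)
    calcium_dependent: bool = False


@dataclass(frozen=True)
class ChannelKinetics:
    """A channel model: gates, reversal potential, V1/2 shift, rate scaling."""

    name: str
    gates: tuple[Gate, ...]
    reversal_potential: float  # mV
    v_half_shift: float = 0.0  # mV, applied as f(v - shift)
    temperature_factor: float = 1.0

    @property
    def calcium_dependent(self) -> bool:
        return any(g.calcium_dependent for g in self.gates)

    def open_fraction(self, v: float, ca: float | None = None,
                      state: dict[str, float] | None = None) -> float:
        """Product of gate^exponent, at steady state or at a given state."""
        out = 1.0
        for g in self.gates:
            x = (state[g.label] if state is not None
                 else self._inf(g, v, ca))
            out *= x ** g.exponent
        return out

    def _inf(self, gate: Gate, v: float, ca: float | None) -> float:
        vv = v - self.v_half_shift
        if gate.calcium_dependent:
            if ca is None:
                raise ValueError(f"{self.name}.{gate.label}: calcium required")
            return gate.steady_state(vv, ca)
        return gate.steady_state(vv)

    def _tau(self, gate: Gate, v: float, ca: float | None) -> float:
        vv = v - self.v_half_shift
        if gate.calcium_dependent:
            if ca is None:
                raise ValueError(f"{self.name}.{gate.label}: calcium required")
            return gate.time_constant(vv, ca)
        return gate.time_constant(vv)


def _mk(name: str, gates: list[tuple[str, int, Callable, Callable]] |
        list[tuple[str, int, Callable, Callable, bool]],
        erev: float) -> ChannelKinetics:
    gs = []
    for g in gates:
        label, expo, inf, tau = g[:4]
        cadep = bool(g[4]) if len(g) > 4 else False
        gs.append(Gate(label, expo, inf, tau, cadep))
    return ChannelKinetics(name=name, gates=tuple(gs), reversal_potential=erev,
                           temperature_factor=temperature_factor(name))


def build_channel_library() -> dict[str, ChannelKinetics]:
    """The full channel registry keyed by channel name."""
    return {
        "Na": _mk("Na", [("m", 3, na_m_inf, na_m_tau),
                         ("h", 1, na_h_inf, na_h_tau)], E_NA),
        "Na_x": _mk("Na_x", [("m", 3, nax_m_inf, nax_m_tau),
                             ("h", 1, nax_h_inf, nax_h_tau)], E_NA),
        "Na_P": _mk("Na_P", [("m", 1, nap_m_inf, nap_m_tau)], E_NA),
        "K_V": _mk("K_V", [("n", 1, kv_n_inf, kv_n_tau)], E_K),
        "K_M": _mk("K_M", [("n", 1, km_n_inf, km_n_tau)], E_K),
        "K_AP": _mk("K_AP", [("n", 4, kap_n_inf, kap_n_tau),
                             ("l", 1, ka_l_inf, ka_l_tau)], E_K),
        "K_AD": _mk("K_AD", [("n", 4, kad_n_inf, kad_n_tau),
                             ("l", 1, ka_l_inf, ka_l_tau)], E_K),
        "K_BK": _mk("K_BK", [("m", 1, bk_m_inf, bk_m_tau, True)], E_K),
        "Ca_HVA": _mk("Ca_HVA", [("m", 2, ca_m_inf, ca_m_tau),
                                 ("h", 1, ca_h_inf, ca_h_tau)], E_CA),
        "Ca_IT2": _mk("Ca_IT2", [("m", 2, it2_m_inf, it2_m_tau),
                                 ("h", 1, it2_h_inf, it2_h_tau)], E_CA),
        "HCN1": _mk("HCN1", [("m", 1, hcn1_m_inf, hcn1_m_tau)], E_H),
        "HCN2": _mk("HCN2", [("m", 1, hcn2_m_inf, hcn2_m_tau)], E_H),
    }


CHANNELS = build_channel_library()


# ---------------------------------------------------------------------------
# operations


def gate_dynamics(channel: ChannelKinetics, v: float, ca: float | None,
                  state: dict[str, float]) -> dict[str, float]:
    """Time derivatives (1/ms) of each gate under first-order kinetics.

    The channel's V1/2 shift is applied to the voltage argument and the
    temperature factor scales the rate.
    """
    out = {}
    for g in channel.gates:
        x = state[g.label]
        if not 0.0 <= x <= 1.0:
            raise ValueError(f"gate {g.label} state {x} outside [0, 1]")
        inf = channel._inf(g, v, ca)
        tau = channel._tau(g, v, ca)
        out[g.label] = channel.temperature_factor * (inf - x) / tau
    return out


def bk_open_fraction(v, ca):
    """Steady-state open fraction of the BK channel at (v, ca).

    Monotone non-decreasing in v at fixed ca and in ca at fixed v.
    Accepts scalars or arrays; ca must be strictly positive.
    """
    v = np.asarray(v, dtype=float)
    ca = np.asarray(ca, dtype=float)
    if np.any(ca <= 0):
        raise ValueError("BK gating requires calcium > 0")
    vh = BK_VH_REF - BK_SHIFT_PER_DECADE * np.log10(ca / BK_CA_REF)
    out = 1.0 / (1.0 + np.exp(-(v - vh) / BK_SLOPE))
    return float(out) if out.ndim == 0 else out


def shift_half_activation(channel: ChannelKinetics, delta: float) -> ChannelKinetics:
    """A copy of ``channel`` whose curves equal the originals at (v - delta).

    Shifts compose additively; a negative delta moves activation toward
    hyperpolarized potentials (higher activation at any fixed voltage for
    an activation gate).
    """
    if not channel.gates:
        raise ValueError("channel has no voltage-dependent gate")
    return replace(channel, v_half_shift=channel.v_half_shift + delta)


@dataclass
class CalciumPool:
    """Single sub-membrane calcium shell with first-order extrusion."""

    concentration: float = CA_RESTING  # mM
    resting_concentration: float = CA_RESTING
    decay_time_constant: float = CA_DECAY_TAU  # ms
    influx_scale: float = CA_INFLUX_SCALE  # mM.cm^2/(ms.mA)

    def __post_init__(self) -> None:
        if self.concentration < self.resting_concentration:
            raise ValueError("concentration below resting level")


def update_calcium(pool: CalciumPool, i_ca: float, dt: float) -> CalciumPool:
    """Advance the pool one explicit step under calcium current ``i_ca``.

    ``i_ca`` is the inward calcium current density in mA/cm²; its magnitude
    drives influx.  The concentration is floored at the resting level.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    c = pool.concentration + dt * (
        pool.influx_scale * abs(i_ca)
        - (pool.concentration - pool.resting_concentration) / pool.decay_time_constant)
    return replace(pool, concentration=max(c, pool.resting_concentration))


def hcn_split(total_density: float) -> tuple[float, float]:
    """Split a total HCN density into (HCN1, HCN2) as 2/3 : 1/3.

    The parts sum to the input exactly.
    """
    if total_density < 0:
        raise ValueError("density must be non-negative")
    h1 = HCN1_FRACTION * total_density
    return h1, total_density - h1


def export_channel_config() -> dict:
    """Declarative summary of the channel library (for the shipped config)."""
    out: dict = {"temperature_C": TEMPERATURE_C, "q10": Q10,
                 "reversal_potentials_mV": {"Na": E_NA, "K": E_K,
                                            "H": E_H, "Ca": E_CA},
                 "calcium_pool": {"resting_mM": CA_RESTING,
                                  "decay_tau_ms": CA_DECAY_TAU,
                                  "shell_depth_um": CA_SHELL_DEPTH},
                 "bk": {"vhalf_ref_mV": BK_VH_REF, "ca_ref_mM": BK_CA_REF,
                        "shift_mV_per_decade": BK_SHIFT_PER_DECADE,
                        "slope_mV": BK_SLOPE, "tau_ms": BK_TAU},
                 "channels": {}}
    for name, ch in CHANNELS.items():
        out["channels"][name] = {
            "reversal_mV": ch.reversal_potential,
            "temperature_factor": round(ch.temperature_factor, 6),
            "gates": [{"label": g.label, "exponent": g.exponent,
                       "calcium_dependent": g.calcium_dependent}
                      for g in ch.gates],
        }
    return out
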