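"""In-silico neuromodulation experiments.

The PKC-activation hypothesis is modelled as a fixed set of channel
modulations: HCN1 conductance reduced to 42.5%, M-type potassium to 76%,
BK to 50%, and the persistent-sodium half-activation shifted by -2 mV.
This module applies such modulation sets to a membrane model, screens
single-channel up/down modulations, and runs the 2^4 subset-necessity
analysis over the four PKC-linked modulations.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .distribution import CHANNEL_INDEX, MembraneModel
from .engine import DEFAULT_DT, run_fi_protocol
from .ephys_features import ap_voltage_threshold, fi_features

#: the four PKC-linked channel modulations
PKC_SCALE_FACTORS = {"HCN1": 0.425, "K_M": 0.76, "K_BK": 0.50}
PKC_V_HALF_SHIFTS = {"Na_P": -2.0}

#: a proper subset "fails" if it reaches less than this fraction of the
#: full set's slope increase or of its rheobase decrease
NECESSITY_FRACTION = 0.80


@dataclass(frozen=True)
class ModulationSet:
    """Per-channel conductance scale factors and half-activation shifts."""

    scale_factors: dict = field(default_factory=dict)   # channel -> factor
    v_half_shifts: dict = field(default_factory=dict)   # channel -> mV
    label: str = ""

    def __post_init__(self) -> None:
        if any(f <= 0 for f in self.scale_factors.values()):
            raise ValueError("scale factors must be positive")

    @property
    def channels(self) -> set:
        return set(self.scale_factors) | set(self.v_half_shifts)


def pkc_modulation() -> ModulationSet:
    """The full four-component PKC modulation set."""
    return ModulationSet(scale_factors=dict(PKC_SCALE_FACTORS),
                         v_half_shifts=dict(PKC_V_HALF_SHIFTS), label="PKC")


def apply_modulation(model: MembraneModel, mset: ModulationSet) -> MembraneModel:
    """Return a modulated copy of ``model``; the original is untouched.

    Conductance factors multiply the channel's density everywhere it is
    expressed (an HCN1 factor touches only the HCN1 share of the HCN
    split); half-activation shifts add to the channel's V1/2 shift.
    """
    for name in mset.channels:
        if name not in CHANNEL_INDEX:
            raise ValueError(f"unknown channel {name!r} in modulation set")
    out = model.copy(label=f"{model.label}+{mset.label}" if mset.label else model.label)
    for name, f in mset.scale_factors.items():
        out.scale_channel(name, f)
    for name, dv in mset.v_half_shifts.items():
        out.shift_channel(name, dv)
    return out


@dataclass
class ScreenRow:
    label: str
    rheobase: float       # pA
    fi_slope: float       # Hz/nA
    rheobase_ratio: float
    slope_ratio: float
    threshold: float | None = None  # mV
    necessity_failed: bool | None = None


@dataclass
class ScreenResult:
    """Tabulated modulation screen, always containing the control row."""

    rows: list[ScreenRow]

    def __getitem__(self, label: str) -> ScreenRow:
        for r in self.rows:
            if r.label == label:
                return r
        raise KeyError(label)

    @property
    def control(self) -> ScreenRow:
        return self["control"]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.rows])


def _fi_sweep_features(model: MembraneModel, amplitudes, dt: float,
                       with_threshold: bool = False):
    ts = run_fi_protocol(model, dt=dt, amplitudes=amplitudes)
    fit = fi_features(ts)
    thr = None
    if with_threshold:
        for tr in ts:
            if fit.counts[float(tr.stimulus_amplitude)] > 0:
                thr = ap_voltage_threshold(tr)
                break
    return fit, thr


def default_amplitude_grid(max_amplitude: float = 600.0,
                           increment: float = 50.0) -> np.ndarray:
    return np.arange(0.0, max_amplitude + 0.5 * increment, increment)


def screen_single_modulations(model: MembraneModel,
                              channels: list[str] | None = None,
                              factors=(0.5, 0.75, 1.25, 1.5),
                              amplitudes=None, dt: float = DEFAULT_DT,
                              with_threshold: bool = False) -> ScreenResult:
    """Screen one-channel density up/down modulations against control.

    For each (channel, factor) pair the F-I protocol is run and rheobase /
    F-I slope are tabulated as ratios to the unmodulated control.
    """
    if channels is None:
        channels = [n for n, i in CHANNEL_INDEX.items() if model.G[i].sum() > 0]
    if amplitudes is None:
        amplitudes = default_amplitude_grid()
    ctrl_fit, ctrl_thr = _fi_sweep_features(model, amplitudes, dt, with_threshold)
    rows = [ScreenRow("control", ctrl_fit.rheobase, ctrl_fit.slope,
                      1.0, 1.0, ctrl_thr)]
    for name in channels:
        for f in factors:
            mset = ModulationSet(scale_factors={name: f}, label=f"{name}x{f:g}")
            m = apply_modulation(model, mset)
            fit, thr = _fi_sweep_features(m, amplitudes, dt, with_threshold)
            rows.append(ScreenRow(mset.label, fit.rheobase, fit.slope,
                                  fit.rheobase / ctrl_fit.rheobase,
                                  fit.slope / ctrl_fit.slope, thr))
    return ScreenResult(rows)


def _subset_mset(names: tuple[str, ...]) -> ModulationSet:
    scale = {n: PKC_SCALE_FACTORS[n] for n in names if n in PKC_SCALE_FACTORS}
    shift = {n: PKC_V_HALF_SHIFTS[n] for n in names if n in PKC_V_HALF_SHIFTS}
    label = "+".join(names) if names else "control"
    return ModulationSet(scale_factors=scale, v_half_shifts=shift, label=label)


def pkc_subset_analysis(model: MembraneModel, amplitudes=None,
                        dt: float = DEFAULT_DT) -> ScreenResult:
    """Run all 16 subsets of the four PKC modulations.

    The full-set row carries the headline slope and rheobase ratios; every
    proper subset gets a necessity flag marking whether it fails the joint
    criterion (reaching at least 80% of the full set's slope increase and
    80% of its rheobase decrease).
    """
    if amplitudes is None:
        amplitudes = default_amplitude_grid()
    components = ("HCN1", "K_M", "K_BK", "Na_P")
    fits = {}
    for r in range(len(components) + 1):
        for names in itertools.combinations(components, r):
            mset = _subset_mset(names)
            m = apply_modulation(model, mset) if names else model
            fits[names] = (mset.label, _fi_sweep_features(m, amplitudes, dt)[0])
    _, ctrl = fits[()]
    _, full = fits[components]
    full_slope_gain = full.slope / ctrl.slope - 1.0
    full_rheo_drop = 1.0 - full.rheobase / ctrl.rheobase
    rows = []
    for names, (label, fit) in fits.items():
        sr = fit.slope / ctrl.slope
        rr = fit.rheobase / ctrl.rheobase
        if names and names != components:
            failed = ((sr - 1.0) < NECESSITY_FRACTION * full_slope_gain
                      or (1.0 - rr) < NECESSITY_FRACTION * full_rheo_drop)
        else:
            failed = None
        rows.append(ScreenRow(label, fit.rheobase, fit.slope, rr, sr,
                              necessity_failed=failed))
    return ScreenResult(rows)


def single_modulation_ranking(result: ScreenResult) -> list[str]:
    """Single-component PKC modulations ordered by effect size.

    The effect size of a single modulation is its fractional rheobase
    reduction (1 - rheobase_ratio), the dominant and robustly measurable
    single-channel effect on excitability; fitted-slope ratios of single
    modulations are strongly quantized by the amplitude grid and are not
    part of the metric.
    """
    singles = [r for r in result.rows
               if r.label in ("HCN1", "K_M", "K_BK", "Na_P")]
    singles.sort(key=lambda r: 1.0 - r.rheobase_ratio)
    return [r.label for r in singles]


def threshold_invariance_check(model: MembraneModel, mset: ModulationSet,
                               amplitudes=None,
                               dt: float = DEFAULT_DT) -> tuple[float, float]:
    """AP voltage threshold at rheobase for control vs modulated model.

    The threshold is measured on the first spike of the lowest
    suprathreshold amplitude; both models must fire somewhere on the grid.
    """
    if amplitudes is None:
        amplitudes = default_amplitude_grid()
    out = []
    for m in (model, apply_modulation(model, mset)):
        _, thr = _fi_sweep_features(m, amplitudes, dt, with_threshold=True)
        if thr is None:
            raise ValueError(f"model {m.label!r} fired no spike on the tested grid")
        out.append(thr)
    return tuple(out)
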