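"""Synthetic paired cohorts and trace fixtures.

No raw per-cell recordings from the underlying study were ever published -
only group means and SEMs.  This module generates (a) paired
control/treatment cohorts of per-cell excitability features with the same
statistical structure the paired comparisons assume, and (b) piecewise-
analytic current-clamp trace families with known ground-truth features, so
the feature-extraction and statistics stages are fully testable end to end.

Between-cell variation is log-normal (features are positive and
right-skewed); the treatment effect is multiplicative with an optional
linear age dependence; measurement noise is additive Gaussian in both
arms.  Default specs split the tabulated group variance 80% biological /
20% measurement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .engine import Trace, TraceSet

log = logging.getLogger(__name__)

AGE_RANGE = (11.0, 27.0)  # postnatal days
BIOLOGICAL_VARIANCE_FRACTION = 0.8

#: named age-effect scenario reproducing a negative effect-vs-age trend of
#: the input-resistance effect
AGE_SCENARIOS = {"rin_age_negative": {"input_resistance": -0.03}}


@dataclass
class FeatureSpec:
    control_mean: float
    effect: float = 1.0          # multiplicative treatment effect
    dispersion_cv: float = 0.3   # between-cell coefficient of variation
    noise_sd: float = 0.0        # additive measurement noise
    control_sem: float | None = None  # tabulated SEM, for consistency checks


@dataclass
class CohortSpec:
    features: dict[str, FeatureSpec]
    n_cells: int = 10
    age_range: tuple[float, float] = AGE_RANGE
    age_effect_slope: dict[str, float] = field(default_factory=dict)  # per day
    seed: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        if self.n_cells < 3:
            raise ValueError("n_cells must be at least 3")
        for name, f in self.features.items():
            if f.control_mean <= 0:
                raise ValueError(f"{name}: control mean must be positive")
            if f.control_sem is not None:
                implied = f.control_mean * f.dispersion_cv / np.sqrt(self.n_cells)
                if not 0.3 <= implied / f.control_sem <= 3.0:
                    log.warning("%s: dispersion CV %.3g implies SEM %.3g, "
                                "tabulated SEM is %.3g", name,
                                f.dispersion_cv, implied, f.control_sem)


@dataclass
class PairedCohort:
    """Per-cell paired features: one row per cell, both arms side by side."""

    table: pd.DataFrame  # columns: cell, age, control_<f>, treatment_<f>
    spec: CohortSpec

    @property
    def n(self) -> int:
        return len(self.table)

    def arm(self, which: str) -> pd.DataFrame:
        cols = [c for c in self.table.columns if c.startswith(f"{which}_")]
        return self.table[cols].rename(columns=lambda c: c[len(which) + 1:])


def generate_paired_cohort(spec: CohortSpec) -> PairedCohort:
    """Draw a paired cohort; fully reproducible from ``spec.seed``.

    Baselines are log-normal around the control means with the spec's
    dispersion; treatment values are baseline x effect x (1 + age-slope x
    (age - mean age)); both arms get additive measurement noise.  Specs
    that produce negative feature values at more than 1% rate are rejected.
    """
    rng = np.random.default_rng(spec.seed)
    ages = rng.uniform(*spec.age_range, size=spec.n_cells)
    mean_age = float(np.mean(spec.age_range))
    data = {"cell": np.arange(spec.n_cells), "age": ages}
    n_bad = 0
    n_tot = 0
    for name, f in spec.features.items():
        sigma2 = np.log1p(f.dispersion_cv ** 2)
        mu = np.log(f.control_mean) - sigma2 / 2.0
        base = rng.lognormal(mu, np.sqrt(sigma2), size=spec.n_cells)
        slope = spec.age_effect_slope.get(name, 0.0)
        eff = f.effect * (1.0 + slope * (ages - mean_age))
        ctrl = base + rng.normal(0.0, f.noise_sd, spec.n_cells)
        trt = base * eff + rng.normal(0.0, f.noise_sd, spec.n_cells)
        n_bad += int(np.sum(ctrl <= 0) + np.sum(trt <= 0))
        n_tot += 2 * spec.n_cells
        # physical features are positive: redraw the measurement noise of
        # any non-positive value (the underlying rate is guarded below)
        for arr, mean_arr in ((ctrl, base), (trt, base * eff)):
            for _ in range(100):
                bad = arr <= 0
                if not bad.any():
                    break
                arr[bad] = mean_arr[bad] + rng.normal(0.0, f.noise_sd,
                                                      int(bad.sum()))
            np.clip(arr, 1e-6, None, out=arr)
        data[f"control_{name}"] = ctrl
        data[f"treatment_{name}"] = trt
    if n_bad / n_tot > 0.01:
        raise ValueError(
            f"spec produced {n_bad}/{n_tot} non-positive feature values; "
            "reduce noise or dispersion")
    return PairedCohort(pd.DataFrame(data), spec)


def load_cohort_presets() -> dict:
    with resources.files("l5sim.config").joinpath("cohorts.yaml").open() as fh:
        return yaml.safe_load(fh)


def spec_from_preset(column: str, n_cells: int | None = None, seed: int = 0,
                     age_scenario: str | None = None) -> CohortSpec:
    """Build a CohortSpec from one tabulated comparison column.

    The tabulated SEM fixes the total between-cell spread (CV =
    SEM*sqrt(n)/mean); 80% of the variance is assigned to biology and 20%
    to measurement noise.  The multiplicative effect is the ratio of group
    means.
    """
    presets = load_cohort_presets()
    if column not in presets["columns"]:
        raise KeyError(f"unknown preset {column!r}; have {list(presets['columns'])}")
    col = presets["columns"][column]
    n_tab = int(col["n"])
    feats = {}
    for name, v in col.items():
        if name == "n":
            continue
        c_mean, c_sem = (float(x) for x in v["control"])
        t_mean, _ = (float(x) for x in v["treatment"])
        cv_total = c_sem * np.sqrt(n_tab) / c_mean
        feats[name] = FeatureSpec(
            control_mean=c_mean,
            effect=t_mean / c_mean,
            dispersion_cv=cv_total * np.sqrt(BIOLOGICAL_VARIANCE_FRACTION),
            noise_sd=c_mean * cv_total * np.sqrt(1 - BIOLOGICAL_VARIANCE_FRACTION),
            control_sem=c_sem)
    slopes = AGE_SCENARIOS.get(age_scenario, {}) if age_scenario else {}
    return CohortSpec(features=feats, n_cells=n_cells or n_tab,
                      age_effect_slope=dict(slopes), seed=seed, label=column)


# ---------------------------------------------------------------------------
# trace fixtures


def _spike_waveform(dt: float) -> np.ndarray:
    """Stereotyped 3-ms action potential shape (mV, relative to baseline)."""
    t = np.arange(0.0, 3.0, dt)
    rise = np.exp(-((t - 1.0) / 0.18) ** 2)     # sharp upstroke/peak at 1 ms
    dip = -0.12 * np.exp(-((t - 1.9) / 0.35) ** 2)
    return 95.0 * rise + 95.0 * dip


def generate_trace_fixture(rheobase: float = 125.0, fi_slope: float = 80.0,
                           input_resistance: float = 80.0,
                           ahp_amplitude: float = 5.0,
                           noise_sd: float = 0.0, seed: int = 0,
                           amplitudes=None, duration: float = 1000.0,
                           pre_ms: float = 100.0, post_ms: float = 1000.0,
                           rest: float = -70.0, dt: float = 0.1,
                           membrane_tau: float = 20.0) -> TraceSet:
    """Piecewise-analytic current-clamp family with known ground truth.

    Subthreshold traces are single-exponential RC responses consistent with
    ``input_resistance``; suprathreshold traces carry evenly spaced
    stereotyped spikes at the rate implied by the target F-I line (counts
    are integers, so recovered rheobase/slope are quantized by the
    amplitude grid); spiking traces end in an alpha-shaped afterhyper-
    polarization of exactly ``ahp_amplitude`` depth.  Gaussian noise of
    ``noise_sd`` mV is added throughout.
    """
    if amplitudes is None:
        amplitudes = np.arange(-50.0, 400.0 + 1.0, 50.0)
    if not (amplitudes.min() <= rheobase <= amplitudes.max()):
        raise ValueError("rheobase target outside the amplitude grid")
    rng = np.random.default_rng(seed)
    n_pre = int(round(pre_ms / dt))
    n_stim = int(round(duration / dt))
    n_post = int(round(post_ms / dt))
    t_stim = np.arange(1, n_stim + 1) * dt
    t_post = np.arange(1, n_post + 1) * dt
    spike = _spike_waveform(dt)
    traces = []
    for amp in amplitudes:
        amp = float(amp)
        dv = amp * input_resistance * 1e-3  # pA * MΩ -> mV
        rate = max(fi_slope * (amp - rheobase) * 1e-3, 0.0)  # Hz
        n_spikes = int(round(rate * duration / 1000.0))
        v = np.empty(n_pre + n_stim + n_post)
        v[:n_pre] = rest
        # subthreshold plateau saturates near threshold once firing starts
        plateau = rest + dv if n_spikes == 0 else min(rest + dv, -52.0)
        v_stim = plateau + (rest - plateau) * np.exp(-t_stim / membrane_tau)
        if n_spikes > 0:
            base = v_stim.copy()
            period = duration / n_spikes
            for k in range(n_spikes):
                i0 = int(round((k * period + 0.35 * period) / dt))
                i1 = min(i0 + len(spike), n_stim)
                v_stim[i0:i1] = base[i0:i1] + spike[:i1 - i0]
        v[n_pre:n_pre + n_stim] = v_stim
        v_end = v_stim[-1] if n_spikes == 0 else plateau
        relax = rest + (v_end - rest) * np.exp(-t_post / membrane_tau)
        if n_spikes > 0 and ahp_amplitude > 0:
            tau_ahp = 120.0
            x = t_post / tau_ahp
            relax = relax - ahp_amplitude * x * np.exp(1.0 - x)
        v[n_pre + n_stim:] = relax
        if noise_sd > 0:
            v = v + rng.normal(0.0, noise_sd, len(v))
        traces.append(Trace(values=v, sampling_interval=dt,
                            stimulus_amplitude=amp, mode="current_clamp",
                            t_stim_on=pre_ms, t_stim_off=pre_ms + duration,
                            metadata={"synthetic": True, "seed": seed}))
    return TraceSet(traces)


def cohort_traceset(cell_features: dict, noise_sd: float = 0.2,
                    seed: int = 0, **kwargs) -> TraceSet:
    """Trace family for one synthetic cell given its feature dict."""
    return generate_trace_fixture(
        rheobase=cell_features.get("rheobase", 125.0),
        fi_slope=cell_features.get("fi_slope", 80.0),
        input_resistance=cell_features.get("input_resistance", 80.0),
        ahp_amplitude=cell_features.get("ahp_amplitude", 5.0),
        noise_sd=noise_sd, seed=seed, **kwargs)
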