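"""Excitability-feature extraction from current-clamp trace families.

Implements the conventional definitions: spikes are upward threshold
crossings; the F-I relation is fit by least squares over its first linear
portion, with the rheobase taken as the abscissa intercept of that fit;
input resistance is the slope of the steady-state I-V relation around
rest; the AHP amplitude is the depth of the post-train undershoot below
the settled post-stimulus potential; and the AP voltage threshold is the
membrane potential at the first peak of the third voltage derivative
before the spike peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .engine import Trace, TraceSet

SPIKE_THRESHOLD_MV = -10.0
SPIKE_REFRACTORY_MS = 2.0

#: first-linear-portion selection parameters
FI_MIN_TRAIN_SPIKES = 3
FI_MIN_POINTS = 2
FI_MAX_POINTS = 5
FI_R2_MIN = 0.98
FI_INCREMENTAL_SLOPE_FRACTION = 0.5

#: AHP measurement windows (ms)
AHP_SEARCH_MS = 500.0
AHP_STEADY_MS = 100.0
AHP_MIN_POST_MS = 600.0

#: third-derivative smoothing: local polynomial of this order over ~1 ms
THRESHOLD_SAVGOL_ORDER = 4
THRESHOLD_WINDOW_MS = 1.0
THRESHOLD_SEARCH_MS = 10.0


@dataclass
class FeatureSet:
    """Per-cell excitability metrics."""

    rheobase: float | None = None          # pA
    fi_slope: float | None = None          # Hz/nA
    input_resistance: float | None = None  # MΩ
    ahp_amplitude: float | None = None     # mV
    ap_threshold: float | None = None      # mV
    spike_counts: dict = field(default_factory=dict)  # pA -> count
    fit_points_used: list = field(default_factory=list)  # pA

    def as_dict(self) -> dict:
        return {"rheobase_pA": self.rheobase, "fi_slope_Hz_per_nA": self.fi_slope,
                "input_resistance_MOhm": self.input_resistance,
                "ahp_amplitude_mV": self.ahp_amplitude,
                "ap_threshold_mV": self.ap_threshold}


def detect_spikes(trace: Trace, threshold: float = SPIKE_THRESHOLD_MV,
                  refractory: float = SPIKE_REFRACTORY_MS) -> np.ndarray:
    """Spike times (ms): upward crossings of ``threshold``, 2 ms refractory."""
    if trace.mode != "current_clamp":
        raise ValueError("spike detection requires a current-clamp trace")
    v = np.asarray(trace.values)
    up = np.flatnonzero((v[1:] >= threshold) & (v[:-1] < threshold)) + 1
    times = up * trace.sampling_interval
    if len(times) == 0:
        return times
    kept = [times[0]]
    for t in times[1:]:
        if t - kept[-1] >= refractory:
            kept.append(t)
    return np.asarray(kept)


def spike_count(trace: Trace, window: tuple[float, float] | None = None) -> int:
    """Number of spikes, optionally restricted to a (t0, t1) window in ms."""
    times = detect_spikes(trace)
    if window is None:
        if trace.t_stim_on is not None:
            window = (trace.t_stim_on, trace.t_stim_off)
        else:
            return len(times)
    t0, t1 = window
    return int(np.sum((times >= t0) & (times <= t1)))


@dataclass
class FIFit:
    rheobase: float            # pA
    slope: float               # Hz/nA
    amplitudes_used: list      # pA
    rates: dict                # pA -> Hz
    counts: dict               # pA -> spike count


def _linfit(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Least-squares slope, intercept and R²."""
    a, b = np.polyfit(x, y, 1)
    yhat = a * x + b
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return float(a), float(b), r2


def fi_features(traceset: TraceSet) -> FIFit:
    """Rheobase (pA) and gain (Hz/nA) from the first linear F-I portion.

    Points enter the fit starting at the first suprathreshold amplitude and
    extend (2-5 points) while the fit stays linear (R² >= 0.98) and the
    incremental slope does not collapse below half the initial pairwise
    slope; the rheobase is the fit's abscissa intercept and may fall
    between tested amplitudes.
    """
    order = np.argsort(traceset.amplitudes)
    amps = traceset.amplitudes[order]
    durations = []
    counts = []
    for k in order:
        tr = traceset[k]
        counts.append(spike_count(tr))
        durations.append((tr.t_stim_off or tr.time[-1]) - (tr.t_stim_on or 0.0))
    counts = np.asarray(counts)
    rates = counts / (np.asarray(durations) / 1000.0)  # Hz
    # a step-onset transient (1-2 spikes) is not a sustained rate: the
    # linear portion starts at the first amplitude with a spike train
    supra = np.flatnonzero(counts >= FI_MIN_TRAIN_SPIKES)
    if len(supra) == 0:
        supra = np.flatnonzero(counts > 0)
    if len(supra) < 1 or supra[0] + FI_MIN_POINTS > len(counts):
        raise ValueError("need at least two suprathreshold amplitudes for the F-I fit")
    i0 = supra[0]
    # skip any leading plateau where the rate is not yet rising
    while i0 + FI_MIN_POINTS < len(counts) and counts[i0 + 1] <= counts[i0]:
        i0 += 1
    # the linear portion requires locally consistent increments: advance
    # past onset curvature where successive rate increments disagree by
    # more than 2.5x (both concave-up onsets and band-edge jumps)
    while i0 + 2 < len(counts):
        inc1 = max(float(counts[i0 + 1] - counts[i0]), 0.0)
        inc2 = max(float(counts[i0 + 2] - counts[i0 + 1]), 0.0)
        lo, hi = min(inc1, inc2), max(inc1, inc2)
        if lo >= 1.0 and hi <= 2.5 * lo:
            break
        i0 += 1
    xs = amps[i0:] * 1e-3  # nA
    ys = rates[i0:]
    if len(xs) < FI_MIN_POINTS:
        raise ValueError("not enough F-I points above rheobase")
    n_sel = FI_MIN_POINTS
    init_slope = (ys[1] - ys[0]) / (xs[1] - xs[0])
    while n_sel < min(FI_MAX_POINTS, len(xs)):
        nxt = n_sel  # candidate index of the next point
        inc_slope = (ys[nxt] - ys[nxt - 1]) / (xs[nxt] - xs[nxt - 1])
        _, _, r2 = _linfit(xs[:nxt + 1], ys[:nxt + 1])
        if r2 < FI_R2_MIN or inc_slope < FI_INCREMENTAL_SLOPE_FRACTION * init_slope:
            break
        n_sel += 1
    a, b, _ = _linfit(xs[:n_sel], ys[:n_sel])
    if a <= 0:
        raise ValueError("non-positive F-I slope; cannot define a rheobase")
    rheobase_pA = -b / a * 1e3
    used = list(np.round(xs[:n_sel] * 1e3, 6))
    return FIFit(rheobase=float(rheobase_pA), slope=float(a),
                 amplitudes_used=used,
                 rates={float(A): float(r) for A, r in zip(amps, rates)},
                 counts={float(A): int(c) for A, c in zip(amps, counts)})


def input_resistance(traces: TraceSet | list[Trace],
                     steady_window_ms: float = 200.0) -> float:
    """Input resistance (MΩ) from the I-V slope of subthreshold steps.

    Uses the steady-state voltage (mean over the last ``steady_window_ms``
    of each step) of the -50, 0 and +50 pA traces; any spike in the inputs
    is an error.
    """
    trs = list(traces)
    if len(trs) < 2:
        raise ValueError("need at least two amplitudes for the I-V fit")
    amps, vss = [], []
    for tr in trs:
        if len(detect_spikes(tr)) > 0:
            raise ValueError(
                f"spike detected in the {tr.stimulus_amplitude:g} pA trace; "
                "input resistance requires subthreshold steps")
        t1 = tr.t_stim_off if tr.t_stim_off is not None else tr.time[-1]
        sel = (tr.time > t1 - steady_window_ms) & (tr.time <= t1)
        amps.append(tr.stimulus_amplitude)
        vss.append(float(np.mean(tr.values[sel])))
    a, _, _ = _linfit(np.asarray(amps), np.asarray(vss))  # mV per pA
    r = a * 1e3  # MΩ
    if r <= 0:
        raise ValueError("non-positive input resistance")
    return r


def ahp_amplitude(trace: Trace, search_ms: float = AHP_SEARCH_MS,
                  steady_ms: float = AHP_STEADY_MS) -> float:
    """Post-train AHP depth (mV, >= 0).

    Difference between the settled post-stimulus potential (mean of the
    final ``steady_ms``) and the deepest hyperpolarization within
    ``search_ms`` after stimulus offset; 0 when there is no undershoot.
    """
    if trace.t_stim_off is None:
        raise ValueError("trace has no stimulus offset")
    t = trace.time
    post = t > trace.t_stim_off
    if not np.any(post) or (t[-1] - trace.t_stim_off) < AHP_MIN_POST_MS:
        raise ValueError("need post-stimulus recording after the stimulus offset")
    steady = float(np.mean(trace.values[t > t[-1] - steady_ms]))
    window = post & (t <= trace.t_stim_off + search_ms)
    # smooth over ~2 ms before the trough search so measurement noise does
    # not bias the minimum downward
    seg = np.asarray(trace.values[window], dtype=float)
    k = max(1, int(round(2.0 / trace.sampling_interval)))
    if k > 1 and len(seg) > k:
        seg = np.convolve(seg, np.ones(k) / k, mode="valid")
    trough = float(np.min(seg))
    return max(steady - trough, 0.0)


def ap_voltage_threshold(trace: Trace, first_spike: float | None = None) -> float:
    """AP voltage threshold (mV): V at the first peak of d³V/dt³.

    The third derivative is estimated by a quartic local-polynomial
    (Savitzky-Golay) filter over a ~1 ms window; the first local maximum in
    the few ms preceding the first spike peak defines the threshold time.
    """
    dt = trace.sampling_interval
    if dt > 0.1 + 1e-12:
        raise ValueError("sampling interval > 0.1 ms: derivative unreliable")
    if first_spike is None:
        spikes = detect_spikes(trace)
        if len(spikes) == 0:
            raise ValueError("no spike in trace")
        first_spike = float(spikes[0])
    v = np.asarray(trace.values, dtype=float)
    t = trace.time
    # spike peak: maximum within 2 ms after the threshold crossing
    sel = (t >= first_spike) & (t <= first_spike + 2.0)
    peak_idx = np.flatnonzero(sel)[np.argmax(v[sel])]
    win = max(THRESHOLD_SAVGOL_ORDER + 2, int(round(THRESHOLD_WINDOW_MS / dt)) | 1)
    if win % 2 == 0:
        win += 1
    d3 = savgol_filter(v, window_length=win, polyorder=THRESHOLD_SAVGOL_ORDER,
                       deriv=3, delta=dt)
    start = max(0, peak_idx - int(round(THRESHOLD_SEARCH_MS / dt)))
    seg = d3[start:peak_idx + 1]
    if len(seg) < 3:
        raise ValueError("too few samples before the spike peak")
    floor = 0.05 * float(np.max(seg))
    for i in range(1, len(seg) - 1):
        if seg[i] >= seg[i - 1] and seg[i] > seg[i + 1] and seg[i] > floor:
            return float(v[start + i])
    # monotone rise up to the peak: fall back to the maximum
    return float(v[start + int(np.argmax(seg))])


def extract_features(fi_traces: TraceSet,
                     iv_traces: TraceSet | None = None,
                     ahp_trace: Trace | None = None,
                     threshold_trace: Trace | None = None) -> FeatureSet:
    """Assemble a full :class:`FeatureSet` from protocol outputs."""
    fit = fi_features(fi_traces)
    fs = FeatureSet(rheobase=fit.rheobase, fi_slope=fit.slope,
                    spike_counts=fit.counts, fit_points_used=fit.amplitudes_used)
    if iv_traces is not None:
        fs.input_resistance = input_resistance(iv_traces)
    if ahp_trace is not None:
        fs.ahp_amplitude = ahp_amplitude(ahp_trace)
    if threshold_trace is not None:
        fs.ap_threshold = ap_voltage_threshold(threshold_trace)
    return fs


def traceset_from_table(table: pd.DataFrame, mode: str = "current_clamp",
                        t_stim_on: float | None = None,
                        t_stim_off: float | None = None) -> TraceSet:
    """Build a TraceSet from a delimited table (time_ms, value, amplitude)."""
    traces = []
    for amp, grp in table.groupby("amplitude"):
        tt = grp["time_ms"].to_numpy()
        si = float(np.median(np.diff(tt)))
        traces.append(Trace(values=grp["value"].to_numpy(), sampling_interval=si,
                            stimulus_amplitude=float(amp), mode=mode,
                            t_stim_on=t_stim_on, t_stim_off=t_stim_off))
    return TraceSet(traces)
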