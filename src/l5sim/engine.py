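"""Implicit cable-equation integrator and stimulation protocols.

The membrane equation per compartment,

    C dV/dt = -(g_leak (V - E_leak) + sum_c g_c(t) (V - E_c))
              + sum_axial g_ij (V_j - V_i) + I_inj,

is advanced with a staggered scheme: gating variables move one step by
exponential (Rush-Larsen) integration at the current voltages, then the
voltage step is taken fully implicitly (backward Euler) with the updated
conductances, solving the tree-structured linear system by Hines
elimination (O(N), unconditionally stable for the passive dynamics).
Voltage clamp is an ideal (zero series resistance) somatic clamp,
implemented as a stiff penalty conductance at the soma.

Engine units: mV, ms, nA, µS, nF; protocol amplitudes are given in the
conventional pA (current clamp) and mV (voltage clamp).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from . import channels as ch
from .distribution import CHANNEL_INDEX, MembraneModel

DEFAULT_DT = 0.025        # ms
DEFAULT_RECORD_DT = 0.05  # ms
SETTLE_MS = 2000.0        # pre-protocol settling at 0 pA
_GCLAMP = 1e6             # µS, ideal-clamp penalty conductance

# state-row layout of the gating matrix S
_NA_M, _NA_H, _NAX_M, _NAX_H, _NAP_M, _KV_N, _KM_N, _KAP_N, _KAP_L, \
    _KAD_N, _KAD_L, _BK_M, _CA_M, _CA_H, _IT2_M, _IT2_H, _H1_M, _H2_M, _CAI \
    = range(19)
N_STATES = 19

# channel rows of the conductance matrix G (see distribution.CHANNEL_INDEX)
_iNA, _iNAX, _iNAP, _iKV, _iKM, _iKAP, _iKAD, _iKBK, _iCA, _iIT2, _iH1, _iH2 \
    = (CHANNEL_INDEX[n] for n in ch.CHANNEL_NAMES)

#: per-channel Q10 rate multipliers, in CHANNEL_INDEX order
TADJ = np.array([ch.temperature_factor(n) for n in ch.CHANNEL_NAMES])


@njit(cache=True)
def _gexp(x: float, inf: float, tau: float, dtq: float) -> float:
    """One Rush-Larsen step: relax x toward inf with rate dtq/tau."""
    return inf + (x - inf) * np.exp(-dtq / tau)


@njit(cache=True)
def _run(v, S, parent, g_ax, c_nF, g_leak, area, G, shifts, tadj,
         e_leak, dt, n_steps, inj_site, inj_nA, clamp, v_cmd,
         record_every, rec_site, out):
    """Advance the model ``n_steps``; mutates v and S, fills ``out``.

    Returns (status, step): status 0 on success, otherwise 1 + index of the
    first compartment whose voltage became non-finite.
    """
    n = v.shape[0]
    d = np.empty(n)
    rhs = np.empty(n)
    e_na, e_k, e_h, e_ca = ch.E_NA, ch.E_K, ch.E_H, ch.E_CA
    ca_rest, ca_tau, ca_scale = ch.CA_RESTING, ch.CA_DECAY_TAU, ch.CA_INFLUX_SCALE
    k_out = 0
    for step in range(n_steps):
        for i in range(n):
            vi = v[i]
            gtot = g_leak[i]
            ge = g_leak[i] * e_leak
            if G[_iNA, i] > 0.0:
                vv = vi - shifts[_iNA]
                q = dt * tadj[_iNA]
                S[_NA_M, i] = _gexp(S[_NA_M, i], ch.na_m_inf(vv), ch.na_m_tau(vv), q)
                S[_NA_H, i] = _gexp(S[_NA_H, i], ch.na_h_inf(vv), ch.na_h_tau(vv), q)
                g = G[_iNA, i] * S[_NA_M, i] ** 3 * S[_NA_H, i]
                gtot += g
                ge += g * e_na
            if G[_iNAX, i] > 0.0:
                vv = vi - shifts[_iNAX]
                q = dt * tadj[_iNAX]
                S[_NAX_M, i] = _gexp(S[_NAX_M, i], ch.nax_m_inf(vv), ch.nax_m_tau(vv), q)
                S[_NAX_H, i] = _gexp(S[_NAX_H, i], ch.nax_h_inf(vv), ch.nax_h_tau(vv), q)
                g = G[_iNAX, i] * S[_NAX_M, i] ** 3 * S[_NAX_H, i]
                gtot += g
                ge += g * e_na
            if G[_iNAP, i] > 0.0:
                vv = vi - shifts[_iNAP]
                q = dt * tadj[_iNAP]
                S[_NAP_M, i] = _gexp(S[_NAP_M, i], ch.nap_m_inf(vv), ch.nap_m_tau(vv), q)
                g = G[_iNAP, i] * S[_NAP_M, i]
                gtot += g
                ge += g * e_na
            if G[_iKV, i] > 0.0:
                vv = vi - shifts[_iKV]
                q = dt * tadj[_iKV]
                S[_KV_N, i] = _gexp(S[_KV_N, i], ch.kv_n_inf(vv), ch.kv_n_tau(vv), q)
                g = G[_iKV, i] * S[_KV_N, i]
                gtot += g
                ge += g * e_k
            if G[_iKM, i] > 0.0:
                vv = vi - shifts[_iKM]
                q = dt * tadj[_iKM]
                S[_KM_N, i] = _gexp(S[_KM_N, i], ch.km_n_inf(vv), ch.km_n_tau(vv), q)
                g = G[_iKM, i] * S[_KM_N, i]
                gtot += g
                ge += g * e_k
            if G[_iKAP, i] > 0.0:
                vv = vi - shifts[_iKAP]
                q = dt * tadj[_iKAP]
                S[_KAP_N, i] = _gexp(S[_KAP_N, i], ch.kap_n_inf(vv), ch.kap_n_tau(vv), q)
                S[_KAP_L, i] = _gexp(S[_KAP_L, i], ch.ka_l_inf(vv), ch.ka_l_tau(vv), q)
                g = G[_iKAP, i] * S[_KAP_N, i] ** 4 * S[_KAP_L, i]
                gtot += g
                ge += g * e_k
            if G[_iKAD, i] > 0.0:
                vv = vi - shifts[_iKAD]
                q = dt * tadj[_iKAD]
                S[_KAD_N, i] = _gexp(S[_KAD_N, i], ch.kad_n_inf(vv), ch.kad_n_tau(vv), q)
                S[_KAD_L, i] = _gexp(S[_KAD_L, i], ch.ka_l_inf(vv), ch.ka_l_tau(vv), q)
                g = G[_iKAD, i] * S[_KAD_N, i] ** 4 * S[_KAD_L, i]
                gtot += g
                ge += g * e_k
            # calcium currents drive the pool; pool drives BK
            i_ca_nA = 0.0
            if G[_iCA, i] > 0.0:
                vv = vi - shifts[_iCA]
                q = dt * tadj[_iCA]
                S[_CA_M, i] = _gexp(S[_CA_M, i], ch.ca_m_inf(vv), ch.ca_m_tau(vv), q)
                S[_CA_H, i] = _gexp(S[_CA_H, i], ch.ca_h_inf(vv), ch.ca_h_tau(vv), q)
                g = G[_iCA, i] * S[_CA_M, i] ** 2 * S[_CA_H, i]
                gtot += g
                ge += g * e_ca
                i_ca_nA += g * (vi - e_ca)
            if G[_iIT2, i] > 0.0:
                vv = vi - shifts[_iIT2]
                q = dt * tadj[_iIT2]
                S[_IT2_M, i] = _gexp(S[_IT2_M, i], ch.it2_m_inf(vv), ch.it2_m_tau(vv), q)
                S[_IT2_H, i] = _gexp(S[_IT2_H, i], ch.it2_h_inf(vv), ch.it2_h_tau(vv), q)
                g = G[_iIT2, i] * S[_IT2_M, i] ** 2 * S[_IT2_H, i]
                gtot += g
                ge += g * e_ca
                i_ca_nA += g * (vi - e_ca)
            if i_ca_nA != 0.0 or S[_CAI, i] > ca_rest:
                dens = abs(i_ca_nA) * 1e-6 / area[i]  # mA/cm², inward magnitude
                cai = S[_CAI, i] + dt * (ca_scale * dens
                                         - (S[_CAI, i] - ca_rest) / ca_tau)
                S[_CAI, i] = cai if cai > ca_rest else ca_rest
            if G[_iKBK, i] > 0.0:
                vv = vi - shifts[_iKBK]
                q = dt * tadj[_iKBK]
                cai = S[_CAI, i]
                S[_BK_M, i] = _gexp(S[_BK_M, i], ch.bk_m_inf(vv, cai),
                                    ch.bk_m_tau(vv, cai), q)
                g = G[_iKBK, i] * S[_BK_M, i]
                gtot += g
                ge += g * e_k
            if G[_iH1, i] > 0.0:
                vv = vi - shifts[_iH1]
                q = dt * tadj[_iH1]
                S[_H1_M, i] = _gexp(S[_H1_M, i], ch.hcn1_m_inf(vv), ch.hcn1_m_tau(vv), q)
                g = G[_iH1, i] * S[_H1_M, i]
                gtot += g
                ge += g * e_h
            if G[_iH2, i] > 0.0:
                vv = vi - shifts[_iH2]
                q = dt * tadj[_iH2]
                S[_H2_M, i] = _gexp(S[_H2_M, i], ch.hcn2_m_inf(vv), ch.hcn2_m_tau(vv), q)
                g = G[_iH2, i] * S[_H2_M, i]
                gtot += g
                ge += g * e_h
            d[i] = c_nF[i] / dt + gtot
            rhs[i] = c_nF[i] / dt * vi + ge
        rhs[inj_site] += inj_nA
        if clamp == 1:
            d[0] += _GCLAMP
            rhs[0] += _GCLAMP * v_cmd
        # couple to parents and eliminate leaves first (parent[i] < i)
        for i in range(1, n):
            d[i] += g_ax[i]
            d[parent[i]] += g_ax[i]
        for i in range(n - 1, 0, -1):
            f = g_ax[i] / d[i]
            d[parent[i]] -= f * g_ax[i]
            rhs[parent[i]] += f * rhs[i]
        v[0] = rhs[0] / d[0]
        for i in range(1, n):
            v[i] = (rhs[i] + g_ax[i] * v[parent[i]]) / d[i]
        if (step + 1) % record_every == 0 and k_out < out.shape[0]:
            if clamp == 1:
                out[k_out] = _GCLAMP * (v_cmd - v[0])
            else:
                out[k_out] = v[rec_site]
            k_out += 1
        if (step + 1) % 400 == 0:
            for i in range(n):
                if not np.isfinite(v[i]):
                    return 1 + i, step
    return 0, n_steps


# ---------------------------------------------------------------------------
# protocol and trace containers


@dataclass(frozen=True)
class StimulusProtocol:
    """A sequence of constant steps, executed back to back."""

    mode: str  # 'current_clamp' | 'voltage_clamp'
    steps: tuple[tuple[float, float], ...]  # (amplitude pA|mV, duration ms)
    injection_site: int = 0
    holding: float = 0.0  # pA (or mV for voltage clamp)

    def __post_init__(self) -> None:
        if self.mode not in ("current_clamp", "voltage_clamp"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if any(dur <= 0 for _, dur in self.steps):
            raise ValueError("step durations must be positive")


@dataclass
class Trace:
    """Uniformly sampled voltage (mV) or clamp-current (pA) recording."""

    values: np.ndarray
    sampling_interval: float  # ms
    stimulus_amplitude: float  # pA or mV
    mode: str = "current_clamp"
    t_stim_on: float | None = None  # ms
    t_stim_off: float | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def time(self) -> np.ndarray:
        return np.arange(1, len(self.values) + 1) * self.sampling_interval

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class TraceSet:
    """An amplitude-indexed family of traces from one protocol."""

    traces: list[Trace]

    @property
    def amplitudes(self) -> np.ndarray:
        return np.array([t.stimulus_amplitude for t in self.traces])

    def __iter__(self):
        return iter(self.traces)

    def __len__(self) -> int:
        return len(self.traces)

    def __getitem__(self, k: int) -> Trace:
        return self.traces[k]

    def to_dataframe(self) -> pd.DataFrame:
        frames = []
        for tr in self.traces:
            frames.append(pd.DataFrame({
                "time_ms": tr.time, "value": tr.values,
                "amplitude": tr.stimulus_amplitude}))
        return pd.concat(frames, ignore_index=True)

    def save(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


class IntegrationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# state handling


def initial_state(model: MembraneModel) -> tuple[np.ndarray, np.ndarray]:
    """Uniform voltage with every gate at its local steady state."""
    n = model.n
    v0 = model.v_init
    v = np.full(n, v0)
    S = np.zeros((N_STATES, n))
    sh = model.v_shift
    pairs = [
        (_NA_M, _iNA, ch.na_m_inf), (_NA_H, _iNA, ch.na_h_inf),
        (_NAX_M, _iNAX, ch.nax_m_inf), (_NAX_H, _iNAX, ch.nax_h_inf),
        (_NAP_M, _iNAP, ch.nap_m_inf), (_KV_N, _iKV, ch.kv_n_inf),
        (_KM_N, _iKM, ch.km_n_inf), (_KAP_N, _iKAP, ch.kap_n_inf),
        (_KAP_L, _iKAP, ch.ka_l_inf), (_KAD_N, _iKAD, ch.kad_n_inf),
        (_KAD_L, _iKAD, ch.ka_l_inf), (_CA_M, _iCA, ch.ca_m_inf),
        (_CA_H, _iCA, ch.ca_h_inf), (_IT2_M, _iIT2, ch.it2_m_inf),
        (_IT2_H, _iIT2, ch.it2_h_inf), (_H1_M, _iH1, ch.hcn1_m_inf),
        (_H2_M, _iH2, ch.hcn2_m_inf),
    ]
    for row, chan_idx, fn in pairs:
        S[row, :] = fn(v0 - sh[chan_idx])
    S[_CAI, :] = model.ca_resting
    S[_BK_M, :] = ch.bk_m_inf(v0 - sh[CHANNEL_INDEX["K_BK"]], model.ca_resting)
    return v, S


def _kernel_call(model: MembraneModel, v, S, dt, n_steps, inj_site, inj_nA,
                 clamp, v_cmd, record_every, rec_site, out) -> None:
    status, step = _run(v, S, model.parent, model.g_ax, model.c, model.g_leak,
                        model.area, model.G, model.v_shift, TADJ,
                        model.e_leak, dt, n_steps, inj_site, inj_nA,
                        clamp, v_cmd, record_every, rec_site, out)
    if status != 0:
        comp = status - 1
        raise IntegrationError(
            f"non-finite voltage in compartment {comp} "
            f"({model.tree.compartments[comp].region}) at t = {step * dt:.3f} ms")


def steady_state(model: MembraneModel, dt: float = DEFAULT_DT,
                 settle_ms: float = SETTLE_MS) -> tuple[np.ndarray, np.ndarray]:
    """Resting state after settling at 0 pA; cached per (dt, settle)."""
    key = (round(dt, 9), round(settle_ms, 3))
    if key not in model._steady_cache:
        v, S = initial_state(model)
        n_steps = int(round(settle_ms / dt))
        out = np.empty(0)
        _kernel_call(model, v, S, dt, n_steps, 0, 0.0, 0, 0.0,
                     n_steps + 1, 0, out)
        model._steady_cache[key] = (v, S)
    v, S = model._steady_cache[key]
    return v.copy(), S.copy()


def resting_potential(model: MembraneModel, dt: float = DEFAULT_DT) -> float:
    """Somatic resting potential (mV) after full settling."""
    v, _ = steady_state(model, dt)
    return float(v[0])


# ---------------------------------------------------------------------------
# protocols


def integrate(model: MembraneModel, protocol: StimulusProtocol,
              dt: float = DEFAULT_DT, record_dt: float = DEFAULT_RECORD_DT,
              settle_ms: float = SETTLE_MS, rec_site: int = 0) -> Trace:
    """Run one protocol from the settled resting state and record the soma.

    Current-clamp traces are membrane potential in mV; voltage-clamp traces
    are the clamp current in pA.
    """
    if dt > 0.025 + 1e-12:
        # accuracy contract for production runs with active channels
        if np.any(model.G[[_iNA, _iNAX], :] > 0):
            raise ValueError("dt must be <= 0.025 ms for models with fast sodium")
    record_every = max(1, int(round(record_dt / dt)))
    clamp = 1 if protocol.mode == "voltage_clamp" else 0
    v, S = steady_state(model, dt, settle_ms)
    if clamp:
        # equilibrate under the holding command before the steps
        hold_steps = int(round(1000.0 / dt))
        _kernel_call(model, v, S, dt, hold_steps, 0, 0.0, 1, protocol.holding,
                     hold_steps + 1, rec_site, np.empty(0))
    chunks = []
    t_on = t_off = None
    t_cursor = 0.0
    for amplitude, duration in protocol.steps:
        n_steps = int(round(duration / dt))
        out = np.empty(n_steps // record_every)
        if clamp:
            _kernel_call(model, v, S, dt, n_steps, 0, 0.0, 1, amplitude,
                         record_every, rec_site, out)
            out = out * 1e3  # nA -> pA
        else:
            _kernel_call(model, v, S, dt, n_steps, protocol.injection_site,
                         amplitude * 1e-3, 0, 0.0, record_every, rec_site, out)
        if amplitude != protocol.holding and t_on is None:
            t_on, t_off = t_cursor, t_cursor + duration
        t_cursor += duration
        chunks.append(out)
    amps = [a for a, _ in protocol.steps if a != protocol.holding]
    stim_amp = amps[0] if amps else protocol.holding
    return Trace(values=np.concatenate(chunks), sampling_interval=record_dt,
                 stimulus_amplitude=stim_amp, mode=protocol.mode,
                 t_stim_on=t_on, t_stim_off=t_off,
                 metadata={"model": model.label, "dt": dt})


def run_fi_protocol(model: MembraneModel, max_amplitude: float = 600.0,
                    increment: float = 50.0, duration: float = 1000.0,
                    pre_ms: float = 50.0, post_ms: float = 0.0,
                    dt: float = DEFAULT_DT,
                    record_dt: float = DEFAULT_RECORD_DT,
                    amplitudes=None) -> TraceSet:
    """Family of 1-s rectangular current steps from 0 to ``max_amplitude``.

    The state is re-initialized (full re-equilibration) between steps,
    standing in for the long inter-step interval of the experimental
    protocol.
    """
    if increment <= 0:
        raise ValueError("increment must be positive")
    if amplitudes is None:
        amplitudes = np.arange(0.0, max_amplitude + 0.5 * increment, increment)
    traces = []
    for amp in amplitudes:
        steps = [(0.0, pre_ms)] if pre_ms > 0 else []
        steps.append((float(amp), duration))
        if post_ms > 0:
            steps.append((0.0, post_ms))
        proto = StimulusProtocol(mode="current_clamp", steps=tuple(steps))
        tr = integrate(model, proto, dt=dt, record_dt=record_dt)
        tr.t_stim_on, tr.t_stim_off = pre_ms, pre_ms + duration
        tr.stimulus_amplitude = float(amp)
        traces.append(tr)
    return TraceSet(traces)


#: channels whose currents confound the M-current tail measurement
TAIL_CONFOUNDS = ("Na", "Na_x", "Na_P", "Ca_HVA", "Ca_IT2", "HCN1", "HCN2")


def run_im_tail_protocol(model: MembraneModel, depol: float = -30.0,
                         depol_duration: float = 30000.0,
                         deactivation: float = -50.0, tail_ms: float = 1500.0,
                         dt: float = DEFAULT_DT,
                         mask_confounds: bool = True,
                         measure_delay_ms: float = 20.0) -> tuple[Trace, float]:
    """M-current deactivation-tail protocol under ideal somatic clamp.

    Long depolarization at ``depol`` followed by a step to the deactivating
    voltage; the tail amplitude is the current ``measure_delay_ms`` after
    the step (past the axial/capacitive redistribution of the unclamped
    dendrites) minus the steady-state current at the deactivating voltage
    (pA).  With ``mask_confounds`` the sodium, calcium and HCN conductances
    are removed, mirroring pharmacological blockade.
    """
    m = model.masked(drop=list(TAIL_CONFOUNDS)) if mask_confounds else model
    proto = StimulusProtocol(
        mode="voltage_clamp", holding=deactivation,
        steps=((depol, depol_duration), (deactivation, tail_ms)))
    tr = integrate(m, proto, dt=dt)
    tail_start = int(round(depol_duration / tr.sampling_interval))
    tail = tr.values[tail_start:]
    k = int(round(measure_delay_ms / tr.sampling_interval))
    steady = float(np.mean(tail[-max(1, int(100 / tr.sampling_interval)):]))
    tail_amplitude = float(tail[min(k, len(tail) - 1)] - steady)
    tail_trace = Trace(values=tail, sampling_interval=tr.sampling_interval,
                       stimulus_amplitude=deactivation, mode="voltage_clamp",
                       t_stim_on=0.0, t_stim_off=tail_ms,
                       metadata=dict(tr.metadata, phase="tail"))
    return tail_trace, tail_amplitude


# ---------------------------------------------------------------------------
# independent steady-state cable solver (passive oracle)


def passive_input_resistance(model: MembraneModel, site: int = 0) -> float:
    """Analytic input resistance (MΩ) of the passive tree at ``site``.

    Solves the steady-state cable system G v = I directly (sparse LU),
    independent of the time-stepping integrator; active conductances are
    ignored.
    """
    from scipy.sparse import lil_matrix
    from scipy.sparse.linalg import spsolve

    n = model.n
    A = lil_matrix((n, n))
    for i in range(n):
        A[i, i] = model.g_leak[i]
    for i in range(1, n):
        p = model.parent[i]
        g = model.g_ax[i]
        A[i, i] += g
        A[p, p] += g
        A[i, p] -= g
        A[p, i] -= g
    I = np.zeros(n)
    I[site] = 1.0  # nA
    v = spsolve(A.tocsr(), I)
    return float(v[site])  # mV / nA = MΩ
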