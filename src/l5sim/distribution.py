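"""Spatial channel-density profiles and assembly of the membrane model.

Each channel's conductance density over the tree is declared by a
:class:`DensityRule` (uniform, linear, exponential growth/decay with a
length constant, optionally restricted to a distance window).  Two
pseudo-channels exist at the rule level: ``HCN`` (split 2/3 HCN1 : 1/3
HCN2) and ``K_A`` (split into the proximal ``K_AP`` and distal ``K_AD``
variants, exchanged linearly over the first 300 µm of dendrite).

Densities are given in pS/µm² (1 pS/µm² = 1e-4 S/cm²).  Assembly converts
them, together with the spine factor, into absolute compartment
conductances for the integration engine.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import yaml

from . import channels as chan
from .morphology import CompartmentTree

log = logging.getLogger(__name__)

#: pS/µm² -> S/cm²
PSUM2_TO_SCM2 = 1e-4

#: span of the proximal->distal A-type exchange, µm
KA_EXCHANGE_SPAN = 300.0

PROFILES = ("uniform", "linear", "exponential", "linear_exchange")

#: channel order used by the engine's conductance matrix
CHANNEL_INDEX = {name: i for i, name in enumerate(chan.CHANNEL_NAMES)}
N_CHANNELS = len(chan.CHANNEL_NAMES)

_PSEUDO = {"HCN", "K_A"}


@dataclass(frozen=True)
class DensityRule:
    """One channel's density profile in one region."""

    channel: str
    region: str
    profile: str = "uniform"
    start_density: float = 0.0   # pS/µm²
    end_or_factor: float | None = None  # pS/µm² endpoint (linear) or cap factor
    length_constant: float | None = None  # µm (exponential only)
    grow: bool = False           # exponential growth vs decay
    cap_factor: float | None = None  # growth cap, multiple of start
    span: float = KA_EXCHANGE_SPAN  # µm (linear_exchange only)
    onset: float = 0.0           # density is 0 at or below this distance
    extent: float | None = None  # density is 0 beyond this distance
    region_length: float | None = None  # µm, for the linear profile
    variant: str | None = None   # 'proximal'/'distal' for exchanged pairs

    def __post_init__(self) -> None:
        if self.profile not in PROFILES:
            raise ValueError(f"unknown profile {self.profile!r}")
        if self.start_density < 0:
            raise ValueError("start_density must be non-negative")
        if self.profile == "exponential" and not (self.length_constant or 0) > 0:
            raise ValueError("exponential profile needs a positive length constant")
        if self.cap_factor is not None and self.cap_factor < 1:
            raise ValueError("cap_factor must be >= 1")


def ka_exchange_fraction(path_distance: float, span: float = KA_EXCHANGE_SPAN):
    """Fraction of the distal A-type variant at a given dendritic distance.

    Rises linearly from 0 at the soma to 1 at ``span`` and clamps there.
    """
    d = np.asarray(path_distance, dtype=float)
    out = np.clip(d / span, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def density_at(rule: DensityRule, path_distance: float) -> float:
    """Evaluate a rule's density (pS/µm²) at a path distance within its region."""
    d = float(path_distance)
    if d < 0:
        raise ValueError("path_distance must be non-negative")
    if rule.onset > 0 and d <= rule.onset:
        return 0.0
    if rule.extent is not None and d > rule.extent:
        return 0.0
    if rule.profile == "uniform":
        base = rule.start_density
    elif rule.profile == "linear":
        if not rule.region_length:
            raise ValueError("linear profile needs region_length")
        frac = min(max(d / rule.region_length, 0.0), 1.0)
        base = rule.start_density + (rule.end_or_factor - rule.start_density) * frac
    elif rule.profile == "exponential":
        lam = rule.length_constant
        if rule.grow:
            base = rule.start_density * math.exp(d / lam)
            if rule.cap_factor is not None:
                base = min(base, rule.cap_factor * rule.start_density)
        else:
            base = rule.start_density * math.exp(-d / lam)
    elif rule.profile == "linear_exchange":
        if not rule.region_length:
            raise ValueError("linear_exchange needs region_length for its total")
        # total may itself be uniform (end==start) or linear
        end = rule.end_or_factor if rule.end_or_factor is not None else rule.start_density
        frac = min(max(d / rule.region_length, 0.0), 1.0)
        total = rule.start_density + (end - rule.start_density) * frac
        x = ka_exchange_fraction(d, rule.span)
        base = total * (x if rule.variant == "distal" else 1.0 - x)
    else:  # pragma: no cover
        raise AssertionError(rule.profile)
    return base


@dataclass
class MembraneModel:
    """Simulation-ready model: geometry, passive and active conductances.

    All per-compartment quantities are in engine units: capacitance nF,
    conductances µS, voltages mV, time ms, currents nA.
    """

    tree: CompartmentTree
    parent: np.ndarray          # int32[N], -1 at root, parent[i] < i
    g_ax: np.ndarray            # µS coupling to parent
    c: np.ndarray               # nF
    area: np.ndarray            # cm²
    g_leak: np.ndarray          # µS
    e_leak: float               # mV
    G: np.ndarray               # µS, shape (N_CHANNELS, N)
    v_shift: np.ndarray         # mV per channel
    v_init: float = -70.0
    ca_resting: float = chan.CA_RESTING
    ca_tau: float = chan.CA_DECAY_TAU
    ca_influx_scale: float = chan.CA_INFLUX_SCALE
    label: str = "control"
    _steady_cache: dict = field(default_factory=dict, repr=False)

    @property
    def n(self) -> int:
        return len(self.parent)

    def copy(self, label: str | None = None) -> "MembraneModel":
        return replace(
            self, G=self.G.copy(), v_shift=self.v_shift.copy(),
            parent=self.parent.copy(), g_ax=self.g_ax.copy(),
            c=self.c.copy(), area=self.area.copy(),
            g_leak=self.g_leak.copy(),
            label=self.label if label is None else label, _steady_cache={})

    def channel_density(self, name: str, comp_id: int) -> float:
        """Resolved conductance density (pS/µm², incl. spine factor)."""
        g_uS = self.G[CHANNEL_INDEX[name], comp_id]
        return g_uS / (self.area[comp_id] * 100.0)

    def scale_channel(self, name: str, factor: float) -> None:
        if name not in CHANNEL_INDEX:
            raise ValueError(f"unknown channel {name!r}")
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        self.G[CHANNEL_INDEX[name]] *= factor

    def shift_channel(self, name: str, delta: float) -> None:
        if name not in CHANNEL_INDEX:
            raise ValueError(f"unknown channel {name!r}")
        self.v_shift[CHANNEL_INDEX[name]] += delta

    def masked(self, keep: list[str] | None = None,
               drop: list[str] | None = None) -> "MembraneModel":
        """Copy with all channels outside ``keep`` (or inside ``drop``) removed."""
        m = self.copy(label=f"{self.label}|masked")
        for name, idx in CHANNEL_INDEX.items():
            if keep is not None and name not in keep:
                m.G[idx] = 0.0
            if drop is not None and name in drop:
                m.G[idx] = 0.0
        return m


def _axial_conductance_uS(tree: CompartmentTree) -> np.ndarray:
    """Series half-cylinder axial conductance between each compartment and parent."""
    comps = tree.compartments
    g = np.zeros(len(comps))
    index = {c.id: c for c in comps}
    for i, c in enumerate(comps):
        if c.parent_id is None:
            continue
        p = index[c.parent_id]
        r_ohm = 0.0
        for seg in (c, p):
            l_cm = seg.length * 1e-4
            a_cm2 = math.pi * (seg.diameter * 1e-4 / 2.0) ** 2
            r_ohm += seg.ra * (l_cm / 2.0) / a_cm2
        g[i] = 1e6 / r_ohm
    return g


def build_membrane_model(tree: CompartmentTree, rules: list[DensityRule],
                         kinetics: dict[str, chan.ChannelKinetics] | None = None,
                         e_leak: float = -70.0, v_init: float = -70.0,
                         label: str = "control") -> MembraneModel:
    """Assemble the simulation-ready model from a tree and density rules.

    Every compartment receives density x spine-factor for each applicable
    rule, evaluated at the compartment's (distal-end) path distance.  Rules
    for the ``HCN`` pseudo-channel are split 2/3:1/3 into HCN1/HCN2; rules
    for ``K_A`` must come as a proximal/distal ``linear_exchange`` pair.
    """
    if not rules:
        raise ValueError("empty rule list")
    kinetics = chan.CHANNELS if kinetics is None else kinetics
    for r in rules:
        if r.channel not in _PSEUDO and r.channel not in kinetics:
            raise ValueError(f"rule references unknown channel {r.channel!r}")
    tree.validate()
    if any(c.cm is None or c.rm is None for c in tree.compartments):
        raise ValueError("passive properties must be assigned before assembly")

    comps = tree.compartments
    n = len(comps)
    order = {c.id: i for i, c in enumerate(comps)}
    parent = np.array([-1 if c.parent_id is None else order[c.parent_id]
                       for c in comps], dtype=np.int32)
    if not all(parent[i] < i for i in range(n)):
        raise ValueError("compartments must be ordered parent before child")
    area = np.array([c.area * 1e-8 for c in comps])  # cm²
    c_nF = np.array([c.cm * a * 1e3 for c, a in zip(comps, area)])
    g_leak = np.array([a * 1e3 / c.rm for c, a in zip(comps, area)])  # µS
    g_ax = _axial_conductance_uS(tree)

    G = np.zeros((N_CHANNELS, n))
    # resolve per-region rule lists once
    by_region: dict[str, list[DensityRule]] = {}
    for r in rules:
        rl = r.region_length
        if rl is None and r.profile in ("linear", "linear_exchange"):
            rl = tree.max_path_distance(r.region)
            r = replace(r, region_length=rl)
        by_region.setdefault(r.region, []).append(r)

    present: dict[str, set[str]] = {}
    for i, comp in enumerate(comps):
        for r in by_region.get(comp.region, []):
            dens = density_at(r, comp.path_distance) * comp.spine_factor
            if dens <= 0:
                continue
            g_uS = dens * area[i] * 100.0  # pS/µm² * cm² -> µS
            if r.channel == "HCN":
                h1, h2 = chan.hcn_split(g_uS)
                G[CHANNEL_INDEX["HCN1"], i] += h1
                G[CHANNEL_INDEX["HCN2"], i] += h2
                present.setdefault(comp.region, set()).update({"HCN1", "HCN2"})
            elif r.channel == "K_A":
                name = "K_AD" if r.variant == "distal" else "K_AP"
                G[CHANNEL_INDEX[name], i] += g_uS
                present.setdefault(comp.region, set()).add(name)
            else:
                G[CHANNEL_INDEX[r.channel], i] += g_uS
                present.setdefault(comp.region, set()).add(r.channel)

    for region in sorted({c.region for c in comps}):
        have = present.get(region, set())
        if not have:
            log.warning("region %r carries no active channels", region)
            continue
        if not have & {"Na", "Na_x", "Na_P"} or not any(h.startswith("K") for h in have):
            raise ValueError(f"region {region!r} lacks a Na or K rule")

    return MembraneModel(tree=tree, parent=parent, g_ax=g_ax, c=c_nF,
                         area=area, g_leak=g_leak, e_leak=e_leak, G=G,
                         v_shift=np.zeros(N_CHANNELS), v_init=v_init,
                         label=label)


# ---------------------------------------------------------------------------
# shipped default rules


def load_density_config() -> dict:
    with resources.files("l5sim.config").joinpath("densities.yaml").open() as fh:
        return yaml.safe_load(fh)


#: regions whose Na / Na_x / K_V densities the baseline calibration may
#: rescale (dendritic gradients always keep their table values)
CALIBRATION_REGIONS = ("soma", "axon")


def rules_from_config(config: dict | None = None,
                      calibration: dict[str, float] | None = None) -> list[DensityRule]:
    """Instantiate the rule list from the declarative density config.

    ``calibration`` maps channel names to density multipliers for the
    somatic/axonal rules (the recorded baseline calibration of
    Na/Na_x/K_V); dendritic rules are never rescaled.
    """
    if config is None:
        config = load_density_config()
    calibration = calibration or {}
    out = []
    for entry in config["rules"]:
        e = dict(entry)
        f = (calibration.get(e["channel"], 1.0)
             if e["region"] in CALIBRATION_REGIONS else 1.0)
        e["start_density"] = float(e["start_density"]) * f
        if e.get("end_or_factor") is not None and e.get("profile") in (
                "linear", "linear_exchange"):
            e["end_or_factor"] = float(e["end_or_factor"]) * f
        out.append(DensityRule(**e))
    return out


def load_biophys_config() -> dict:
    with resources.files("l5sim.config").joinpath("biophys.yaml").open() as fh:
        return yaml.safe_load(fh)


def default_model(label: str = "control",
                  calibration: dict[str, float] | None = None,
                  e_leak: float | None = None) -> MembraneModel:
    """The calibrated reference model: stylized cell + shipped densities.

    Builds the stylized layer 5 morphology, assigns the passive profile and
    spine correction, and assembles the membrane model with the density
    table and the recorded baseline calibration from the shipped config.
    """
    from . import morphology as morph

    bio = load_biophys_config()
    tree = morph.make_reference_morphology()
    morph.assign_passive(tree, cm=bio["passive"]["cm"], ra=bio["passive"]["ra"],
                         rm_soma=bio["passive"]["rm_soma"],
                         rm_tip=bio["passive"]["rm_tip"])
    morph.apply_spine_correction(
        tree, basal_onset=bio["spine_correction"]["basal_onset"],
        apical_onset=bio["spine_correction"]["apical_onset"])
    rules = rules_from_config(
        calibration=bio["calibration"] if calibration is None else calibration)
    return build_membrane_model(
        tree, rules,
        e_leak=bio["passive"]["e_leak"] if e_leak is None else e_leak,
        v_init=bio["passive"]["v_init"], label=label)


def density_report(model: MembraneModel, distances=None) -> "pandas.DataFrame":
    """Tabulate the resolved density of every channel at sampled distances."""
    import pandas as pd

    rows = []
    for comp in model.tree.compartments:
        if distances is not None and not any(
                abs(comp.path_distance - d) <= comp.length for d in distances):
            continue
        for name in chan.CHANNEL_NAMES:
            dens = model.channel_density(name, comp.id)
            if dens > 0:
                rows.append({"compartment": comp.id, "region": comp.region,
                             "path_distance_um": round(comp.path_distance, 2),
                             "channel": name, "density_pS_um2": dens})
    return pd.DataFrame(rows)
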