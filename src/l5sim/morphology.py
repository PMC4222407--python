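"""Compartmental morphology: SWC loading, a stylized layer 5 cell, passive
properties and the dendritic-spine correction.

The morphology is represented as a tree of cylindrical compartments.  Each
compartment carries its region (soma / axon / apical / basal), geometry,
path distance from the soma centre and the passive membrane parameters
(specific capacitance ``cm``, axial resistivity ``ra``, specific membrane
resistance ``rm``).  Unmodelled dendritic spines are compensated by the
classic factor-2 correction (cm and active conductance densities doubled,
rm halved) beyond a region-specific onset distance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable

import numpy as np
import yaml

REGIONS = ("soma", "axon", "apical", "basal")
_SWC_TYPE_TO_REGION = {1: "soma", 2: "axon", 3: "basal", 4: "apical"}
_REGION_TO_SWC_TYPE = {v: k for k, v in _SWC_TYPE_TO_REGION.items()}

#: Default passive parameters: uniform specific capacitance (µF/cm²),
#: uniform axial resistivity (Ω·cm; the source prints "68.0 Ω", Ω·cm is the
#: standard usage and is assumed here), and the soma-to-tip range of the
#: sigmoidal specific membrane resistance profile (kΩ·cm²).
DEFAULT_CM = 1.5
DEFAULT_RA = 68.0
DEFAULT_RM_SOMA = 36.0
DEFAULT_RM_TIP = 5.4

#: Spine-correction onset distances (µm) and the correction factor.
BASAL_SPINE_ONSET = 20.0
APICAL_SPINE_ONSET = 100.0
SPINE_FACTOR = 2.0

#: Maximum electrical segment length (µm) used when discretizing.
MAX_SEGMENT_LENGTH = 20.0


class SWCError(ValueError):
    """Malformed SWC content (bad columns, unknown type code, ...)."""


class StructureError(ValueError):
    """Structurally invalid tree (undefined parent, cycle, multiple roots)."""


@dataclass
class Compartment:
    """One cylindrical electrical compartment.

    ``path_distance`` is measured from the soma centre to the *distal* end
    of the compartment, accumulated along 3-D sample points.
    """

    id: int
    parent_id: int | None
    region: str
    length: float  # µm
    diameter: float  # µm
    path_distance: float  # µm, distal end
    cm: float | None = None  # µF/cm²
    ra: float | None = None  # Ω·cm
    rm: float | None = None  # kΩ·cm²
    spine_corrected: bool = False
    spine_factor: float = 1.0

    @property
    def area(self) -> float:
        """Lateral membrane area in µm²."""
        return math.pi * self.diameter * self.length

    @property
    def mid_path_distance(self) -> float:
        return max(self.path_distance - 0.5 * self.length, 0.0)


@dataclass
class CompartmentTree:
    """Connected, acyclic collection of compartments, parent before child."""

    compartments: list[Compartment] = field(default_factory=list)
    #: raw SWC samples (id, type, x, y, z, radius, parent) kept for round-trip
    swc_samples: list[tuple[int, int, float, float, float, float, int]] | None = None

    def __post_init__(self) -> None:
        self._index = {c.id: c for c in self.compartments}

    def __len__(self) -> int:
        return len(self.compartments)

    def __iter__(self) -> Iterable[Compartment]:
        return iter(self.compartments)

    def __getitem__(self, cid: int) -> Compartment:
        return self._index[cid]

    @property
    def adjacency(self) -> dict[int, list[int]]:
        adj: dict[int, list[int]] = {c.id: [] for c in self.compartments}
        for c in self.compartments:
            if c.parent_id is not None:
                adj[c.parent_id].append(c.id)
        return adj

    @property
    def root(self) -> Compartment:
        roots = [c for c in self.compartments if c.parent_id is None]
        if len(roots) != 1:
            raise StructureError(f"expected exactly one root, found {len(roots)}")
        return roots[0]

    def max_path_distance(self, region: str | None = None) -> float:
        sel = [c.path_distance for c in self.compartments
               if region is None or c.region == region]
        return max(sel) if sel else 0.0

    @property
    def max_dendritic_distance(self) -> float:
        return max(self.max_path_distance("apical"), self.max_path_distance("basal"))

    def total_area(self) -> float:
        return sum(c.area for c in self.compartments)

    def copy(self) -> "CompartmentTree":
        return CompartmentTree(
            [replace(c) for c in self.compartments],
            swc_samples=None if self.swc_samples is None else list(self.swc_samples),
        )

    def validate(self) -> None:
        """Check the structural invariants; raise ``StructureError`` if broken."""
        if not self.compartments:
            raise StructureError("empty tree")
        root = self.root
        if root.region != "soma":
            raise StructureError("root compartment must be the soma")
        seen: set[int] = set()
        for c in self.compartments:
            if c.region not in REGIONS:
                raise StructureError(f"unknown region {c.region!r}")
            if c.length <= 0 or c.diameter <= 0:
                raise StructureError(f"compartment {c.id}: non-positive geometry")
            if c.path_distance < 0:
                raise StructureError(f"compartment {c.id}: negative path distance")
            if c.parent_id is not None:
                if c.parent_id not in seen:
                    raise StructureError(
                        f"compartment {c.id}: parent {c.parent_id} not defined before child")
                parent = self._index[c.parent_id]
                if c.path_distance < parent.path_distance - 1e-9:
                    raise StructureError(
                        f"compartment {c.id}: path distance not monotone")
            seen.add(c.id)


def load_swc(swc_text: str) -> CompartmentTree:
    """Parse SWC content into a :class:`CompartmentTree`.

    All type-1 (soma) samples are merged into a single equivalent-area soma
    compartment.  A sample coincident with its parent point (zero segment
    length, a common branch-anchor idiom) is merged into its parent.  Path
    distances are cumulative 3-D point-to-point distances from the soma.
    """
    samples: dict[int, tuple[int, int, float, float, float, float, int]] = {}
    order: list[int] = []
    for lineno, raw in enumerate(swc_text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split()
        if len(cols) != 7:
            raise SWCError(f"line {lineno}: expected 7 columns, got {len(cols)}: {raw!r}")
        try:
            sid, stype, parent = int(cols[0]), int(cols[1]), int(cols[6])
            x, y, z, radius = (float(v) for v in cols[2:6])
        except ValueError as exc:
            raise SWCError(f"line {lineno}: {exc}: {raw!r}") from None
        if stype not in _SWC_TYPE_TO_REGION:
            raise SWCError(f"line {lineno}: unknown SWC type code {stype}: {raw!r}")
        if radius <= 0:
            raise SWCError(f"line {lineno}: non-positive radius: {raw!r}")
        if sid in samples:
            raise StructureError(f"line {lineno}: duplicate sample id {sid}")
        if parent == -1:
            if any(samples[i][6] == -1 for i in order):
                raise StructureError(f"line {lineno}: multiple root samples")
            if stype != 1:
                raise StructureError(f"line {lineno}: root sample must be soma (type 1)")
        elif parent not in samples:
            raise StructureError(
                f"line {lineno}: parent {parent} referenced before definition")
        samples[sid] = (sid, stype, x, y, z, radius, parent)
        order.append(sid)
    if not order:
        raise SWCError("no samples in SWC content")

    # --- merge soma samples into one equivalent-area compartment
    soma_ids = [i for i in order if samples[i][1] == 1]
    if not soma_ids:
        raise StructureError("SWC contains no soma sample")
    soma_area = 0.0
    soma_len = 0.0
    for i in soma_ids:
        _, _, x, y, z, r, p = samples[i]
        if p == -1 or samples[p][1] != 1:
            soma_area += 4.0 * math.pi * r * r  # lone point: sphere
        else:
            _, _, px, py, pz, pr, _ = samples[p]
            seg = math.dist((x, y, z), (px, py, pz))
            soma_len += seg
            soma_area += math.pi * (r + pr) * seg  # frustum lateral area
    soma_length = soma_len if soma_len > 0 else 2.0 * samples[soma_ids[0]][5]
    soma_diam = soma_area / (math.pi * soma_length)

    comps = [Compartment(id=0, parent_id=None, region="soma",
                         length=soma_length, diameter=soma_diam, path_distance=0.0)]
    # sample id -> (compartment id it maps to, path distance at its point)
    anchor: dict[int, tuple[int, float]] = {i: (0, 0.0) for i in soma_ids}
    next_id = 1
    for i in order:
        sid, stype, x, y, z, r, p = samples[i]
        if stype == 1:
            continue
        if p == -1:
            raise StructureError(f"sample {sid}: non-soma root")
        if p not in anchor:
            raise StructureError(f"sample {sid}: parent {p} undefined")
        pcid, pdist = anchor[p]
        px, py, pz = samples[p][2:5]
        seg = math.dist((x, y, z), (px, py, pz))
        if seg < 1e-9:  # coincident anchor point: merge into parent
            anchor[sid] = (pcid, pdist)
            continue
        comps.append(Compartment(
            id=next_id, parent_id=pcid, region=_SWC_TYPE_TO_REGION[stype],
            length=seg, diameter=2.0 * r, path_distance=pdist + seg))
        anchor[sid] = (next_id, pdist + seg)
        next_id += 1

    tree = CompartmentTree(comps, swc_samples=[samples[i] for i in order])
    tree.validate()
    return tree


def to_swc(tree: CompartmentTree) -> str:
    """Serialize a tree back to SWC text.

    Trees loaded from SWC re-emit their original sample coordinates; trees
    built programmatically are written as one sample per compartment laid
    out along a straight line per branch (geometry-faithful in length and
    radius, not in 3-D embedding).
    """
    lines = ["# SWC written by l5sim"]
    if tree.swc_samples is not None:
        for sid, stype, x, y, z, r, p in tree.swc_samples:
            lines.append(f"{sid} {stype} {x:.17g} {y:.17g} {z:.17g} {r:.17g} {p}")
        return "\n".join(lines) + "\n"
    # synthetic embedding: place each compartment end at x = path_distance
    for c in tree.compartments:
        sid = c.id + 1
        parent = -1 if c.parent_id is None else c.parent_id + 1
        x = 0.0 if c.region == "soma" else c.path_distance
        lines.append(
            f"{sid} {_REGION_TO_SWC_TYPE[c.region]} {x:.17g} 0 0 {c.diameter / 2:.17g} {parent}")
    return "\n".join(lines) + "\n"


def _subdivide(comps: list[Compartment], max_len: float) -> list[Compartment]:
    """Split compartments longer than ``max_len`` into equal sub-segments."""
    out: list[Compartment] = []
    remap: dict[int, int] = {}
    next_id = 0
    for c in comps:
        parent = None if c.parent_id is None else remap[c.parent_id]
        n = max(1, math.ceil(c.length / max_len)) if c.region != "soma" else 1
        seg_len = c.length / n
        start = c.path_distance - c.length
        for k in range(n):
            out.append(replace(
                c, id=next_id, parent_id=parent,
                length=seg_len, path_distance=start + (k + 1) * seg_len))
            parent = next_id
            next_id += 1
        remap[c.id] = next_id - 1
    return out


def make_reference_morphology(config: dict | None = None) -> CompartmentTree:
    """Build the stylized layer 5 pyramidal cell shipped with the package.

    The geometry (soma, axon initial segment + axon, tapering apical trunk
    with a tuft, several basal dendrites) is fixed in
    ``config/reference_morphology.yaml`` and the construction is fully
    deterministic: repeated calls return identical trees.
    """
    if config is None:
        config = load_reference_config()
    sections = config["sections"]
    comps: list[Compartment] = []
    sec_tip: dict[str, tuple[int, float]] = {}  # section name -> (tip comp id, tip dist)
    next_id = 0
    for sec in sections:
        region = sec["region"]
        if region == "soma":
            comps.append(Compartment(
                id=next_id, parent_id=None, region="soma",
                length=float(sec["length"]), diameter=float(sec["diameter"]),
                path_distance=0.0))
            sec_tip[sec["name"]] = (next_id, 0.0)
            next_id += 1
            continue
        parent_name = sec["parent"]
        pid, pdist = sec_tip[parent_name]
        length = float(sec["length"])
        n = max(1, math.ceil(length / MAX_SEGMENT_LENGTH))
        seg = length / n
        d0 = float(sec.get("diameter_start", sec.get("diameter")))
        d1 = float(sec.get("diameter_end", sec.get("diameter")))
        for k in range(n):
            frac = (k + 0.5) / n
            comps.append(Compartment(
                id=next_id, parent_id=pid, region=region,
                length=seg, diameter=d0 + (d1 - d0) * frac,
                path_distance=pdist + (k + 1) * seg))
            pid = next_id
            next_id += 1
        sec_tip[sec["name"]] = (pid, pdist + length)
    tree = CompartmentTree(comps)
    tree.validate()
    return tree


def load_reference_config() -> dict:
    with resources.files("l5sim.config").joinpath("reference_morphology.yaml").open() as fh:
        return yaml.safe_load(fh)


def sigmoid_rm_profile(path_distance, max_distance: float,
                       rm_soma: float = DEFAULT_RM_SOMA,
                       rm_tip: float = DEFAULT_RM_TIP,
                       span_fraction: float = 0.99):
    """Logistic specific-membrane-resistance profile along the dendrites.

    Midpoint at half the maximal dendritic path distance; the slope is set
    so that at least ``span_fraction`` of the soma-to-tip range is spanned
    between distance 0 and ``max_distance``.  At the midpoint the value is
    exactly the arithmetic mean of the endpoints.
    """
    d = np.asarray(path_distance, dtype=float)
    half = 0.5 * max_distance
    # logistic reaches span_fraction of its range at the endpoints
    k = half / math.log(span_fraction / (1.0 - span_fraction)) if half > 0 else 1.0
    return rm_tip + (rm_soma - rm_tip) / (1.0 + np.exp((d - half) / k))


def assign_passive(tree: CompartmentTree, cm: float = DEFAULT_CM,
                   ra: float = DEFAULT_RA, rm_soma: float = DEFAULT_RM_SOMA,
                   rm_tip: float = DEFAULT_RM_TIP,
                   span_fraction: float = 0.99) -> CompartmentTree:
    """Assign uniform cm/ra and the sigmoidal rm profile (in place).

    Soma and axon take ``rm_soma``; dendritic rm follows the logistic
    profile of path distance, from ``rm_soma`` at the soma to ``rm_tip`` at
    the maximal dendritic path distance.
    """
    if cm <= 0 or ra <= 0 or rm_tip <= 0:
        raise ValueError("cm, ra and rm must be positive")
    if not rm_soma > rm_tip:
        raise ValueError("rm_soma must exceed rm_tip")
    dmax = tree.max_dendritic_distance
    for c in tree.compartments:
        c.cm, c.ra = cm, ra
        if c.region in ("soma", "axon"):
            c.rm = rm_soma
        else:
            c.rm = float(sigmoid_rm_profile(
                c.path_distance, dmax, rm_soma, rm_tip, span_fraction))
    return tree


def apply_spine_correction(tree: CompartmentTree,
                           basal_onset: float = BASAL_SPINE_ONSET,
                           apical_onset: float = APICAL_SPINE_ONSET) -> CompartmentTree:
    """Apply the factor-2 spine correction beyond the onset distances.

    Dendritic compartments at or beyond the onset (inclusive boundary) get
    cm doubled, rm halved and a recorded spine factor of 2 that later
    multiplies active channel densities.  Soma and axon are never touched.
    Idempotent: corrected compartments are skipped on repeat calls.
    """
    for c in tree.compartments:
        if c.spine_corrected or c.region in ("soma", "axon"):
            continue
        if c.cm is None:
            raise ValueError("assign_passive must run before the spine correction")
        onset = basal_onset if c.region == "basal" else apical_onset
        if c.path_distance >= onset:
            c.cm *= SPINE_FACTOR
            c.rm /= SPINE_FACTOR
            c.spine_factor = SPINE_FACTOR
            c.spine_corrected = True
    return tree
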