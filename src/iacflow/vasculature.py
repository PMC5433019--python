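"""Synthetic carotid-tree geometry and catheter placement.

Builds idealized but anatomically structured networks of the common carotid
artery (CCA) and its division into the internal carotid artery (ICA) and the
external carotid artery (ECA) with its named branches: superior thyroid
(SThA), lingual (LA), occipital (OA), facial (FA), posterior auricular (PAA),
middle meningeal (MMA), maxillary (MA) and superficial temporal (STA)
arteries.  The ECA trunk is represented as a tapering sequence of conduit
sub-segments; each branch attaches at an ostium characterized by its axial
position along the trunk and its angle in the distal-view cross-section.

Convention (documented choice): distal-view ostium angles are measured in
radians, 0 = anterior, counterclockwise positive.  Horizontal catheter shifts
are F (toward the target ostium angle), B (opposite), L (+90°), R (−90°),
with magnitude one quarter of the local ECA trunk diameter.

The catheter (default diameter 1.3 mm) enters retrogradely via the STA, which
is ligated around it, so the catheter body occupies the trunk lumen from the
STA end down to the tip.  Vertical tip classes follow the clinical grid:

1. midway between the carotid bifurcation and the LA origin,
2. at the LA origin,
3. midway between the LA and FA origins,
4. inserted into the target branch (superselective).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "VesselSegment",
    "VesselNetwork",
    "CatheterPlacement",
    "NetworkVariantConfig",
    "generate_network",
    "place_catheter",
    "enumerate_model_grid",
    "relative_label",
    "write_network",
    "read_network",
]

TARGET_BRANCHES = ("LA", "OA", "FA")

#: ECA branch-order variants reported in cadaver studies (caudal side first).
#: LFT = linguofacial common trunk; TLT = thyrolingual common trunk.
KNOWN_BRANCH_ORDERS = (
    ("LA", "FA", "OA"),
    ("LA", "OA", "FA"),
    ("OA", "LA", "FA"),
    ("LFT", "OA"),
    ("OA", "LFT"),
    ("TLT", "FA", "OA"),
)

_COMMON_TRUNKS = {"LFT": ("LA", "FA"), "TLT": ("SThA", "LA")}

# Distal-view ostium angle cycles that reproduce the two clinical cases'
# shared-column label conventions (case B is the contralateral mirror).
_CASE_ANGLES = {
    "A": {"LA": 0.0, "OA": math.pi / 2, "FA": -math.pi / 2},
    "B": {"LA": 0.0, "OA": -math.pi / 2, "FA": math.pi},
}
_MINOR_ANGLES = {"SThA": 3 * math.pi / 4, "PAA": math.pi / 4, "MMA": 2 * math.pi / 3}

# Default branch radii (m); LA is case-dependent (about 3.0 mm diameter in
# the case-B-like geometry, 2.0 mm in case A).
_BRANCH_RADII = {
    "SThA": 0.8e-3,
    "OA": 1.0e-3,
    "FA": 1.2e-3,
    "PAA": 0.6e-3,
    "MMA": 0.7e-3,
    "MA": 1.3e-3,
    "STA": 1.1e-3,
}
_LA_RADIUS = {"A": 1.0e-3, "B": 1.5e-3}


@dataclass(frozen=True)
class VesselSegment:
    """One vessel segment of the tree (SI units: m, radians)."""

    id: str
    name: str
    radius: float
    length: float
    parent: str | None
    ostium_angle: float | None = None
    ostium_axial_position: float | None = None

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError(f"segment {self.id!r}: radius must be positive")
        if self.length <= 0:
            raise ValueError(f"segment {self.id!r}: length must be positive")

    @property
    def diameter(self) -> float:
        return 2.0 * self.radius


@dataclass(frozen=True)
class VesselNetwork:
    """Directed tree of vessel segments rooted at the CCA inlet."""

    case: str
    segments: tuple[VesselSegment, ...]
    ligated_outlets: frozenset[str]
    trunk_root_radius: float
    trunk_end_radius: float
    trunk_length: float

    def __post_init__(self) -> None:
        ids = [s.id for s in self.segments]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate segment ids")
        roots = [s for s in self.segments if s.parent is None]
        if len(roots) != 1 or roots[0].id != "CCA":
            raise ValueError("network must have exactly one root segment 'CCA'")
        by_id = {s.id: s for s in self.segments}
        for s in self.segments:
            if s.parent is not None and s.parent not in by_id:
                raise ValueError(f"segment {s.id!r}: unknown parent {s.parent!r}")
        # no cycles / connectivity: every segment must reach the root
        for s in self.segments:
            seen, cur = set(), s
            while cur.parent is not None:
                if cur.id in seen:
                    raise ValueError("cycle detected in segment parents")
                seen.add(cur.id)
                cur = by_id[cur.parent]

    # -- lookup helpers -------------------------------------------------
    def __getitem__(self, seg_id: str) -> VesselSegment:
        return {s.id: s for s in self.segments}[seg_id]

    def children(self, seg_id: str) -> list[VesselSegment]:
        return [s for s in self.segments if s.parent == seg_id]

    def leaves(self) -> list[VesselSegment]:
        parents = {s.parent for s in self.segments}
        return [s for s in self.segments if s.id not in parents]

    def outlet_ids(self) -> list[str]:
        """Open (non-ligated) outlet segments, in tree order."""
        return [s.id for s in self.leaves() if s.id not in self.ligated_outlets]

    def trunk_branches(self) -> list[VesselSegment]:
        """Branches attached to the ECA trunk, ordered by ostium position."""
        att = [s for s in self.segments if s.ostium_axial_position is not None]
        return sorted(att, key=lambda s: s.ostium_axial_position)

    def trunk_radius_at(self, x: float) -> float:
        """ECA trunk lumen radius at axial position ``x`` (linear taper)."""
        if not 0.0 <= x <= self.trunk_length + 1e-12:
            raise ValueError(f"axial position {x} outside trunk [0, {self.trunk_length}]")
        t = x / self.trunk_length
        return self.trunk_root_radius + t * (self.trunk_end_radius - self.trunk_root_radius)

    def descend_to(self, target: str) -> list[str]:
        """Segment ids from the trunk-attached carrier down to ``target``."""
        by_id = {s.id: s for s in self.segments}
        if target not in by_id:
            raise ValueError(f"unknown segment {target!r}")
        chain = [target]
        cur = by_id[target]
        while cur.ostium_axial_position is None:
            if cur.parent is None:
                raise ValueError(f"{target!r} is not on the ECA trunk")
            cur = by_id[cur.parent]
            chain.append(cur.id)
        return list(reversed(chain))

    def carrier_of(self, target: str) -> VesselSegment:
        """The trunk-attached segment through which ``target`` is reached."""
        return self[self.descend_to(target)[0]]


@dataclass(frozen=True)
class CatheterPlacement:
    """Catheter tip position and orientation within the network."""

    tip_axial_position: float  # m along the ECA trunk from the bifurcation
    vertical_class: int  # 1-4
    horizontal_class: str  # C/F/B/L/R
    target_branch: str
    tip_offset: float  # m from the trunk centerline (magnitude)
    tip_angle: float  # distal-view direction of the offset (radians)
    catheter_radius: float = 0.65e-3
    pivot_distance: float = 10e-3
    inside_branch: str | None = None  # set for superselective (class 4) tips
    label: str = ""
    relative_labels: dict = field(default_factory=dict, compare=False)


def relative_label(direction_angle: float, branch_angle: float) -> str:
    """Horizontal-shift label of a physical direction relative to a branch ostium.

    F = toward the ostium, B = away, L = +90°, R = −90° in distal view.
    """
    delta = (direction_angle - branch_angle) % (2 * math.pi)
    idx = round(delta / (math.pi / 2)) % 4
    return ("F", "L", "B", "R")[idx]


@dataclass(frozen=True)
class NetworkVariantConfig:
    """Configuration of one synthetic carotid-tree variant."""

    case: str = "A"
    branch_order: tuple[str, ...] = ("LA", "OA", "FA")
    include_PAA: bool = True
    include_MMA: bool = True
    trunk_taper: float = 0.625  # end radius / bifurcation radius
    seed: int = 0
    jitter: float = 0.02  # fractional geometric perturbation
    la_radius: float | None = None  # default per case (1.0 / 1.5 mm)
    ostium_angles: dict | None = None  # override distal-view angles

    def __post_init__(self) -> None:
        order = tuple(self.branch_order)
        expanded: list[str] = []
        for token in order:
            if token in _COMMON_TRUNKS:
                expanded.extend(_COMMON_TRUNKS[token])
            elif token in TARGET_BRANCHES:
                expanded.append(token)
            else:
                raise ValueError(f"unknown branch label {token!r} in branch_order")
        for t in TARGET_BRANCHES:
            if expanded.count(t) > 1:
                raise ValueError(f"duplicate branch {t!r} in branch_order")
            if t not in expanded:
                raise ValueError(f"branch_order must place {t!r} (directly or via a common trunk)")
        if not 0.0 < self.trunk_taper <= 1.0:
            raise ValueError("trunk_taper must lie in (0, 1]")
        if self.jitter < 0 or self.jitter > 0.2:
            raise ValueError("jitter must lie in [0, 0.2]")


def generate_network(config: NetworkVariantConfig = NetworkVariantConfig()) -> VesselNetwork:
    """Generate a synthetic carotid tree for one anatomical variant.

    Deterministic for a fixed seed.  The ECA trunk tapers linearly; ordered
    branches are attached at jittered ostium positions; every outlet stub is
    cut at a length of five diameters so that outlet boundary effects stay
    away from the region of interest.
    """
    rng = np.random.default_rng(config.seed)

    def jit() -> float:
        return 1.0 + config.jitter * rng.uniform(-1.0, 1.0)

    case = config.case
    angles = dict(_CASE_ANGLES.get(case, _CASE_ANGLES["A"]))
    angles.update(_MINOR_ANGLES)
    if config.ostium_angles:
        angles.update(config.ostium_angles)

    trunk_scale = jit()
    trunk_root_r = 2.4e-3 * trunk_scale
    trunk_end_r = trunk_root_r * config.trunk_taper
    trunk_len = 45e-3

    radii = dict(_BRANCH_RADII)
    radii["LA"] = config.la_radius or _LA_RADIUS.get(case, 1.0e-3)
    radii = {k: v * jit() for k, v in radii.items()}

    # ostium axial slots (m): SThA proximal, ordered targets, then accessories
    slots = [12e-3, 20e-3, 28e-3]
    positions: dict[str, float] = {}
    if "TLT" not in config.branch_order:
        positions["SThA"] = 3e-3
    for token, x in zip(config.branch_order, slots):
        positions[token] = x
    if config.include_PAA:
        positions["PAA"] = 34e-3
    if config.include_MMA:
        positions["MMA"] = 38e-3
    positions = {k: min(x + config.jitter * rng.uniform(-1e-3, 1e-3), trunk_len)
                 for k, x in positions.items()}
    positions["MA"] = trunk_len
    positions["STA"] = trunk_len

    def trunk_radius_at(x: float) -> float:
        return trunk_root_r + (x / trunk_len) * (trunk_end_r - trunk_root_r)

    segments: list[VesselSegment] = []
    cca_r = 3.25e-3 * jit()
    ica_r = 2.74e-3 * jit()
    segments.append(VesselSegment("CCA", "CCA", cca_r, 10 * cca_r, None))
    segments.append(VesselSegment("ICA", "ICA", ica_r, 10 * ica_r, "CCA"))

    # ECA trunk conduit pieces between consecutive ostia
    events = sorted({x for x in positions.values()})
    prev_x, prev_id = 0.0, "CCA"
    piece_parent: dict[float, str] = {}
    for i, x in enumerate(events, start=1):
        pid = f"ECA_{i}"
        r_mid = trunk_radius_at(0.5 * (prev_x + x))
        segments.append(VesselSegment(pid, "ECA trunk", r_mid, x - prev_x, prev_id))
        piece_parent[x] = pid
        prev_x, prev_id = x, pid

    def common_trunk_radius(children: tuple[str, ...]) -> float:
        return sum(radii[c] ** 3 for c in children) ** (1.0 / 3.0)

    for token, x in sorted(positions.items(), key=lambda kv: kv[1]):
        parent = piece_parent[x]
        if token in _COMMON_TRUNKS:
            kids = _COMMON_TRUNKS[token]
            r_ct = common_trunk_radius(kids)
            segments.append(VesselSegment(token, token, r_ct, 6e-3, parent,
                                          ostium_angle=angles["LA"],
                                          ostium_axial_position=x))
            for kid in kids:
                segments.append(VesselSegment(kid, kid, radii[kid], 10 * radii[kid], token))
        else:
            angle = angles.get(token)
            segments.append(VesselSegment(token, token, radii[token], 10 * radii[token],
                                          parent, ostium_angle=angle,
                                          ostium_axial_position=x))

    return VesselNetwork(
        case=case,
        segments=tuple(segments),
        ligated_outlets=frozenset({"STA"}),
        trunk_root_radius=trunk_root_r,
        trunk_end_radius=trunk_end_r,
        trunk_length=trunk_len,
    )


def place_catheter(
    network: VesselNetwork,
    vertical_class: int,
    horizontal_class: str,
    target_branch: str = "LA",
    catheter_radius: float = 0.65e-3,
    pivot_distance: float = 10e-3,
) -> CatheterPlacement:
    """Place the catheter tip according to the vertical/horizontal class grid."""
    if vertical_class not in (1, 2, 3, 4):
        raise ValueError(f"vertical class must be 1-4, got {vertical_class!r}")
    if horizontal_class not in ("C", "F", "B", "L", "R"):
        raise ValueError(f"horizontal class must be one of C/F/B/L/R, got {horizontal_class!r}")
    if target_branch not in TARGET_BRANCHES:
        raise ValueError(f"target branch must be one of {TARGET_BRANCHES}, got {target_branch!r}")

    la_x = network.carrier_of("LA").ostium_axial_position
    fa_x = network.carrier_of("FA").ostium_axial_position
    target_carrier = network.carrier_of(target_branch)
    theta_t = target_carrier.ostium_angle
    if theta_t is None:
        raise ValueError(f"target branch {target_branch!r} has no ostium angle")

    if vertical_class == 4:
        target_seg = network[target_branch]
        if catheter_radius >= target_seg.radius:
            raise ValueError(
                f"catheter radius {catheter_radius} does not fit inside "
                f"{target_branch} (radius {target_seg.radius})")
        return CatheterPlacement(
            tip_axial_position=target_carrier.ostium_axial_position,
            vertical_class=4, horizontal_class="C", target_branch=target_branch,
            tip_offset=0.0, tip_angle=theta_t, catheter_radius=catheter_radius,
            pivot_distance=pivot_distance, inside_branch=target_branch,
            label=f"{network.case}4")

    x_tip = {1: 0.5 * la_x, 2: la_x, 3: 0.5 * (la_x + fa_x)}[vertical_class]
    if horizontal_class == "C":
        offset, angle = 0.0, theta_t
        labels = {b.name: "C" for b in network.trunk_branches() if b.name in TARGET_BRANCHES}
        label = f"{network.case}{vertical_class}-C"
    else:
        angle = theta_t + {"F": 0.0, "B": math.pi, "L": math.pi / 2, "R": -math.pi / 2}[horizontal_class]
        angle = math.atan2(math.sin(angle), math.cos(angle))
        offset = network.trunk_radius_at(x_tip) / 2.0  # quarter of local diameter
        labels = {}
        for b in network.trunk_branches():
            if b.ostium_angle is not None and (b.name in TARGET_BRANCHES or b.name in _COMMON_TRUNKS):
                labels[b.name] = relative_label(angle, b.ostium_angle)
        label = f"{network.case}{vertical_class}-{target_branch}({horizontal_class})"
    return CatheterPlacement(
        tip_axial_position=x_tip, vertical_class=vertical_class,
        horizontal_class=horizontal_class, target_branch=target_branch,
        tip_offset=offset, tip_angle=angle, catheter_radius=catheter_radius,
        pivot_distance=pivot_distance, label=label, relative_labels=labels)


def enumerate_model_grid(network: VesselNetwork,
                         catheter_radius: float = 0.65e-3) -> list[CatheterPlacement]:
    """The 16-model catheter grid for one network.

    Classes 1–3 each at the center and at the four quarter-diameter shifts
    (enumerated relative to the LA, which by the shared-column convention
    also names the corresponding OA- and FA-relative shifts), plus the single
    superselective class-4 model.  Two networks give the full 32-model set.
    """
    placements = []
    for vclass in (1, 2, 3):
        for h in ("C", "F", "L", "R", "B"):
            placements.append(place_catheter(network, vclass, h, "LA",
                                             catheter_radius=catheter_radius))
    placements.append(place_catheter(network, 4, "C", "LA",
                                     catheter_radius=catheter_radius))
    return placements


# ----------------------------------------------------------------------
# Structured-text (JSON) network files

_SEGMENT_FIELDS = ("id", "name", "radius", "length", "parent",
                   "ostium_angle", "ostium_axial_position")
_REQUIRED_SEGMENT_FIELDS = ("id", "name", "radius", "length", "parent")


def write_network(network: VesselNetwork, path) -> None:
    """Write a network to a structured JSON file (SI units, radians)."""
    doc = {
        "format": "iacflow-network",
        "case": network.case,
        "trunk": {
            "root_radius": network.trunk_root_radius,
            "end_radius": network.trunk_end_radius,
            "length": network.trunk_length,
        },
        "ligated_outlets": sorted(network.ligated_outlets),
        "segments": [
            {k: getattr(s, k) for k in _SEGMENT_FIELDS}
            for s in network.segments
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def read_network(path) -> VesselNetwork:
    """Read a network file written by :func:`write_network`.

    Unknown keys are tolerated with a warning (forward compatibility);
    missing required keys raise a :class:`ValueError` naming the field.
    """
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ValueError(f"malformed network file {path}: {exc}") from exc
    known_top = {"format", "case", "trunk", "ligated_outlets", "segments"}
    _warn_unknown(doc, known_top, "top level")
    for key in ("case", "trunk", "segments"):
        if key not in doc:
            raise ValueError(f"network file missing required field {key!r}")
    trunk = doc["trunk"]
    _warn_unknown(trunk, {"root_radius", "end_radius", "length"}, "trunk")
    for key in ("root_radius", "end_radius", "length"):
        if key not in trunk:
            raise ValueError(f"network file missing required field trunk.{key!r}")
    segments = []
    for entry in doc["segments"]:
        _warn_unknown(entry, set(_SEGMENT_FIELDS), f"segment {entry.get('id', '?')!r}")
        for key in _REQUIRED_SEGMENT_FIELDS:
            if key not in entry:
                raise ValueError(
                    f"segment {entry.get('id', '?')!r} missing required field {key!r}")
        segments.append(VesselSegment(
            id=entry["id"], name=entry["name"], radius=entry["radius"],
            length=entry["length"], parent=entry["parent"],
            ostium_angle=entry.get("ostium_angle"),
            ostium_axial_position=entry.get("ostium_axial_position")))
    return VesselNetwork(
        case=doc["case"], segments=tuple(segments),
        ligated_outlets=frozenset(doc.get("ligated_outlets", ())),
        trunk_root_radius=trunk["root_radius"],
        trunk_end_radius=trunk["end_radius"],
        trunk_length=trunk["length"])


def _warn_unknown(mapping: dict, known: set, where: str) -> None:
    extra = set(mapping) - known
    if extra:
        warnings.warn(f"ignoring unknown keys {sorted(extra)} at {where} of network file",
                      stacklevel=3)
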