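"""Steady laminar network hydraulics with the catheter in place.

The resolved carotid tree is reduced to a resistive network: every vessel
segment is a Poiseuille conductor ``G = πr⁴/(8 μ_m l)``; where the catheter
body occupies the lumen (the ECA trunk between the tip and the ligated STA,
plus the target branch for a superselective tip) the exact concentric-annulus
Poiseuille conductance is used.  Two flow sources drive the network — the CCA
inlet (mean velocity × area) and the catheter tip (prescribed infusion
velocity × lumen area) — and each open outlet drains to a reference ground
either through its lumped peripheral resistance (``zerod`` mode) or at zero
pressure (``zero-pressure`` mode).  Nodal pressures solve the resulting
linear system (dense; the networks have a few tens of nodes).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .vasculature import CatheterPlacement, VesselNetwork

__all__ = [
    "Edge",
    "SolverGraph",
    "FlowSolution",
    "catheter_inlet_velocity",
    "ml_per_hour_to_m3s",
    "reynolds_number",
    "conductance_tube",
    "conductance_annulus",
    "build_solver_graph",
    "solve_linear_network",
    "class4_tip_depth",
]


def ml_per_hour_to_m3s(rate_ml_h: float) -> float:
    return rate_ml_h * 1e-6 / 3600.0


def catheter_inlet_velocity(infusion_rate: float, catheter_diameter: float) -> float:
    """Uniform tip velocity (m/s) from the volumetric infusion rate (m³/s)."""
    if infusion_rate < 0 or catheter_diameter <= 0:
        raise ValueError("infusion rate must be non-negative, diameter positive")
    return infusion_rate / (math.pi * (catheter_diameter / 2.0) ** 2)


def reynolds_number(rho: float, velocity: float, diameter: float, mu: float) -> float:
    """Tube Reynolds number ρ·v·d/μ."""
    if rho <= 0 or diameter <= 0 or mu <= 0:
        raise ValueError("density, diameter and viscosity must be positive")
    return rho * velocity * diameter / mu


def conductance_tube(radius: float, length: float, mu: float) -> float:
    """Open-tube Poiseuille conductance πr⁴/(8μl) (m³/s per Pa)."""
    if radius <= 0 or length <= 0 or mu <= 0:
        raise ValueError("radius, length and viscosity must be positive")
    return math.pi * radius ** 4 / (8.0 * mu * length)


def conductance_annulus(outer_radius: float, inner_radius: float,
                        length: float, mu: float) -> float:
    """Concentric-annulus Poiseuille conductance (m³/s per Pa).

    ``G = π/(8μl) · [R⁴ − a⁴ − (R² − a²)²/ln(R/a)]``; reduces to the open
    tube as the inner radius vanishes.
    """
    if inner_radius < 0 or inner_radius >= outer_radius:
        raise ValueError("inner radius must satisfy 0 <= a < R")
    if inner_radius == 0.0:
        return conductance_tube(outer_radius, length, mu)
    r2, a2 = outer_radius ** 2, inner_radius ** 2
    k = (outer_radius ** 4 - inner_radius ** 4
         - (r2 - a2) ** 2 / math.log(outer_radius / inner_radius))
    return math.pi * k / (8.0 * mu * length)


def class4_tip_depth(radius: float, length: float) -> float:
    """Axial depth of a superselective tip inside its target branch (m)."""
    return min(0.5 * length, 2.0 * radius)


@dataclass(frozen=True)
class Edge:
    """One hydraulic conductor of the solver graph."""

    id: str
    u: str
    v: str
    radius: float
    length: float
    kind: str = "tube"  # "tube" | "annulus"
    inner_radius: float = 0.0
    segment_id: str | None = None

    def conductance(self, mu: float) -> float:
        if self.kind == "annulus":
            return conductance_annulus(self.radius, self.inner_radius, self.length, mu)
        return conductance_tube(self.radius, self.length, mu)


@dataclass(frozen=True)
class SolverGraph:
    edges: tuple[Edge, ...]
    nodes: tuple[str, ...]
    inlet_node: str
    tip_node: str
    outlet_nodes: dict  # outlet segment id -> node name
    tip_distal_edge: str | None  # trunk edge immediately distal of the tip


def build_solver_graph(network: VesselNetwork, placement: CatheterPlacement) -> SolverGraph:
    """Reduce the network + catheter to a hydraulic graph.

    Trunk conduits are cut at every ostium and at the tip; conduits lying
    between the tip and the STA end carry the catheter and become annular.
    For a class-4 (superselective) tip, the carrier path into the target
    branch is annular down to the tip depth.
    """
    edges: list[Edge] = []
    cath_a = placement.catheter_radius
    class4 = placement.inside_branch is not None

    cca = network["CCA"]
    ica = network["ICA"]
    edges.append(Edge("CCA", "inlet", "bif", cca.radius, cca.length, segment_id="CCA"))
    edges.append(Edge("ICA", "bif", "out:ICA", ica.radius, ica.length, segment_id="ICA"))

    branches = network.trunk_branches()
    events = sorted({b.ostium_axial_position for b in branches})
    node_at = {0.0: "bif"}
    for i, x in enumerate(events, start=1):
        node_at[x] = f"trunk@{i}"

    x_tip = placement.tip_axial_position
    # catheter occupies the trunk from its entry (STA end) down to:
    cath_from = x_tip if not class4 else network.carrier_of(
        placement.inside_branch).ostium_axial_position
    cuts = sorted(set(events) | {0.0, x_tip} | {network.trunk_length})
    tip_on_trunk = not class4
    # the tip may coincide with an ostium node (e.g. a class-2 tip at the
    # LA origin); reuse that node as the injection site in that case
    tip_name = (node_at.get(x_tip, "tip") if tip_on_trunk else "tip")
    for i, (x0, x1) in enumerate(zip(cuts[:-1], cuts[1:])):
        if x1 - x0 <= 1e-12:
            continue
        u = node_at.get(x0, tip_name if (tip_on_trunk and x0 == x_tip) else None)
        v = node_at.get(x1, tip_name if (tip_on_trunk and x1 == x_tip) else None)
        if u is None or v is None:
            raise RuntimeError("trunk cut without node")  # pragma: no cover
        mid_r = network.trunk_radius_at(0.5 * (x0 + x1))
        annular = x0 >= cath_from - 1e-12
        edges.append(Edge(f"trunk[{i}]", u, v, mid_r, x1 - x0,
                          kind="annulus" if annular else "tube",
                          inner_radius=cath_a if annular else 0.0))

    def add_branch(seg, parent_node: str) -> None:
        if seg.id in network.ligated_outlets:
            return  # ligated: treated as a wall, no edge
        kids = network.children(seg.id)
        on_cath_path = class4 and seg.id in network.descend_to(placement.inside_branch)
        if seg.id == placement.inside_branch:
            depth = class4_tip_depth(seg.radius, seg.length)
            edges.append(Edge(f"{seg.id}:annulus", parent_node, "tip", seg.radius,
                              depth, kind="annulus", inner_radius=cath_a,
                              segment_id=seg.id))
            edges.append(Edge(f"{seg.id}:open", "tip", f"out:{seg.id}", seg.radius,
                              seg.length - depth, segment_id=seg.id))
            return
        end_node = f"j:{seg.id}" if kids else f"out:{seg.id}"
        edges.append(Edge(seg.id, parent_node, end_node, seg.radius, seg.length,
                          kind="annulus" if on_cath_path else "tube",
                          inner_radius=cath_a if on_cath_path else 0.0,
                          segment_id=seg.id))
        for kid in kids:
            add_branch(kid, end_node)

    for b in branches:
        add_branch(b, node_at[b.ostium_axial_position])

    nodes = []
    for e in edges:
        for n in (e.u, e.v):
            if n not in nodes:
                nodes.append(n)
    outlet_nodes = {o: f"out:{o}" for o in network.outlet_ids()
                    if f"out:{o}" in nodes}
    tip_distal = None
    if tip_on_trunk:
        for e in edges:
            if e.u == tip_name and e.id.startswith("trunk") and e.kind == "annulus":
                tip_distal = e.id
                break
    return SolverGraph(tuple(edges), tuple(nodes), "inlet", tip_name,
                       outlet_nodes, tip_distal)


@dataclass
class FlowSolution:
    """Converged (or single-pass) steady flow on the solver graph."""

    node_pressure: dict  # Pa
    edge_flow: dict  # edge id -> m3/s, positive u -> v
    branch_flow: dict  # segment id -> m3/s entering the branch
    outlet_flow: dict  # outlet id -> m3/s leaving the domain
    outlet_mass_flow: dict  # outlet id -> kg/s
    outlet_pressure_mmhg: dict
    q_cca: float
    q_injection: float
    trunk_flow_at_tip: float
    mode: str = "zerod"
    iterations: list = field(default_factory=list)
    converged: bool = True

    def mass_balance_residual(self) -> float:
        """|Σ outlet flow − (CCA + catheter inflow)| / total inflow."""
        total_in = self.q_cca + self.q_injection
        return abs(sum(self.outlet_flow.values()) - total_in) / total_in


def solve_linear_network(graph: SolverGraph, mu_edge: dict, q_cca: float,
                         q_injection: float, mode: str = "zerod",
                         outlet_resistance_si: dict | None = None) -> dict:
    """Solve nodal pressures and edge flows for fixed viscosities and outlets.

    ``outlet_resistance_si`` maps outlet segment id to a lumped resistance in
    Pa/(m³/s) (``zerod`` mode); in ``zero-pressure`` mode outlets are held at
    the zero reference pressure.  Returns ``{"pressure": .., "flow": ..}``.
    """
    idx = {n: i for i, n in enumerate(graph.nodes)}
    n = len(graph.nodes)
    a = np.zeros((n, n))
    b = np.zeros(n)
    cond = {}
    for e in graph.edges:
        g = e.conductance(mu_edge.get(e.id, mu_edge.get("default")))
        cond[e.id] = g
        i, j = idx[e.u], idx[e.v]
        a[i, i] += g
        a[j, j] += g
        a[i, j] -= g
        a[j, i] -= g
    b[idx[graph.inlet_node]] += q_cca
    if graph.tip_node in idx:
        b[idx[graph.tip_node]] += q_injection
    if mode == "zerod":
        if outlet_resistance_si is None:
            raise ValueError("zerod mode requires outlet resistances")
        for outlet, node in graph.outlet_nodes.items():
            a[idx[node], idx[node]] += 1.0 / outlet_resistance_si[outlet]
    elif mode == "zero-pressure":
        for node in graph.outlet_nodes.values():
            i = idx[node]
            a[i, :] = 0.0
            a[i, i] = 1.0
            b[i] = 0.0
    else:
        raise ValueError(f"unknown outlet boundary mode {mode!r}")
    try:
        p = np.linalg.solve(a, b)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular hydraulic network (disconnected outlet?)") from exc
    pressure = {node: p[idx[node]] for node in graph.nodes}
    flow = {e.id: cond[e.id] * (pressure[e.u] - pressure[e.v]) for e in graph.edges}
    return {"pressure": pressure, "flow": flow}
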