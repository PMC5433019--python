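"""Coupled steady solution: network flow ↔ 0D outlet pressures ↔ species.

The outer fixed-point loop mirrors the multiscale coupling of the full
simulation: (i) every outlet's peripheral-tree resistance is rebuilt from the
current outlet flow and agent fraction (terminal update, ``zerod`` mode);
(ii) the resistive network is solved for flows with mixture viscosities from
the current agent distribution; (iii) the streamtube transport redistributes
the injected agent.  Convergence is monitored on the per-outlet agent mass
flows, declared when their change falls below ``agent_tol`` (default
1e-9 kg/s, well under 0.01% of the injected flux).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .flow import (FlowSolution, SolverGraph, build_solver_graph,
                   ml_per_hour_to_m3s, solve_linear_network)
from .peripheral import (MMHG_PA, PeripheralTreeSpec, ResistanceState,
                         update_terminal_state)
from .rheology import RheologyParams, mixture_density, mixture_viscosity
from .transport import (DistributionReport, SpeciesField, advect_species,
                        agent_fraction_from_flux)
from .vasculature import CatheterPlacement, VesselNetwork

__all__ = [
    "BoundaryConditions",
    "SolverOptions",
    "SimulationResult",
    "solve_flow",
]


@dataclass(frozen=True)
class BoundaryConditions:
    """Inflow boundary data.

    ``tip_velocity`` is the clinically prescribed uniform injection velocity
    (0.01 m/s for 50 mL/h through the 1.3 mm catheter); set
    ``infusion_rate_ml_h`` to derive the velocity from an exact rate instead.
    """

    cca_mean_velocity: float = 0.38  # m/s, patient-measured mean CCA velocity
    tip_velocity: float = 0.01  # m/s
    infusion_rate_ml_h: float | None = None

    def injection_flow(self, catheter_radius: float) -> float:
        if self.infusion_rate_ml_h is not None:
            return ml_per_hour_to_m3s(self.infusion_rate_ml_h)
        return self.tip_velocity * math.pi * catheter_radius ** 2


@dataclass(frozen=True)
class SolverOptions:
    max_iterations: int = 60
    agent_tol: float = 1e-9  # kg/s, convergence of monitored agent mass flows
    n_r: int = 50
    n_theta: int = 160  # 50 x 160 = 8000 streamtubes
    diffusion_coefficient: float = 0.0  # m2/s; 0 = pure advection
    relax: float = 1.0  # under-relaxation of the outlet Y0 update


@dataclass
class SimulationResult:
    flow: FlowSolution
    species: SpeciesField
    report: DistributionReport
    resistance_state: ResistanceState | None
    graph: SolverGraph
    converged: bool
    iterations: list


def _edge_y0(graph: SolverGraph, network: VesselNetwork,
             placement: CatheterPlacement, report: DistributionReport | None) -> dict:
    """Per-edge agent mass fraction used for the mixture viscosity."""
    if report is None:
        return {}
    y0 = {}
    agent_out = report.agent_mass_flow
    # branch edges inherit the y0 of the outlets they feed
    for e in graph.edges:
        if e.segment_id and e.segment_id not in ("CCA", "ICA"):
            leaves = _leaves_under(network, e.segment_id)
            a = sum(agent_out.get(l, 0.0) for l in leaves)
            q = sum(report.outlet_flow.get(l, 0.0) for l in leaves)
            y0[e.id] = agent_fraction_from_flux(a, q)
    # trunk pieces distal of the tip carry Y0 of order 1e-3 at these flow
    # ratios; their viscosity is left at the blood value (< 0.1% effect)
    return y0


def _leaves_under(network: VesselNetwork, seg_id: str) -> list:
    kids = network.children(seg_id)
    if not kids:
        return [seg_id]
    out = []
    for k in kids:
        out.extend(_leaves_under(network, k.id))
    return out


def solve_flow(
    network: VesselNetwork,
    placement: CatheterPlacement,
    boundary: BoundaryConditions = BoundaryConditions(),
    mode: str = "zerod",
    rheology: RheologyParams = RheologyParams(),
    options: SolverOptions = SolverOptions(),
    resistance_state: ResistanceState | None = None,
) -> SimulationResult:
    """Solve the coupled flow/transport problem for one catheter model.

    ``mode`` selects the outlet boundary condition: ``"zerod"`` couples each
    outlet to its self-similar peripheral tree; ``"zero-pressure"`` holds
    outlets at the zero reference.  Passing ``resistance_state`` freezes the
    outlet resistances (e.g. to the tabulated patient values) instead of
    rebuilding them from the peripheral model.
    """
    graph = build_solver_graph(network, placement)
    outlets = list(graph.outlet_nodes)
    rho_blood = rheology.blood.density
    q_cca = boundary.cca_mean_velocity * math.pi * network["CCA"].radius ** 2
    q_inj = boundary.injection_flow(placement.catheter_radius)
    total_in = q_cca + q_inj

    fixed_resistance = resistance_state is not None
    specs = {
        o: PeripheralTreeSpec(root_radius=network[o].radius, rheology=rheology)
        for o in outlets
    }
    q_out = {o: total_in / len(outlets) for o in outlets}
    y0_out = {o: 0.0 for o in outlets}
    report = None
    state = resistance_state
    log: list[dict] = []
    prev_agent = None
    converged = False

    for it in range(options.max_iterations):
        if mode == "zerod" and not fixed_resistance:
            state = update_terminal_state(specs, q_out, y0_out)
        if mode == "zerod":
            r_si = {o: state.resistance_si(o) for o in outlets}
        else:
            r_si = None

        mu_edge = _edge_y0(graph, network, placement, report)
        mu_map = {eid: mixture_viscosity(y) for eid, y in mu_edge.items()}
        mu_map["default"] = rheology.blood.viscosity
        sol = solve_linear_network(graph, mu_map, q_cca, q_inj, mode, r_si)

        flow = _assemble_flow_solution(graph, network, sol, q_cca, q_inj,
                                       mode, r_si, y0_out, rheology)
        species, report = advect_species(
            flow, network, placement, n_r=options.n_r, n_theta=options.n_theta,
            diffusion_coefficient=options.diffusion_coefficient,
            agent=rheology.agent, blood=rheology.blood)

        new_y0 = report.outlet_y0
        y0_out = {o: (1 - options.relax) * y0_out[o] + options.relax * new_y0[o]
                  for o in outlets}
        q_out = {o: max(flow.outlet_flow[o], 1e-12) for o in outlets}

        agent = [report.agent_mass_flow[o] for o in outlets]
        delta = (max(abs(a - b) for a, b in zip(agent, prev_agent))
                 if prev_agent is not None else float("inf"))
        log.append({"iteration": it, "agent_delta_kg_s": delta,
                    "mass_balance_residual": flow.mass_balance_residual()})
        prev_agent = agent
        if delta < options.agent_tol:
            converged = True
            break

    if not converged:
        raise RuntimeError(
            "coupled solve did not converge within "
            f"{options.max_iterations} iterations; residual history: "
            + ", ".join(f"{e['agent_delta_kg_s']:.3e}" for e in log[-5:]))
    flow.iterations = log
    flow.converged = converged
    return SimulationResult(flow=flow, species=species, report=report,
                            resistance_state=state if mode == "zerod" else None,
                            graph=graph, converged=converged, iterations=log)


def _assemble_flow_solution(graph, network, sol, q_cca, q_inj, mode, r_si,
                            y0_out, rheology) -> FlowSolution:
    flow_e = sol["flow"]
    pressure = sol["pressure"]
    branch_flow = {}
    for e in graph.edges:
        if e.segment_id:
            # the edge entering a branch (carrier part for split segments)
            if e.id.endswith(":open"):
                continue
            branch_flow[e.segment_id] = flow_e[e.id]
    outlet_flow = {}
    for o, node in graph.outlet_nodes.items():
        q = sum(flow_e[e.id] for e in graph.edges if e.v == node)
        q -= sum(flow_e[e.id] for e in graph.edges if e.u == node)
        outlet_flow[o] = q
    outlet_mass = {}
    outlet_p = {}
    for o in outlet_flow:
        rho = mixture_density(y0_out.get(o, 0.0), rheology.agent, rheology.blood)
        outlet_mass[o] = rho * outlet_flow[o]
        if mode == "zerod":
            outlet_p[o] = pressure[graph.outlet_nodes[o]] / MMHG_PA
        else:
            outlet_p[o] = 0.0
    trunk_at_tip = (flow_e[graph.tip_distal_edge] if graph.tip_distal_edge
                    else sum(outlet_flow.values()))
    return FlowSolution(
        node_pressure=pressure, edge_flow=flow_e, branch_flow=branch_flow,
        outlet_flow=outlet_flow, outlet_mass_flow=outlet_mass,
        outlet_pressure_mmhg=outlet_p, q_cca=q_cca, q_injection=q_inj,
        trunk_flow_at_tip=trunk_at_tip, mode=mode)
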