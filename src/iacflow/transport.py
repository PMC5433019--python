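"""Cross-sectional streamtube transport of the infused agent.

The agent is advected with the blood; at the tip Reynolds number (~13) the
injection momentum is negligible, so the injected fluid simply joins the
local streamtubes of the ECA trunk.  The trunk cross-section at the tip is
decomposed into polar streamtubes weighted by the Poiseuille velocity
profile; the catheter tip seeds the streamtubes covered by the injection
disc with agent, and each downstream branch ostium captures a contiguous
angular sector centred on its distal-view angle, widened symmetrically until
the captured streamtube flow matches the branch's solved flow.  Agent mass
flux is carried per streamtube, so its delivery to each outlet follows the
streamline-contact mechanism: a branch receives agent exactly when its
capture region intersects the injection disc (in the zero-diffusion limit).

An optional inter-streamtube exchange models transverse diffusion; at the
physical diffusivity of the agent (2.299e-9 m²/s) the Péclet number is so
large that the exchange is negligible, and it is off by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .flow import FlowSolution
from .rheology import AGENT, BLOOD, FluidSpecies
from .vasculature import CatheterPlacement, VesselNetwork

__all__ = [
    "StreamtubeGrid",
    "SpeciesField",
    "DistributionReport",
    "advect_species",
    "streamline_contact",
    "agent_fraction_from_flux",
]


def agent_fraction_from_flux(agent_mass_flow: float, volumetric_flow: float,
                             agent: FluidSpecies = AGENT,
                             blood: FluidSpecies = BLOOD) -> float:
    """Agent mass fraction Y₀ consistent with a mixture carrying the given
    agent mass flux in the given volumetric flow.

    Solves ``Y₀ · ρ_m(Y₀) · Q = ṁ_agent`` in closed form.
    """
    if volumetric_flow <= 0:
        return 0.0
    alpha = agent_mass_flow / volumetric_flow  # kg of agent per m3 of mixture
    r0, r1 = agent.density, blood.density
    y0 = alpha * r0 / (r0 * r1 - alpha * (r1 - r0))
    return float(min(max(y0, 0.0), 1.0))


@dataclass(frozen=True)
class StreamtubeGrid:
    """Polar decomposition of a circular cross-section into streamtubes.

    Rings are equal-area; each ring is split into ``n_theta`` sectors.  The
    flow weight of a ring follows the Poiseuille profile: for normalized
    squared radius s = (r/R)², the flow fraction between s₀ and s₁ is
    (s₁ − s₀)(2 − s₀ − s₁).
    """

    radius: float
    n_r: int = 50
    n_theta: int = 160

    def cells(self):
        """(r, theta, weight, x, y) arrays of all streamtube cells, flattened."""
        s_edges = np.linspace(0.0, 1.0, self.n_r + 1)
        s0, s1 = s_edges[:-1], s_edges[1:]
        ring_frac = (s1 - s0) * (2.0 - s0 - s1)
        r_cent = self.radius * np.sqrt(0.5 * (s0 + s1))
        theta = (np.arange(self.n_theta) + 0.5) * 2.0 * math.pi / self.n_theta
        rr = np.repeat(r_cent, self.n_theta)
        tt = np.tile(theta, self.n_r)
        ww = np.repeat(ring_frac / self.n_theta, self.n_theta)
        return rr, tt, ww, rr * np.cos(tt), rr * np.sin(tt)


@dataclass
class SpeciesField:
    """Streamtube state at the tip cross-section and its capture bookkeeping."""

    grid: StreamtubeGrid
    q: np.ndarray  # per-streamtube volumetric flow at the tip plane (m3/s)
    m0: np.ndarray  # per-streamtube agent mass flux as injected (kg/s)
    disc_mask: np.ndarray  # streamtubes seeded by the catheter tip
    capture_fraction: dict  # branch segment id -> fraction of each cell captured
    branch_y0: dict = field(default_factory=dict)  # segment id -> agent mass fraction
    trunk_y0: dict = field(default_factory=dict)  # trunk edge id -> Y0 downstream of tip


@dataclass
class DistributionReport:
    """Per-outlet agent delivery, Tables-style."""

    injected_mass_flow: float  # kg/s of agent leaving the catheter tip
    agent_mass_flow: dict  # outlet id -> kg/s
    rate_pct: dict  # outlet id -> % of injected
    contact: dict  # branch id -> streamline-contact flag
    outlet_flow: dict  # outlet id -> m3/s (mixture)
    outlet_y0: dict  # outlet id -> agent mass fraction

    def to_dataframe(self):
        import pandas as pd

        rows = [
            {
                "outlet": o,
                "mass_flow_kg_s": self.agent_mass_flow[o],
                "distribution_rate_pct": self.rate_pct[o],
                "contact_flag": bool(self.contact.get(o, False)),
            }
            for o in self.agent_mass_flow
        ]
        return pd.DataFrame(rows)


def _wrapped_angular_distance(theta: np.ndarray, target: float) -> np.ndarray:
    d = np.abs((theta - target + math.pi) % (2.0 * math.pi) - math.pi)
    return d


def _disc_overlap_fraction(grid: StreamtubeGrid, cx: float, cy: float,
                           disc_radius: float, n_sub: int = 4) -> np.ndarray:
    """Fraction of each streamtube cell lying inside the injection disc.

    Deterministic sub-sampling (n_sub² points per cell in the equal-area
    (s, θ) parameterization); smooth seeding of partially covered cells is
    what makes the delivered fractions converge under grid refinement.
    """
    s_edges = np.linspace(0.0, 1.0, grid.n_r + 1)
    t_edges = np.arange(grid.n_theta + 1) * 2.0 * math.pi / grid.n_theta
    offs = (np.arange(n_sub) + 0.5) / n_sub
    s_sub = s_edges[:-1, None] + np.diff(s_edges)[:, None] * offs[None, :]
    t_sub = t_edges[:-1, None] + (2.0 * math.pi / grid.n_theta) * offs[None, :]
    r_sub = grid.radius * np.sqrt(s_sub)  # (n_r, n_sub)
    # broadcast to (n_r, n_sub_r, n_theta, n_sub_t)
    rr = r_sub[:, :, None, None]
    tt = t_sub[None, None, :, :]
    inside = ((rr * np.cos(tt) - cx) ** 2 + (rr * np.sin(tt) - cy) ** 2
              <= disc_radius ** 2)
    frac = inside.mean(axis=(1, 3))  # (n_r, n_theta)
    return frac.ravel()


def _sector_capture(q: np.ndarray, remaining: np.ndarray, n_r: int,
                    n_theta: int, ostium_angle: float, q_branch: float
                    ) -> np.ndarray:
    """Fraction of each cell captured by a branch of flow ``q_branch``.

    The capture region is a contiguous angular sector centred on the ostium
    angle, widened symmetrically until the still-available streamtube flow
    inside it matches the branch flow; the boundary columns are taken
    fractionally, which keeps the captured agent a smooth function of the
    flows and of the grid resolution.
    """
    theta = (np.arange(n_theta) + 0.5) * 2.0 * math.pi / n_theta
    dtheta = np.round(_wrapped_angular_distance(theta, ostium_angle), 12)
    avail = (remaining * q).reshape(n_r, n_theta)
    col_avail = avail.sum(axis=0)
    col_frac = np.zeros(n_theta)
    taken = 0.0
    for d in np.unique(dtheta):  # ascending angular distance, symmetric pairs
        cols = np.nonzero(dtheta == d)[0]
        g_flow = col_avail[cols].sum()
        if g_flow <= 0.0:
            col_frac[cols] = 1.0  # nothing left here; widen through it
            continue
        if taken + g_flow <= q_branch:
            col_frac[cols] = 1.0
            taken += g_flow
        else:
            col_frac[cols] = (q_branch - taken) / g_flow
            taken = q_branch
            break
    return (remaining.reshape(n_r, n_theta) * col_frac[None, :]).ravel()


def _leaf_flows(network: VesselNetwork, seg_id: str, flow: FlowSolution) -> dict:
    kids = network.children(seg_id)
    if not kids:
        return {seg_id: flow.outlet_flow.get(seg_id, flow.branch_flow.get(seg_id, 0.0))}
    out: dict = {}
    for kid in kids:
        out.update(_leaf_flows(network, kid.id, flow))
    return out


def _diffuse(m: np.ndarray, grid: StreamtubeGrid, beta: float) -> np.ndarray:
    """One symmetric neighbour-exchange step on the polar grid (conservative)."""
    field2 = m.reshape(grid.n_r, grid.n_theta)
    lap = (np.roll(field2, 1, axis=1) + np.roll(field2, -1, axis=1) - 2 * field2)
    radial = np.zeros_like(field2)
    radial[1:, :] += field2[:-1, :] - field2[1:, :]
    radial[:-1, :] += field2[1:, :] - field2[:-1, :]
    return (field2 + beta * (lap + radial)).ravel()


def advect_species(
    flow: FlowSolution,
    network: VesselNetwork,
    placement: CatheterPlacement,
    n_r: int = 50,
    n_theta: int = 160,
    diffusion_coefficient: float = 0.0,
    agent: FluidSpecies = AGENT,
    blood: FluidSpecies = BLOOD,
) -> tuple[SpeciesField, DistributionReport]:
    """Advect the injected agent from the tip to the outlets.

    Requires a solved :class:`~iacflow.flow.FlowSolution`.  Agent mass flux
    is conserved exactly: the per-outlet fluxes sum to the injected flux.
    """
    injected = agent.density * flow.q_injection
    outlets = network.outlet_ids()
    agent_out = {o: 0.0 for o in outlets}
    contact = {o: False for o in outlets}

    if placement.inside_branch is not None:
        # superselective: the entire infusion enters the target branch
        leaves = _leaf_flows(network, placement.inside_branch, flow)
        total = sum(leaves.values())
        for leaf, q in leaves.items():
            agent_out[leaf] = injected * (q / total if total > 0 else 1.0 / len(leaves))
            contact[leaf] = True
        grid = StreamtubeGrid(network[placement.inside_branch].radius, 1, 1)
        species = SpeciesField(grid, np.array([flow.trunk_flow_at_tip]),
                               np.array([injected]), np.array([True]), {})
    else:
        x_tip = placement.tip_axial_position
        r_tip = network.trunk_radius_at(x_tip)
        grid = StreamtubeGrid(r_tip, n_r, n_theta)
        rr, tt, ww, xx, yy = grid.cells()
        q = flow.trunk_flow_at_tip * ww

        cx = placement.tip_offset * math.cos(placement.tip_angle)
        cy = placement.tip_offset * math.sin(placement.tip_angle)
        frac_in = _disc_overlap_fraction(grid, cx, cy, placement.catheter_radius)
        if frac_in.sum() == 0.0:  # disc smaller than one cell
            frac_in = np.zeros_like(q)
            frac_in[np.argmin((xx - cx) ** 2 + (yy - cy) ** 2)] = 1.0
        disc = frac_in > 0.0
        # agent joins the covered streamtubes in proportion to their covered
        # flow, capped at pure agent in the covered part (m <= rho0 * q * f)
        seed = q * frac_in
        m = np.minimum(injected * seed / seed.sum(), agent.density * seed)
        short = injected - m.sum()
        if short > 1e-18 * injected:  # cap engaged: spill to nearest tubes
            order = np.argsort((xx - cx) ** 2 + (yy - cy) ** 2)
            for k in order:
                room = agent.density * q[k] - m[k]
                take = min(room, short)
                m[k] += take
                short -= take
                if short <= 0:
                    break
        m *= injected / m.sum()  # exact conservation of the injected flux

        m0 = m.copy()
        capture_fraction: dict = {}
        trunk_y0: dict = {}
        remaining = np.ones_like(q)
        capture_branches = [
            b for b in network.trunk_branches()
            if b.ostium_axial_position > x_tip + 1e-12
            and b.ostium_angle is not None and b.id not in network.ligated_outlets
        ]
        beta = 0.0
        if diffusion_coefficient > 0.0:
            v_mean = flow.trunk_flow_at_tip / (math.pi * r_tip ** 2)
            cell_size = r_tip / n_r
            prev_x = x_tip
        for b in sorted(capture_branches, key=lambda b: b.ostium_axial_position):
            if diffusion_coefficient > 0.0:
                dt = (b.ostium_axial_position - prev_x) / max(v_mean, 1e-12)
                beta = min(0.2, diffusion_coefficient * dt / cell_size ** 2)
                m = _diffuse(m, grid, beta)
                prev_x = b.ostium_axial_position
            q_b = flow.branch_flow.get(b.id, 0.0)
            frac = np.zeros_like(q)
            if q_b > 0.0:
                frac = _sector_capture(q, remaining, n_r, n_theta,
                                       b.ostium_angle, q_b)
                remaining = remaining - frac
            capture_fraction[b.id] = frac
            # frac is a fraction of the *original* cell; the agent still in
            # the trunk lives in the cell's uncaptured part, so the branch
            # takes frac / (fraction remaining before this capture) of it
            rem_before = frac + remaining
            take_of_current = np.where(frac > 0, frac / np.maximum(rem_before, 1e-300), 0.0)
            captured_m = float((take_of_current * m).sum())
            m = m * (1.0 - take_of_current)
            # distribute to the leaves under this branch in proportion to flow
            leaves = _leaf_flows(network, b.id, flow)
            total = sum(leaves.values())
            for leaf, ql in leaves.items():
                share = ql / total if total > 0 else 1.0 / len(leaves)
                agent_out[leaf] += captured_m * share
            if bool((frac[disc] > 0).any()):
                for leaf in leaves:
                    contact[leaf] = True
        # remainder continues into the trunk-end vessels (MA; STA is ligated)
        end_branches = [
            b for b in network.trunk_branches()
            if b.ostium_axial_position > x_tip + 1e-12
            and b.ostium_angle is None and b.id not in network.ligated_outlets
        ]
        leftover = injected - sum(agent_out.values())
        if end_branches:
            flows = {b.id: flow.branch_flow.get(b.id, 0.0) for b in end_branches}
            total = sum(flows.values())
            for b in end_branches:
                leaves = _leaf_flows(network, b.id, flow)
                sub = sum(leaves.values())
                share_b = flows[b.id] / total if total > 0 else 1.0 / len(end_branches)
                for leaf, ql in leaves.items():
                    agent_out[leaf] += leftover * share_b * (
                        ql / sub if sub > 0 else 1.0 / len(leaves))
                if leftover > 1e-15 * injected:
                    for leaf in leaves:
                        contact[leaf] = True
        species = SpeciesField(grid, q, m0, disc, capture_fraction, trunk_y0=trunk_y0)

    rate = {o: 100.0 * agent_out[o] / injected for o in outlets}
    y0_out = {o: agent_fraction_from_flux(agent_out[o], flow.outlet_flow.get(o, 0.0),
                                          agent, blood) for o in outlets}
    species.branch_y0 = y0_out
    report = DistributionReport(
        injected_mass_flow=injected,
        agent_mass_flow=agent_out,
        rate_pct=rate,
        contact=contact,
        outlet_flow=dict(flow.outlet_flow),
        outlet_y0=y0_out,
    )
    return species, report


def streamline_contact(species: SpeciesField, report: DistributionReport,
                       branch: str) -> bool:
    """True iff the branch's capture region intersects the injection disc.

    In the zero-diffusion limit this is equivalent to a nonzero agent
    delivery to the branch.
    """
    if branch in report.contact:
        return bool(report.contact[branch])
    frac = species.capture_fraction.get(branch)
    if frac is None:
        return False
    return bool((frac[species.disc_mask] > 0).any())
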