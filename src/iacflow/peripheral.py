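"""Self-similar 0D peripheral resistance model for outlet boundary conditions.

Each outlet of the resolved carotid network is terminated by a lumped,
structured binary tree: every parent vessel splits into two identical
daughters carrying half the flow, with daughter radius reduced by the Murray
factor 2^(−1/3), down to a terminal radius of 12 μm where a fixed terminal
pressure of 30 mmHg is imposed.  Each generation contributes its Poiseuille
resistance 8μλ/(πr³) (λ = length/radius taken from the diameter group it
falls in); two identical daughters in parallel halve the daughter-side
resistance, and the terminal resistance P_terminal/Q_terminal is updated with
the current outlet flow so that the periphery always drains to the
physiological terminal pressure.

Internally everything is SI (Pa, m³/s → Pa·s/m³); resistances are reported
in mmHg/(kg/s) at the interface, matching clinical convention.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

from .rheology import RheologyParams, blood_viscosity_0d, mixture_density

__all__ = [
    "MMHG_PA",
    "VesselGroup",
    "DEFAULT_GROUPS",
    "PeripheralTreeSpec",
    "ResistanceState",
    "group_for_diameter",
    "segment_resistance",
    "build_tree_resistance",
    "outlet_pressure",
    "update_terminal_state",
    "resistance_si_to_mmhg_per_kg_s",
]

MMHG_PA = 133.322  # Pa per mmHg


@dataclass(frozen=True)
class VesselGroup:
    """One diameter class of the peripheral network (mm units, as tabulated)."""

    name: str
    mean_diameter_mm: float
    min_diameter_mm: float
    length_mm: float
    lam: float  # ratio of vessel length to vessel radius

    def lam_from_geometry(self) -> float:
        return self.length_mm / (self.mean_diameter_mm / 2.0)


#: Diameter groups of the peripheral network.  The ICA row's λ is kept as
#: tabulated even though it is not length/radius-consistent; the arterioles
#: row uses the self-consistent parse (length 2 mm, λ 40).  The capillary
#: group is only reached if the terminal radius is lowered below its default.
DEFAULT_GROUPS = (
    VesselGroup("ICA", 5.4834, 4.0, 117.3925, 50.0154),
    VesselGroup("large arteries", 6.5, 2.0, 200.0, 61.5385),
    VesselGroup("main artery branches", 2.4, 1.2, 100.0, 83.3333),
    VesselGroup("terminal artery branches", 1.2, 0.1, 10.0, 16.6667),
    VesselGroup("arterioles", 0.1, 0.015, 2.0, 40.0),
    VesselGroup("capillaries", 0.008, 0.004, 1.0, 250.0),
)


def group_for_diameter(d_m: float, groups: tuple[VesselGroup, ...] = DEFAULT_GROUPS) -> VesselGroup:
    """Diameter group of a vessel of diameter ``d_m`` (m).

    The group with the smallest mean diameter not below ``d_m`` is chosen
    (clamped to the largest group above the table's range), so each vessel
    inherits the λ of the finest class it still fits into.
    """
    if d_m <= 0:
        raise ValueError("diameter must be positive")
    d_mm = d_m * 1e3
    for g in sorted(groups, key=lambda g: g.mean_diameter_mm):
        if d_mm <= g.mean_diameter_mm:
            return g
    return max(groups, key=lambda g: g.mean_diameter_mm)


def segment_resistance(radius: float, lam: float, mu: float) -> float:
    """Poiseuille resistance 8μλ/(πr³) = 8μl/(πr⁴) of one segment (Pa·s/m³)."""
    if radius <= 0 or lam < 0 or mu <= 0:
        raise ValueError("radius and viscosity must be positive, lambda non-negative")
    return 8.0 * mu * lam / (math.pi * radius ** 3)


@dataclass(frozen=True)
class PeripheralTreeSpec:
    """Geometry and boundary data of one outlet's peripheral tree."""

    root_radius: float  # m, radius of the resolved outlet feeding the tree
    terminal_radius: float = 12e-6  # m
    p_terminal_mmhg: float = 30.0
    radius_ratio: float = 2.0 ** (-1.0 / 3.0)  # Murray daughter/parent ratio
    groups: tuple[VesselGroup, ...] = DEFAULT_GROUPS
    rheology: RheologyParams = field(default=RheologyParams())

    def __post_init__(self) -> None:
        if self.root_radius <= self.terminal_radius:
            raise ValueError("root radius must exceed the terminal radius")
        if not 0.0 < self.radius_ratio < 1.0:
            raise ValueError("radius_ratio must lie in (0, 1) for a decreasing taper")
        if self.p_terminal_mmhg <= 0:
            raise ValueError("terminal pressure must be positive")

    def generation_radii(self) -> list[float]:
        """Radii of generations 0..n, ending at the first radius ≤ terminal."""
        radii = [self.root_radius]
        while radii[-1] > self.terminal_radius:
            radii.append(radii[-1] * self.radius_ratio)
        return radii


def build_tree_resistance(spec: PeripheralTreeSpec, y0: float, root_flow: float) -> float:
    """Root input resistance of the peripheral tree (Pa·s/m³).

    Backward recursion from the terminal generation: the terminal load is
    P_terminal/Q_terminal with Q_terminal the root flow halved at each of the
    n bifurcations; each generation adds its viscous resistance, and the two
    identical daughters in parallel halve the daughter-side input resistance.
    """
    if root_flow <= 0:
        raise ValueError("root flow must be positive")
    radii = spec.generation_radii()
    n = len(radii) - 1  # number of bifurcations down to the terminals
    q_terminal = root_flow / 2.0 ** n
    p_terminal = spec.p_terminal_mmhg * MMHG_PA
    r_load = p_terminal / q_terminal  # Eq. of the terminal update
    for j in range(n, -1, -1):
        r_j = radii[j]
        group = group_for_diameter(2.0 * r_j, spec.groups)
        mu = blood_viscosity_0d(2.0 * r_j * 1e6, y0, spec.rheology)
        r_in = segment_resistance(r_j, group.lam, mu) + r_load
        if j > 0:
            r_load = 0.5 * r_in  # two identical daughters in parallel
    return r_in


def resistance_si_to_mmhg_per_kg_s(r_si: float, rho: float) -> float:
    """Convert Pa/(m³/s) to mmHg/(kg/s) for a fluid of density ``rho``."""
    return r_si / (MMHG_PA * rho)


def outlet_pressure(resistance_mmhg_per_kg_s: float, mass_flow: float,
                    p_floor_mmhg: float = 30.0) -> float:
    """Outlet pressure (mmHg) from the lumped resistance and outlet mass flow.

    A negative (reverse) outlet flow has no defined behaviour in a pure
    resistance model; it is flagged with a warning and the pressure is
    floored at the terminal pressure.
    """
    if resistance_mmhg_per_kg_s <= 0:
        raise ValueError("resistance must be positive")
    if mass_flow < 0:
        warnings.warn("reverse flow at a resistance outlet; pressure floored "
                      "at the terminal pressure", stacklevel=2)
        return p_floor_mmhg
    return resistance_mmhg_per_kg_s * mass_flow


@dataclass(frozen=True)
class ResistanceState:
    """Converged per-outlet 0D state (reporting units: mmHg, kg/s)."""

    resistance_mmhg_per_kg_s: dict
    y0: dict
    pressure_mmhg: dict

    def resistance_si(self, outlet: str) -> float:
        rho = mixture_density(self.y0.get(outlet, 0.0))
        return self.resistance_mmhg_per_kg_s[outlet] * MMHG_PA * rho


def update_terminal_state(specs: dict, volumetric_flows: dict, y0: dict | None = None,
                          ) -> ResistanceState:
    """Rebuild every outlet's tree resistance from the current outlet flows.

    One step of the terminal update: with the present flow, the terminal
    resistance is set so that each terminal sits exactly at the terminal
    pressure, and the outlet pressure follows as R·ṁ.  Iterating this step
    against the network solve is the outer coupling loop.
    """
    y0 = y0 or {}
    resist, press = {}, {}
    for outlet, spec in specs.items():
        q = volumetric_flows[outlet]
        if q <= 0:
            raise ValueError(f"outlet {outlet!r}: flow must be positive to update "
                             "the terminal state")
        y = y0.get(outlet, 0.0)
        r_si = build_tree_resistance(spec, y, q)
        rho = mixture_density(y)
        r_rep = resistance_si_to_mmhg_per_kg_s(r_si, rho)
        resist[outlet] = r_rep
        press[outlet] = outlet_pressure(r_rep, rho * q)
    return ResistanceState(resistance_mmhg_per_kg_s=resist,
                           y0={k: y0.get(k, 0.0) for k in specs},
                           pressure_mmhg=press)
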