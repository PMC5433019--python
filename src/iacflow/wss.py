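"""Analytic wall-shear-stress estimation and acute-risk screening.

Fully developed laminar profiles give closed-form wall shear stress for the
two lumen shapes that occur in the reduced model: the open tube
(τ = 4μQ/(πr³)) and the concentric annulus around the catheter body, where
the velocity gradient at both walls follows from the annular Poiseuille
profile.  A catheter inserted into a small branch narrows the lumen to a
thin annulus and sharply raises the wall gradient — the mechanism behind the
elevated shear reported for superselective catheterization — so every
segment's stress is screened against an acute vascular yield threshold
(default 37.9 Pa).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .solver import SimulationResult
from .vasculature import VesselNetwork

__all__ = [
    "ACUTE_YIELD_STRESS_PA",
    "WSSReport",
    "tube_wss",
    "annulus_wss",
    "network_wss",
    "flag_risk",
]

#: Reported acute yield stress of the vascular wall (Pa).
ACUTE_YIELD_STRESS_PA = 37.9


def tube_wss(q: float, radius: float, mu: float) -> float:
    """Poiseuille wall shear stress τ = 4μQ/(πr³) of an open tube (Pa)."""
    if radius <= 0 or mu <= 0:
        raise ValueError("radius and viscosity must be positive")
    return 4.0 * mu * abs(q) / (math.pi * radius ** 3)


def annulus_wss(q: float, outer_radius: float, inner_radius: float,
                mu: float) -> tuple[float, float]:
    """Wall shear stress at both walls of a concentric annulus (Pa).

    Returns ``(τ_vessel, τ_catheter)`` for volumetric flow ``q`` through the
    gap between the vessel wall (outer) and catheter body (inner).  As the
    inner radius vanishes the vessel-wall value reduces to :func:`tube_wss`;
    as it approaches the vessel wall the stress grows without bound.
    """
    if outer_radius <= 0 or mu <= 0:
        raise ValueError("radius and viscosity must be positive")
    if inner_radius < 0 or inner_radius >= outer_radius:
        raise ValueError("inner radius must satisfy 0 <= a < R")
    if inner_radius == 0.0:
        return tube_wss(q, outer_radius, mu), 0.0
    r, a = outer_radius, inner_radius
    ln = math.log(r / a)
    k = r ** 4 - a ** 4 - (r ** 2 - a ** 2) ** 2 / ln
    g = 8.0 * mu * abs(q) / (math.pi * k)  # pressure gradient dP/dx
    b = (r ** 2 - a ** 2) / ln  # radius² of maximum velocity × 2... (2 r_max²)
    tau_vessel = (g / 4.0) * abs(2.0 * r - b / r)
    tau_catheter = (g / 4.0) * abs(2.0 * a - b / a)
    return tau_vessel, tau_catheter


@dataclass
class WSSReport:
    """Per-site wall shear stress (Pa) with risk screening metadata."""

    vessel_wss: dict  # edge id -> Pa at the vessel wall
    catheter_wss: dict  # edge id -> Pa at the catheter wall (annular edges)
    bifurcation_wss: float  # proxy: max of the segments adjoining the bifurcation
    threshold: float = ACUTE_YIELD_STRESS_PA
    placement_label: str = ""

    def max_site(self) -> tuple[str, float]:
        return max(self.vessel_wss.items(), key=lambda kv: kv[1])


def network_wss(result: SimulationResult, network: VesselNetwork,
                mu: float | None = None,
                threshold: float = ACUTE_YIELD_STRESS_PA) -> WSSReport:
    """Evaluate wall shear stress on every solver edge of a converged run.

    Uses the blood viscosity unless ``mu`` overrides it; annular edges
    (catheter present) report both wall values.
    """
    from .rheology import BLOOD

    mu = mu if mu is not None else BLOOD.viscosity
    vessel, catheter = {}, {}
    for e in result.graph.edges:
        q = result.flow.edge_flow[e.id]
        if e.kind == "annulus":
            tv, tc = annulus_wss(q, e.radius, e.inner_radius, mu)
            vessel[e.id] = tv
            catheter[e.id] = tc
        else:
            vessel[e.id] = tube_wss(q, e.radius, mu)
    adjoining = [eid for eid in ("CCA", "ICA", "trunk[0]") if eid in vessel]
    bif = max(vessel[eid] for eid in adjoining) if adjoining else 0.0
    return WSSReport(vessel_wss=vessel, catheter_wss=catheter,
                     bifurcation_wss=bif, threshold=threshold)


def flag_risk(report: WSSReport, threshold: float | None = None) -> list[tuple[str, float]]:
    """Sites whose vessel-wall shear stress exceeds the acute yield threshold."""
    thr = threshold if threshold is not None else report.threshold
    return sorted(((site, tau) for site, tau in report.vessel_wss.items()
                   if tau > thr), key=lambda kv: -kv[1])
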