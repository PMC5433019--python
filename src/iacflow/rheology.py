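"""Blood, agent, and mixture rheology.

The simulated fluid is a two-species mixture of an aqueous anticancer agent
(species 0, water-like) and whole blood (species 1).  In the resolved vessel
network blood is treated as a Newtonian fluid; inside the lumped peripheral
trees the apparent viscosity of blood follows the Fåhraeus–Lindqvist effect,
modelled with the Pries–Secomb in-vitro tube-flow relation together with a
diameter-dependent microvascular hematocrit.

Units: SI throughout (Pa·s, kg/m³, m²/s) except vessel diameters passed to
:func:`hematocrit` and :func:`apparent_viscosity`, which are in micrometres —
the natural unit of the empirical fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FluidSpecies",
    "RheologyParams",
    "AGENT",
    "BLOOD",
    "mixture_density",
    "mixture_viscosity",
    "hematocrit",
    "apparent_viscosity",
    "blood_viscosity_0d",
]


@dataclass(frozen=True)
class FluidSpecies:
    """Physical properties of one species of the infused mixture."""

    name: str
    density: float  # kg/m3
    viscosity: float  # Pa s
    diffusion_coefficient: float | None = None  # m2/s, agent only


#: The anticancer agent is treated as a continuum of water at 25 °C; its
#: diffusion coefficient into blood is the self-diffusion coefficient of water.
AGENT = FluidSpecies("agent", density=998.2, viscosity=1.0e-3,
                     diffusion_coefficient=2.299e-9)

#: Whole blood, Newtonian in the resolved (supra-arteriolar) network.
BLOOD = FluidSpecies("blood", density=1050.0, viscosity=4.6e-3)


@dataclass(frozen=True)
class RheologyParams:
    """Tunable constants of the microvascular viscosity model.

    ``mu_newtonian`` is the asymptotic large-diameter apparent viscosity of
    blood at the systemic hematocrit; the relative Pries–Secomb curve is
    scaled so that its large-diameter limit (relative viscosity 3.2) maps to
    this absolute value, i.e. the implied plasma viscosity is
    ``mu_newtonian / 3.2``.
    """

    hct_systemic: float = 0.45
    d_threshold_um: float = 300.0  # hematocrit reduction sets in below this
    mu_newtonian: float = 4.06e-3  # Pa s, large-diameter blood viscosity
    smooth_hematocrit: bool = False
    agent: FluidSpecies = field(default=AGENT)
    blood: FluidSpecies = field(default=BLOOD)

    def __post_init__(self) -> None:
        if self.hct_systemic <= 0 or self.d_threshold_um <= 0 or self.mu_newtonian <= 0:
            raise ValueError("rheology parameters must be positive")

    @property
    def plasma_scale(self) -> float:
        """Absolute viscosity corresponding to relative viscosity 1 (Pa s)."""
        return self.mu_newtonian / 3.2


def _check_fraction(y0) -> np.ndarray:
    y = np.asarray(y0, dtype=float)
    if np.any(y < 0.0) or np.any(y > 1.0):
        raise ValueError(f"agent mass fraction must lie in [0, 1], got {y0!r}")
    return y


def mixture_density(y0, agent: FluidSpecies = AGENT, blood: FluidSpecies = BLOOD):
    """Density of the agent/blood mixture (kg/m³).

    Harmonic (mass-fraction-weighted specific volume) mean:
    ``1/ρ_m = Y0/ρ_agent + (1 − Y0)/ρ_blood``.
    """
    y = _check_fraction(y0)
    rho = 1.0 / (y / agent.density + (1.0 - y) / blood.density)
    return float(rho) if np.isscalar(y0) else rho


def mixture_viscosity(y0, agent: FluidSpecies = AGENT, blood: FluidSpecies = BLOOD):
    """Viscosity of the agent/blood mixture (Pa·s): linear blend in mass fraction."""
    y = _check_fraction(y0)
    mu = y * agent.viscosity + (1.0 - y) * blood.viscosity
    return float(mu) if np.isscalar(y0) else mu


def hematocrit(d_um, params: RheologyParams = RheologyParams()):
    """Tube hematocrit as a function of vessel diameter ``d_um`` (μm).

    Above the threshold diameter (default 300 μm) the systemic value 0.45 is
    used; below it the empirical reduction
    ``0.45 · (0.196·log10 d − 0.117)`` applies, clipped at zero (the fit
    crosses zero near d ≈ 4 μm, well below the 24 μm terminal diameter of the
    peripheral trees).  The printed law is discontinuous at the threshold;
    ``params.smooth_hematocrit`` rescales the lower branch to be continuous.
    """
    d = np.asarray(d_um, dtype=float)
    if np.any(d <= 0.0):
        raise ValueError(f"vessel diameter must be positive, got {d_um!r}")
    h0 = params.hct_systemic
    reduced = h0 * (0.196 * np.log10(d) - 0.117)
    if params.smooth_hematocrit:
        at_thr = 0.196 * np.log10(params.d_threshold_um) - 0.117
        reduced = h0 * (0.196 * np.log10(d) - 0.117) / at_thr
    hct = np.where(d > params.d_threshold_um, h0, np.clip(reduced, 0.0, h0))
    return float(hct) if np.isscalar(d_um) else hct


def _mu_45_relative(d: np.ndarray) -> np.ndarray:
    # Relative apparent viscosity at Hct = 0.45 (large-d limit 3.2).
    return 6.0 * np.exp(-0.085 * d) + 3.2 - 2.44 * np.exp(-0.06 * d ** 0.645)


def _shape_exponent(d: np.ndarray) -> np.ndarray:
    # Hct-dependence exponent C(d); -> ~1 for d >> 10 um ... actually -> 0
    # for very large d through the 10^-11 d^12 sigmoid.
    sig = 1.0 / (1.0 + 1.0e-11 * d ** 12)
    return (0.8 + np.exp(-0.075 * d)) * (-1.0 + sig) + sig


def apparent_viscosity(d_um, hct, params: RheologyParams = RheologyParams()):
    """Apparent viscosity of blood in a tube of diameter ``d_um`` μm (Pa·s).

    Pries–Secomb in-vitro relation: relative viscosity
    ``μ_rel = 1 + (μ45(d) − 1)·((1 − Hct)^C − 1)/((1 − 0.45)^C − 1)``,
    made absolute with the plasma scale so that ``μ_rel = 3.2`` (the
    large-diameter limit at Hct 0.45) equals ``params.mu_newtonian``.
    The curve is non-monotone in d, with the Fåhraeus–Lindqvist minimum near
    7–10 μm.  Diameters at or below 1.1 μm are rejected.
    """
    d = np.asarray(d_um, dtype=float)
    if np.any(d <= 1.1):
        raise ValueError(f"diameter must exceed 1.1 um, got {d_um!r}")
    h = np.asarray(hct, dtype=float)
    if np.any(h < 0.0) or np.any(h >= 1.0):
        raise ValueError(f"hematocrit must lie in [0, 1), got {hct!r}")
    c = _shape_exponent(d)
    mu45 = _mu_45_relative(d)
    denom = (1.0 - 0.45) ** c - 1.0
    frac = np.where(h > 0.0, ((1.0 - h) ** c - 1.0) / denom, 0.0)
    mu_rel = 1.0 + (mu45 - 1.0) * frac
    mu = mu_rel * params.plasma_scale
    return float(mu) if (np.isscalar(d_um) and np.isscalar(hct)) else mu


def blood_viscosity_0d(d_um, y0: float, params: RheologyParams = RheologyParams()):
    """Viscosity used inside the lumped peripheral trees (Pa·s).

    The diameter-dependent apparent viscosity of blood is blended with the
    agent viscosity using the mixture rule, with a single per-outlet agent
    mass fraction ``y0``.
    """
    if not 0.0 <= y0 <= 1.0:
        raise ValueError(f"agent mass fraction must lie in [0, 1], got {y0!r}")
    mu_app = apparent_viscosity(d_um, hematocrit(d_um, params), params)
    return y0 * params.agent.viscosity + (1.0 - y0) * mu_app
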