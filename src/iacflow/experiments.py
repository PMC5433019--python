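"""Experiment orchestration: catheter sweeps, boundary-condition comparisons,
summary statistics, and the packaged clinical reference tables.

The study design is a grid of catheter models per synthetic network: three
vertical tip classes × five horizontal positions plus one superselective
model (16 per network, 32 for the standard two-network study).  Reference
tables from the source clinical study — per-model distribution rates and
per-outlet 0D resistances — ship as machine-readable fixtures so that
table-level statistics can be computed without running the solver, and so
that solver runs can reuse the tabulated outlet resistances.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from importlib import resources

import pandas as pd

from .peripheral import ResistanceState
from .rheology import RheologyParams
from .solver import BoundaryConditions, SolverOptions, solve_flow
from .vasculature import (NetworkVariantConfig, enumerate_model_grid,
                          generate_network)

__all__ = [
    "RunConfig",
    "run_sweep",
    "compare_outlet_bc",
    "table_means",
    "sweep_table",
    "load_printed_distribution_table",
    "load_printed_resistances",
    "fixture_resistance_state",
    "default_study_config",
]

#: Mean CCA velocities of the two clinical cases (m/s).
CASE_CCA_VELOCITY = {"A": 0.38, "B": 0.43}


def load_printed_distribution_table() -> pd.DataFrame:
    """The tabulated per-model distribution rates of the two clinical cases.

    Long format: one row per (case, model, artery) with the agent mass flow
    (×10⁻⁶ kg/s), the distribution rate (%), and the shared-column relative
    labels of each horizontal position with respect to LA, OA and FA
    (``C`` = centred, ``S`` = superselective class 4).
    """
    with resources.files("iacflow.data").joinpath(
            "printed_distribution_rates.csv").open() as fh:
        return pd.read_csv(fh)


def load_printed_resistances() -> pd.DataFrame:
    """Tabulated per-outlet 0D resistances (mmHg/(kg/s)) and the centred
    class-1 distribution rates under both outlet boundary conditions."""
    with resources.files("iacflow.data").joinpath(
            "printed_outlet_resistances.csv").open() as fh:
        return pd.read_csv(fh)


def fixture_resistance_state(case: str) -> ResistanceState:
    """Outlet resistances of one clinical case as a frozen 0D state."""
    tab = load_printed_resistances()
    sel = tab[tab["case"] == case]
    if sel.empty:
        raise ValueError(f"unknown case {case!r}")
    r = dict(zip(sel["artery"], sel["resistance_mmhg_per_kg_s"].astype(float)))
    return ResistanceState(resistance_mmhg_per_kg_s=r,
                           y0={k: 0.0 for k in r},
                           pressure_mmhg={k: float("nan") for k in r})


@dataclass(frozen=True)
class RunConfig:
    """Validated, hashable configuration of one study."""

    networks: tuple[NetworkVariantConfig, ...] = (
        NetworkVariantConfig(case="A"),
        NetworkVariantConfig(case="B"),
    )
    cca_velocity: dict = field(default_factory=lambda: dict(CASE_CCA_VELOCITY))
    tip_velocity: float = 0.01
    mode: str = "zerod"
    rheology: RheologyParams = RheologyParams()
    options: SolverOptions = SolverOptions()
    seed: int = 0

    def digest(self) -> str:
        """Short provenance hash embedded in every report row."""
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def boundary_for(self, case: str) -> BoundaryConditions:
        v = self.cca_velocity.get(case, CASE_CCA_VELOCITY["A"])
        return BoundaryConditions(cca_mean_velocity=v, tip_velocity=self.tip_velocity)


def default_study_config(seed: int = 0) -> RunConfig:
    """The standard two-case, 32-model study configuration."""
    return RunConfig(networks=(
        NetworkVariantConfig(case="A", include_PAA=False, include_MMA=False, seed=seed),
        NetworkVariantConfig(case="B", seed=seed + 1),
    ), seed=seed)


def run_sweep(config: RunConfig = None) -> pd.DataFrame:
    """Run the full catheter-model grid over every configured network.

    Returns a long-format table, one row per (model, outlet), carrying the
    agent mass flow and distribution rate, streamline-contact flag, the
    shared-column relative labels, convergence diagnostics and the config
    hash.  A model that fails to converge is logged and skipped.
    """
    config = config or default_study_config()
    digest = config.digest()
    rows = []
    for net_cfg in config.networks:
        network = generate_network(net_cfg)
        boundary = config.boundary_for(network.case)
        for placement in enumerate_model_grid(network):
            try:
                result = solve_flow(network, placement, boundary,
                                    mode=config.mode, rheology=config.rheology,
                                    options=config.options)
            except RuntimeError as exc:  # non-convergence aborts only this row
                rows.append({"case": network.case, "model": placement.label,
                             "error": str(exc), "config_hash": digest})
                continue
            labels = placement.relative_labels
            residual = result.iterations[-1]["agent_delta_kg_s"]
            for outlet in result.report.agent_mass_flow:
                rows.append({
                    "case": network.case,
                    "model": placement.label,
                    "vertical_class": placement.vertical_class,
                    "position": ("S" if placement.vertical_class == 4
                                 else placement.horizontal_class),
                    "la_label": labels.get("LA", "S"),
                    "oa_label": labels.get("OA", "S"),
                    "fa_label": labels.get("FA", "S"),
                    "outlet": outlet,
                    "mass_flow_kg_s": result.report.agent_mass_flow[outlet],
                    "rate_pct": result.report.rate_pct[outlet],
                    "contact": bool(result.report.contact.get(outlet, False)),
                    "outlet_pressure_mmhg": result.flow.outlet_pressure_mmhg[outlet],
                    "converged": result.converged,
                    "agent_residual_kg_s": residual,
                    "config_hash": digest,
                })
    return pd.DataFrame(rows)


def sweep_table(sweep: pd.DataFrame) -> pd.DataFrame:
    """Pivot a sweep to the clinical-table layout (models × outlets, % rates)."""
    return sweep.pivot_table(index=["case", "model"], columns="outlet",
                             values="rate_pct", aggfunc="first").fillna(0.0)


def table_means(table: pd.DataFrame, branch: str, classes, shifts,
                cases=None) -> float:
    """Mean distribution rate of ``branch`` over selected classes and shifts.

    Operates on any long-format table with ``artery``/``outlet``,
    ``vertical_class``, per-branch relative label columns and ``rate_pct`` —
    both the packaged printed table and :func:`run_sweep` output qualify.
    ``shifts`` select on the branch-relative label (e.g. ``{"L", "R"}``).
    """
    col = "artery" if "artery" in table.columns else "outlet"
    label_col = f"{branch.lower()}_label"
    if label_col not in table.columns:
        raise ValueError(f"table has no column {label_col!r}")
    sel = table[(table[col] == branch)
                & table["vertical_class"].isin(list(classes))
                & table[label_col].isin(list(shifts))]
    if cases is not None:
        sel = sel[sel["case"].isin(list(cases))]
    if sel.empty:
        raise ValueError("selection is empty")
    return float(sel["rate_pct"].mean())


def compare_outlet_bc(config: RunConfig = None,
                      placements: str = "center-class1") -> pd.DataFrame:
    """Paired runs under the 0D-resistance and zero-pressure outlet models.

    Returns one row per (case, outlet) with both modes' distribution rates
    and their signed difference (0D minus zero-pressure).
    """
    config = config or default_study_config()
    rows = []
    for net_cfg in config.networks:
        network = generate_network(net_cfg)
        boundary = config.boundary_for(network.case)
        from .vasculature import place_catheter

        placement = place_catheter(network, 1, "C", "LA")
        rates = {}
        for mode in ("zerod", "zero-pressure"):
            result = solve_flow(network, placement, boundary, mode=mode,
                                rheology=config.rheology, options=config.options)
            rates[mode] = result.report.rate_pct
        for outlet in rates["zerod"]:
            rows.append({
                "case": network.case,
                "model": placement.label,
                "outlet": outlet,
                "rate_zerod_pct": rates["zerod"][outlet],
                "rate_zero_pressure_pct": rates["zero-pressure"][outlet],
                "difference_pct": rates["zerod"][outlet] - rates["zero-pressure"][outlet],
                "config_hash": config.digest(),
            })
    return pd.DataFrame(rows)
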