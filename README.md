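# iacflow

Reduced-order simulation of anticancer-agent distribution in the external
carotid artery (ECA) during intra-arterial chemotherapy (IAC).

In IAC for oral cancer, a catheter is threaded retrogradely through the
superficial temporal artery and an anticancer agent is infused into the ECA,
ideally reaching the tumor-feeding branch (the lingual artery, LA, for tongue
cancer). Whether the agent actually enters the target branch depends on where
the catheter tip sits relative to the branch ostia: the agent travels along
blood streamlines, so a branch receives agent only when the streamlines
feeding it pass through the tip's injection region. `iacflow` models this
mechanism at desk scale for researchers studying catheter-placement strategy
and for engineers prototyping multiscale outflow boundary conditions.

## Model

The carotid tree (CCA → ICA + ECA trunk with branches SThA, LA, OA, FA,
PAA, MMA, MA; STA ligated around the catheter) is reduced to a steady laminar
resistive network. Each segment is a Poiseuille conductor `G = πr⁴/(8 μ_m l)`;
segments containing the catheter body use the exact concentric-annulus
conductance. Flow sources are the CCA inlet (`Q = v̄·A`, patient-measured mean
velocity 0.38 or 0.43 m/s) and the catheter tip (prescribed 0.01 m/s for
50 mL/h through a 1.3 mm lumen).

Each outlet drains through a **self-similar 0D peripheral tree**: generations
of identical daughter pairs (radius ratio 2^(−1/3), flow halved per
generation) down to 12 μm terminals held at 30 mmHg. A generation's
resistance is `8 μ λ/(π r³)` with the length-to-radius ratio λ taken from a
six-group diameter table, and the viscosity from the Pries–Secomb apparent
viscosity `μ_app(d, Hct)` with a diameter-dependent hematocrit, blended with
the agent by the mixture laws

    ρ_m = 1 / Σᵢ(Yᵢ/ρᵢ),    μ_m = Σᵢ Yᵢ μᵢ,

where `Y₀` is the agent mass fraction (1 at the tip, 0 at the CCA inlet).
The terminal resistance `P_terminal/Q_terminal` is rebuilt from the current
outlet flow in an outer fixed-point loop (flow ↔ outlet pressure ↔ mixture
properties) that converges when the monitored per-outlet agent mass flows
change by less than 10⁻⁹ kg/s.

Transport replaces a 3D species solver with a **cross-sectional streamtube
model**: the trunk section at the tip is decomposed into Poiseuille-weighted
streamtubes, the injection disc seeds them with agent, and each downstream
ostium captures an angular sector sized so the captured streamtube flow
equals the branch's solved flow. Agent mass flux is conserved exactly, and
delivery to a branch is equivalent to streamline contact with the tip. Wall
shear stress is evaluated analytically per segment (tube `τ = 4μQ/(πr³)`,
annulus from the exact profile) and screened against the 37.9 Pa acute
vascular yield threshold.

## Worked example

```python
from iacflow import (BoundaryConditions, NetworkVariantConfig,
                     generate_network, place_catheter, solve_flow)

net = generate_network(NetworkVariantConfig(case="B", seed=1))
tip = place_catheter(net, vertical_class=1, horizontal_class="F",
                     target_branch="LA")
result = solve_flow(net, tip, BoundaryConditions(cca_mean_velocity=0.43))
print(result.report.to_dataframe().to_string(index=False))
```

prints (`examples/04_single_model.py`):

```
outlet  mass_flow_kg_s  distribution_rate_pct  contact_flag
   ICA        0.000000                    0.0         False
  SThA        0.000000                    0.0         False
    LA        0.000013                  100.0          True
    OA        0.000000                    0.0         False
    FA        0.000000                    0.0         False
   PAA        0.000000                    0.0         False
   MMA        0.000000                    0.0         False
    MA        0.000000                    0.0         False
```

A class-1 tip placed below the LA origin and shifted a quarter diameter
toward the LA ostium sends the entire injected 13.2×10⁻⁶ kg/s of agent into
the lingual artery; blood streamlines toward every other outlet miss the
injection disc (`contact_flag` False), so those outlets receive nothing.

The `examples/` directory holds one narrative script per capability
(geometry generation, rheology, peripheral resistance, single model, the
32-model sweep, WSS screening). A thin CLI mirrors the main entry points:

```sh
iacflow run --case A --vclass 1 --shift F --target LA
iacflow sweep --out sweep.csv
iacflow compare-bc
```

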