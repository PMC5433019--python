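# Methods

`iacflow` is a desk-scale, reduced-order model of intra-arterial chemotherapy
(IAC) hydraulics in the carotid tree: where does an agent infused through a
catheter in the external carotid artery (ECA) actually go, and what does the
catheter do to wall shear stress? This note records the model, its
assumptions, the parameters that matter, and what the implementation does and
does not claim.

## Scope and central reduction

The full problem is a 3D steady species-transport computation on
patient-specific geometry. `iacflow` replaces the 3D field solution with two
coupled reductions:

1. **Network hydraulics.** Every vessel segment becomes a Poiseuille
   conductor; nodal pressures solve a small dense linear system. Segments
   containing the catheter body (ECA trunk between the tip and the ligated
   STA; the target branch for a superselective tip) use the exact
   concentric-annulus conductance
   `G = π[R⁴ − a⁴ − (R²−a²)²/ln(R/a)]/(8μl)`.
2. **Streamtube transport.** The trunk cross-section at the tip is split into
   polar streamtubes weighted by the Poiseuille profile
   (flow fraction `(s₁−s₀)(2−s₀−s₁)` per equal-area ring, `s = (r/R)²`).
   The injection disc (catheter radius, at the tip offset) seeds agent mass
   flux into the streamtubes it covers; each downstream branch ostium captures
   a contiguous angular sector centred on its distal-view angle, widened
   until the captured streamtube flow equals the branch's solved flow, with
   fractionally captured boundary columns. Captured agent goes to the branch
   (splitting over sub-branches in proportion to flow); the remainder
   continues into the trunk-end maxillary artery.

This encodes the governing mechanism directly: a branch receives agent if
and only if its capture region intersects the injection disc — the
streamline-contact criterion. Consequences built in by construction: no
delivery to branches at or proximal to the tip; 100% delivery for a tip
inside the target branch; agent mass conserved exactly (zero diffusion).

The reduction discards secondary flows, jet momentum (tip Reynolds ≈ 13,
justifying the neglect), bifurcation-local 3D effects, and pulsatility
(steady infusion over ~1 h). Individual patient-table entries are therefore
not reproduced numerically; the model targets mechanisms, trends, and
table-level statistics.

## Synthetic vasculature

The generator emulates two patient-like cases: case A (no posterior
auricular or middle meningeal artery, lingual artery ~2 mm diameter) and
case B (full branch set, lingual ~3 mm). Defaults: CCA diameter 6.5 mm, ICA
5.48 mm, ECA trunk tapering linearly from 4.8 mm to 3.0 mm over 45 mm, branch
ostia at fixed axial slots (SThA 3 mm; targets at 12/20/28 mm in the
configured caudal order, default LA→OA→FA; accessories more distal), branch
diameters from the peripheral group ranges, outlet stubs cut at five
diameters. A seed drives a small (±2%) deterministic jitter; the trunk is
scaled by a single factor so its taper stays monotone. Branch-order variants
cover the reported anatomical configurations, including linguofacial and
thyrolingual common trunks (modelled as a short carrier segment splitting
into its two members, with Murray-combined radius).

Distal-view convention (the source fixes none): angle 0 = anterior,
counterclockwise positive; shifts F/B/L/R = toward the target ostium,
opposite, +90°, −90°, magnitude one quarter of the local trunk diameter.
Case A uses ostium angles LA 0°, OA +90°, FA −90°; case B (contralateral)
LA 0°, OA −90°, FA 180°. These cycles reproduce the shared-column label
conventions of the two clinical reference tables, and were validated by
recomputing the printed class-2/3 facial-artery means from them.

Catheter grid: vertical classes 1–4 (midway bifurcation→LA origin; at the LA
origin; midway LA→FA origins; inside the target branch) × horizontal
{C, F, L, R, B} for classes 1–3, i.e. 16 models per network, 32 for the
standard study. The 10 mm pivot of the clinical catheter is reduced to the
tip position and offset; catheter-body curvature does not enter the model.

## Rheology

Mixture laws: harmonic density `ρ_m = 1/Σ(Yᵢ/ρᵢ)` and linear viscosity
`μ_m = ΣYᵢμᵢ` in mass fraction, with agent (998.2 kg/m³, 1.0 mPa·s,
D = 2.299×10⁻⁹ m²/s — water at 25 °C) and blood (1050 kg/m³, 4.6 mPa·s).
Blood is Newtonian in the resolved network; the microvascular apparent
viscosity applies only inside the 0D trees.

The microvascular law printed in the source is self-referential (the
apparent viscosity appears on both sides of its own definition) and mixes a
relative-viscosity expression with an absolute constant. We implement the
published Pries–Secomb in-vitro relation:
`μ_rel = 1 + (μ45 − 1)·((1−H)^C − 1)/((0.55)^C − 1)` with
`μ45(d) = 6e^{−0.085d} + 3.2 − 2.44e^{−0.06 d^0.645}` and the standard
exponent `C(d)`, made absolute by scaling so that the large-diameter value at
hematocrit 0.45 equals 4.06 mPa·s (implied plasma scale 4.06/3.2 mPa·s).
Diameters ≤ 1.1 μm are rejected. Hematocrit: 0.45 above 300 μm,
`0.45(0.196·log₁₀ d − 0.117)` below (base-10; clipped at zero, which only
matters below ~4 μm); the discontinuity at the threshold is kept as printed,
with an off-by-default smoothing flag.

## Peripheral resistance (0D outflow)

Each outlet's unresolved periphery is a symmetric structured tree: daughter
radius = parent × 2^(−1/3) (Murray's law, consistent with halved flow per
generation), from the outlet radius down to the first generation at or below
the 12 μm terminal radius, where the pressure is 30 mmHg. Per generation:
viscous resistance `8μλ/(πr³)`, λ from the diameter group table
(ICA 50.0154; large arteries 61.5385; main branches 83.3333; terminal
branches 16.6667; arterioles 40; capillaries 250 — the arterioles row uses
the self-consistent parse length 2 mm/λ 40; the ICA row's λ is kept as
tabulated although it is not length/radius-consistent; both are
configurable and excluded from consistency tests). Group assignment picks
the smallest group mean diameter not below the vessel's diameter. Two
identical daughters in parallel halve the daughter-side resistance; the
terminal load `P_terminal/Q_terminal` is rebuilt from the current outlet
flow at every coupling step, which makes the terminal contribution to the
root exactly `P_terminal/Q_root` and guarantees the terminals sit at
30 mmHg at convergence.

Note that with a 12 μm terminal radius the tree stops in the arteriole
group; the capillary row participates only if the terminal radius is
lowered. Branch-scale outlets (0.5–2 mm radius) produce resistances of
10⁴–10⁶ mmHg/(kg/s), the range of the tabulated patient values; ICA-scale
roots (~2.7 mm) come out a few-fold below their tabulated values — a known
limitation of the symmetric Murray taper at large radii.

Reverse outlet flow has no meaning in a pure resistance element; it is
flagged with a warning and the pressure floored at the terminal value.
Units are SI internally; mmHg/(kg/s) at the reporting interface.

## Coupling and numerics

Outer fixed-point loop per model: (re)build outlet resistances from current
flows and agent fractions → linear network solve (dense `numpy` solve;
networks have a few tens of nodes) → streamtube transport → update per-outlet
agent fractions and per-edge mixture viscosities. Convergence is declared
when every outlet's agent mass flow changes by < 10⁻⁹ kg/s (about 0.007% of
the injected 1.32×10⁻⁵ kg/s); typical runs converge in 4–6 iterations, and
non-convergence within 60 iterations raises an error carrying the residual
history. The solver is fully deterministic; randomness exists only in the
geometry generator's seed. Trunk-piece viscosities are left at the blood
value (the agent fraction there is ~10⁻³, a <0.1% viscosity effect);
branch and outlet viscosities use the mixture rule.

Streamtube resolution defaults to 50 equal-area rings × 160 sectors (8,000
streamtubes); injection-disc seeding uses 4×4 sub-sampled per-cell overlap
fractions. The resolution was chosen by the self-convergence rule that a
10× refinement must change no outlet's delivered fraction by more than 1%
of the injected amount; at the default the worst case across all 32 study
models is 0.49%. The optional inter-streamtube diffusion exchange
(neighbour exchange with coefficient `D·Δt/h²` per inter-ostium reach,
clipped for stability) is off by default: at the physical diffusivity the
transverse diffusion length over the trunk transit (~13 μm) is far below
the streamtube size, and enabling it changes deliveries by well under 1%.
It is a crude mixing surrogate, not a discretized diffusion operator.

Two outlet boundary modes are exposed: `zerod` (peripheral trees, the
physiological default) and `zero-pressure` (all outlets grounded), which
reproduce the qualitative finding that the outlet model changes the
distribution pattern. Tabulated patient resistances ship as a fixture and
can be frozen in place of the 0D model.

## Wall shear stress

Per-segment analytic WSS from the converged flow: `τ = 4μQ/(πr³)` for open
tubes; both wall gradients of the exact annular profile where the catheter
occupies the lumen. The carotid-bifurcation value is proxied by the maximum
over the adjoining CCA/ICA/first-trunk segments (a documented proxy, not a
3D field value). Sites exceeding the acute vascular yield threshold
(37.9 Pa, configurable) are flagged. Values are screening estimates: real
bifurcation WSS fields, entrance effects, and eccentric catheter positions
are outside the model.

## Synthetic data versus real data

The generator reproduces the topology, branch sets, printed branch order,
quarter-diameter shift geometry, and scale of the two clinical cases — not
their centerlines, cross-section shapes, or measured branch diameters, which
the source does not provide. Passing tests therefore demonstrate the
mechanisms (contact criterion, placement trends, boundary-condition
sensitivity, annular shear amplification) and the numerics (conservation,
oracle agreement, grid convergence), not patient-specific reproduction:
per-model distribution tables computed on synthetic geometry agree with the
clinical tables in structure and trend, not entry by entry. Table-level
statistics asserted numerically (the class-2/3 facial-artery means) are
computed from the packaged printed table itself.

## Known limitations

- Steady, rigid-wall, laminar; no pulsatility or fluid–structure
  interaction.
- No secondary flows or jet momentum; capture regions are angular sectors.
- Symmetric peripheral trees; no Windkessel compliance or wave effects.
- ICA-scale 0D resistance underestimates tabulated values (see above).
- WSS is per-segment analytic, not a wall field.
- The class-4 (superselective) transport shortcut assigns all agent to the
  target branch rather than resolving the annular species field inside it.
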