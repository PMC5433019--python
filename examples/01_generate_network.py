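"""Generate the two synthetic carotid-tree variants and inspect their anatomy.

Builds a case-A-like network (no posterior auricular or middle meningeal
artery, ~2 mm lingual artery) and a case-B-like network (full branch set,
~3 mm lingual artery), prints each segment's dimensions, and shows the
round-trip through the JSON network file format.
"""

import tempfile
from pathlib import Path

from iacflow import NetworkVariantConfig, generate_network, read_network, write_network

for cfg in (NetworkVariantConfig(case="A", include_PAA=False, include_MMA=False, seed=0),
            NetworkVariantConfig(case="B", seed=1)):
    net = generate_network(cfg)
    print(f"case {net.case}: outlets {net.outlet_ids()}; ligated {sorted(net.ligated_outlets)}")
    for seg in net.trunk_branches():
        print(f"  {seg.id:5s} diameter {seg.diameter*1e3:4.2f} mm, "
              f"ostium at {seg.ostium_axial_position*1e3:5.1f} mm along the ECA trunk")
    path = Path(tempfile.mkdtemp()) / "network.json"
    write_network(net, path)
    assert read_network(path) == net
    print(f"  round-tripped through {path.name} without loss\n")

# Every branch diameter is in millimetres; ostium positions are measured
# distally from the carotid bifurcation. The superficial temporal artery
# (STA) is ligated around the catheter and carries no flow.
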