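"""Mixture properties and the Fåhraeus–Lindqvist apparent viscosity of blood.

Evaluates the agent/blood mixture laws at a few compositions, then sweeps
the microvascular apparent-viscosity model across vessel diameters to show
the hematocrit reduction and the approach to the large-vessel Newtonian
value (4.06 mPa·s at hematocrit 0.45).
"""

from iacflow import apparent_viscosity, hematocrit, mixture_density, mixture_viscosity

print("agent mass fraction -> mixture density (kg/m3), viscosity (mPa s)")
for y0 in (0.0, 0.25, 0.5, 1.0):
    print(f"  Y0 = {y0:4.2f}: rho_m = {mixture_density(y0):7.1f},"
          f" mu_m = {mixture_viscosity(y0)*1e3:5.2f}")

print("\nvessel diameter (um) -> hematocrit, apparent viscosity (mPa s)")
for d in (5000, 1000, 300, 100, 30, 10):
    h = hematocrit(d)
    print(f"  d = {d:5d}: Hct = {h:5.3f}, mu_app = {apparent_viscosity(d, h)*1e3:5.3f}")

# Above 300 um the hematocrit stays systemic (0.45) and the viscosity sits
# near the Newtonian 4.06 mPa s; below it both fall, which lowers the
# resistance the peripheral trees assign to their smallest generations.
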