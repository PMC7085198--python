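"""Evaluate the Carreau shear-thinning law for blood and the porous
microcirculation closure (Kozeny-Carman permeability and Darcy drag)."""

from stenoflow import (CarreauParams, PorousParams, carreau_viscosity,
                       permeability, porous_sink)

blood = CarreauParams()           # mu0=0.056, mu_inf=0.00345 Pa*s
print("Carreau viscosity of blood:")
for gamma in (0.0, 1.0, 10.0, 100.0, 1000.0, 1e6):
    print(f"  shear rate {gamma:>9.1f} 1/s -> mu = "
          f"{carreau_viscosity(blood, gamma):.5f} Pa*s")
print("(bounded between the zero-shear 0.0560 and infinite-shear 0.00345)")

bed = PorousParams()              # porosity 0.5, microvessel diameter 100 um
k = permeability(bed)
print(f"\nmicrocirculation permeability k = {k:.4e} m^2")
drag = porous_sink(0.01, blood.mu_inf, bed)
print(f"Darcy drag at u = 1 cm/s (eta = mu_inf): {drag:.4e} Pa/m")
print("(this drag, integrated over the bed length, is the outlet impedance)")
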