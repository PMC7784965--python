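"""Total-sulfide speciation and diffusive time scales.

H₂S microsensors only see the protonated species; combining the H₂S reading
with pH at each depth reconstructs the total sulfide pool S_tot.  The same
module answers how long a small organic molecule needs to diffuse between
the photosynthetic layer and the sulfide producers ~1 mm below.
"""

import numpy as np

from matbgc import SpeciationParams, diffusion_time, h2s_fraction, stot_from_h2s

params = SpeciationParams(temperature=20.0, salinity=0.0)
print(f"pK1(H2S) at 20 C, fresh water: {params.pk1:.3f}")

depths = np.array([0.0, 0.5, 1.0, 2.0, 4.0])
h2s = np.array([20.0, 45.0, 80.0, 150.0, 240.0])  # µmol/L
ph = np.array([7.4, 7.3, 7.2, 7.1, 7.0])
stot = stot_from_h2s(h2s, ph, params)

print("\ndepth_mm  H2S(µM)  pH    alpha0  S_tot(µM)")
for z, h, p, s in zip(depths, h2s, ph, stot):
    print(f"{z:7.1f} {h:8.1f} {p:5.2f}  {h2s_fraction(p, params):.3f} {s:9.1f}")
print("\nS_tot exceeds H2S by the factor 1/alpha0 — the HS- share grows with pH.")

t = diffusion_time(1.0, 1.0e-5)
print(
    f"\nAcetate-sized solute over 1 mm: {t.seconds:.0f} s = {t.minutes:.1f} min."
    "\nThat is short enough to couple photosynthate excretion to sulfide"
    "\nproduction within the same light phase."
)
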