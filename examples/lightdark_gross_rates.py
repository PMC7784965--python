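"""Gross photosynthesis rates from simulated light-dark shifts.

Immediately after darkening, diffusion has not yet re-equilibrated, so the
initial O₂ decline rate equals gross oxygenic photosynthesis (OP) and the
initial total-sulfide rise equals gross anoxygenic photosynthesis (AP) at
that depth.  Longer fit windows underestimate the rates as the gradients
relax - the classic bias of the method, shown below.
"""

import numpy as np

from matbgc import get_scenario, gross_rate_lightdark, simulate_lightdark

scenario = get_scenario("op_sob_below")  # OP regime, SOB below the cyanobacteria
transient = simulate_lightdark(scenario, switch_time_s=0.0, duration_s=15.0, dt_s=0.05)

depth = 0.7  # mm, mid-photic
for solute, mode, imposed in (("O2", "OP", 0.5), ("S_tot", "AP", 0.05)):
    t, v = transient.series(solute, depth)
    keep = np.isclose(np.mod(t, 0.5), 0, atol=1e-9)  # 0.5 s sensor sampling
    rate = gross_rate_lightdark(t[keep], v[keep], window_s=3.0, mode=mode)
    print(
        f"gross {mode} at {depth} mm: {rate:.4f} nmol cm-3 s-1 "
        f"(imposed {imposed})"
    )

print("\nwindow (s)   gross OP estimate near the zone edge (0.35 mm)")
t, v = transient.series("O2", 0.35)
keep = np.isclose(np.mod(t, 0.5), 0, atol=1e-9)
for window in (2.0, 4.0, 8.0, 14.0):
    g = gross_rate_lightdark(t[keep], v[keep], window_s=window, mode="OP")
    print(f"{window:9.1f}   {g:.4f}")
print("\nThe estimate only drops as the window grows (never up). At mid-photic")
print("depths the 3 s default is nearly bias-free; at the very edge of the")
print("photic zone diffusion bites within seconds and the method reads low.")
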