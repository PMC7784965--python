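"""Carbon fixation predicted from sulfide-oxidation stoichiometry.

Sulfur-oxidizing bacteria conserve a fixed ~16.9% of the energy of aerobic
sulfide oxidation but can vary the product between elemental sulfur
(incomplete, little O₂, little C fixed) and sulfate (complete, much O₂,
five times the C yield).  The observed S_tot:O₂ consumption-flux ratio pins
the product mixture - and with it the layer's CO₂ fixation.
"""

from matbgc import REACTIONS, budget, sob_partition_from_ratio

print("End-member reactions:")
for label in ("SOB_incomplete", "SOB_complete"):
    print(f"  {label:15s} {REACTIONS[label]}")

for ratio in (2.5, 2.3, 0.85, 2.0 / 3.0):
    p = sob_partition_from_ratio(ratio)
    print(
        f"\nS_tot:O2 ratio {ratio:.3f}: f(S0) = {p.f_s0:.3f}, "
        f"C yield = {p.c_yield:.3f} mol C (mol S)^-1"
    )
print(
    "\nAt the measured ratio ~2.3 oxidation is almost entirely incomplete"
    "\n(yield ~0.11); at ~0.85 it has switched to mostly complete oxidation."
)

b = budget(gross_op_areal=0.04, gross_ap_areal=0.004, j_stot_sob=0.0075, r=2.3)
print(
    f"\nExample budget (nmol C cm-2 s-1): OP {b.cfix_op:.4f} + "
    f"AP {b.cfix_ap:.4f} + SOB {b.cfix_sob:.5f} = {b.cfix_total:.4f}; "
    f"AP fraction of photosynthesis {b.ap_fraction:.3f}"
)
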