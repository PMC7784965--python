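"""A simulated diel ¹³C-labeling experiment and its analysis.

The schedule mirrors the incubation: darkness, then anoxygenic photosynthesis
(AP) under low light, then oxygenic photosynthesis (OP) under high light,
with the dissolved inorganic carbon pool labeled to a 6% ¹³C atom fraction.
The pipeline recovers the imposed carbon-fixation flux per phase from bulk
mat labeling, and the relative ¹³C uptake-rate contributions (FA-RUR) of the
three sulfate/sulfur-reducer fatty-acid subgroups reveal which populations
feed on fresh photosynthate.
"""

from matbgc import (
    delta_delta,
    fa_rur,
    get_scenario,
    mat_cfix_flux,
    simulate_diel_sip,
)
from matbgc.sip import SRB_SUBGROUPS

scenario = get_scenario("diel_sip")
result = simulate_diel_sip(scenario)

print("phase     imposed F   recovered F  (mmol C m-2 h-1)")
for name, interval in result.truth.phase_intervals.items():
    f = mat_cfix_flux(
        result.series["mat_bulk"], result.series["DIC"],
        scenario.areal_carbon, interval=interval,
    )
    print(f"{name:9s} {result.truth.cfix_flux_per_phase[name]:9.2f} {f:12.2f}")

doc = result.series["DOC"]
print(
    f"\nDOC 13C/12C relative to t0: start {doc.values[0]:.2f}, "
    f"end of AP {doc.values[abs(doc.times_h - 14.0).argmin()]:.2f}, "
    f"end of OP {doc.values[-1]:.2f}"
)
print("Label appears in the DOC pool only once oxygenic photosynthesis runs —")
print("the excreted photosynthate that feeds the sulfide producers.")

members = [f"FA:{n}" for grp in SRB_SUBGROUPS.values() for n in grp]
deltas = {k: delta_delta(v) for k, v in result.series.items() if k.startswith("FA:")}
print("\nFA-RUR of the SRB subgroups per phase:")
for name, interval in result.truth.phase_intervals.items():
    r = fa_rur(deltas, interval, members=members)
    shares = {
        grp: sum(r.contributions[f"FA:{n}"] for n in fas)
        for grp, fas in SRB_SUBGROUPS.items()
    }
    pretty = ", ".join(f"{g}: {s:.2f}" for g, s in shares.items())
    print(f"  {name:9s} {pretty}")
print("\nSubgroup 1 only becomes active during OP; subgroup 3 dominates in the")
print("dark and under AP — two sulfide-producing populations on different diets.")
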