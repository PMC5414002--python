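"""Treadmilling requires the polymerization-associated switch.

Runs two stochastic filament simulations against a fixed monomer bath:

* a 'switch' filament (dG_switch = 8 kT, association 5x faster at the
  plus end, hydrolysis on): subunits join at the plus end and fall off
  the minus end, so the filament body drifts;
* a 'rigid' filament (no switch, symmetric ends): no net drift.
"""

import math

from ftszkit import SimParams, measure_treadmilling, run_ssa

switch = SimParams(
    variant="switch", dG_switch=8.0, dG_interface_T=-12.0, dG_interface_D=-8.0,
    k_hyd=0.3, k_exch=10.0, end_asymmetry=5.0, asymmetric_end="plus",
    mode="fixed_monomer", c_free=0.2, init_filament_length=60, init_nucleotide="T",
)
rigid = SimParams.rigid(
    dG_interface_T=-3.0, dG_interface_D=-3.0, k_hyd=0.0, k_exch=0.0,
    mode="fixed_monomer", c_free=math.exp(-3.0), init_filament_length=100,
)

v_switch = measure_treadmilling(run_ssa(switch, t_max=300.0, seed=7))
v_rigid = measure_treadmilling(run_ssa(rigid, t_max=5000.0, seed=8))

for name, v in (("switch", v_switch), ("rigid", v_rigid)):
    lo, hi = v["ci"]
    print(f"{name:>6s} filament: velocity {v['velocity']:+.3f} subunits/s "
          f"(95% CI {lo:+.3f} .. {hi:+.3f}), "
          f"plus flux {v['plus_flux']:+.3f}, minus flux {v['minus_flux']:+.3f}")
print()
print("The switch filament's confidence interval excludes zero: net growth")
print("at one end, net loss at the other — treadmilling with the drift")
print("direction set by structural polarity.  The rigid filament's interval")
print("contains zero: without the switch, the two ends are kinetically")
print("equivalent and no robust treadmilling is possible.")
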