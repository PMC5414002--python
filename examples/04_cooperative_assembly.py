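"""Cooperativity of single-stranded assembly from the switch alone.

Compares equilibrium polymer mass versus concentration for an
isodesmic filament (dG_switch = 0: every association step identical)
and a switch filament (dG_switch = 4 kT: dimer nucleation pays two
switches for one interface).  Both use the same elongation constant
K = exp(3), so any difference is pure nucleation cooperativity.
"""

import math

from ftszkit import SimParams, equilibrium_mass_fraction, estimate_onset, mass_curve

iso = SimParams(variant="switch", dG_switch=0.0, dG_interface_T=-3.0, dG_interface_D=-3.0,
                k_hyd=0.0, k_exch=0.0, mode="closed_system", n_total=150, allow_annealing=True)
coop = SimParams(variant="switch", dG_switch=4.0, dG_interface_T=-7.0, dG_interface_D=-7.0,
                 k_hyd=0.0, k_exch=0.0, mode="closed_system", n_total=150, allow_annealing=True)

grid = [0.03, 0.05, 0.08, 0.12, 0.16, 0.2]
df_iso = mass_curve(iso, grid, t_eq=1500.0, replicates=3, seed=1)
df_coop = mass_curve(coop, grid, t_eq=3000.0, replicates=3, seed=2)

print("c_total   isodesmic (sim/theory)   cooperative (sim/theory)")
for c, fi, fc in zip(grid, df_iso["mass_fraction"], df_coop["mass_fraction"]):
    ti = equilibrium_mass_fraction(c, -3.0, 0.0)
    tc = equilibrium_mass_fraction(c, -7.0, 4.0)
    print(f"  {c:5.2f}     {fi:.3f} / {ti:.3f}          {fc:.3f} / {tc:.3f}")

c_crit = math.exp(-7.0 + 4.0)
print()
print(f"nucleation-elongation critical concentration: {c_crit:.4f} c0 (prediction)")
print(f"onset estimated from the simulated curve    : {estimate_onset(df_coop):.4f} c0")
print()
print("The isodesmic curve rises smoothly from zero; the cooperative curve")
print("stays near zero below the critical concentration and then grows with")
print("free monomer pinned at c_crit — the hallmark of nucleated assembly,")
print("here produced solely by the closed->open conformational switch.")
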