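"""All-vs-all Calpha RMSD matrix and an open/closed census table.

Generates a small family of conformers from one parent chain — two
'closed' copies (small perturbations) and two 'open' copies (rotated
~27 deg) — and shows that the RMSD matrix separates the two groups
while the census table labels each member.
"""

from ftszkit import census, rmsd_matrix
from ftszkit.synthgen import SynthSpec, make_two_domain_structure, perturb_conformation

closed, domains = make_two_domain_structure(SynthSpec(seed=1))
family = {
    "closed_ref": closed,
    "closed_b": perturb_conformation(closed, domains, SynthSpec(seed=11, noise_sigma=0.3)),
    "open_a": perturb_conformation(closed, domains, SynthSpec(seed=12, applied_angle=27.0, noise_sigma=0.3)),
    "open_b": perturb_conformation(closed, domains, SynthSpec(seed=13, applied_angle=25.0, noise_sigma=0.3)),
}

matrix = rmsd_matrix(family, rejection_cycles=0)
print("all-vs-all Calpha RMSD (A), no outlier rejection:")
print(matrix.round(2).to_string())
print()
table = census(family, closed, domains, nucleotide={"open_a": "GTP", "open_b": "GDP"})
print("census versus the closed reference:")
print(table.to_string(index=False))
print()
print("Within-group RMSDs stay near the noise floor while open-vs-closed")
print("pairs are dominated by the CTD rotation; the census angle column")
print("splits cleanly across the 15 deg open/closed threshold.")
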