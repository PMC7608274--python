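"""Elementary substitution features from the embedded amino-acid scales.

Builds no structure at all: just the property-change features for a single
missense change, the way the featurizer consumes them.
"""

from protvp import charge_transition, hydrophobic_loss, parse_protein_hgvs, volume_bin, volume_change

ref, pos, alt = parse_protein_hgvs("p.(Leu216Arg)")
print(f"variant: {ref}{pos}{alt}")

dv = volume_change(ref, alt)
print(f"volume change V(ref)-V(alt): {dv:+.1f} A^3 -> bin {volume_bin(dv).value}")
# negative change means a larger residue was squeezed in

print(f"charge transition: {charge_transition(ref, alt).value}")
# Leu -> Arg introduces a positive charge (criterion f3)

print(f"hydrophobic loss: {hydrophobic_loss(ref, alt)}")
# a hydrophobic residue replaced by a charged one: relevant inside the membrane
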