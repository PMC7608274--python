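"""Geometric features on a synthetic helix bundle.

Generates a small membrane-protein stand-in, then shows the three structural
operations: modelled-region membership, intracellular/extracellular sidedness
(angle at the centre of mass against an intracellular anchor residue), and
the rotamer-minimized van der Waals clash score for an introduced side chain.
"""

from protvp import clash_score, in_modelled_region, sidedness
from protvp.synthetic_fixtures import FixtureSpec, make_helix_bundle

model, topology, refseq = make_helix_bundle(FixtureSpec(seed=1))
print(f"bundle: {len(model)} modelled residues, sequence length {topology.sequence_length}")
print(f"modelled ranges: {topology.modelled_ranges}")
print(f"reference (intracellular anchor) residue: {topology.reference_residue}")

pos = topology.modelled_ranges[0][0] + 5
print(f"\nposition {pos} modelled: {in_modelled_region(topology, pos)}")
unmod = topology.ctd_range[0]
print(f"position {unmod} (CTD) modelled: {in_modelled_region(topology, unmod)}")

side = sidedness(model, topology, pos)
print(f"sidedness of {pos}: {side.side.value} (angle {side.angle_deg:.1f} deg)")
# angle < 90 deg at the centre of mass means the residue sits on the same
# membrane side as the anchor, i.e. intracellular

for alt in ("G", "A", "W"):
    res = clash_score(model, pos, alt)
    print(f"clash score for {refseq[pos]}{pos}{alt}: {res.score:.3f} "
          f"(rotamer {res.rotamer_id}, {res.n_overlapping_atoms} overlapping atoms)")
# 0 means the best rotamer fits without van der Waals overlap; more negative
# means the least-clashing rotamer still overlaps neighbouring atoms
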