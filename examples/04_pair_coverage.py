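"""Pair coverage: do two related dimers share the same interaction type?

PC = NCP_M^2 / (NCP_AB * NCP_A'B') measures how much of two interfaces
overlaps under a residue correspondence.  Related pairs with PC >= 0.4
are taken to bind the same way.  Here the second dimer keeps 8 of the
first's 12 contact pairs plus 3 contacts of its own.
"""

from pairpssm import pair_coverage, same_interaction_type
from pairpssm.geometry import ContactMap, ContactPair, ResidueRef
from pairpssm.library import CorrespondenceMap


def contact_map(pairs):
    return ContactMap(
        pairs=[ContactPair(ResidueRef("A", a, "", "A"),
                           ResidueRef("B", b, "", "G"), 4.0)
               for a, b in pairs],
        cutoff=4.5,
    )


shared = [(i, i + 2) for i in range(1, 9)]         # 8 conserved contacts
cm1 = contact_map(shared + [(20, 25), (21, 26), (22, 27), (23, 28)])
cm2 = contact_map(shared + [(30, 35), (31, 36), (32, 37)])
identity = CorrespondenceMap({i: i for i in range(1, 40)})

pc = pair_coverage(cm1, cm2, identity, identity)
print(f"NCP_M = {pc.ncp_m} shared contact pairs")
print(f"NCP_AB = {pc.ncp_ab}, NCP_A'B' = {pc.ncp_apbp}")
print(f"PC = {pc.ncp_m}^2 / ({pc.ncp_ab} * {pc.ncp_apbp}) = {pc.pc:.3f}")
print(f"same interaction type (PC >= 0.4): {same_interaction_type(pc)}")
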