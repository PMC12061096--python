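"""Parse glycan compositions, compute masses, and build decoy panels.

Glycans are identified by monosaccharide composition only (no linkage
information); the decoy panel supports target-decoy FDR estimation for
glycan assignment.
"""

import glycopipe as gp

# the search engine prints compositions as Symbol(count); a bare symbol
# means count 1 — glycation (one hexose on lysine) is just "Hex"
g = gp.parse_glycan_composition("HexNAc(4)Hex(5)Fuc(1)NeuAc(2)")
print("composition:", g.counts)
print("canonical:  ", g.render())
print(f"mass:        {gp.glycan_monoisotopic_mass(g):.4f} Da")

glycation = gp.parse_glycan_composition("Hex")
print("\nglycation adduct on K:", gp.classify_modification("K", glycation))
print("N-glycan sequon ANKSA@2:", gp.validate_nglyco_motif("ANKSA", 2))
print("N-glycan sequon ANPSA@2:", gp.validate_nglyco_motif("ANPSA", 2), "(proline blocks it)")

db = gp.builtin_glycan_database()
print(f"\nsynthetic panel: {db.n_targets} targets, {db.n_decoys} mass-matched decoys")
decoys = gp.generate_decoy_glycans(db.targets, n=5, seed=1)
print("example decoys:", [d.render() for d in decoys])
# Mass-matched decoys let the FDR procedure count wrong glycan
# assignments the same way sequence decoys count wrong peptides.
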