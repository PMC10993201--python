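"""Enumerate the oligomer ions of a capped peptide.

Builds the Ac-PHF6-NH2 monomer (the tau hexapeptide VQIVYK with acetyl
and amide caps), derives its elemental composition and monoisotopic mass,
and lists every n^z+ = [nM + zH]^z+ species inside the instrument's m/z
range.  Oligomers with the same n:z ratio share an m/z channel (an
isobaric family) and can only be told apart by ion mobility.
"""

import oligomob as om

peptide = om.parse_peptide("Ac-VQIVYK-NH2")
comp = om.composition_of(peptide)
M = om.monoisotopic_mass(comp)
print(f"{peptide}: {comp.formula()}, monoisotopic mass {M:.4f} Da")

species = om.enumerate_species(M, mz_range=(50, 3000), n_max=25, z_max=8)
print(f"{len(species)} candidate oligomer ions in m/z 50-3000")

print("\nthe m/z 1580 isobaric family ([2n]^nz+):")
for ion in om.isobaric_family(1580.0, 0.5, M, n_max=12, z_max=6):
    print(f"  {ion.label:>6}  m/z {ion.mz:9.4f}  label {om.mz_label(ion.mz)}")

# every member prints the same channel label: only mobility separates them.
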