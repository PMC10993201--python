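"""Read the charge state of an oligomer from its isotopologue spacing.

The envelope of an n-mer at charge z has adjacent peaks about 1.00336/z Th
apart, so the spacing alone reveals z, and with the monomer mass the
oligomer order n follows.  This is how members of one isobaric family are
identified in mobility-gated mass spectra.
"""

import oligomob as om

comp = om.composition_of(om.AC_PHF6_NH2)
M = om.monoisotopic_mass(comp)

for n, z in [(2, 1), (8, 4)]:
    env = om.isotope_envelope(comp, n=n, z=z)
    print(f"{n}^{z}+ envelope: {len(env.peaks)} peaks, "
          f"spacing {env.spacing:.4f} Th, base peak m/z {env.base_peak_mz:.4f}")

# invert: an observed species at m/z 1580.0 with 0.25 Th spacing
result = om.infer_n_z(observed_mz=1580.0, isotope_spacing=0.25, M=M)
print(f"\nm/z 1580.0, spacing 0.25 Th -> {result.ion.label} "
      f"(mass error {result.ppm_error:.1f} ppm, assigned={result.assigned})")
# 0.25 Th spacing means z=4; the quadruply charged octamer, not the dimer.
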