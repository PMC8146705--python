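"""Fragment-ion arithmetic for a single marker peptide.

Computes the protonated precursor and the monitored a/b/y product ions of
the alfalfa marker VEGGLSIMSPPER, as they would appear in an MRM method
table.  The numbers are m/z values in Da per unit charge.
"""

from mrmkit import chem

PEPTIDE = "VEGGLSIMSPPER"

print(f"marker peptide: {PEPTIDE} ({len(PEPTIDE)} residues)")
print(f"neutral monoisotopic mass: {chem.peptide_mass(PEPTIDE):.4f} Da")
print(f"[M+2H]2+ precursor m/z:    {chem.precursor_mz(PEPTIDE, 2):.1f}")
for label in ("y4", "y5", "y6"):
    series, index, charge = chem.parse_ion_label(label)
    mz = chem.fragment_mz(PEPTIDE, series, index, charge)
    print(f"product {label:>6}: m/z {mz:.1f}")

# complementary b/y pairs sum to M + 2 protons -- a useful self-check
b6 = chem.fragment_mz(PEPTIDE, "b", 6, 1)
y7 = chem.fragment_mz(PEPTIDE, "y", 7, 1)
total = chem.peptide_mass(PEPTIDE) + 2 * chem.DEFAULT_CONSTANTS.proton
print(f"b6 + y7 = {b6 + y7:.4f}  vs  M + 2H = {total:.4f}")
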