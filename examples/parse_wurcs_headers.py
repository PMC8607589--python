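"""Read WURCS 2.0 headers and apply the single-extension rule.

The header of a WURCS string carries three counts: unique residues,
residues, linkages.  A glycosyl transfer adds exactly one residue, so a
reaction product must have one residue more than its acceptor.
"""

from glycopath import is_single_extension, parse_wurcs_header

acceptor = "WURCS=2.0/4,4,3/[a2122h-1b_1-5][a1221m-1a_1-5][a2112h-1b_1-5][a2122h-1x_1-5]/1-2-3-4/a4-b1_b3-c1_c2-d1"
product = "WURCS=2.0/5,5,4/[a2122h-1b_1-5][a1221m-1a_1-5][a2112h-1b_1-5][a2122h-1x_1-5][a2122h-1a_1-5]/1-2-3-4-5/a4-b1_b3-c1_c2-d1_d6-e1"

for label, text in (("acceptor", acceptor), ("product", product)):
    desc = parse_wurcs_header(text)
    print(
        f"{label}: version {desc.version}, "
        f"{desc.unique_residue_count} unique / {desc.residue_count} residues / "
        f"{desc.linkage_count} linkages"
    )

print("single extension:", is_single_extension(acceptor, product))
# The product carries 5 residues against the acceptor's 4: one glycosyl
# transfer separates them, so the extension rule holds.
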