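"""Compute the descriptor sheet for the packaged triazole-aniline panel.

Parses the fifteen structures, computes molecular weight, monoisotopic
mass, TPSA, molar refraction, H-bond donors/acceptors and rotatable bonds,
and prints the report table. Rows within a series (e.g. 2a/2b/2c) are
identical except for the compound id: positional isomers share every 2D
descriptor.
"""

from chromlip import descriptor_sheet, load_triazole_panel, sheet_frame

descs = descriptor_sheet(load_triazole_panel())
print(sheet_frame(descs).to_string(index=False))
print(
    "\nEach row: average MW (g/mol), monoisotopic mass (Da), acceptor counts"
    "\nunder the N+O and pharmacophore conventions, donors, Wildman-Crippen"
    "\nmolar refraction, Ertl TPSA (A^2) and rotatable bonds."
)
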