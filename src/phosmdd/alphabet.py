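"""Amino-acid alphabet constants shared across the package."""

AA20 = "ACDEFGHIKLMNPQRSTVWY"
"""The twenty standard amino acids, alphabetical one-letter codes."""

AA_INDEX = {aa: i for i, aa in enumerate(AA20)}

PAD = "X"
"""Pad character for windows overhanging protein termini."""

PHOSPHO_RESIDUES = ("S", "T", "Y")
"""Residue classes that can carry a phosphate group."""
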