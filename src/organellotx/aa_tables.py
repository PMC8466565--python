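"""Bundled amino-acid hydropathy tables.

``KYTE_DOOLITTLE`` is the standard Kyte & Doolittle (1982, J Mol Biol 157)
per-residue hydropathy scale (positive = hydrophobic).  ``IMGT_ORDER`` is the
IMGT hydrophobicity ranking of the 20 residues from most hydrophobic (I,
rank 1) to least (R, rank 20); ``IMGT_CLASS`` partitions the same ordering
into the three IMGT hydropathy classes (hydrophobic I..A, neutral W..H,
hydrophilic N..R).
"""

KYTE_DOOLITTLE: dict[str, float] = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}

IMGT_ORDER: list[str] = list("IVLFCMAWGTSYPHNDQEKR")

IMGT_RANK: dict[str, int] = {aa: i + 1 for i, aa in enumerate(IMGT_ORDER)}

IMGT_CLASS: dict[str, str] = {
    **{aa: "hydrophobic" for aa in "IVLFCMA"},
    **{aa: "neutral" for aa in "WGTSYPH"},
    **{aa: "hydrophilic" for aa in "NDQEKR"},
}
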