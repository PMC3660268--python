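"""Amino-acid naming tables shared across the package.

Sequence positions are 1-based (UniProt convention); residue identity is
carried internally as the lowercase full name and mapped to three- and
one-letter codes here.
"""

from __future__ import annotations

#: full name -> (three-letter code, one-letter code)
AMINO_ACIDS = {
    "alanine": ("Ala", "A"),
    "arginine": ("Arg", "R"),
    "asparagine": ("Asn", "N"),
    "aspartate": ("Asp", "D"),
    "cysteine": ("Cys", "C"),
    "glutamate": ("Glu", "E"),
    "glutamine": ("Gln", "Q"),
    "glycine": ("Gly", "G"),
    "histidine": ("His", "H"),
    "isoleucine": ("Ile", "I"),
    "leucine": ("Leu", "L"),
    "lysine": ("Lys", "K"),
    "methionine": ("Met", "M"),
    "phenylalanine": ("Phe", "F"),
    "proline": ("Pro", "P"),
    "serine": ("Ser", "S"),
    "threonine": ("Thr", "T"),
    "tryptophan": ("Trp", "W"),
    "tyrosine": ("Tyr", "Y"),
    "valine": ("Val", "V"),
}

#: Alternative spellings accepted on input (mapped to the canonical name).
NAME_ALIASES = {
    "aspartic acid": "aspartate",
    "glutamic acid": "glutamate",
}

THREE_TO_FULL = {three.lower(): full for full, (three, _) in AMINO_ACIDS.items()}
ONE_TO_FULL = {one: full for full, (_, one) in AMINO_ACIDS.items()}
FULL_TO_ONE = {full: one for full, (_, one) in AMINO_ACIDS.items()}
FULL_TO_THREE = {full: three for full, (three, _) in AMINO_ACIDS.items()}

TERMINI = ("N-terminus", "C-terminus")


def canonical_residue(name: str) -> str:
    """Map a full name, alias, three-letter or one-letter code to the
    canonical lowercase full name.  Raises KeyError for unknown input."""
    key = name.strip()
    low = key.lower()
    if low in AMINO_ACIDS:
        return low
    if low in NAME_ALIASES:
        return NAME_ALIASES[low]
    if low in THREE_TO_FULL:
        return THREE_TO_FULL[low]
    if len(key) == 1 and key.upper() in ONE_TO_FULL:
        return ONE_TO_FULL[key.upper()]
    raise KeyError(f"unknown amino acid: {name!r}")
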