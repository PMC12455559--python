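"""Amino-acid alphabet, substitution matrices, hydropathy scale and residue classes."""

from __future__ import annotations

import numpy as np
from Bio.Align import substitution_matrices

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
GAP = "-"
AMBIGUOUS = "X"
VALID_RESIDUES = set(AMINO_ACIDS) | {AMBIGUOUS}

#: Kyte-Doolittle hydropathy scale.
KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}

#: Physicochemical residue classes used for differential-conservation analysis.
RESIDUE_CLASSES = {
    "hydrophobic": set("AVLIMFWYC"),
    "aromatic": set("FWYH"),
    "aliphatic": set("AVLI"),
    "polar": set("STNQYCHKRDE"),
    "positive": set("KRH"),
    "negative": set("DE"),
    "charged": set("KRHDE"),
    "small": set("ACDGNPSTV"),
    "proline_glycine": set("PG"),
}

#: Uniform background; configurable alternatives may be passed where accepted.
UNIFORM_BACKGROUND = np.full(20, 1.0 / 20.0)

_MATRIX_CACHE: dict[str, np.ndarray] = {}


def load_matrix(name: str = "BLOSUM62") -> np.ndarray:
    """Return a 21x21 integer substitution matrix over AMINO_ACIDS + 'X'.

    'X' scores 0 against everything (including itself).
    """
    if name not in _MATRIX_CACHE:
        bm = substitution_matrices.load(name)
        m = np.zeros((21, 21), dtype=np.float64)
        for i, a in enumerate(AMINO_ACIDS):
            for j, b in enumerate(AMINO_ACIDS):
                m[i, j] = bm[a, b]
        _MATRIX_CACHE[name] = m
    return _MATRIX_CACHE[name]


def encode(seq: str) -> np.ndarray:
    """Encode residues as integer indices; 'X' maps to 20."""
    out = np.empty(len(seq), dtype=np.int64)
    for i, c in enumerate(seq):
        if c == AMBIGUOUS:
            out[i] = 20
        else:
            try:
                out[i] = AA_INDEX[c]
            except KeyError:
                raise ValueError(f"invalid residue {c!r}") from None
    return out
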