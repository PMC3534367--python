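"""Amino-acid alphabet shared by every module.

The emission alphabet is fixed at 21 symbols: the 20 standard amino acids
plus ``X`` for an unknown residue.  Other IUPAC ambiguity codes (B/Z/U/O)
are collapsed to ``X`` at parse time so that downstream probability tables
keep a fixed width.
"""

from __future__ import annotations

import numpy as np

AA20: str = "ACDEFGHIKLMNPQRSTVWY"
UNKNOWN: str = "X"
ALPHABET: str = AA20 + UNKNOWN  # 21 symbols, X last
GAP: str = "-"

AA_INDEX: dict[str, int] = {a: i for i, a in enumerate(ALPHABET)}
X_INDEX: int = AA_INDEX[UNKNOWN]

#: ambiguity codes folded into X (keeps the 21-symbol alphabet closed)
FOLD_TO_X: frozenset[str] = frozenset("BZUOJ")

# Robinson & Robinson amino-acid frequencies, the field's stock background
# for globular proteins; normalised at import.
_RR = {
    "A": 0.0780, "R": 0.0512, "N": 0.0448, "D": 0.0536, "C": 0.0192,
    "Q": 0.0426, "E": 0.0629, "G": 0.0738, "H": 0.0219, "I": 0.0514,
    "L": 0.0901, "K": 0.0574, "M": 0.0224, "F": 0.0385, "P": 0.0520,
    "S": 0.0711, "T": 0.0584, "W": 0.0132, "Y": 0.0321, "V": 0.0644,
}


def background20() -> np.ndarray:
    """Background frequencies over the 20 standard amino acids (AA20 order)."""
    v = np.array([_RR[a] for a in AA20], dtype=float)
    return v / v.sum()


def encode(residues: str) -> np.ndarray:
    """Encode a residue string as alphabet indices (int64)."""
    return np.array([AA_INDEX[c] for c in residues], dtype=np.int64)
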