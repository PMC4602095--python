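"""Amino-acid alphabet shared across the package.

The working alphabet has 21 states: the 20 standard amino acids in
alphabetical one-letter order followed by the gap symbol ``-``. Potts
models are fitted over all 21 states; coupling scores are computed over
the 20 amino-acid states only.
"""

from __future__ import annotations

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
ALPHABET = AMINO_ACIDS + GAP
N_STATES = len(ALPHABET)  # 21
GAP_STATE = ALPHABET.index(GAP)  # 20

#: Characters silently mapped to gap when coercion is requested.
AMBIGUOUS = set("BZXJOU*")

_INDEX = {c: i for i, c in enumerate(ALPHABET)}

THREE_TO_ONE = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


class AlphabetError(ValueError):
    """A sequence contains a character outside the 21-state alphabet."""


def encode(seq: str, coerce_ambiguous: bool = False) -> np.ndarray:
    """Encode a sequence string into integer states.

    ``.`` is treated as ``-``. With ``coerce_ambiguous``, rare letters
    (B/Z/X and friends) become gaps; otherwise they raise
    :class:`AlphabetError` naming the offending symbol.
    """
    out = np.empty(len(seq), dtype=np.int8)
    for k, c in enumerate(seq.upper().replace(".", GAP)):
        i = _INDEX.get(c)
        if i is None:
            if coerce_ambiguous and c in AMBIGUOUS:
                i = GAP_STATE
            else:
                raise AlphabetError(
                    f"character {c!r} at position {k} is not in the "
                    f"20-amino-acid + gap alphabet"
                )
        out[k] = i
    return out


def decode(states: np.ndarray) -> str:
    return "".join(ALPHABET[int(s)] for s in states)
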