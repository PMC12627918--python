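"""Low-level nucleotide utilities shared across modules.

IUPAC degenerate codes are represented as 4-bit masks (A=1, C=2, G=4, T=8)
so that set relations between codes reduce to bitwise arithmetic.
"""

from __future__ import annotations

import numpy as np

IUPAC_MASK: dict[str, int] = {
    "A": 1, "C": 2, "G": 4, "T": 8, "U": 8,
    "R": 1 | 4, "Y": 2 | 8, "S": 2 | 4, "W": 1 | 8,
    "K": 4 | 8, "M": 1 | 2,
    "B": 2 | 4 | 8, "D": 1 | 4 | 8, "H": 1 | 2 | 8, "V": 1 | 2 | 4,
    "N": 1 | 2 | 4 | 8,
}

_COMPLEMENT = str.maketrans(
    "ACGTURYSWKMBDHVNacgturyswkmbdhvn",
    "TGCAAYRSWMKVHDBNtgcaayrswmkvhdbn",
)

GAP_CHARS = frozenset("-.")


def revcomp(seq: str) -> str:
    """Reverse complement, preserving IUPAC degeneracy."""
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_masks(seq: str) -> np.ndarray:
    """Encode a sequence as an array of 4-bit IUPAC masks.

    Raises ValueError on any character that is not an IUPAC nucleotide code.
    """
    try:
        return np.array([IUPAC_MASK[c] for c in seq.upper()], dtype=np.uint8)
    except KeyError as exc:
        raise ValueError(f"invalid IUPAC nucleotide code: {exc.args[0]!r}") from exc


def encode_bytes(seq: str) -> np.ndarray:
    """Encode a sequence as raw uppercase byte codes (for exact-equality DPs)."""
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8).copy()


def degap(seq: str) -> str:
    return seq.replace("-", "").replace(".", "")


def degap_with_map(aligned: str) -> tuple[str, np.ndarray]:
    """Remove gaps and return (ungapped sequence, column index per residue).

    ``col_map[i]`` is the alignment column holding residue ``i`` of the
    ungapped sequence.
    """
    cols = [i for i, c in enumerate(aligned) if c not in GAP_CHARS]
    ungapped = "".join(aligned[i] for i in cols)
    return ungapped, np.array(cols, dtype=np.int64)


def n_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    s = seq.upper()
    return s.count("N") / len(s)
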