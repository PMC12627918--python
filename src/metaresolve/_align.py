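"""Numba kernel for overlap (free-end-gap) alignment.

The pairwise similarity S_XY is defined on the best semi-global alignment
with end gaps free on both sequences, under the classic unit scoring
match +1, mismatch -1, gap -1 (score-maximizing). Among score-optimal
alignments the one maximizing the number of matching columns is used, and
among those the one with the fewest aligned columns. Terminal gap runs are
excluded from the column count, so S_XY = matches / aligned columns.

A pure edit-cost minimization with free end gaps is degenerate here: the
empty (or any chance one-column) overlap costs zero and would always win;
the match reward removes that degeneracy and reproduces the behaviour of
global-identity tools at default scoring.

The lexicographic objective (score, matches, -columns) is additive along an
alignment path, so a standard dynamic programme applies.
"""

from __future__ import annotations

import numpy as np
from numba import njit


# The lexicographic triple is packed into one int64 key so each DP cell is a
# single max: key = (score + 2^16) << 44 | matches << 22 | (2^21 - columns).
# Fields never borrow or carry for sequences up to ~3*10^4 bp.
_S0 = 1 << 16
_C0 = 1 << 21
_BASE = (_S0 << 44) + _C0
_MATCH_STEP = (1 << 44) + (1 << 22) - 1   # score +1, matches +1, columns +1
_MISMATCH_STEP = -(1 << 44) - 1           # score -1, columns +1
_GAP_STEP = -(1 << 44) - 1                # score -1, columns +1
_F22 = (1 << 22) - 1


@njit(cache=False)
def _overlap_key(a: np.ndarray, b: np.ndarray) -> np.int64:
    n = a.shape[0]
    m = b.shape[0]
    row = np.full(m + 1, _BASE, dtype=np.int64)
    best = _BASE  # covers every boundary end cell (free leading + trailing)
    for i in range(n):
        ai = a[i]
        diag = row[0]
        prev = _BASE
        for j in range(1, m + 1):
            up = row[j]
            if ai == b[j - 1]:
                cand = diag + _MATCH_STEP
            else:
                cand = diag + _MISMATCH_STEP
            if up + _GAP_STEP > cand:
                cand = up + _GAP_STEP
            if prev + _GAP_STEP > cand:
                cand = prev + _GAP_STEP
            diag = up
            row[j] = cand
            prev = cand
        if row[m] > best:  # end cell on the last column: b fully consumed
            best = row[m]
    for j in range(m + 1):  # end cells on the last row: a fully consumed
        if row[j] > best:
            best = row[j]
    return best


def overlap_align(a: np.ndarray, b: np.ndarray) -> tuple[int, int, int]:
    """Return (score, matches, columns) of the optimal overlap alignment."""
    key = int(_overlap_key(a, b))
    score = (key >> 44) - _S0
    matches = (key >> 22) & _F22
    columns = _C0 - (key & _F22)
    return score, matches, columns
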