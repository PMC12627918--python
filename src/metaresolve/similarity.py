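"""Pairwise similarity S_XY between metabarcode sequences.

S_XY is the ratio of matching columns to the total alignment length of the
best free-end-gap alignment, excluding terminal gaps. Internal gap columns
count toward the alignment length (each as a non-match); ambiguity codes
("N" or any two different IUPAC characters) count as mismatching columns.

Similarities are stored as exact (matches, columns) integer pairs and only
converted to fractions at comparison time, which removes float artefacts at
thresholds such as S_XY = S_T exactly.

The optional k-mer prescreen reproduces the candidate restriction to pairs
estimated at >= 90% similarity: it is permissive (a superset of the true
candidates on indel-free data), and pairs it drops are interpretable
downstream as S_XY below the prescreen threshold.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from fractions import Fraction
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from ._align import overlap_align
from ._seq import encode_bytes


@dataclass(frozen=True)
class PairwiseSimilarity:
    id_a: str
    id_b: str
    matches: int
    aligned_columns: int

    @property
    def s_xy(self) -> float:
        return self.matches / self.aligned_columns if self.aligned_columns else 0.0

    @property
    def s_exact(self) -> Fraction:
        if not self.aligned_columns:
            return Fraction(0)
        return Fraction(self.matches, self.aligned_columns)


def pairwise_similarity(x: str, y: str, id_a: str = "x", id_b: str = "y"
                        ) -> PairwiseSimilarity:
    """S_XY for one sequence pair (order-free)."""
    if not x or not y:
        raise ValueError("sequences must be non-empty")
    _, matches, columns = overlap_align(encode_bytes(x), encode_bytes(y))
    return PairwiseSimilarity(id_a, id_b, matches, columns)


def _kmer_counts(seq: str, k: int) -> Counter:
    return Counter(seq[i:i + k] for i in range(len(seq) - k + 1))


def kmer_prescreen(sequences: Mapping[str, str], threshold: float, k: int = 8
                   ) -> list[tuple[str, str]]:
    """Candidate pairs whose shared k-mer count is compatible with similarity
    >= ``threshold``.

    With at most ``e = floor(L * (1 - threshold))`` substitutions on an
    indel-free pair of length L, at least ``L - k + 1 - k * e`` k-mers must
    still be shared, so every true positive survives; pairs below the
    threshold may also survive (the screen is permissive, never exclusive).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if not 0 <= threshold < 1:
        raise ValueError("threshold must be in [0, 1)")
    ids = sorted(sequences)
    counts = {i: _kmer_counts(sequences[i], k) for i in ids}
    out: list[tuple[str, str]] = []
    for a, b in combinations(ids, 2):
        L = min(len(sequences[a]), len(sequences[b]))
        budget = int(L * (1 - threshold))
        needed = (L - k + 1) - k * budget
        if needed <= 0:
            out.append((a, b))
            continue
        shared = sum((counts[a] & counts[b]).values())
        if shared >= needed:
            out.append((a, b))
    return out


@dataclass
class SimilarityTable:
    """Exact pairwise similarities keyed by the unordered id pair.

    When ``prescreen_threshold`` is set, absent pairs mean "similarity below
    the prescreen threshold" rather than "not computed".
    """

    entries: dict[tuple[str, str], tuple[int, int]] = field(default_factory=dict)
    prescreen_threshold: float | None = None

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def add(self, a: str, b: str, matches: int, columns: int) -> None:
        self.entries[self._key(a, b)] = (matches, columns)

    def get(self, a: str, b: str) -> tuple[int, int] | None:
        if a == b:
            return (1, 1)
        return self.entries.get(self._key(a, b))

    def s(self, a: str, b: str) -> Fraction | None:
        entry = self.get(a, b)
        if entry is None:
            return None
        matches, columns = entry
        return Fraction(matches, columns) if columns else Fraction(0)

    def ids(self) -> set[str]:
        out: set[str] = set()
        for a, b in self.entries:
            out.add(a)
            out.add(b)
        return out

    def __len__(self) -> int:
        return len(self.entries)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {"id_a": a, "id_b": b, "matches": m, "columns": c,
             "s_xy": (m / c if c else 0.0)}
            for (a, b), (m, c) in sorted(self.entries.items())
        ]
        return pd.DataFrame(rows, columns=["id_a", "id_b", "matches", "columns",
                                           "s_xy"])

    def write_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path,
                 prescreen_threshold: float | None = None) -> "SimilarityTable":
        df = pd.read_csv(path, sep="\t", dtype={"id_a": str, "id_b": str})
        table = cls(prescreen_threshold=prescreen_threshold)
        for row in df.itertuples(index=False):
            table.add(str(row.id_a), str(row.id_b), int(row.matches),
                      int(row.columns))
        return table


def all_vs_all(sequences: Mapping[str, str], prescreen: float | None = None,
               k: int = 8,
               pairs: Iterable[tuple[str, str]] | None = None) -> SimilarityTable:
    """Score all (or prescreen-candidate) unordered pairs.

    Exhaustive mode (``prescreen=None``) scores every pair; prescreen mode
    scores only the k-mer candidates and records the threshold so absent
    pairs are interpretable.
    """
    if len(sequences) < 2:
        raise ValueError("need at least two sequences")
    if pairs is None:
        if prescreen is None:
            pairs = combinations(sorted(sequences), 2)
        else:
            pairs = kmer_prescreen(sequences, prescreen, k)
    table = SimilarityTable(prescreen_threshold=prescreen)
    encoded = {i: encode_bytes(s) for i, s in sequences.items()}
    for a, b in pairs:
        _, matches, columns = overlap_align(encoded[a], encoded[b])
        table.add(a, b, matches, columns)
    return table
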