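"""Over-splitting / over-merging error rates against the BIN baseline.

An over-splitting error is an intra-BIN sequence pair whose similarity falls
below the threshold (S_XY < S_T); an over-merging error is an inter-BIN pair
at or above it (S_XY >= S_T). Rates are proportions of all unordered pairs
of the relevant class in the dataset, evaluated over a grid of thresholds
(integer percents 90-99 by default); the global error at each threshold is
their sum, and S_OPT is the grid point minimizing it.

Pairs absent from a prescreened similarity table are below the prescreen
threshold by construction, so they are over-splitting errors and never
over-merging errors for any S_T at or above that threshold. Threshold
comparisons use exact rationals throughout.
"""

from __future__ import annotations

import warnings
from bisect import bisect_left
from dataclasses import dataclass, field
from fractions import Fraction
from itertools import combinations
from pathlib import Path
from typing import Sequence

import pandas as pd

from .similarity import SimilarityTable

DEFAULT_GRID: tuple[int, ...] = tuple(range(90, 100))

#: Sentinel ranking below every real similarity: a pair dropped by the
#: prescreen has S_XY < prescreen <= any grid threshold.
_BELOW_PRESCREEN = Fraction(-1)


class UndefinedRateError(ValueError):
    """A rate's pair class is empty, so the proportion is undefined."""


@dataclass
class BinAssignment:
    """Sequence -> BIN mapping plus optional sequence -> taxonomy mapping.

    Taxonomy tuples are (species, genus, family, order); fields may be empty.
    """

    bins: dict[str, str]
    taxonomy: dict[str, tuple[str, str, str, str]] = field(default_factory=dict)

    def ids(self) -> list[str]:
        return sorted(self.bins)

    def restrict(self, ids: Sequence[str]) -> "BinAssignment":
        keep = set(ids)
        return BinAssignment(
            {i: b for i, b in self.bins.items() if i in keep},
            {i: t for i, t in self.taxonomy.items() if i in keep},
        )

    def rank(self, seq_id: str, rank: str) -> str:
        idx = {"species": 0, "genus": 1, "family": 2, "order": 3}[rank]
        return self.taxonomy.get(seq_id, ("", "", "", ""))[idx]

    @classmethod
    def read_tsv(cls, path: str | Path) -> "BinAssignment":
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        bins = dict(zip(df["sequence_id"], df["bin_id"]))
        taxonomy = {}
        if {"species", "genus", "family", "order"} <= set(df.columns):
            for row in df.itertuples(index=False):
                taxonomy[row.sequence_id] = (row.species, row.genus,
                                             row.family, row.order)
        return cls(bins, taxonomy)

    def write_tsv(self, path: str | Path) -> None:
        rows = []
        for i in self.ids():
            sp, ge, fa, od = self.taxonomy.get(i, ("", "", "", ""))
            rows.append({"sequence_id": i, "bin_id": self.bins[i],
                         "species": sp, "genus": ge, "family": fa, "order": od})
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass
class ErrorProfile:
    metabarcode: str
    thresholds: tuple[int | float, ...]
    oversplit_rate: list[float]
    overmerge_rate: list[float]
    global_error: list[float]
    n_intra_pairs: int
    n_inter_pairs: int

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "metabarcode": self.metabarcode,
            "s_t": list(self.thresholds),
            "oversplit": self.oversplit_rate,
            "overmerge": self.overmerge_rate,
            "global_error": self.global_error,
        })


@dataclass(frozen=True)
class OptimalThreshold:
    metabarcode: str
    s_opt: int | float
    ge_min: float
    ge_max: float


def _pair_values(similarities: SimilarityTable, bins: BinAssignment
                 ) -> tuple[list[Fraction], list[Fraction]]:
    """Similarities of all intra-BIN and inter-BIN unordered pairs, sorted."""
    intra: list[Fraction] = []
    inter: list[Fraction] = []
    for a, b in combinations(bins.ids(), 2):
        s = similarities.s(a, b)
        if s is None:
            if similarities.prescreen_threshold is None:
                raise KeyError(
                    f"pair ({a}, {b}) missing from an exhaustive similarity "
                    "table")
            s = _BELOW_PRESCREEN
        (intra if bins.bins[a] == bins.bins[b] else inter).append(s)
    intra.sort()
    inter.sort()
    return intra, inter


def _as_fraction(s_t) -> Fraction:
    """Threshold percent as an exact rational (e.g. 97 -> 97, 97.5 -> 195/2)."""
    return Fraction(str(s_t)) if isinstance(s_t, float) else Fraction(s_t)


def _count_below(sorted_values: list[Fraction], s_t) -> int:
    return bisect_left(sorted_values, _as_fraction(s_t) / 100)


def oversplit_rate(similarities: SimilarityTable, bins: BinAssignment,
                   s_t: int | float) -> float:
    """Fraction of intra-BIN pairs with S_XY < S_T (percent)."""
    intra, _ = _pair_values(similarities, bins)
    if not intra:
        raise UndefinedRateError("no intra-BIN pairs in the dataset")
    return _count_below(intra, s_t) / len(intra)


def overmerge_rate(similarities: SimilarityTable, bins: BinAssignment,
                   s_t: int | float) -> float:
    """Fraction of inter-BIN pairs with S_XY >= S_T (percent)."""
    _, inter = _pair_values(similarities, bins)
    if not inter:
        raise UndefinedRateError("no inter-BIN pairs in the dataset")
    return (len(inter) - _count_below(inter, s_t)) / len(inter)


def error_profile(similarities: SimilarityTable, bins: BinAssignment,
                  grid: Sequence[int | float] = DEFAULT_GRID,
                  metabarcode: str = "") -> ErrorProfile:
    """Both error rates and their sum at every grid threshold."""
    if not grid:
        raise ValueError("threshold grid is empty")
    intra, inter = _pair_values(similarities, bins)
    if not intra:
        raise UndefinedRateError("no intra-BIN pairs in the dataset")
    if not inter:
        raise UndefinedRateError("no inter-BIN pairs in the dataset")
    oversplit = [_count_below(intra, t) / len(intra) for t in grid]
    overmerge = [(len(inter) - _count_below(inter, t)) / len(inter)
                 for t in grid]
    global_error = [a + b for a, b in zip(oversplit, overmerge)]
    return ErrorProfile(metabarcode, tuple(grid), oversplit, overmerge,
                        global_error, len(intra), len(inter))


def find_s_opt(profile: ErrorProfile) -> OptimalThreshold:
    """Grid threshold minimizing the global error; ties break toward the
    lower threshold."""
    best_idx = min(range(len(profile.thresholds)),
                   key=lambda i: (profile.global_error[i],
                                  profile.thresholds[i]))
    return OptimalThreshold(profile.metabarcode,
                            profile.thresholds[best_idx],
                            min(profile.global_error),
                            max(profile.global_error))


def grouped_profiles(similarities: SimilarityTable, bins: BinAssignment,
                     group_by: str = "order", min_bins: int = 100,
                     grid: Sequence[int | float] = DEFAULT_GRID,
                     metabarcode: str = "") -> dict[str, ErrorProfile]:
    """Recompute profiles within each taxonomic group holding more than
    ``min_bins`` BINs; pairs spanning two groups are excluded."""
    groups: dict[str, list[str]] = {}
    for seq_id in bins.ids():
        name = bins.rank(seq_id, group_by)
        if name:
            groups.setdefault(name, []).append(seq_id)
    out: dict[str, ErrorProfile] = {}
    for name, members in sorted(groups.items()):
        n_bins = len({bins.bins[i] for i in members})
        if n_bins <= min_bins:
            continue
        out[name] = error_profile(similarities, bins.restrict(members), grid,
                                  metabarcode=metabarcode)
    if not out:
        warnings.warn(f"no {group_by} group holds more than {min_bins} BINs",
                      stacklevel=2)
    return out
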