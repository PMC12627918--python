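"""Metabarcode gaps: similarity thresholds delineating taxonomic levels.

For each of four taxonomic levels the intra-taxon distribution is built from
sequence pairs belonging to *different sub-taxa of the same taxon*:
intra-BIN (sub-taxa = individual sequences), intra-genus (sub-taxa = BINs),
intra-family (sub-taxa = genera) and intra-order (sub-taxa = families). Only
taxa with at least two sequences from two different sub-taxa contribute.

A metabarcode gap is the midpoint between the first quartile of the
distribution at one level and the third quartile at the next level down the
similarity ladder: MG_BIN pairs intra-BIN with intra-genus, MG_GEN pairs
intra-genus with intra-family, MG_FAM pairs intra-family with intra-order.
Quartiles use linear interpolation between order statistics.

Two variants are first-class: the default summarises each taxon by its mean
pair similarity before taking quartiles; the all-pairs variant pools the raw
pair similarities (taxa then weigh in proportion to their pair counts).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import BinAssignment
from .similarity import SimilarityTable

#: Ladder of levels ordered from highest to lowest expected similarity.
LEVELS: tuple[str, ...] = ("BIN", "genus", "family", "order")


@dataclass(frozen=True)
class IntraTaxonSimilarity:
    taxon_id: str
    level: str
    mean_s: float
    n_pairs: int


@dataclass(frozen=True)
class GapEstimate:
    metabarcode: str
    mg_bin: float
    mg_gen: float
    mg_fam: float
    variant: str  # "per_taxon_means" | "all_pairs"


def _taxon_and_subtaxon(bins: BinAssignment, seq_id: str, level: str
                        ) -> tuple[str, str]:
    if level == "BIN":
        return bins.bins[seq_id], seq_id
    if level == "genus":
        return bins.rank(seq_id, "genus"), bins.bins[seq_id]
    if level == "family":
        return bins.rank(seq_id, "family"), bins.rank(seq_id, "genus")
    if level == "order":
        return bins.rank(seq_id, "order"), bins.rank(seq_id, "family")
    raise ValueError(f"unknown taxonomic level {level!r}")


def _cross_subtaxa_pairs(similarities: SimilarityTable, bins: BinAssignment,
                         level: str) -> dict[str, list[float]]:
    """Per qualifying taxon: similarities of cross-sub-taxa sequence pairs."""
    members: dict[str, list[tuple[str, str]]] = {}
    for seq_id in bins.ids():
        taxon, subtaxon = _taxon_and_subtaxon(bins, seq_id, level)
        if not taxon:
            continue
        members.setdefault(taxon, []).append((seq_id, subtaxon))
    out: dict[str, list[float]] = {}
    for taxon, seqs in sorted(members.items()):
        if len(seqs) < 2 or len({sub for _, sub in seqs}) < 2:
            continue
        values: list[float] = []
        for (a, sub_a), (b, sub_b) in combinations(seqs, 2):
            if sub_a == sub_b:
                continue
            s = similarities.s(a, b)
            if s is None:
                raise KeyError(
                    f"pair ({a}, {b}) missing from the similarity table; the "
                    "intra-taxa analysis needs exhaustive similarities")
            values.append(float(s))
        if values:
            out[taxon] = values
    return out


def intra_taxon_similarities(similarities: SimilarityTable,
                             bins: BinAssignment, level: str
                             ) -> list[IntraTaxonSimilarity]:
    """Mean cross-sub-taxa similarity per qualifying taxon at one level."""
    per_taxon = _cross_subtaxa_pairs(similarities, bins, level)
    if not per_taxon:
        warnings.warn(f"no taxon qualifies at level {level}", stacklevel=2)
    return [IntraTaxonSimilarity(taxon, level, float(np.mean(v)), len(v))
            for taxon, v in per_taxon.items()]


def all_pairs_variant(similarities: SimilarityTable, bins: BinAssignment,
                      level: str) -> list[float]:
    """Raw cross-sub-taxa pair similarities pooled over taxa."""
    per_taxon = _cross_subtaxa_pairs(similarities, bins, level)
    if not per_taxon:
        warnings.warn(f"no taxon qualifies at level {level}", stacklevel=2)
    return [s for values in per_taxon.values() for s in values]


def metabarcode_gap(upper: Sequence[float] | Sequence[IntraTaxonSimilarity],
                    lower: Sequence[float] | Sequence[IntraTaxonSimilarity]
                    ) -> float:
    """(Q1 of the higher-similarity level + Q3 of the next level down) / 2."""
    def values(dist):
        return [d.mean_s if isinstance(d, IntraTaxonSimilarity) else float(d)
                for d in dist]
    up, low = values(upper), values(lower)
    if not up or not low:
        raise ValueError("both distributions must be non-empty")
    return float((np.percentile(up, 25) + np.percentile(low, 75)) / 2)


def gap_estimate(similarities: SimilarityTable, bins: BinAssignment,
                 metabarcode: str = "", variant: str = "per_taxon_means"
                 ) -> GapEstimate:
    """MG_BIN, MG_GEN and MG_FAM for one metabarcode."""
    if variant == "per_taxon_means":
        dists = {lvl: [it.mean_s for it in
                       intra_taxon_similarities(similarities, bins, lvl)]
                 for lvl in LEVELS}
    elif variant == "all_pairs":
        dists = {lvl: all_pairs_variant(similarities, bins, lvl)
                 for lvl in LEVELS}
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return GapEstimate(
        metabarcode,
        mg_bin=metabarcode_gap(dists["BIN"], dists["genus"]),
        mg_gen=metabarcode_gap(dists["genus"], dists["family"]),
        mg_fam=metabarcode_gap(dists["family"], dists["order"]),
        variant=variant,
    )


def intra_taxa_dataframe(similarities: SimilarityTable, bins: BinAssignment,
                         metabarcode: str = "") -> pd.DataFrame:
    rows = []
    for level in LEVELS:
        for it in intra_taxon_similarities(similarities, bins, level):
            rows.append({"metabarcode": metabarcode, "level": level,
                         "taxon_id": it.taxon_id, "mean_s": it.mean_s,
                         "n_pairs": it.n_pairs})
    return pd.DataFrame(rows, columns=["metabarcode", "level", "taxon_id",
                                       "mean_s", "n_pairs"])
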