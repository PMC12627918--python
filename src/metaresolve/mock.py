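"""Mock communities of known BIN composition.

Samples communities of controlled species richness (number of BINs) and
sequence redundancy (sequences per BIN) from a reference set, clusters each
community de novo, and scores the OTU partition against the BIN truth. As
richness grows, the error balance is expected to shift from over-splitting
toward over-merging; the sweep quantifies that transition per clustering
threshold.

Vacuous error classes (a single BIN gives no inter-BIN pairs; redundancy 1
gives no intra-BIN pairs) are flagged ``*_defined = False`` and encoded 0,
never silently folded into trend statistics.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .clustering import cluster
from .errors import BinAssignment
from .similarity import SimilarityTable

DEFAULT_GRID: tuple[int, ...] = tuple(range(90, 100))


@dataclass(frozen=True)
class MockCommunitySpec:
    n_bins: int  # richness
    seqs_per_bin: int  # redundancy
    replicates: int = 20
    seed: int = 0
    method: str = "upgma"
    c_t_grid: tuple[int, ...] = DEFAULT_GRID

    def __post_init__(self) -> None:
        if self.n_bins < 1 or self.seqs_per_bin < 1 or self.replicates < 1:
            raise ValueError("n_bins, seqs_per_bin and replicates must be >= 1")
        if not self.c_t_grid:
            raise ValueError("c_t_grid is empty")


def sample_community(bins: BinAssignment, spec: MockCommunitySpec,
                     replicate_index: int) -> tuple[list[str], list[str]]:
    """Draw ``n_bins`` BINs uniformly without replacement, then
    ``seqs_per_bin`` sequences per BIN without replacement.

    BINs holding fewer sequences than requested are sampled exhaustively and
    reported in the second return value. Fully determined by
    (spec.seed, replicate_index).
    """
    members: dict[str, list[str]] = {}
    for seq_id in bins.ids():
        members.setdefault(bins.bins[seq_id], []).append(seq_id)
    bin_ids = sorted(members)
    if spec.n_bins > len(bin_ids):
        raise ValueError(
            f"cannot draw {spec.n_bins} BINs from a reference with only "
            f"{len(bin_ids)}")
    rng = np.random.default_rng([spec.seed, replicate_index])
    chosen = rng.choice(bin_ids, size=spec.n_bins, replace=False)
    ids: list[str] = []
    exhausted: list[str] = []
    for bin_id in sorted(chosen):
        pool = members[bin_id]
        if len(pool) <= spec.seqs_per_bin:
            if len(pool) < spec.seqs_per_bin:
                exhausted.append(bin_id)
            ids.extend(pool)
        else:
            ids.extend(sorted(rng.choice(pool, size=spec.seqs_per_bin,
                                         replace=False)))
    return sorted(ids), exhausted


def _pairs(labels: Mapping[str, str | int], ids: Sequence[str]) -> int:
    counts = Counter(labels[i] for i in ids)
    return sum(c * (c - 1) // 2 for c in counts.values())


def run_mock_sweep(similarities: SimilarityTable, bins: BinAssignment,
                   specs: Sequence[MockCommunitySpec],
                   sequences: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Cluster and score every (spec, replicate, C_T) combination.

    Linkage methods need only the similarity table; SWARM-style and greedy
    centroid clustering additionally need the raw sequences.
    """
    rows = []
    for spec in specs:
        for rep in range(spec.replicates):
            ids, exhausted = sample_community(bins, spec, rep)
            sub_bins = bins.restrict(ids)
            if sequences is not None:
                sub_seqs = {i: sequences[i] for i in ids}
            else:
                sub_seqs = {i: "" for i in ids}  # linkage methods ignore it
            n = len(ids)
            intra = _pairs(sub_bins.bins, ids)
            inter = n * (n - 1) // 2 - intra
            for c_t in spec.c_t_grid:
                otus = cluster(sub_seqs, similarities, spec.method, c_t)
                joint = _pairs({i: (sub_bins.bins[i], otus.assignment[i])
                                for i in ids}, ids)
                otu_pairs = _pairs(otus.assignment, ids)
                oversplit = (intra - joint) / intra if intra else 0.0
                overmerge = (otu_pairs - joint) / inter if inter else 0.0
                rows.append({
                    "n_bins": spec.n_bins,
                    "seqs_per_bin": spec.seqs_per_bin,
                    "replicate": rep,
                    "seed": spec.seed,
                    "method": spec.method,
                    "c_t": c_t,
                    "oversplit": oversplit,
                    "overmerge": overmerge,
                    "global_error": oversplit + overmerge,
                    "n_otus": otus.n_otus,
                    "oversplit_defined": intra > 0,
                    "overmerge_defined": inter > 0,
                    "n_exhausted_bins": len(exhausted),
                })
    return pd.DataFrame(rows)


def richness_trend(results: pd.DataFrame, c_t: int | float
                   ) -> tuple[float, float]:
    """Spearman correlation between richness and the over-merging rate at a
    fixed clustering threshold, over replicates with a defined rate."""
    sub = results[(results["c_t"] == c_t) & results["overmerge_defined"]]
    if sub["n_bins"].nunique() < 2:
        raise ValueError("need at least two richness levels with defined "
                         "over-merging rates")
    rho, p = spearmanr(sub["n_bins"], sub["overmerge"])
    return float(rho), float(p)
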