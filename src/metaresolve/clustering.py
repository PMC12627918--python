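"""Reference-free OTU clustering and its evaluation against BINs.

Implements the clustering families used to benchmark de novo OTU formation:
hierarchical linkage (nearest neighbour / single, furthest neighbour /
complete, UPGMA) cut at 1 - C_T/100; SWARM-style clustering that links
sequences within d differences (d derived from the longest sequence and the
clustering threshold) and takes connected components; and greedy centroid
clustering that scans sequences by decreasing length and joins the first
centroid at or above C_T. OTU partitions are scored against the BIN baseline
with the same pair-level over-splitting/over-merging definitions as the raw
similarity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import edlib
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .errors import BinAssignment, UndefinedRateError, _as_fraction
from .similarity import SimilarityTable, pairwise_similarity

LINKAGE_METHODS = {"single": "single", "complete": "complete",
                   "upgma": "average"}
ALL_METHODS = ("single", "complete", "upgma", "swarm_like", "greedy_centroid")

#: Tolerance added to the dendrogram cut height so merges at exactly the cut
#: are included (inclusive cut, mirroring the S_XY >= S_T convention) despite
#: binary floating point.
_CUT_EPS = 1e-9


@dataclass(frozen=True)
class OtuAssignment:
    method: str
    c_t: int | float
    assignment: dict[str, int]  # sequence id -> OTU id

    @property
    def n_otus(self) -> int:
        return len(set(self.assignment.values()))


@dataclass(frozen=True)
class SwarmParams:
    d: int
    longest_length: int
    c_t: int | float


def swarm_d(longest_length: int, c_t: int | float, literal: bool = False) -> int:
    """Maximum differences between directly connected sequences.

    The threshold is a similarity, so the difference budget comes from its
    complement: d = floor(L_max * (1 - C_T/100)). ``literal=True`` selects
    the degenerate reading d = floor(L_max * C_T/100) for audit only.
    """
    frac = _as_fraction(c_t) / 100
    return int(longest_length * (frac if literal else 1 - frac))


class _UnionFind:
    def __init__(self, items):
        self.parent = {i: i for i in items}

    def find(self, i):
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


def _components_to_assignment(ids: Sequence[str], uf: _UnionFind
                              ) -> dict[str, int]:
    labels: dict[str, int] = {}
    out: dict[str, int] = {}
    for i in ids:
        root = uf.find(i)
        out[i] = labels.setdefault(root, len(labels))
    return out


def linkage_cluster(similarities: SimilarityTable, ids: Sequence[str],
                    method: str, c_t: int | float) -> OtuAssignment:
    """Agglomerative clustering on distance 1 - S_XY, cut at 1 - C_T/100.

    Merges at exactly the cut height are included. Pairs absent from a
    prescreened table are treated as more distant than the cut.
    """
    if method not in LINKAGE_METHODS:
        raise ValueError(f"unknown linkage method {method!r}; "
                         f"expected one of {sorted(LINKAGE_METHODS)}")
    ids = sorted(ids)
    n = len(ids)
    if n == 1:
        return OtuAssignment(method, c_t, {ids[0]: 0})
    dist = np.ones((n, n))
    np.fill_diagonal(dist, 0.0)
    for i, j in combinations(range(n), 2):
        s = similarities.s(ids[i], ids[j])
        if s is not None:
            dist[i, j] = dist[j, i] = 1.0 - float(s)
    Z = linkage(squareform(dist, checks=False), method=LINKAGE_METHODS[method])
    cut = 1.0 - float(_as_fraction(c_t)) / 100.0
    labels = fcluster(Z, t=cut + _CUT_EPS, criterion="distance")
    return OtuAssignment(method, c_t, {i: int(l) - 1 for i, l in zip(ids, labels)})


def swarm_like_cluster(sequences: Mapping[str, str], c_t: int | float,
                       literal: bool = False) -> OtuAssignment:
    """Link sequence pairs within d edit differences; OTUs are the connected
    components of that graph (transitive, single-linkage-like growth)."""
    if not sequences:
        raise ValueError("no sequences to cluster")
    ids = sorted(sequences)
    longest = max(len(s) for s in sequences.values())
    d = swarm_d(longest, c_t, literal=literal)
    uf = _UnionFind(ids)
    for a, b in combinations(ids, 2):
        res = edlib.align(sequences[a], sequences[b], task="distance", k=d)
        if res["editDistance"] != -1:
            uf.union(a, b)
    return OtuAssignment("swarm_like", c_t, _components_to_assignment(ids, uf))


def greedy_centroid_cluster(sequences: Mapping[str, str], c_t: int | float
                            ) -> OtuAssignment:
    """Linearized centroid clustering: scan by decreasing length (ties by
    id); join the first centroid with S_XY >= C_T, else open a new one."""
    if not sequences:
        raise ValueError("no sequences to cluster")
    threshold = _as_fraction(c_t) / 100
    order = sorted(sequences, key=lambda i: (-len(sequences[i]), i))
    centroids: list[tuple[str, str]] = []  # (id, sequence)
    assignment: dict[str, int] = {}
    for seq_id in order:
        seq = sequences[seq_id]
        for otu, (_, centroid_seq) in enumerate(centroids):
            sim = pairwise_similarity(seq, centroid_seq)
            if sim.s_exact >= threshold:
                assignment[seq_id] = otu
                break
        else:
            assignment[seq_id] = len(centroids)
            centroids.append((seq_id, seq))
    return OtuAssignment("greedy_centroid", c_t, assignment)


def cluster(sequences: Mapping[str, str], similarities: SimilarityTable,
            method: str, c_t: int | float) -> OtuAssignment:
    if method in LINKAGE_METHODS:
        return linkage_cluster(similarities, sorted(sequences), method, c_t)
    if method == "swarm_like":
        return swarm_like_cluster(sequences, c_t)
    if method == "greedy_centroid":
        return greedy_centroid_cluster(sequences, c_t)
    raise ValueError(f"unknown clustering method {method!r}")


def otu_vs_bin_errors(otus: OtuAssignment, bins: BinAssignment
                      ) -> tuple[float, float]:
    """Pairwise OTU errors against BINs.

    Over-splitting: intra-BIN pairs split across OTUs, over all intra-BIN
    pairs. Over-merging: inter-BIN pairs sharing an OTU, over all inter-BIN
    pairs.
    """
    ids = sorted(otus.assignment)
    missing = [i for i in ids if i not in bins.bins]
    if missing:
        raise KeyError(f"sequences without a BIN: {missing[:5]}")
    n = len(ids)

    def pair_count(labels: Mapping) -> int:
        counts: dict = {}
        for i in ids:
            counts[labels[i]] = counts.get(labels[i], 0) + 1
        return sum(c * (c - 1) // 2 for c in counts.values())

    intra_pairs = pair_count(bins.bins)
    otu_pairs = pair_count(otus.assignment)
    joint = pair_count({i: (bins.bins[i], otus.assignment[i]) for i in ids})
    total = n * (n - 1) // 2
    inter_pairs = total - intra_pairs
    if intra_pairs == 0:
        raise UndefinedRateError("no intra-BIN pairs among clustered sequences")
    if inter_pairs == 0:
        raise UndefinedRateError("no inter-BIN pairs among clustered sequences")
    oversplit = (intra_pairs - joint) / intra_pairs
    overmerge = (otu_pairs - joint) / inter_pairs
    return oversplit, overmerge


@dataclass
class ClusterErrorProfile:
    method: str
    thresholds: tuple[int | float, ...]
    oversplit_rate: list[float]
    overmerge_rate: list[float]
    global_error: list[float]
    c_opt: int | float

    def to_dataframe(self, metabarcode: str = "") -> pd.DataFrame:
        return pd.DataFrame({
            "metabarcode": metabarcode,
            "method": self.method,
            "c_t": list(self.thresholds),
            "oversplit": self.oversplit_rate,
            "overmerge": self.overmerge_rate,
            "global_error": self.global_error,
        })


def cluster_error_profile(sequences: Mapping[str, str],
                          similarities: SimilarityTable, bins: BinAssignment,
                          methods: Sequence[str] = ALL_METHODS,
                          grid: Sequence[int | float] = tuple(range(90, 100)),
                          ) -> list[ClusterErrorProfile]:
    """Cluster then score per method and grid threshold; C_OPT per method
    (ties toward the lower threshold)."""
    profiles = []
    for method in methods:
        oversplit, overmerge = [], []
        for c_t in grid:
            otus = cluster(sequences, similarities, method, c_t)
            os_rate, om_rate = otu_vs_bin_errors(otus, bins)
            oversplit.append(os_rate)
            overmerge.append(om_rate)
        global_error = [a + b for a, b in zip(oversplit, overmerge)]
        best = min(range(len(grid)), key=lambda i: (global_error[i], grid[i]))
        profiles.append(ClusterErrorProfile(method, tuple(grid), oversplit,
                                            overmerge, global_error,
                                            grid[best]))
    return profiles
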