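"""Independent reference implementations used as test oracles.

These deliberately share no code with the package: alignment is done by
exhaustive path enumeration (tiny inputs) or memoised suffix recursion;
rates are naive double loops; clustering is a greedy O(n^3) agglomerative
merge loop.
"""

from __future__ import annotations

from fractions import Fraction
from functools import lru_cache
from itertools import combinations

IUPAC = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"}, "H": {"A", "C", "T"},
    "V": {"A", "C", "G"}, "N": {"A", "C", "G", "T"},
}

_COMP = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    return seq.upper().translate(_COMP)[::-1]


# -- alignment -------------------------------------------------------------

def align_suffix_oracle(x: str, y: str) -> tuple[int, int, int]:
    """Best (score, matches, columns) overlap alignment via memoised
    recursion over suffixes, trying every one-sided leading trim."""
    n, m = len(x), len(y)

    @lru_cache(maxsize=None)
    def suffix(i: int, j: int) -> tuple[int, int, int]:
        if i == n or j == m:  # remaining characters are a free trailing gap
            return (0, 0, 0)
        eq = x[i] == y[j]
        d = suffix(i + 1, j + 1)
        best = (d[0] + (1 if eq else -1), d[1] + (1 if eq else 0), d[2] - 1)
        for nxt in (suffix(i + 1, j), suffix(i, j + 1)):
            cand = (nxt[0] - 1, nxt[1], nxt[2] - 1)
            if cand > best:
                best = cand
        return best

    best = (0, 0, 0)  # the empty overlap
    for i0 in range(n):
        best = max(best, suffix(i0, 0))
    for j0 in range(m):
        best = max(best, suffix(0, j0))
    return best[0], best[1], -best[2]


def align_enum_oracle(x: str, y: str) -> tuple[int, int, int]:
    """Best overlap alignment by brute-force enumeration of every global
    alignment path, with homogeneous terminal gap runs free. Tiny inputs
    only (the path count explodes combinatorially)."""
    n, m = len(x), len(y)
    best = (0, 0, 0)  # (score, matches, -columns); empty overlap allowed

    def evaluate(cols: list[tuple[str, str]]) -> tuple[int, int, int]:
        # a terminal gap run is free only while it keeps gapping the same
        # sequence (a path along the dynamic-programme boundary)
        lo = 0
        if cols and "-" in cols[0]:
            side = cols[0].index("-")
            while lo < len(cols) and cols[lo][side] == "-":
                lo += 1
        hi = len(cols)
        if hi > lo and "-" in cols[hi - 1]:
            side = cols[hi - 1].index("-")
            while hi > lo and cols[hi - 1][side] == "-":
                hi -= 1
        score = matches = 0
        for a, b in cols[lo:hi]:
            if a == "-" or b == "-":
                score -= 1
            elif a == b:
                score += 1
                matches += 1
            else:
                score -= 1
        return (score, matches, -(hi - lo))

    def walk(i: int, j: int, cols: list[tuple[str, str]]) -> None:
        nonlocal best
        if i == n and j == m:
            best = max(best, evaluate(cols))
            return
        if i < n and j < m:
            walk(i + 1, j + 1, cols + [(x[i], y[j])])
        if i < n:
            walk(i + 1, j, cols + [(x[i], "-")])
        if j < m:
            walk(i, j + 1, cols + [("-", y[j])])

    walk(0, 0, [])
    return best[0], best[1], -best[2]


def similarity_oracle(x: str, y: str) -> Fraction:
    _, matches, columns = align_suffix_oracle(x, y)
    return Fraction(matches, columns) if columns else Fraction(0)


# -- primer sites ----------------------------------------------------------

def _mm(template_char: str, primer_char: str) -> bool:
    return not IUPAC[template_char] <= IUPAC[primer_char]


def _one_strand_sites(template: str, primer: str, max_mm: int, max_indel: int,
                      strand: str) -> set[tuple]:
    L, m = len(template), len(primer)
    out: set[tuple] = set()
    for s in range(L - m + 1):  # no indel
        mm = sum(_mm(template[s + j], primer[j]) for j in range(m))
        if mm <= max_mm:
            out.add((s, s + m, mm, 0, strand))
    if max_indel >= 1 and m >= 2:
        for s in range(L - (m - 1) + 1):  # one primer base unaligned
            best = None
            for k in range(m):
                window = template[s:s + m - 1]
                pr = primer[:k] + primer[k + 1:]
                mm = sum(_mm(t, p) for t, p in zip(window, pr))
                best = mm if best is None else min(best, mm)
            if best is not None and best <= max_mm:
                out.add((s, s + m - 1, best, 1, strand))
        for s in range(L - (m + 1) + 1):  # one extra template base
            best = None
            for k in range(1, m):
                window = template[s:s + k] + template[s + k + 1:s + m + 1]
                mm = sum(_mm(t, p) for t, p in zip(window, primer))
                best = mm if best is None else min(best, mm)
            if best is not None and best <= max_mm:
                out.add((s, s + m + 1, best, 1, strand))
    return out


def primer_sites_oracle(template: str, primer: str, max_mm: int = 5,
                        max_indel: int = 1) -> set[tuple]:
    """All (start, end, mismatches, indels, strand) sites, both strands."""
    template = template.upper()
    return (_one_strand_sites(template, primer.upper(), max_mm, max_indel,
                              "sense")
            | _one_strand_sites(template, revcomp(primer), max_mm, max_indel,
                                "antisense"))


# -- pair-level error rates ------------------------------------------------

def rates_oracle(sims: dict[frozenset, Fraction], bins: dict[str, str],
                 s_t: Fraction) -> tuple[Fraction, Fraction]:
    """(oversplit, overmerge) by naive enumeration of all unordered pairs."""
    intra_err = intra_tot = inter_err = inter_tot = 0
    for a, b in combinations(sorted(bins), 2):
        s = sims[frozenset((a, b))]
        if bins[a] == bins[b]:
            intra_tot += 1
            intra_err += s < s_t
        else:
            inter_tot += 1
            inter_err += s >= s_t
    return (Fraction(intra_err, intra_tot), Fraction(inter_err, inter_tot))


def otu_errors_oracle(otus: dict[str, int], bins: dict[str, str]
                      ) -> tuple[Fraction, Fraction]:
    split = intra = merged = inter = 0
    for a, b in combinations(sorted(otus), 2):
        if bins[a] == bins[b]:
            intra += 1
            split += otus[a] != otus[b]
        else:
            inter += 1
            merged += otus[a] == otus[b]
    return Fraction(split, intra), Fraction(merged, inter)


# -- clustering ------------------------------------------------------------

def naive_agglomerative(dist, method: str, cut: float) -> list[int]:
    """Greedy agglomerative merge loop; UPGMA distance is the unweighted mean
    over all original cross pairs. Returns labels per input index."""
    import numpy as np
    dist = np.asarray(dist, dtype=float)
    reduce = {"single": np.min, "complete": np.max, "upgma": np.mean}[method]
    clusters: list[list[int]] = [[i] for i in range(len(dist))]
    while len(clusters) > 1:
        best = None
        for a, b in combinations(range(len(clusters)), 2):
            d = float(reduce(dist[np.ix_(clusters[a], clusters[b])]))
            if best is None or d < best[0]:
                best = (d, a, b)
        if best is None or best[0] > cut:
            break
        _, a, b = best
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    labels = [0] * len(dist)
    for label, members in enumerate(clusters):
        for i in members:
            labels[i] = label
    return labels


def components_at_threshold(ids: list[str], sims: dict[frozenset, Fraction],
                            threshold: Fraction) -> dict[str, int]:
    """Connected components of the graph with edges S_XY >= threshold."""
    parent = {i: i for i in ids}

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for a, b in combinations(ids, 2):
        if sims[frozenset((a, b))] >= threshold:
            parent[find(a)] = find(b)
    roots: dict[str, int] = {}
    return {i: roots.setdefault(find(i), len(roots)) for i in ids}


def quartiles_oracle(values: list[float]) -> tuple[float, float]:
    """Q1/Q3 with linear interpolation between order statistics."""
    v = sorted(values)
    n = len(v)

    def q(p: float) -> float:
        h = (n - 1) * p
        lo = int(h)
        if lo + 1 >= n:
            return v[-1]
        return v[lo] + (h - lo) * (v[lo + 1] - v[lo])

    return q(0.25), q(0.75)
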