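"""In-silico metabarcode extraction.

Locates degenerate primers on each gene sequence with a bounded error budget
(at most five primer-template mismatches and at most one insertion or
deletion), picks the forward/reverse site pair whose implied insert length is
closest to the documented mean, fixes a consensus start/end across all
sequences in alignment-column coordinates, and extracts the quality-filtered
inserts. Metabarcodes are the inter-primer insert; primer-binding regions are
excluded.

Primer sets flagged ``orientation="reverse"`` are annotated on the antisense
strand: their amplicon is located by swapping the primer roles on the sense
strand and the extracted insert is reverse-complemented into metabarcode
orientation at the end, so all sequences of one metabarcode share a single
strand convention.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from ._seq import degap_with_map, iupac_masks, n_fraction, revcomp
from .primers import PrimerSet

MAX_MISMATCH_DEFAULT = 5
MAX_INDEL_DEFAULT = 1

_PAD = 16  # outside the 4-bit IUPAC mask space: never matches anything


class NoAmpliconError(ValueError):
    """No valid forward/reverse site combination exists on this sequence."""


@dataclass(frozen=True)
class PrimerMatch:
    """One approximate primer occurrence on the ungapped gene (0-based
    half-open template coordinates)."""

    primer_index: int
    start: int
    end: int
    mismatches: int
    indels: int
    strand: str  # "sense" | "antisense"

    @property
    def cost(self) -> int:
        return self.mismatches + self.indels


@dataclass(frozen=True)
class ConsensusWindow:
    metabarcode: str
    start_col: int
    end_col: int
    support: float


@dataclass(frozen=True)
class MetabarcodeSequence:
    accession: str
    metabarcode: str
    sequence: str
    n_fraction: float = field(default=-1.0)

    def __post_init__(self) -> None:
        if self.n_fraction < 0:
            object.__setattr__(self, "n_fraction", n_fraction(self.sequence))

    @property
    def empty(self) -> bool:
        return not self.sequence


def _mismatch_rows(tmask: np.ndarray, pmask: np.ndarray, delta: int) -> np.ndarray:
    """``M[j, s]`` = primer position ``j`` mismatches template position
    ``s + j + delta``; out-of-range template positions always mismatch."""
    m, L = len(pmask), len(tmask)
    padded = np.full(L + m + 2, _PAD, dtype=np.uint8)
    padded[1:L + 1] = tmask
    M = np.empty((m, L), dtype=np.int32)
    inv = ~pmask
    for j in range(m):
        lo = 1 + j + delta
        M[j] = (padded[lo:lo + L] & inv[j]) != 0
    return M


def _sites_one_strand(tmask: np.ndarray, pmask: np.ndarray, max_mismatch: int,
                      max_indel: int, primer_index: int, strand: str
                      ) -> list[PrimerMatch]:
    m, L = len(pmask), len(tmask)
    out: list[PrimerMatch] = []
    if L < m - min(max_indel, 1):
        return out
    M0 = _mismatch_rows(tmask, pmask, 0)
    P0 = np.zeros((m + 1, L), dtype=np.int32)
    np.cumsum(M0, axis=0, out=P0[1:])

    # no indel: windows [s, s+m)
    if L >= m:
        mm0 = P0[m]
        for s in np.nonzero(mm0[:L - m + 1] <= max_mismatch)[0]:
            out.append(PrimerMatch(primer_index, int(s), int(s) + m,
                                   int(mm0[s]), 0, strand))
    if max_indel >= 1 and m >= 2:
        # one primer base unaligned (deletion): windows [s, s+m-1)
        Mm1 = _mismatch_rows(tmask, pmask, -1)
        S1 = np.zeros((m + 1, L), dtype=np.int32)
        S1[:m] = np.cumsum(Mm1[::-1], axis=0)[::-1]  # S1[k] = sum_{j>=k}
        ks = np.arange(m)
        mm_del = (P0[ks] + S1[ks + 1]).min(axis=0)
        hi = L - (m - 1) + 1
        for s in np.nonzero(mm_del[:hi] <= max_mismatch)[0]:
            out.append(PrimerMatch(primer_index, int(s), int(s) + m - 1,
                                   int(mm_del[s]), 1, strand))
        # one extra template base (insertion): windows [s, s+m+1)
        if L >= m + 1:
            Mp1 = _mismatch_rows(tmask, pmask, +1)
            Sp = np.zeros((m + 1, L), dtype=np.int32)
            Sp[:m] = np.cumsum(Mp1[::-1], axis=0)[::-1]
            ks = np.arange(1, m)
            mm_ins = (P0[ks] + Sp[ks]).min(axis=0)
            hi = L - (m + 1) + 1
            for s in np.nonzero(mm_ins[:hi] <= max_mismatch)[0]:
                out.append(PrimerMatch(primer_index, int(s), int(s) + m + 1,
                                       int(mm_ins[s]), 1, strand))
    return out


def find_primer_sites(template: str, primer: str,
                      max_mismatch: int = MAX_MISMATCH_DEFAULT,
                      max_indel: int = MAX_INDEL_DEFAULT,
                      primer_index: int = 0) -> list[PrimerMatch]:
    """All approximate occurrences of ``primer`` (sense pass) and of its
    reverse complement (antisense pass) on ``template``.

    A degenerate primer position matches, at zero cost, any template base in
    its IUPAC expansion; a template base outside the expansion (including any
    ambiguity code not covered) is a mismatch. Matches are sorted by
    (mismatches + indels, start).
    """
    if not template or not primer:
        raise ValueError("template and primer must be non-empty")
    tmask = iupac_masks(template)
    matches = _sites_one_strand(tmask, iupac_masks(primer), max_mismatch,
                                max_indel, primer_index, "sense")
    matches += _sites_one_strand(tmask, iupac_masks(revcomp(primer)),
                                 max_mismatch, max_indel, primer_index,
                                 "antisense")
    matches.sort(key=lambda p: (p.cost, p.start, p.end))
    return matches


def choose_primer_pair(forward_matches: Sequence[PrimerMatch],
                       reverse_matches: Sequence[PrimerMatch],
                       documented_length: int
                       ) -> tuple[PrimerMatch, PrimerMatch]:
    """Pick the site pair whose insert length is closest to the documented
    mean; ties by fewest total primer-template errors, then leftmost sites.

    Forward sites must be sense-strand occurrences; reverse sites are the
    antisense occurrences (the reverse complement of the reverse primer on
    the sense strand), downstream of the forward site.
    """
    best: tuple | None = None
    for f in forward_matches:
        if f.strand != "sense":
            continue
        for r in reverse_matches:
            if r.strand != "antisense" or r.start < f.end:
                continue
            insert_len = r.start - f.end
            key = (abs(insert_len - documented_length),
                   f.mismatches + r.mismatches,
                   f.indels + r.indels,
                   f.start, r.start)
            if best is None or key < best[0]:
                best = (key, f, r)
    if best is None:
        raise NoAmpliconError("no valid forward/reverse combination")
    return best[1], best[2]


def consensus_window(per_sequence_windows: Sequence[tuple[int, int]],
                     metabarcode: str = "") -> ConsensusWindow:
    """Most frequently observed start and end alignment columns, determined
    independently; ties break toward the smaller column index."""
    if not per_sequence_windows:
        raise ValueError("no per-sequence windows to take a consensus over")
    starts = Counter(w[0] for w in per_sequence_windows)
    ends = Counter(w[1] for w in per_sequence_windows)
    start_col = min(c for c, n in starts.items() if n == max(starts.values()))
    end_col = min(c for c, n in ends.items() if n == max(ends.values()))
    agree = sum(1 for w in per_sequence_windows
                if w[0] == start_col and w[1] == end_col)
    return ConsensusWindow(metabarcode, start_col, end_col,
                           agree / len(per_sequence_windows))


def extract_metabarcodes(alignment: Mapping[str, str], window: ConsensusWindow
                         ) -> list[MetabarcodeSequence]:
    """Degapped characters of columns [start_col, end_col) per sequence."""
    out = []
    for acc, aligned in alignment.items():
        chunk = aligned[window.start_col:window.end_col]
        seq = chunk.replace("-", "").replace(".", "")
        out.append(MetabarcodeSequence(acc, window.metabarcode, seq))
    return out


def qc_filter(metabarcodes: Sequence[MetabarcodeSequence]
              ) -> tuple[list[MetabarcodeSequence],
                         list[tuple[MetabarcodeSequence, str]]]:
    """Reject abnormal extractions: length below half the first quartile or
    above twice the third quartile, or more than 10% missing nucleotides."""
    kept: list[MetabarcodeSequence] = []
    rejected: list[tuple[MetabarcodeSequence, str]] = []
    lengths = np.array([len(m.sequence) for m in metabarcodes])
    if len(metabarcodes) >= 4:
        q1, q3 = np.percentile(lengths, [25, 75])
    else:
        warnings.warn("fewer than 4 sequences: length-quartile filter skipped",
                      stacklevel=2)
        q1 = q3 = None
    for m in metabarcodes:
        n = len(m.sequence)
        if q1 is not None and n < q1 / 2:
            rejected.append((m, f"length {n} < Q1/2 ({q1 / 2:g})"))
        elif q3 is not None and n > 2 * q3:
            rejected.append((m, f"length {n} > 2*Q3 ({2 * q3:g})"))
        elif m.n_fraction > 0.10:
            rejected.append((m, f"N fraction {m.n_fraction:.3f} > 0.10"))
        else:
            kept.append(m)
    return kept, rejected


@dataclass
class ExtractionResult:
    primer_set: PrimerSet
    window: ConsensusWindow | None
    kept: list[MetabarcodeSequence]
    rejected: list[tuple[str, str]]  # (accession, reason)
    report: list[dict]

    @property
    def sequences(self) -> dict[str, str]:
        return {m.accession: m.sequence for m in self.kept}


def extract_metabarcode_set(alignment: Mapping[str, str], primer_set: PrimerSet,
                            max_mismatch: int = MAX_MISMATCH_DEFAULT,
                            max_indel: int = MAX_INDEL_DEFAULT
                            ) -> ExtractionResult:
    """Run the full per-metabarcode extraction over one gene alignment.

    Sequences without any valid primer pair are excluded with reason
    "no amplicon" (this is the expected, clean outcome for primer sets that
    cannot be reliably matched, such as long highly degenerate ones).
    """
    swap = primer_set.orientation == "reverse"
    five_prime = primer_set.reverse_seqs if swap else primer_set.forward_seqs
    three_prime = primer_set.forward_seqs if swap else primer_set.reverse_seqs

    windows: dict[str, tuple[int, int]] = {}
    pair_info: dict[str, tuple[PrimerMatch, PrimerMatch]] = {}
    rejected: list[tuple[str, str]] = []
    report: list[dict] = []
    for acc, aligned in alignment.items():
        ungapped, colmap = degap_with_map(aligned)
        if not ungapped:
            rejected.append((acc, "empty sequence"))
            continue
        fwd: list[PrimerMatch] = []
        rev: list[PrimerMatch] = []
        for i, p in enumerate(five_prime):
            fwd += find_primer_sites(ungapped, p, max_mismatch, max_indel, i)
        for i, p in enumerate(three_prime):
            rev += find_primer_sites(ungapped, p, max_mismatch, max_indel, i)
        try:
            f, r = choose_primer_pair(fwd, rev, primer_set.documented_length)
        except NoAmpliconError:
            rejected.append((acc, "no amplicon"))
            report.append({"accession": acc, "metabarcode": primer_set.short_name,
                           "start": None, "end": None, "mismatches": None,
                           "indels": None, "reason": "no amplicon"})
            continue
        if r.start <= f.end:
            rejected.append((acc, "empty insert"))
            continue
        start_col = int(colmap[f.end])
        end_col = int(colmap[r.start - 1]) + 1
        windows[acc] = (start_col, end_col)
        pair_info[acc] = (f, r)
        report.append({"accession": acc, "metabarcode": primer_set.short_name,
                       "start": start_col, "end": end_col,
                       "mismatches": f.mismatches + r.mismatches,
                       "indels": f.indels + r.indels, "reason": ""})

    if not windows:
        return ExtractionResult(primer_set, None, [], rejected, report)

    window = consensus_window(list(windows.values()), primer_set.short_name)
    sub_alignment = {acc: alignment[acc] for acc in windows}
    extracted = extract_metabarcodes(sub_alignment, window)
    if swap:
        extracted = [MetabarcodeSequence(m.accession, m.metabarcode,
                                         revcomp(m.sequence))
                     for m in extracted]
    nonempty = [m for m in extracted if not m.empty]
    rejected += [(m.accession, "empty in consensus window")
                 for m in extracted if m.empty]
    kept, qc_rejected = qc_filter(nonempty) if nonempty else ([], [])
    rejected += [(m.accession, reason) for m, reason in qc_rejected]
    return ExtractionResult(primer_set, window, kept, rejected, report)
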