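"""Primer sets used to delimit fish eDNA metabarcodes.

A :class:`PrimerSet` holds the degenerate forward/reverse primers of one
metabarcode, the gene it sits on, its documented mean insert length and its
orientation relative to the reference strand. The built-in registry covers
the published fish-specific sets; users can supply their own table as TSV
with the same columns.

Dual-variant sets (several published forward or reverse primers amplifying
the same locus) carry more than one sequence per side; primer matching pools
candidate sites over all variants.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

from ._seq import IUPAC_MASK

ORIENTATIONS = ("normal", "reverse")


@dataclass(frozen=True)
class PrimerSet:
    short_name: str
    forward_seqs: tuple[str, ...]
    reverse_seqs: tuple[str, ...]
    gene: str
    documented_length: int
    orientation: str = "normal"

    def __post_init__(self) -> None:
        if not self.forward_seqs or not self.reverse_seqs:
            raise ValueError(f"{self.short_name}: need >=1 primer per side")
        for seq in (*self.forward_seqs, *self.reverse_seqs):
            bad = set(seq.upper()) - set(IUPAC_MASK)
            if bad:
                raise ValueError(
                    f"{self.short_name}: invalid IUPAC codes {sorted(bad)} in {seq}")
        if self.documented_length <= 0:
            raise ValueError(f"{self.short_name}: documented_length must be > 0")
        if self.orientation not in ORIENTATIONS:
            raise ValueError(f"{self.short_name}: orientation must be one of "
                             f"{ORIENTATIONS}")


def _ps(name, fwd, rev, gene, length, orientation="normal"):
    fwd = (fwd,) if isinstance(fwd, str) else tuple(fwd)
    rev = (rev,) if isinstance(rev, str) else tuple(rev)
    return PrimerSet(name, fwd, rev, gene, length, orientation)


#: Published fish metabarcode primer sets plus the COI barcoding primers.
#: Insert lengths are the documented study means.
DEFAULT_PRIMER_SETS: dict[str, PrimerSet] = {p.short_name: p for p in [
    _ps("12SF1R1", "ACTGGGATTAGATACCCC", "TAGAACAGGCTCCTCTAG", "12S", 106),
    _ps("12SV5", "TAGAACAGGCTCCTCTAG", "TTAGATACCCCACTATGC", "12S", 99, "reverse"),
    _ps("16SFD", "GACCCTATGGAGCTTTAGAC", "CGCTGTTATCCCTADRGTAACT", "16S", 204),
    _ps("Ac12S", "ACTGGGATTAGATACCCCACTATG", "GAGAGTGACGGGCGGTGT", "12S", 390),
    _ps("Ac16S", "CCTTTTGCATCATGATTTAGC", "CAGGTGGCTGCTTTTAGGC", "16S", 338),
    _ps("AcMDB", "GCCTATATACCGCCGTCG", "GTACACTTACCATGTTACGACTT", "12S", 281),
    _ps("Fish16S", "GGTCGCCCCAACCRAAG", "CGAGAAGACCCTWTGGAGCTTNAG", "16S", 68,
        "reverse"),
    _ps("Fish2b-deg", "GATGGCGTAGGCAAACAAGA", "ACAACTTCACCCCTGCAAAC", "CytB", 40,
        "reverse"),
    _ps("FishCB", "TCCTTTTGAGGCGCTACAGT", "GGAATGCGAAGAATCGTGTT", "CytB", 91),
    _ps("FishF1-R1", "TCAACCAACCACAAAGACATTGGCAC", "ACTTCAGGGTGACCGAAGAATCAGAA",
        "COI", 652),
    _ps("L14735c-c2", "AAAAACCACCGTTGTTATTCAACTA",
        ("ACTTCAGGGTGACCGAAGAATCAGAA", "GCDCCTCARAATGAYATTTGTCCTCA"),
        "CytB", 413),
    _ps("L14841", "AAAAAGCTTCCATCCAACATCTCAGCATGATGAAA",
        "AAACTGCAGCCCCTCAGAATGATATTTGTCCTCA", "CytB", 307),
    _ps("L14912", "TTCCTAGCCATACAYTAYAC", "GGTGGCKCCTCAGAAGGACATTTGKCCYCA",
        "CytB", 235),
    _ps("L2513", "GCCTGTTTACCAAAAACATCAC", "CTCCATAGGGTCTTCTCGTCTT", "16S", 203),
    _ps("MiFish", "GTCGGTAAAACTCGTGCCAGC", "CATAGTGGGGTATCTAATCCCAGTTTG", "12S",
        171),
    _ps("Minibar", "TCCACTAATCACAARGATATTGGTAC", "GAAAATCATAATGAAGGCATGAGC",
        "COI", 127),
    _ps("PS1", "ACCTGCCTGCCGTATTTGGYGCYTGRGCCGGRATAGT",
        "ACGCCACCGAGCCARAARCTYATRTTRTTYATTCG", "COI", 247),
    _ps("Teleo1", "ACACCGCCCGTCACTCT", "CTTCCGGTACACTTACCATG", "12S", 63),
    _ps("Teleo2", "AAACTCGTGCCAGCCACC", "GGGTATCTAATCCCAGTTTG", "12S", 167),
    _ps("Ve16S", "CGAGAAGACCCTATGGAGCTTA", "AATCGTTGAACAAACGAACC", "16S", 317),
    _ps("Vert16S", "AGACGAGAAGACCCYDTGGAGCTT", "GATCCAACATCGAGGTCGTAA", "16S",
        266),
]}

_COLUMNS = ("short_name", "forward", "reverse", "gene", "documented_length",
            "orientation")


def load_primer_table(path: str | Path) -> dict[str, PrimerSet]:
    """Read a primer table TSV. Multiple primer variants are comma-separated."""
    sets: dict[str, PrimerSet] = {}
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        missing = set(_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        for row in reader:
            ps = PrimerSet(
                short_name=row["short_name"],
                forward_seqs=tuple(s.strip() for s in row["forward"].split(",") if s.strip()),
                reverse_seqs=tuple(s.strip() for s in row["reverse"].split(",") if s.strip()),
                gene=row["gene"],
                documented_length=int(row["documented_length"]),
                orientation=row["orientation"].strip().lower() or "normal",
            )
            sets[ps.short_name] = ps
    return sets


def write_primer_table(sets: dict[str, PrimerSet], path: str | Path) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t")
        writer.writerow(_COLUMNS)
        for ps in sets.values():
            writer.writerow([
                ps.short_name, ",".join(ps.forward_seqs), ",".join(ps.reverse_seqs),
                ps.gene, ps.documented_length, ps.orientation,
            ])
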