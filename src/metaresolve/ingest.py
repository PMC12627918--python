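"""Mitogenome flat-file ingest and target-gene extraction.

Parses annotated (possibly circular) mitogenome records from GenBank flat
files, pulls out the four genes that host fish metabarcodes (COI, CytB, 12S,
16S) using the annotated first/last nucleotide positions, and applies the
structural quality filters: implausible rRNA gene lengths and
reverse-oriented assemblies.

Coordinates stored on :class:`MitogenomeRecord` are 1-based inclusive, as in
the source flat files; all internal arithmetic converts to 0-based half-open
and converts back at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import (CompoundLocation, SeqFeature, SimpleLocation)
from Bio.SeqRecord import SeqRecord

from ._seq import revcomp

TARGET_GENES = ("COI", "CytB", "12S", "16S")

#: Case-insensitive annotation-name synonyms for each target gene. Flat files
#: vary widely in how they label mitochondrial genes.
GENE_SYNONYMS: dict[str, str] = {}
for _canon, _names in {
    "COI": ("COI", "CO1", "COX1", "COXI", "MT-CO1", "cytochrome c oxidase subunit 1",
            "cytochrome c oxidase subunit I", "cytochrome oxidase subunit 1"),
    "CytB": ("CYTB", "COB", "CYB", "MT-CYB", "cytochrome b"),
    "12S": ("12S", "RRNS", "12S rRNA", "12S ribosomal RNA", "s-rRNA",
            "small subunit ribosomal RNA", "MT-RNR1", "rrn12"),
    "16S": ("16S", "RRNL", "16S rRNA", "16S ribosomal RNA", "l-rRNA",
            "large subunit ribosomal RNA", "MT-RNR2", "rrn16"),
}.items():
    for _n in _names:
        GENE_SYNONYMS[_n.upper()] = _canon


class FlatfileParseError(ValueError):
    """A flat-file entry could not be interpreted."""


class GeneAbsentError(KeyError):
    """The requested gene is not annotated on the record."""


class ExtensionOutOfRangeError(ValueError):
    """The upstream extension window does not exist on a linear record."""


@dataclass(frozen=True)
class GeneFeature:
    """One annotated gene: 1-based inclusive coordinates on the source strand.

    On a circular record a feature spanning the origin has ``start > end``.
    """

    gene: str
    start: int
    end: int
    strand: int = 1


@dataclass
class MitogenomeRecord:
    accession: str
    sequence: str
    circular: bool = False
    species: str = ""
    genus: str = ""
    family: str = ""
    order: str = ""
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.accession}: empty sequence")
        n = len(self.sequence)
        for f in self.features:
            if not (1 <= f.start <= n and 1 <= f.end <= n):
                raise ValueError(
                    f"{self.accession}: feature {f.gene} at {f.start}..{f.end} "
                    f"outside sequence of length {n}")
            if not self.circular and f.start > f.end:
                raise ValueError(
                    f"{self.accession}: origin-spanning feature {f.gene} on a "
                    "linear record")

    def feature_for(self, gene: str) -> GeneFeature | None:
        canon = GENE_SYNONYMS.get(gene.upper(), gene)
        for f in self.features:
            if f.gene == canon:
                return f
        return None

    @property
    def missing_genes(self) -> tuple[str, ...]:
        return tuple(g for g in TARGET_GENES if self.feature_for(g) is None)

    @property
    def incomplete(self) -> bool:
        """True when any of the four target genes lacks an annotation."""
        return bool(self.missing_genes)


@dataclass(frozen=True)
class GeneSequence:
    accession: str
    gene: str
    sequence: str
    upstream_extension: int = 0

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.accession}/{self.gene}: empty gene sequence")
        if self.upstream_extension not in (0, 100):
            raise ValueError("upstream_extension must be 0 or 100")


def _canonical_gene_name(feature: SeqFeature) -> str | None:
    for key in ("gene", "product", "note", "standard_name"):
        for value in feature.qualifiers.get(key, []):
            canon = GENE_SYNONYMS.get(value.strip().upper())
            if canon:
                return canon
    return None


def _location_to_coords(location, seq_len: int, circular: bool) -> tuple[int, int, int]:
    """Convert a Biopython location to 1-based inclusive (start, end, strand).

    A two-part ``join`` whose first part ends at the sequence terminus is read
    as an origin-spanning feature on a circular record (start > end).
    """
    strand = int(location.strand or 1)
    if isinstance(location, CompoundLocation):
        parts = sorted(location.parts, key=lambda p: int(p.start))
        if circular and len(parts) == 2 and int(parts[-1].end) == seq_len and int(parts[0].start) == 0:
            # join(x..L, 1..y): wraps the origin
            return int(parts[1].start) + 1, int(parts[0].end), strand
        return int(parts[0].start) + 1, int(parts[-1].end), strand
    return int(location.start) + 1, int(location.end), strand


_ORDER_SUFFIXES = ("FORMES",)
_FAMILY_SUFFIXES = ("IDAE",)


def _taxonomy_from_annotations(record: SeqRecord) -> tuple[str, str, str, str]:
    species = record.annotations.get("organism", "") or ""
    genus = species.split()[0] if species else ""
    family = order = ""
    for name in record.annotations.get("taxonomy", []) or []:
        upper = name.upper()
        if not order and upper.endswith(_ORDER_SUFFIXES):
            order = name
        elif not family and upper.endswith(_FAMILY_SUFFIXES):
            family = name
    return species, genus, family, order


def parse_flatfile(path: str | Path) -> list[MitogenomeRecord]:
    """Parse a (multi-entry) GenBank flat file into mitogenome records.

    Records lacking one of the four target-gene annotations are returned with
    ``incomplete=True`` rather than dropped, so callers can report them.
    """
    path = Path(path)
    records: list[MitogenomeRecord] = []
    try:
        seq_records = list(SeqIO.parse(str(path), "genbank"))
    except OSError:
        raise
    except Exception as exc:  # malformed entry inside the file
        raise FlatfileParseError(f"{path}: {exc}") from exc
    for rec in seq_records:
        try:
            circular = (rec.annotations.get("topology", "linear") == "circular")
            features: list[GeneFeature] = []
            seen: set[tuple[str, int, int]] = set()
            for feat in rec.features:
                if feat.type not in ("gene", "CDS", "rRNA", "tRNA", "misc_feature"):
                    continue
                canon = _canonical_gene_name(feat)
                if canon is None:
                    continue
                start, end, strand = _location_to_coords(
                    feat.location, len(rec.seq), circular)
                key = (canon, start, end)
                if key in seen:
                    continue
                seen.add(key)
                features.append(GeneFeature(canon, start, end, strand))
            species, genus, family, order = _taxonomy_from_annotations(rec)
            records.append(MitogenomeRecord(
                accession=rec.id or rec.name,
                sequence=str(rec.seq).upper(),
                circular=circular,
                species=species, genus=genus, family=family, order=order,
                features=features,
            ))
        except ValueError as exc:
            raise FlatfileParseError(f"entry {rec.id or rec.name}: {exc}") from exc
    return records


def write_flatfile(records: Iterable[MitogenomeRecord], path: str | Path) -> None:
    """Write records back to GenBank flat-file form (round-trip safe)."""
    out: list[SeqRecord] = []
    for r in records:
        seq_rec = SeqRecord(
            Seq(r.sequence), id=r.accession, name=r.accession,
            description=f"{r.species} mitochondrion".strip(),
        )
        seq_rec.annotations["molecule_type"] = "DNA"
        seq_rec.annotations["topology"] = "circular" if r.circular else "linear"
        seq_rec.annotations["organism"] = r.species
        seq_rec.annotations["source"] = r.species
        lineage = [x for x in (r.order, r.family, r.genus) if x]
        seq_rec.annotations["taxonomy"] = lineage
        n = len(r.sequence)
        for f in r.features:
            if f.start <= f.end:
                loc = SimpleLocation(f.start - 1, f.end, strand=f.strand)
            else:  # origin-spanning on a circular record
                loc = CompoundLocation([
                    SimpleLocation(f.start - 1, n, strand=f.strand),
                    SimpleLocation(0, f.end, strand=f.strand),
                ])
            ftype = "rRNA" if f.gene in ("12S", "16S") else "CDS"
            feat = SeqFeature(loc, type=ftype, qualifiers={"gene": [f.gene]})
            seq_rec.features.append(feat)
        out.append(seq_rec)
    SeqIO.write(out, str(path), "genbank")


def _slice_circular(seq: str, start0: int, end0: int, circular: bool) -> str:
    """0-based half-open slice, wrapping through the origin when needed."""
    n = len(seq)
    start0 %= n
    end0 = end0 % n if end0 % n or end0 == 0 else n
    if start0 < end0:
        return seq[start0:end0]
    if not circular:
        raise ExtensionOutOfRangeError("wrap-around slice on a linear record")
    return seq[start0:] + seq[:end0]


def extract_gene(record: MitogenomeRecord, gene: str,
                 cytb_extension: int = 100) -> GeneSequence:
    """Extract one annotated gene, honouring circular coordinates.

    CytB is returned with ``cytb_extension`` bp of immediately upstream
    sequence prepended (in gene orientation), because one CytB primer set
    anneals ahead of the annotated gene start. Minus-strand features are
    reverse-complemented so the output is always in sense orientation.
    """
    feat = record.feature_for(gene)
    if feat is None:
        raise GeneAbsentError(f"{record.accession}: gene {gene} absent")
    n = len(record.sequence)
    start0, end0 = feat.start - 1, feat.end  # to 0-based half-open
    if feat.start > feat.end:  # wraps the origin
        if not record.circular:
            raise FlatfileParseError(
                f"{record.accession}: origin-spanning {gene} on linear record")
        body = record.sequence[start0:] + record.sequence[:end0]
    else:
        body = record.sequence[start0:end0]

    extension = cytb_extension if GENE_SYNONYMS.get(gene.upper(), gene) == "CytB" else 0
    if extension:
        if feat.strand >= 0:
            up_start, up_end = start0 - extension, start0
            if up_start < 0 and not record.circular:
                raise ExtensionOutOfRangeError(
                    f"{record.accession}: {extension} bp upstream of CytB does "
                    "not exist on this linear record")
            upstream = _slice_circular(record.sequence, up_start % n, start0, record.circular)
        else:
            if end0 + extension > n and not record.circular:
                raise ExtensionOutOfRangeError(
                    f"{record.accession}: {extension} bp upstream of CytB does "
                    "not exist on this linear record")
            upstream = _slice_circular(record.sequence, end0, (end0 + extension) % n or n,
                                       record.circular)
        if feat.strand >= 0:
            seq = upstream + body
        else:
            seq = revcomp(body + upstream)
        return GeneSequence(record.accession, "CytB", seq, upstream_extension=extension)

    seq = body if feat.strand >= 0 else revcomp(body)
    canon = GENE_SYNONYMS.get(gene.upper(), gene)
    return GeneSequence(record.accession, canon, seq)


#: Plausible annotated lengths for the rRNA genes; entries outside the range
#: indicate a broken annotation. Protein-coding genes are not length-filtered.
GENE_LENGTH_BOUNDS: dict[str, tuple[int, int]] = {
    "12S": (500, 2000),
    "16S": (1000, 3000),
}


def filter_gene_lengths(
    genes: Sequence[GeneSequence],
) -> tuple[list[GeneSequence], list[tuple[GeneSequence, str]]]:
    """Partition gene sequences by the rRNA length-plausibility rules."""
    kept: list[GeneSequence] = []
    rejected: list[tuple[GeneSequence, str]] = []
    for g in genes:
        bounds = GENE_LENGTH_BOUNDS.get(g.gene)
        length = len(g.sequence) - g.upstream_extension
        if bounds and not (bounds[0] <= length <= bounds[1]):
            rejected.append((g, f"{g.gene} length {length} outside "
                                f"{bounds[0]}-{bounds[1]} bp"))
        else:
            kept.append(g)
    return kept, rejected


def is_reverse_oriented(record: MitogenomeRecord) -> bool:
    """Majority-strand heuristic for reverse-assembled mitogenomes.

    A record is called reverse-oriented when more than half of its annotated
    gene features lie on the minus strand.
    """
    if not record.features:
        return False
    minus = sum(1 for f in record.features if f.strand < 0)
    return minus * 2 > len(record.features)


def apply_structural_filters(
    records: Sequence[MitogenomeRecord],
) -> tuple[list[MitogenomeRecord], list[tuple[MitogenomeRecord, str]]]:
    """Drop incomplete and reverse-oriented records, with reasons."""
    kept: list[MitogenomeRecord] = []
    rejected: list[tuple[MitogenomeRecord, str]] = []
    for r in records:
        if r.incomplete:
            rejected.append((r, "incomplete: missing " + ",".join(r.missing_genes)))
        elif is_reverse_oriented(r):
            rejected.append((r, "reverse-oriented"))
        else:
            kept.append(r)
    return kept, rejected
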