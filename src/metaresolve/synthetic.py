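"""Synthetic mitogenome datasets with a known taxonomic hierarchy.

Generates an order > family > genus > BIN ladder with controlled per-level
divergence: a root sequence per gene evolves down the hierarchy by
independent per-branch substitutions (Jukes-Cantor-style, uniform among the
three alternative bases, no indels), so the expected pairwise divergence
between two sequences is twice the sum of the per-level branch rates
separating them and the true alignment is the identity. Primer-binding
sites with a controlled number of planted mismatches delimit known inserts,
giving every downstream module an exact truth table.

Realism limits: no indels, no rate heterogeneity among sites, no codon
structure; see the methods note for what this does and does not exercise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from ._seq import IUPAC_MASK, revcomp
from .errors import BinAssignment
from .ingest import GeneFeature, MitogenomeRecord, write_flatfile
from .primers import PrimerSet

_BASES = "ACGT"

#: Default gene lengths (bp): realistic magnitudes for fish mitogenomes, so
#: the rRNA length-plausibility filters pass on generated data.
DEFAULT_GENE_LENGTHS: dict[str, int] = {
    "12S": 950, "16S": 1700, "COI": 1550, "CytB": 1140,
}


@dataclass(frozen=True)
class HierarchySpec:
    """Counts per level, expected pairwise divergence per level (substitutions
    per site between two sequences whose most recent shared rank is that
    level), and the master seed."""

    n_orders: int = 2
    families_per_order: int = 2
    genera_per_family: int = 2
    bins_per_genus: int = 2
    seqs_per_bin: int = 3
    d_bin: float = 0.01
    d_genus: float = 0.08
    d_family: float = 0.15
    d_order: float = 0.22
    seed: int = 0
    gene_lengths: tuple[tuple[str, int], ...] = tuple(
        DEFAULT_GENE_LENGTHS.items())

    def __post_init__(self) -> None:
        counts = (self.n_orders, self.families_per_order,
                  self.genera_per_family, self.bins_per_genus,
                  self.seqs_per_bin)
        if any(c < 1 for c in counts):
            raise ValueError("all hierarchy counts must be >= 1")
        if not 0 <= self.d_bin <= self.d_genus <= self.d_family <= self.d_order:
            raise ValueError(
                "divergences must satisfy 0 <= d_bin <= d_genus <= d_family "
                "<= d_order")

    @property
    def branch_rates(self) -> dict[str, float]:
        """Per-branch substitution rates realizing the expected pairwise
        divergences (each pairwise path crosses two branches per level)."""
        return {
            "seq": self.d_bin / 2,
            "bin": (self.d_genus - self.d_bin) / 2,
            "genus": (self.d_family - self.d_genus) / 2,
            "family": (self.d_order - self.d_family) / 2,
            # depth of the order radiation is unconstrained by the ladder;
            # reuse the family-level step so orders separate further
            "order": (self.d_order - self.d_family) / 2,
        }

    @property
    def n_sequences(self) -> int:
        return (self.n_orders * self.families_per_order
                * self.genera_per_family * self.bins_per_genus
                * self.seqs_per_bin)


@dataclass
class GeneratedDataset:
    spec: HierarchySpec
    genes: dict[str, dict[str, str]]  # gene -> sequence id -> sequence
    truth: pd.DataFrame  # sequence_id, bin_id, species, genus, family, order
    inserts: dict[str, dict[str, str]] = field(default_factory=dict)

    @property
    def sequence_ids(self) -> list[str]:
        return list(self.truth["sequence_id"])

    @property
    def bin_assignment(self) -> BinAssignment:
        bins = dict(zip(self.truth["sequence_id"], self.truth["bin_id"]))
        taxonomy = {
            row.sequence_id: (row.species, row.genus, row.family, row.order)
            for row in self.truth.itertuples(index=False)
        }
        return BinAssignment(bins, taxonomy)

    def realized_divergence(self, gene: str, id_a: str, id_b: str) -> float:
        a, b = self.genes[gene][id_a], self.genes[gene][id_b]
        return sum(x != y for x, y in zip(a, b)) / len(a)


def _mutate(arr: np.ndarray, rate: float, rng: np.random.Generator
            ) -> np.ndarray:
    """Substitute each site with probability ``rate``, uniformly among the
    three alternative bases."""
    out = arr.copy()
    hit = np.nonzero(rng.random(arr.shape[0]) < rate)[0]
    if hit.size:
        out[hit] = (out[hit] + rng.integers(1, 4, hit.size)) % 4
    return out


def _to_str(arr: np.ndarray) -> str:
    return "".join(_BASES[i] for i in arr)


def generate_hierarchy(spec: HierarchySpec) -> GeneratedDataset:
    """Simulate the full hierarchy; deterministic given the spec's seed."""
    rng = np.random.default_rng(spec.seed)
    rates = spec.branch_rates
    gene_lengths = dict(spec.gene_lengths)
    roots = {g: rng.integers(0, 4, L) for g, L in gene_lengths.items()}
    genes: dict[str, dict[str, str]] = {g: {} for g in gene_lengths}
    rows = []
    counter = 0
    for o in range(spec.n_orders):
        order_name = f"Syn{o:02d}formes"
        order_seqs = {g: _mutate(roots[g], rates["order"], rng) for g in roots}
        for f in range(spec.families_per_order):
            family_name = f"Syn{o:02d}x{f:02d}idae"
            fam_seqs = {g: _mutate(order_seqs[g], rates["family"], rng)
                        for g in roots}
            for ge in range(spec.genera_per_family):
                genus_name = f"Syngenus{o:02d}{f:02d}{ge:02d}"
                gen_seqs = {g: _mutate(fam_seqs[g], rates["genus"], rng)
                            for g in roots}
                for b in range(spec.bins_per_genus):
                    bin_name = f"BIN{o:02d}{f:02d}{ge:02d}{b:02d}"
                    species = f"{genus_name} sp{b:02d}"
                    bin_seqs = {g: _mutate(gen_seqs[g], rates["bin"], rng)
                                for g in roots}
                    for _ in range(spec.seqs_per_bin):
                        seq_id = f"SYN{counter:05d}"
                        counter += 1
                        for g in roots:
                            genes[g][seq_id] = _to_str(
                                _mutate(bin_seqs[g], rates["seq"], rng))
                        rows.append({"sequence_id": seq_id, "bin_id": bin_name,
                                     "species": species, "genus": genus_name,
                                     "family": family_name,
                                     "order": order_name})
    truth = pd.DataFrame(rows)
    return GeneratedDataset(spec, genes, truth)


def _realize_primer(primer: str, budget: int, rng: np.random.Generator) -> str:
    """Resolve degenerate positions uniformly, then plant exactly ``budget``
    mismatches (bases outside the primer's IUPAC expansion).

    So that the planted count survives the search's one-indel allowance, a
    mutated base is chosen outside the IUPAC expansion of its own position
    AND of both neighbouring positions, at internal positions only: under
    any single-indel shift each planted base then still mismatches the
    primer base it realigns with, keeping the site's mismatch count exact.
    """
    masks = [IUPAC_MASK[c] for c in primer.upper()]
    out = []
    for mask in masks:
        choices = [b for b in range(4) if mask & (1 << b)]
        out.append(int(rng.choice(choices)))
    mutable = []
    for i in range(1, len(masks) - 1):
        window = masks[i - 1] | masks[i] | masks[i + 1]
        if window != 15:
            mutable.append((i, window))
    if budget > len(mutable):
        raise ValueError(
            f"cannot plant {budget} mismatches: only {len(mutable)} usable "
            "primer positions")
    for i in rng.choice(len(mutable), size=budget, replace=False):
        pos, window = mutable[int(i)]
        outside = [b for b in range(4) if not window & (1 << b)]
        out[pos] = int(rng.choice(outside))
    return "".join(_BASES[b] for b in out)


def plant_genes_and_primers(dataset: GeneratedDataset,
                            primer_sets: Mapping[str, PrimerSet],
                            mismatch_budget: int | Mapping[str, int | tuple[int, int]] = 0,
                            offset: int = 60, gap: int = 30
                            ) -> GeneratedDataset:
    """Plant primer-binding sites delimiting a documented-length insert into
    each gene, recording the true inserts.

    Each construct is written on the sense strand at a fixed in-gene offset:
    5' site, insert (the evolved gene subsequence, untouched), then the
    reverse complement of the 3' site. Several sets on the same gene are
    stacked left to right, separated by ``gap`` bp, so their sites never
    overwrite each other; an input error is raised when a gene cannot host
    its constructs. Each primer copy carries exactly the requested number of
    mismatches (per set: an int for both sides or a (five_prime,
    three_prime) tuple). For reverse-orientation sets the true insert is
    recorded reverse-complemented, in metabarcode orientation.
    """
    rng = np.random.default_rng(dataset.spec.seed + 1)
    cursor: dict[str, int] = {}
    for name in sorted(primer_sets):
        ps = primer_sets[name]
        if isinstance(mismatch_budget, Mapping):
            budget = mismatch_budget.get(name, 0)
        else:
            budget = mismatch_budget
        b5, b3 = budget if isinstance(budget, tuple) else (budget, budget)
        swap = ps.orientation == "reverse"
        p5 = ps.reverse_seqs[0] if swap else ps.forward_seqs[0]
        p3 = ps.forward_seqs[0] if swap else ps.reverse_seqs[0]
        gene_seqs = dataset.genes[ps.gene]
        ilen = ps.documented_length
        start = cursor.get(ps.gene, offset)
        need = start + len(p5) + ilen + len(p3)
        sample_len = len(next(iter(gene_seqs.values())))
        if need > sample_len:
            raise ValueError(
                f"{name}: construct ending at {need} bp does not fit in the "
                f"{sample_len} bp {ps.gene} gene (offset {start})")
        cursor[ps.gene] = need + gap
        truth: dict[str, str] = {}
        for seq_id in sorted(gene_seqs):
            seq = gene_seqs[seq_id]
            site5 = _realize_primer(p5, b5, rng)
            site3 = _realize_primer(p3, b3, rng)
            insert = seq[start + len(p5):start + len(p5) + ilen]
            new = (seq[:start] + site5 + insert + revcomp(site3)
                   + seq[start + len(p5) + ilen + len(p3):])
            gene_seqs[seq_id] = new
            truth[seq_id] = revcomp(insert) if swap else insert
        dataset.inserts[name] = truth
    return dataset


_LAYOUT = ("12S", "16S", "COI", "CytB")
_SPACERS = (70, 70, 70, 120, 60)  # before each gene, plus a trailing spacer


def assemble_mitogenomes(dataset: GeneratedDataset, circular: bool = True
                         ) -> list[MitogenomeRecord]:
    """Concatenate the genes with random spacers into annotated
    mitogenome-like records (1-based inclusive feature coordinates)."""
    rng = np.random.default_rng(dataset.spec.seed + 2)
    records = []
    for row in dataset.truth.itertuples(index=False):
        parts: list[str] = []
        features: list[GeneFeature] = []
        pos = 0
        for gene, spacer in zip(_LAYOUT, _SPACERS):
            parts.append(_to_str(rng.integers(0, 4, spacer)))
            pos += spacer
            gene_seq = dataset.genes[gene][row.sequence_id]
            features.append(GeneFeature(gene, pos + 1, pos + len(gene_seq), 1))
            parts.append(gene_seq)
            pos += len(gene_seq)
        parts.append(_to_str(rng.integers(0, 4, _SPACERS[-1])))
        records.append(MitogenomeRecord(
            accession=row.sequence_id, sequence="".join(parts),
            circular=circular, species=row.species, genus=row.genus,
            family=row.family, order=row.order, features=features))
    return records


def write_fixture(dataset: GeneratedDataset, out_dir: str | Path
                  ) -> dict[str, Path]:
    """Emit the flat-file mitogenomes, per-gene FASTA and truth TSVs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    records = assemble_mitogenomes(dataset)
    paths["mitogenomes"] = out_dir / "mitogenomes.gb"
    write_flatfile(records, paths["mitogenomes"])
    gene_dir = out_dir / "genes"
    gene_dir.mkdir(exist_ok=True)
    for gene, seqs in dataset.genes.items():
        path = gene_dir / f"{gene}.fasta"
        with open(path, "w") as handle:
            for seq_id in sorted(seqs):
                handle.write(f">{seq_id}\n{seqs[seq_id]}\n")
        paths[f"gene_{gene}"] = path
    paths["bins"] = out_dir / "bins.tsv"
    dataset.bin_assignment.write_tsv(paths["bins"])
    if dataset.inserts:
        rows = [{"primer_set": name, "sequence_id": seq_id, "insert": insert}
                for name, table in sorted(dataset.inserts.items())
                for seq_id, insert in sorted(table.items())]
        paths["inserts"] = out_dir / "inserts.tsv"
        pd.DataFrame(rows).to_csv(paths["inserts"], sep="\t", index=False)
    return paths
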