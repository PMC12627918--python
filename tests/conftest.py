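from __future__ import annotations

import pytest

from metaresolve import (HierarchySpec, all_vs_all, extract_metabarcode_set,
                         generate_hierarchy, plant_genes_and_primers)
from metaresolve.primers import DEFAULT_PRIMER_SETS


@pytest.fixture(scope="session")
def planted():
    """Small hierarchy with Teleo1 and MiFish sites planted (2 mismatches per
    primer copy) plus truth tables."""
    spec = HierarchySpec(seed=7)
    dataset = generate_hierarchy(spec)
    sets = {n: DEFAULT_PRIMER_SETS[n] for n in ("Teleo1", "MiFish")}
    plant_genes_and_primers(dataset, sets, mismatch_budget=2)
    return dataset, sets


@pytest.fixture(scope="session")
def teleo1(planted):
    """Extracted Teleo1 metabarcodes, their exhaustive similarity table and
    the matching BIN assignment."""
    dataset, sets = planted
    result = extract_metabarcode_set(dataset.genes["12S"], sets["Teleo1"])
    seqs = result.sequences
    table = all_vs_all(seqs)
    bins = dataset.bin_assignment.restrict(sorted(seqs))
    return seqs, table, bins
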