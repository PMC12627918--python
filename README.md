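# metaresolve

Benchmarking the taxonomic resolution of eDNA metabarcodes against a BIN
(Barcode Index Number) baseline.

## The problem

Environmental-DNA metabarcoding infers community composition by amplifying a
short mitochondrial region (a *metabarcode*) and clustering the resulting
sequences into operational taxonomic units (OTUs). Which metabarcode to use,
which clustering method, and above all which similarity threshold are
routinely chosen arbitrarily — yet they control whether two sequences of the
same species are split apart or two species are merged together.

`metaresolve` quantifies this directly. Given a set of annotated mitogenomes
whose sequences carry BIN labels (species-proxy units from COI barcoding),
it:

1. **extracts genes** (COI, CytB, 12S, 16S) from GenBank flat files,
   honouring circular mitogenome coordinates, and applies structural QC
   (implausible rRNA lengths, reverse-oriented assemblies);
2. **extracts metabarcodes in silico** with degenerate-primer matching (at
   most 5 primer–template mismatches and 1 indel), choosing the primer pair
   whose insert length is closest to the documented mean and fixing a
   consensus window across all sequences;
3. **computes pairwise similarity** S<sub>XY</sub> = matching columns /
   alignment length (terminal gaps excluded) with an exact free-end-gap
   alignment, optionally restricted by a permissive k-mer prescreen;
4. **quantifies errors against BINs** on a similarity-threshold grid
   S<sub>T</sub> = 90–99%:
   - *over-splitting*: intra-BIN pairs with S<sub>XY</sub> < S<sub>T</sub>,
   - *over-merging*: inter-BIN pairs with S<sub>XY</sub> ≥ S<sub>T</sub>,
   - *global error* GE = sum of both rates; S<sub>OPT</sub> is the grid
     threshold minimizing GE;
5. **derives metabarcode gaps**: for the ladder BIN → genus → family →
   order, the gap between adjacent levels is
   MG = (Q1 of intra-taxon similarities at the upper level + Q3 at the
   lower level) / 2, giving per-metabarcode thresholds MG_BIN, MG_GEN,
   MG_FAM that delineate taxonomic levels;
6. **clusters de novo** (nearest/furthest neighbour, UPGMA, SWARM-style
   d-difference components, greedy centroid) and scores each OTU partition
   against the BINs over a clustering-threshold grid (C<sub>OPT</sub>);
7. **simulates mock communities** of controlled richness (BIN count) and
   redundancy (sequences per BIN) to chart how the error balance shifts
   from over-splitting to over-merging as diversity grows.

A synthetic-data generator produces mitogenome-like references with a known
order > family > genus > BIN hierarchy, calibrated per-level divergence and
planted primer sites, so the whole pipeline is testable end to end without
any downloads.

## Worked example

```python
import metaresolve as mr

# a synthetic reference: 2 orders, 24 BINs, 3 sequences per BIN, with
# MiFish primer sites planted at 2 mismatches per primer copy
spec = mr.HierarchySpec(seed=1, n_orders=2, families_per_order=2,
                        genera_per_family=3, bins_per_genus=2, seqs_per_bin=3,
                        gene_lengths=(("12S", 950),))
ds = mr.generate_hierarchy(spec)
sets = {"MiFish": mr.DEFAULT_PRIMER_SETS["MiFish"]}
mr.plant_genes_and_primers(ds, sets, mismatch_budget=2)

result = mr.extract_metabarcode_set(ds.genes["12S"], sets["MiFish"])
table = mr.all_vs_all(result.sequences)
bins = ds.bin_assignment.restrict(sorted(result.sequences))

profile = mr.error_profile(table, bins, metabarcode="MiFish")
opt = mr.find_s_opt(profile)
est = mr.gap_estimate(table, bins, metabarcode="MiFish")
print(f"S_OPT = {opt.s_opt}%  GE_min = {opt.ge_min:.2%}  GE_max = {opt.ge_max:.2%}")
print(f"MG_BIN = {est.mg_bin:.1%}  MG_GEN = {est.mg_gen:.1%}  MG_FAM = {est.mg_fam:.1%}")
```

Output:

```
S_OPT = 96%  GE_min = 0.00%  GE_max = 44.44%
MG_BIN = 96.6%  MG_GEN = 89.2%  MG_FAM = 82.0%
```

Read: for this (synthetic) reference the 96% threshold separates BINs with
zero error, while the worst grid threshold mislabels 44% of all
comparisons; the BIN/genus boundary for this marker sits at 96.6%
similarity, the genus/family boundary at 89.2%, the family/order boundary
at 82.0%.

The same workflow is scriptable from the shell:

```bash
metaresolve simulate --seed 1 --out fixture --primer-sets Teleo1,MiFish
metaresolve extract-genes fixture/mitogenomes.gb --out genes
metaresolve extract-metabarcodes genes/12S.fasta --primer-set MiFish --out mifish.fasta
metaresolve similarity mifish.fasta --out sim.tsv
metaresolve bin-errors sim.tsv fixture/bins.tsv --out profile.csv
metaresolve run config.yaml          # the full configured pipeline
```

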