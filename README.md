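# egt-screen

Tools for asking a specific comparative-genomics question: does a
heterotrophic, plastid-lacking lineage carry a residual footprint of genes
acquired from a photosynthetic endosymbiont?  The motivating case is a
goniomonad cryptomonad whose plastid-bearing relatives (Cryptophyceae)
harbour a red-algal secondary plastid: if the plastid-lacking lineage
descends from a plastid-bearing ancestor, some endosymbiotically
transferred (EGT) genes should still branch with red algae in single-gene
phylogenies.

`egt-screen` implements the screening side of that analysis as a tested,
reusable library plus a thin CLI.  It does **not** run homology searches or
tree inference — BLAST/DIAMOND tables and newick trees with bootstrap-style
supports are its inputs.

## What it computes

**Taxonomic decontamination** (`homology_signal`).  A predicted protein is
assigned to Eukaryota/Bacteria/Archaea when a domain's share of its top 10
hits strictly exceeds 60%; contigs are rescued when >60% of their
non-ambiguous gene models agree; contigs with a bacterial nucleotide hit at
E < 1e-50 are flagged.  All published thresholds are strict inequalities —
boundary values fail.

**Top-hit taxonomy and enrichment.**  Per query, the best hit at E < 1e-10
(after excluding self-genus subjects) is counted by supergroup; enrichment
of a group g between a query and a control profile is
`[f_q(g)/db(g)] / [f_c(g)/db(g)]`, normalising each profile by the group's
database share.

**Paralog merging.**  Queries whose homolog-retrieval lists overlap by
strictly more than 50% — intersection over the smaller list, so a fragment
always merges with its full-length paralog — are collapsed transitively
(connected components of the overlap graph).

**Sister-group classification** (`topology_classify`).  In each rooted
single-gene tree the query clade's sister set is classified as *exclusive*
(a single archaeplastidal lineage, direct affinity), *inclusive* (one
archaeplastidal lineage plus intervening secondary-plastid taxa), or
*unresolved* (mixed, or the defining edge's ultrafast-bootstrap support is
not strictly above 80).  Companion leaves — the plastid-bearing relatives
whose co-branching with the query is recorded per gene — are skipped over
and flagged.  Category counts are compared against a control taxon of
unambiguous non-photosynthetic ancestry (e.g. Amoebozoa) with an exact
binomial tail test: the control's call frequency estimates how often pure
phylogenetic noise produces a sister-group call.

**Gene subsampling** (`subsample_position`).  Marker genes present in the
query and at least one other clade member are randomly split into four
equally sized bins, 25 times, yielding 100 gene-subset units whose trees
(inferred externally) are classified by the focal clade's position —
sister to which combination of archaeplastidal lineages, to a monophyletic
Archaeplastida, to non-archaeplastidal groups, non-monophyletic, or
unresolved — and tallied.

**Simulators** (`synthetic_data`).  Seeded generators produce gene trees
with a planted fraction of transfers (query re-grafted inside a donor
clade) and Poisson-distributed NNI noise, subset trees drawn from a known
position-category distribution, and ranked hit tables mixing a true-origin
group with database background.  Every generator emits truth flags that
downstream tests consume.

## Worked example

Simulate 285 gene trees in which 5% of genes carry a planted red-algal
transfer, under heavy topological noise, then screen them:

```python
import egt_screen as es

layout = ((("Goniomonadea", "Cryptophyceae"), "Opisthokonta"),
          (("Rhodophyta", "Amoebozoa"), "Excavata"))
tips = {"Goniomonadea": 1, "Cryptophyceae": 2, "Opisthokonta": 2,
        "Rhodophyta": 2, "Amoebozoa": 2, "Excavata": 2}
species = es.species_tree_from_layout(layout, tips)
scheme = es.scheme_for_tips(species)
config = es.TreeSimConfig(
    species_tree=species, query_leaf="Goniomonadea_1",
    donor_group="Rhodophyta", n_genes=285, p_egt=0.05, noise_rate=8.0,
    support_resolved=(85.0, 100.0), support_perturbed=(85.0, 100.0), seed=42)
sims = es.simulate_gene_trees(config, scheme)
calls = [es.classify_gene(t, scheme, "Goniomonadea", "Cryptophyceae")
         for t, _ in sims]
tally = es.tally_signals(calls)
print("planted transfers :", sum(t["planted"] for _, t in sims))
print("red-algal calls   :", tally.count_for_group("Rhodophyta"))
print("control calls     :", tally.count_for_group("Amoebozoa"))
ratio, p = es.background_comparison(tally, "Rhodophyta", "Amoebozoa")
print(f"ratio vs control  : {ratio:.2f}   binomial tail p = {p:.3g}")
```

prints

```
planted transfers : 19
red-algal calls   : 23
control calls     : 4
ratio vs control  : 5.75   binomial tail p = 3.19e-11
```

The 19 planted transfers are all recovered; noise adds 4 spurious red calls
and, symmetrically, 4 control calls.  The red-algal count stands far above
the control-taxon background (p ≈ 3e-11), which is exactly the contrast a
genuine endosymbiotic footprint produces — and the contrast that stays flat
when no transfers are planted.

The same operations are exposed on the command line, e.g.:

```bash
egt-screen classify-domains --hits hits.tsv --taxa map.tsv --out calls.tsv
egt-screen tophits --hits hits.tsv --taxa map.tsv --exclude-genus Goniomonas --out dist.json
egt-screen subsample --genes markers.txt --bins 4 --iterations 25 --seed 42 --out bins.json
```

## Layout

- `src/egt_screen/io_taxa.py` — hit-table, taxon-map and newick readers;
  `TaxonScheme`, `HitSet`, `SupportTree`.
- `src/egt_screen/homology_signal.py` — domain calls, contig flags,
  top-hit profiles, enrichment, paralog merging, marker best-hit selection.
- `src/egt_screen/topology_classify.py` — rooting, redundancy trimming,
  sister-affinity classification, tallies, background comparison.
- `src/egt_screen/subsample_position.py` — marker filtering, binning,
  supermatrix bookkeeping, focal-position classification.
- `src/egt_screen/synthetic_data.py` — the seeded generators.
- `docs/methods.md` — model assumptions, parameter choices, limitations.
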