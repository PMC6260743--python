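# Methods

## The screening model

The package formalises a three-part argument used to decide whether a
plastid-lacking lineage retains endosymbiont-derived genes:

1. **Candidate retrieval and hygiene.**  Candidate genes come from
   homology searches; before any phylogenetics, predicted proteins and the
   contigs carrying them are screened for prokaryotic contamination, and
   queries with largely overlapping homolog lists are merged into a single
   analysis unit so in-paralogs are not double-counted.
2. **Per-gene sister-affinity calls.**  Each candidate's maximum-likelihood
   gene tree is classified by what the query clade is sister to, gated on
   bootstrap support.  Counting calls per category turns a pile of trees
   into a signal distribution.
3. **A background null.**  Because gene trees are noisy, some sister-group
   calls arise with no evolutionary cause.  The frequency with which the
   query is called sister to a control clade with unambiguously
   non-photosynthetic ancestry estimates that noise floor; the putative
   donor signal is only meaningful in excess of it.

A companion axis is tracked throughout: whether the query co-branches with
its plastid-bearing relatives (the companion group).  A transfer that
predates the split of the two lineages should show both together inside
the donor clade; a transfer specific to the plastid-bearing branch should
show the companion there without the query.

## Classification rules

Let Q be a maximal query-pure clade in a rooted gene tree.  Walking from Q
toward the root, the sister set at each step is the other leaves under Q's
parent.  Companion-group leaves found there set `companion_cobranching`
and are removed; if nothing else remains the walk continues one level up.
With S the group set of the first non-empty effective sister set:

- `|S| = 1` → **exclusive** call for that group (archaeplastidal or not);
- S contains exactly one archaeplastidal group, at least one
  secondary-plastid group, and nothing else → **inclusive** call for the
  archaeplastidal group;
- anything else (two primary lineages, mixtures with non-photosynthetic
  groups) → **unresolved**.  Published analyses resolve some of these by
  expert judgment; the formalisation deliberately does not.

The call stands only if the support of the edge defining the relationship
— the edge subtending the query(+companion)-plus-sister clade — strictly
exceeds the threshold (default 80 on the 0–100 ultrafast-bootstrap scale).
When that clade's parent is the root the defining bipartition is Q's own
edge, and for a binary root the sibling's support (the same unrooted
split) is accepted as a fallback.  Trees without support values yield only
unresolved calls.  When several query clades exist, every clade is
classified and the gene's reported call is the resolved one with highest
support, ties broken toward co-branching.

For subset (concatenation) trees the analogous rules classify the focal
clade's position: sister to a subset of archaeplastidal lineages, to a
monophyletic Archaeplastida, to non-archaeplastidal groups only (majority
group reported, ties broken lexicographically), mixed, non-monophyletic,
or unresolved.  Here both the focal clade's subtending edge and the sister
edge must pass the gate — a deliberately conservative double gate, since a
position claim rests on both.

## Thresholds

Every published cutoff is read as a strict inequality, matching the ">"
and "<" symbols of the source protocols: >60% of the top 10 hits for a
domain call (6/10 fails), >60% of non-ambiguous gene models for contig
rescue, bacterial contig hits at E < 1e-50 (exactly 1e-50 does not flag),
candidate/marker hits at E < 1e-10 (exactly 1e-10 is rejected), >50% hit
overlap for paralogy (exactly half does not merge), and support > 80
(exactly 80 is unresolved).  The domain-call denominator is the number of
available hits when fewer than 10 exist; a contig whose gene calls are all
ambiguous is itself ambiguous.

Hit ranks are deterministic: ascending E-value, ties by descending
bitscore, then ascending subject identifier.  Hits from multiple databases
are assumed to arrive as one jointly ranked table.

"Overlap" between homolog lists is intersection over the smaller list by
default, so a subset relationship always merges — the right behaviour when
a fragment retrieves a short list contained in its full-length paralog's —
with intersection-over-union and over-mean available as alternatives.
Merging is transitive by construction (connected components), since the
pairwise rule is closed under repetition.

## Background comparison

Given category counts over N trees, the hypothesis group's count h is
compared with the control group's count c via the exact binomial tail
P(X ≥ h), X ~ Binomial(N, c/N), alongside the plain ratio h/c.  The
published analyses make this comparison informally; the exact test is this
package's formalisation and is reported as such.

## Subsampling bookkeeping

Markers are kept when present in the query organism and at least one other
member of its clade.  Each iteration shuffles the kept genes under a
derived seed and deals them round-robin, so bin sizes differ by at most
one: 183 genes into 4 bins gives 46/46/46/45.  (A published figure caption
reporting 46/46/46/47 for 183 genes is internally inconsistent — it sums
to 185 — so the stated gene count is honoured and the caption's sizes are
not reproduced.)  Twenty-five iterations of four bins yield the canonical
100 gene-subset units.  Partition coordinates are 1-based inclusive in
input gene order; taxa missing from a gene are filled with `-`, and the
simple column filter counts `-`, `?` and `X` as gaps (it is a plain
gap-fraction filter, not an entropy-based block remover).

## Simulators

`simulate_gene_trees` starts from a deterministic, group-monophyletic
species tree (ladder over groups, balanced within groups, branch lengths
0.1, supports 100).  Per gene, an independent substream of the master seed
decides: with probability `p_egt` the query tip is pruned and re-grafted
as sister to a uniformly chosen donor-group tip (pendant edges 0.1); then
Poisson(λ) nearest-neighbour-interchange moves are applied, drawn
uniformly over internal non-root edges but never at the planted cherry, so
the truth flag stays meaningful.  Supports are drawn uniformly from the
resolved range (default exactly 100) for untouched edges and from the
perturbed range (default 60–95) for edges a move touched.  Substreams are
counter-based (`default_rng([seed, gene_index])`), so outputs are
bit-reproducible and extending `n_genes` never changes earlier trees.

In the simulated screen the query lineage is a single tip and its group
(Goniomonadea) is distinct from the companion group (Cryptophyceae); with
no noise, an unplanted gene therefore classifies as co-branching with the
companion and sister to the next group in the ladder — never to the donor
— which is what makes planted-transfer recovery exact rather than
approximate.

`simulate_position_trees` draws categories from a supplied distribution
and builds, for each draw, a tree that classifies to that category by
construction (supports 100, except the deliberately failed gate in the
unresolved construction).  `simulate_hit_table` draws each hit's group
from `w·δ(origin) + (1−w)·background` with E-values growing geometrically
with rank from 1e-60, far below every screening cutoff.

**Calibration geometry.**  For the noise-calibration check the species
tree places the hypothesis and control groups as sister clades of equal
size, making them exchangeable under the label-agnostic NNI process; the
observed hypothesis/control counts are then compared with a conditional
binomial test (k_hyp successes out of k_hyp + k_ctrl at p = 0.5).  Under
the check's conditions (λ = 2 on an 11-leaf tree) sister-call events for
either distant group are rare, which mirrors the empirical situation the
null is meant to model: background noise produces occasional, roughly
symmetric calls.

**What the simulators do not model.**  No sequences are evolved:
classification is topology- and support-driven, so branch lengths carry no
information beyond midpoint rooting.  NNI noise is uniform over edges,
unlike real gene-tree error, which concentrates on short internal
branches; supports are drawn independently of topology rather than from a
bootstrap; there is no model of hidden paralogy, contamination, or
long-branch attraction.  Passing recovery tests therefore demonstrates
that the bookkeeping and classification logic are correct under controlled
discordance, not that the screen is robust to every artefact of real data.

## Problem sizes and numerical choices

The packaged checks run at deliberately modest sizes chosen to exercise
the logic well within interactive runtimes: 500 genes per planting
fraction for exact recovery, 1000 trees for calibration and for the
position-tally goodness of fit, 200 random instances (≤50 queries) for the
paralog-merge oracle, and the exhaustive 105 rooted 5-leaf topologies for
the classifier truth table.  Statistical gates use α = 0.01.  Support
values given as fractions in [0, 1] are rescaled ×100 at parse time
(values above 100 are rejected); a support on the root edge is dropped as
meaningless.  Rooting prefers a cleanly separable outgroup edge and falls
back to midpoint rooting (missing branch lengths are treated as 1 for the
midpoint computation only); supports are re-associated with their unrooted
bipartitions after rerooting so no value migrates to a different split.

## Known limitations

- The "ambiguous algal signal" categories that published analyses resolve
  manually are absorbed into the unresolved bucket here; counts for those
  categories are therefore not comparable one-to-one.
- Outgroup rooting requires the outgroup to form one side of an edge; a
  paraphyletic outgroup silently falls back to midpoint rooting.
- The enrichment normalisation assumes both profiles were scored against
  the same database; cross-database comparisons need externally supplied
  composition fractions.
- `reduce_taxonomic_redundancy` needs sequence lengths to prefer long
  representatives; without them it falls back to label order.
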