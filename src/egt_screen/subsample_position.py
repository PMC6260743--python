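"""Marker-gene subsampling machinery: filtering, binning, supermatrix
bookkeeping and tallying a focal clade's position across subset trees.

The procedure mirrors a gene-subsampling robustness check on a
concatenation phylogeny: marker genes present in the query organism and at
least one other member of its clade are randomly partitioned into equally
sized bins (a fresh partition per iteration), each bin is concatenated and
a tree inferred from it externally, and the focal clade's phylogenetic
position in each subset tree is classified and tallied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

import dendropy

from .io_taxa import ARCHAEPLASTIDA_GROUPS, SupportTree, TaxonScheme

__all__ = [
    "BinAssignment",
    "PositionCategory",
    "PositionCall",
    "PositionTally",
    "SISTER_TO_MONOPHYLETIC_ARCHAEPLASTIDA",
    "WITHIN_ARCHAEPLASTIDA_OTHER",
    "FOCAL_NON_MONOPHYLETIC",
    "UNRESOLVED_POSITION",
    "sister_to",
    "non_archaeplastida",
    "filter_marker_genes",
    "partition_genes",
    "repeat_partitions",
    "concatenate_supermatrix",
    "simple_column_filter",
    "classify_clade_position",
    "tally_positions",
    "read_alignment_fasta",
    "write_supermatrix_fasta",
    "write_partition_file",
]

#: Characters counted as missing data by :func:`simple_column_filter`;
#: "-" is also the fill character used when concatenating.
GAP_CHARS = frozenset("-?Xx")


@dataclass(frozen=True)
class BinAssignment:
    """One random partition of the marker genes into equally sized bins."""

    iteration: int
    bins: tuple[tuple[str, ...], ...]
    seed: int

    def __post_init__(self) -> None:
        genes = [g for b in self.bins for g in b]
        if len(genes) != len(set(genes)):
            raise ValueError("bins are not disjoint")
        sizes = [len(b) for b in self.bins]
        if sizes and max(sizes) - min(sizes) > 1:
            raise ValueError("bin sizes differ by more than 1")


@dataclass(frozen=True)
class PositionCategory:
    """Hashable category of the focal clade's position in one subset tree."""

    kind: str
    groups: tuple[str, ...] = ()

    def label(self) -> str:
        if self.groups:
            return f"{self.kind}({'+'.join(self.groups)})"
        return self.kind


SISTER_TO_MONOPHYLETIC_ARCHAEPLASTIDA = PositionCategory(
    "sister_to_monophyletic_archaeplastida"
)
WITHIN_ARCHAEPLASTIDA_OTHER = PositionCategory("within_archaeplastida_other")
FOCAL_NON_MONOPHYLETIC = PositionCategory("focal_non_monophyletic")
UNRESOLVED_POSITION = PositionCategory("unresolved")


def sister_to(groups: Iterable[str]) -> PositionCategory:
    """Focal clade sister to exactly this set of archaeplastidal lineages."""
    groups = tuple(sorted(set(groups)))
    if not groups:
        raise ValueError("sister_to requires at least one group")
    return PositionCategory("sister_to", groups)


def non_archaeplastida(group: str) -> PositionCategory:
    """Focal clade sister to a non-archaeplastidal group."""
    return PositionCategory("non_archaeplastida", (group,))


@dataclass(frozen=True)
class PositionCall:
    tree_id: str
    category: PositionCategory


@dataclass(frozen=True)
class PositionTally:
    counts: Mapping[PositionCategory, int]
    total: int

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.total:
            raise ValueError("position counts must sum to total")


# ---------------------------------------------------------------------------
# marker bookkeeping
# ---------------------------------------------------------------------------


def filter_marker_genes(
    presence: Mapping[str, Iterable[str]],
    query_taxon: str,
    cryptista_taxa: Iterable[str],
) -> list[str]:
    """Markers usable for the focal clade: present in the query organism and
    in at least one other member of its clade.  Input order is preserved."""
    clade = set(cryptista_taxa) - {query_taxon}
    kept = []
    for gene, taxa in presence.items():
        taxa = set(taxa)
        if query_taxon in taxa and clade & taxa:
            kept.append(gene)
    return kept


def partition_genes(
    gene_ids: Sequence[str],
    n_bins: int,
    seed: int,
    iteration: int = 1,
) -> BinAssignment:
    """Shuffle the genes under *seed* and deal them round-robin into
    *n_bins* bins, so bin sizes differ by at most one."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if n_bins > len(gene_ids):
        raise ValueError(
            f"cannot split {len(gene_ids)} genes into {n_bins} bins"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(gene_ids))
    shuffled = [gene_ids[i] for i in order]
    bins = tuple(tuple(shuffled[j::n_bins]) for j in range(n_bins))
    return BinAssignment(iteration, bins, seed)


def _derived_seed(master_seed: int, index: int) -> int:
    state = np.random.SeedSequence([master_seed, index]).generate_state(1)[0]
    return int(state & 0x7FFFFFFF)


def repeat_partitions(
    gene_ids: Sequence[str],
    n_bins: int,
    n_iterations: int,
    seed: int,
) -> list[BinAssignment]:
    """Fresh random partition per iteration, with per-iteration seeds
    derived deterministically from the master seed."""
    return [
        partition_genes(gene_ids, n_bins, _derived_seed(seed, it), iteration=it)
        for it in range(1, n_iterations + 1)
    ]


# ---------------------------------------------------------------------------
# supermatrix bookkeeping
# ---------------------------------------------------------------------------


def concatenate_supermatrix(
    alignments: Mapping[str, Mapping[str, str]],
    taxa: Sequence[str],
) -> tuple[dict[str, str], list[tuple[str, int, int]]]:
    """Concatenate per-gene alignments over a shared taxon set.

    Taxa missing from a gene are filled with ``-``.  Returns the per-taxon
    supermatrix rows and the per-gene coordinate ranges as
    ``(gene, start, end)`` tuples, 1-based inclusive, in input gene order.
    """
    if not alignments:
        raise ValueError("no alignments to concatenate")
    taxa = list(taxa)
    parts: dict[str, list[str]] = {t: [] for t in taxa}
    partitions: list[tuple[str, int, int]] = []
    position = 0
    for gene, aln in alignments.items():
        lengths = {len(s) for s in aln.values()}
        if len(lengths) > 1:
            raise ValueError(f"gene {gene!r}: ragged alignment {sorted(lengths)}")
        length = lengths.pop() if lengths else 0
        extra = set(aln) - set(taxa)
        if extra:
            warnings.warn(
                f"gene {gene!r}: taxa {sorted(extra)} absent from the taxon "
                "list were skipped",
                stacklevel=2,
            )
        for taxon in taxa:
            parts[taxon].append(aln.get(taxon, "-" * length))
        partitions.append((gene, position + 1, position + length))
        position += length
    return {t: "".join(p) for t, p in parts.items()}, partitions


def simple_column_filter(
    alignment: Mapping[str, str], max_gap_fraction: float
) -> dict[str, str]:
    """Drop columns whose gap fraction strictly exceeds *max_gap_fraction*.

    Column order is preserved.  ``-``, ``?`` and ``X`` count as gaps.
    """
    rows = list(alignment.items())
    if not rows:
        return {}
    lengths = {len(s) for _, s in rows}
    if len(lengths) > 1:
        raise ValueError("alignment rows have unequal lengths")
    n_rows = len(rows)
    keep = []
    for col in range(lengths.pop()):
        gaps = sum(1 for _, seq in rows if seq[col] in GAP_CHARS)
        if not gaps / n_rows > max_gap_fraction:
            keep.append(col)
    return {name: "".join(seq[c] for c in keep) for name, seq in rows}


# ---------------------------------------------------------------------------
# focal-clade position
# ---------------------------------------------------------------------------


def _leafset(node: dendropy.Node) -> frozenset[str]:
    return frozenset(leaf.taxon.label for leaf in node.leaf_iter())


def _edge_passes(node: dendropy.Node, threshold: float) -> bool:
    """Pendant edges pass trivially; internal edges need support > threshold."""
    if node.is_leaf():
        return True
    support = getattr(node, "support", None)
    return support is not None and support > threshold


def classify_clade_position(
    tree: SupportTree,
    scheme: TaxonScheme,
    focal_group: str,
    archaeplastida_groups: frozenset[str] = ARCHAEPLASTIDA_GROUPS,
    support_threshold: float = 80.0,
    tree_id: str = "",
) -> PositionCall:
    """Position of the focal group in one (rooted) subset tree.

    Categories: focal not monophyletic; sister to the full archaeplastidal
    set forming a clade; sister to a subset of archaeplastidal lineages;
    sister to non-archaeplastidal groups only (majority group reported);
    a mixed sister set (within_archaeplastida_other); or unresolved when
    the focal clade's subtending edge or the sister edge fails the support
    gate (both must strictly exceed the threshold).
    """
    t = tree.tree
    focal = frozenset(
        l for l in tree.leaf_labels if scheme.group_of(l) == focal_group
    )
    if not focal:
        raise ValueError(f"focal group {focal_group!r} absent from tree")
    node = None
    for nd in t.postorder_node_iter():
        ls = _leafset(nd)
        if focal <= ls:
            node = nd
            break
    assert node is not None
    if _leafset(node) != focal:
        return PositionCall(tree_id, FOCAL_NON_MONOPHYLETIC)
    parent = node.parent_node
    if parent is None:
        raise ValueError("focal clade spans the whole tree")
    sister = _leafset(parent) - focal
    sister_children = [c for c in parent.child_nodes() if c is not node]

    gate = _edge_passes(node, support_threshold) and all(
        _edge_passes(c, support_threshold) for c in sister_children
    )
    if not gate:
        return PositionCall(tree_id, UNRESOLVED_POSITION)

    groups = {scheme.group_of(l) for l in sister}
    if groups == set(archaeplastida_groups):
        forms_clade = len(sister_children) == 1
        if forms_clade:
            return PositionCall(tree_id, SISTER_TO_MONOPHYLETIC_ARCHAEPLASTIDA)
    if groups <= archaeplastida_groups:
        return PositionCall(tree_id, sister_to(groups))
    if not groups & archaeplastida_groups:
        per_group: dict[str, int] = {}
        for l in sister:
            g = scheme.group_of(l)
            per_group[g] = per_group.get(g, 0) + 1
        top = max(per_group.values())
        majority = min(g for g, n in per_group.items() if n == top)
        return PositionCall(tree_id, non_archaeplastida(majority))
    return PositionCall(tree_id, WITHIN_ARCHAEPLASTIDA_OTHER)


def tally_positions(calls: Sequence[PositionCall]) -> PositionTally:
    """Category -> count over subset trees; fixed categories are retained
    at zero so the tally always shows the full outcome space."""
    counts: dict[PositionCategory, int] = {
        SISTER_TO_MONOPHYLETIC_ARCHAEPLASTIDA: 0,
        WITHIN_ARCHAEPLASTIDA_OTHER: 0,
        FOCAL_NON_MONOPHYLETIC: 0,
        UNRESOLVED_POSITION: 0,
    }
    for call in calls:
        counts[call.category] = counts.get(call.category, 0) + 1
    return PositionTally(counts, len(calls))


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------


def read_alignment_fasta(path: str | Path) -> dict[str, str]:
    """Read one gene's alignment from FASTA into a taxon -> row mapping."""
    return {
        rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")
    }


def write_supermatrix_fasta(
    supermatrix: Mapping[str, str], path: str | Path
) -> None:
    records = [
        SeqRecord(Seq(seq), id=taxon, description="")
        for taxon, seq in supermatrix.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def write_partition_file(
    partitions: Sequence[tuple[str, int, int]], path: str | Path
) -> None:
    """RAxML-style partition text: ``GENE = start-end`` per line."""
    with open(path, "w") as fh:
        for gene, start, end in partitions:
            fh.write(f"{gene} = {start}-{end}\n")
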