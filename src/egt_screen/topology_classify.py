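"""Sister-group classification of single-gene trees against reference clades.

Each gene tree is read with the query lineage's leaves located, and the
composition of the query clade's sister set decides the call:

* ``exclusive`` — the sister set is a single archaeplastidal lineage
  (direct affinity), or a single non-archaeplastidal group;
* ``inclusive`` — the sister set mixes exactly one archaeplastidal lineage
  with secondarily photosynthetic taxa (the affinity is mediated);
* ``unresolved`` — mixed composition, or the support of the edge defining
  the relationship does not strictly exceed the support threshold.

Companion-lineage leaves (the plastid-bearing relatives whose co-branching
with the query is recorded per gene) are skipped over: they set the
``companion_cobranching`` flag and are excluded from the sister set.
A background comparison against a control group turns the per-category
counts into an exact binomial tail probability.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import dendropy
from scipy import stats

from .io_taxa import (
    ARCHAEPLASTIDA_GROUPS,
    SECONDARY_PLASTID_GROUPS,
    SupportTree,
    TaxonScheme,
)

__all__ = [
    "TopologyCall",
    "SignalTally",
    "root_tree",
    "reduce_taxonomic_redundancy",
    "locate_query_clades",
    "classify_sister_signal",
    "classify_gene",
    "tally_signals",
    "background_comparison",
]

EXCLUSIVE = "exclusive"
INCLUSIVE = "inclusive"
UNRESOLVED = "unresolved"


@dataclass(frozen=True)
class TopologyCall:
    """Per-gene sister-affinity call for the query lineage."""

    gene_id: str
    companion_cobranching: bool
    sister_group: str | None
    relationship: str  # exclusive | inclusive | unresolved
    support: float | None

    def __post_init__(self) -> None:
        if self.relationship == UNRESOLVED and self.sister_group is not None:
            raise ValueError("unresolved calls carry no sister group")


@dataclass(frozen=True)
class SignalTally:
    """Counts of topology calls keyed by (co-branching, sister group, relationship)."""

    counts: Mapping[tuple[bool, str | None, str], int]
    total_trees: int

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.total_trees:
            raise ValueError("tally counts must sum to total_trees")

    def count_for_group(self, group: str) -> int:
        """Resolved calls whose sister group is *group* (either relationship)."""
        return sum(
            n
            for (_, sg, rel), n in self.counts.items()
            if sg == group and rel != UNRESOLVED
        )


# ---------------------------------------------------------------------------
# tree plumbing
# ---------------------------------------------------------------------------


def _leafset(node: dendropy.Node) -> frozenset[str]:
    return frozenset(leaf.taxon.label for leaf in node.leaf_iter())


def _split_key(side: frozenset[str], all_leaves: frozenset[str]) -> frozenset[str]:
    """Canonical key of the unrooted bipartition containing *side*."""
    other = all_leaves - side
    if len(side) != len(other):
        return side if len(side) < len(other) else other
    return min(side, other, key=lambda s: tuple(sorted(s)))


def root_tree(
    tree: SupportTree,
    scheme: TaxonScheme,
    outgroup: Iterable[str],
) -> SupportTree:
    """Root on the outgroup when it is cleanly separable, else at the midpoint.

    *outgroup* is a set of group labels.  If the tree contains outgroup
    leaves and they form one side of some edge, the tree is rooted on that
    edge; otherwise (no outgroup leaves, or they are not separable) midpoint
    rooting is used.  Supports are re-associated with their unrooted
    bipartitions after rerooting, so no support moves to a different split.
    """
    outgroup = set(outgroup)
    all_leaves = frozenset(tree.leaf_labels)
    if len(all_leaves) < 3:
        raise ValueError("rooting requires at least 3 leaves")
    og_leaves = frozenset(
        l for l in all_leaves if scheme.group_of(l) in outgroup
    )
    if og_leaves == all_leaves:
        raise ValueError("outgroup covers every leaf; nothing to root against")

    work = tree.clone()
    t = work.tree
    support_by_split: dict[frozenset[str], float] = {}
    for nd in t.preorder_node_iter():
        if nd.parent_node is None or nd.is_leaf():
            continue
        sup = getattr(nd, "support", None)
        if sup is not None:
            support_by_split.setdefault(_split_key(_leafset(nd), all_leaves), sup)

    target = None
    if og_leaves:
        for nd in t.preorder_node_iter():
            if nd.parent_node is None:
                continue
            ls = _leafset(nd)
            if ls == og_leaves or ls == all_leaves - og_leaves:
                target = nd
                break
    if target is not None:
        t.reroot_at_edge(target.edge, update_bipartitions=False)
    else:
        for edge in t.preorder_edge_iter():
            if edge.length is None:
                edge.length = 1.0
        t.reroot_at_midpoint(update_bipartitions=False)
    t.suppress_unifurcations()

    for nd in t.preorder_node_iter():
        if nd.is_leaf():
            continue
        if nd.parent_node is None:
            nd.support = None
            continue
        nd.support = support_by_split.get(_split_key(_leafset(nd), all_leaves))
    return SupportTree(t, _normalized=True)


def _maximal_pure_clades(
    tree: SupportTree,
    is_member,
) -> list[dendropy.Node]:
    """Maximal clades whose leaves all satisfy *is_member*."""
    t = tree.tree
    pure: dict[dendropy.Node, bool] = {}
    for nd in t.postorder_node_iter():
        if nd.is_leaf():
            pure[nd] = is_member(nd.taxon.label)
        else:
            pure[nd] = all(pure[c] for c in nd.child_nodes())
    maximal = []
    for nd in t.preorder_node_iter():
        if pure[nd] and (nd.parent_node is None or not pure[nd.parent_node]):
            maximal.append(nd)
    return maximal


def reduce_taxonomic_redundancy(
    tree: SupportTree,
    scheme: TaxonScheme,
    max_per_group_clade: int,
    *,
    seq_lengths: Mapping[str, int] | None = None,
    protected_groups: Iterable[str] = (),
    protected_leaves: Iterable[str] = (),
) -> set[str]:
    """Leaves to drop so that no single-group clade keeps more than
    *max_per_group_clade* representatives.

    Within each maximal clade whose leaves all share one group, the
    representatives kept are those with the longest associated sequences
    (ties broken by label).  Query/companion lineages are protected via
    *protected_groups*; individual leaves via *protected_leaves*.
    """
    if max_per_group_clade < 1:
        raise ValueError("max_per_group_clade must be >= 1")
    lengths = seq_lengths or {}
    protected_groups = set(protected_groups)
    protected_leaves = set(protected_leaves)
    drops: set[str] = set()
    for group in {scheme.group_of(l) for l in tree.leaf_labels}:
        if group in protected_groups:
            continue
        for clade in _maximal_pure_clades(
            tree, lambda l, g=group: scheme.group_of(l) == g
        ):
            leaves = sorted(
                _leafset(clade), key=lambda l: (-lengths.get(l, 0), l)
            )
            for leaf in leaves[max_per_group_clade:]:
                if leaf not in protected_leaves:
                    drops.add(leaf)
    return drops


def locate_query_clades(
    tree: SupportTree,
    scheme: TaxonScheme,
    query_group: str,
) -> list[frozenset[str]]:
    """Maximal clades consisting purely of query-group leaves.

    Their union covers every query leaf; in-paralogs scattered across the
    tree therefore yield several clades.
    """
    nodes = _maximal_pure_clades(
        tree, lambda l: scheme.group_of(l) == query_group
    )
    clades = [_leafset(nd) for nd in nodes]
    if not clades:
        raise ValueError(f"query group {query_group!r} absent from tree")
    return sorted(clades, key=lambda c: tuple(sorted(c)))


def _node_for_clade(
    tree: SupportTree, clade: frozenset[str]
) -> dendropy.Node:
    for nd in tree.tree.preorder_node_iter():
        if _leafset(nd) == clade:
            return nd
    raise ValueError(f"no node spans exactly the clade {sorted(clade)}")


def _relationship_support(
    node: dendropy.Node,
) -> float | None:
    """Support of the edge defining the sister relationship at *node*.

    For a non-root parent this is the parent's subtending edge (the clade
    containing query + sister).  When the parent is the root, the defining
    bipartition is the node's own edge; for a binary root the sibling's
    support is the same unrooted split and is used as a fallback.
    """
    parent = node.parent_node
    if parent.parent_node is not None:
        return getattr(parent, "support", None)
    sup = getattr(node, "support", None)
    if sup is None and len(parent.child_nodes()) == 2:
        sibling = next(c for c in parent.child_nodes() if c is not node)
        sup = getattr(sibling, "support", None)
    return sup


def classify_sister_signal(
    tree: SupportTree,
    query_clade: frozenset[str],
    companion_group: str,
    scheme: TaxonScheme,
    archaeplastida_groups: frozenset[str] = ARCHAEPLASTIDA_GROUPS,
    secondary_groups: frozenset[str] = SECONDARY_PLASTID_GROUPS,
    support_threshold: float = 80.0,
    gene_id: str = "",
) -> TopologyCall:
    """Classify the query clade's sister affinity in a rooted gene tree.

    See the module docstring for the category definitions.  The call is
    resolved only if the support of the edge defining the sister
    relationship strictly exceeds *support_threshold* (supports are on the
    0-100 scale; a tree without supports yields only unresolved calls).
    """
    all_leaves = frozenset(tree.leaf_labels)
    if query_clade == all_leaves:
        raise ValueError("query clade spans the whole tree")
    node = _node_for_clade(tree, query_clade)
    cobranching = False
    sister_groups: set[str] | None = None
    while True:
        parent = node.parent_node
        if parent is None:
            break  # ran off the root: nothing but query+companion in the tree
        sister = _leafset(parent) - _leafset(node)
        companion = {
            l for l in sister if scheme.group_of(l) == companion_group
        }
        if companion:
            cobranching = True
        effective = sister - companion
        if not effective:
            node = parent
            continue
        sister_groups = {scheme.group_of(l) for l in effective}
        break

    if sister_groups is None:
        return TopologyCall(gene_id, cobranching, None, UNRESOLVED, None)

    support = _relationship_support(node)
    if support is None or not support > support_threshold:
        return TopologyCall(gene_id, cobranching, None, UNRESOLVED, support)

    archaeplastidal = sister_groups & archaeplastida_groups
    if len(sister_groups) == 1:
        (group,) = sister_groups
        return TopologyCall(gene_id, cobranching, group, EXCLUSIVE, support)
    if (
        sister_groups <= archaeplastida_groups | secondary_groups
        and len(archaeplastidal) == 1
        and sister_groups & secondary_groups
    ):
        (group,) = archaeplastidal
        return TopologyCall(gene_id, cobranching, group, INCLUSIVE, support)
    return TopologyCall(gene_id, cobranching, None, UNRESOLVED, support)


def classify_gene(
    tree: SupportTree,
    scheme: TaxonScheme,
    query_group: str,
    companion_group: str,
    archaeplastida_groups: frozenset[str] = ARCHAEPLASTIDA_GROUPS,
    secondary_groups: frozenset[str] = SECONDARY_PLASTID_GROUPS,
    support_threshold: float = 80.0,
    gene_id: str = "",
) -> TopologyCall:
    """One call per gene: classify every query clade, report the resolved
    call with the highest support (ties broken toward co-branching)."""
    calls = [
        classify_sister_signal(
            tree,
            clade,
            companion_group,
            scheme,
            archaeplastida_groups,
            secondary_groups,
            support_threshold,
            gene_id,
        )
        for clade in locate_query_clades(tree, scheme, query_group)
    ]
    resolved = [c for c in calls if c.relationship != UNRESOLVED]
    if not resolved:
        return calls[0]
    return max(resolved, key=lambda c: (c.support, c.companion_cobranching))


def tally_signals(calls: Sequence[TopologyCall]) -> SignalTally:
    """Count calls by (co-branching, sister group, relationship)."""
    if not calls:
        raise ValueError("tally_signals requires at least one call")
    counts: dict[tuple[bool, str | None, str], int] = {}
    for call in calls:
        key = (call.companion_cobranching, call.sister_group, call.relationship)
        counts[key] = counts.get(key, 0) + 1
    return SignalTally(counts, len(calls))


def background_comparison(
    tally: SignalTally,
    hypothesis_group: str,
    control_group: str,
) -> tuple[float, float]:
    """Compare the hypothesis group's call frequency against a control group.

    The control group estimates the sister-call frequency expected from
    phylogenetic noise alone.  Returns ``(ratio, p_value)`` where the ratio
    is ``count(hypothesis)/count(control)`` (``inf`` if the control count
    is zero) and the p-value is the exact binomial tail probability of
    observing at least the hypothesis count in ``total_trees`` trials with
    success probability ``count(control)/total_trees``.
    """
    if tally.total_trees == 0:
        raise ValueError("tally is empty")
    n_hyp = tally.count_for_group(hypothesis_group)
    n_ctrl = tally.count_for_group(control_group)
    total = tally.total_trees
    if n_ctrl == 0:
        if n_hyp == 0:
            ratio = 0.0
        else:
            warnings.warn(
                "control group has zero calls; ratio is infinite", stacklevel=2
            )
            ratio = math.inf
    else:
        ratio = n_hyp / n_ctrl
    p_value = float(stats.binom.sf(n_hyp - 1, total, n_ctrl / total))
    return ratio, min(1.0, p_value)
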