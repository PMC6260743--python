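"""Seeded generators for gene trees with planted transfers, subset trees
with a known focal-position distribution, and ranked hit tables with a
controlled taxonomic composition.

These generators define the study conditions under which the screening
pipeline is exercised: every downstream recovery test consumes the truth
flags emitted here rather than re-deriving them.  A single integer master
seed derives per-item substreams by counter-based splitting
(``np.random.default_rng([seed, index])``), so changing the number of
simulated items never reshuffles earlier ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import dendropy

from .io_taxa import (
    DEFAULT_GROUP_DOMAINS,
    HitSet,
    SupportTree,
    TaxonEntry,
    TaxonScheme,
)
from .subsample_position import (
    FOCAL_NON_MONOPHYLETIC,
    SISTER_TO_MONOPHYLETIC_ARCHAEPLASTIDA,
    UNRESOLVED_POSITION,
    WITHIN_ARCHAEPLASTIDA_OTHER,
    PositionCategory,
)

__all__ = [
    "TreeSimConfig",
    "HitSimConfig",
    "build_reference_species_tree",
    "species_tree_from_layout",
    "scheme_for_tips",
    "simulate_gene_trees",
    "simulate_position_trees",
    "simulate_hit_table",
]

GroupLayout = "str | tuple"  # nested tuples of group labels


# ---------------------------------------------------------------------------
# species trees
# ---------------------------------------------------------------------------


def _balanced_clade(tips: Sequence[str], branch_length: float) -> str:
    if len(tips) == 1:
        return f"{tips[0]}:{branch_length:g}"
    mid = len(tips) // 2
    left = _balanced_clade(tips[:mid], branch_length)
    right = _balanced_clade(tips[mid:], branch_length)
    return f"({left},{right})100:{branch_length:g}"


def _tips_for(group: str, n: int) -> list[str]:
    return [f"{group}_{i}" for i in range(1, n + 1)]


def _layout_newick(
    layout, tips_per_group: Mapping[str, int], branch_length: float
) -> str:
    if isinstance(layout, str):
        tips = _tips_for(layout, tips_per_group[layout])
        return _balanced_clade(tips, branch_length)
    parts = [
        _layout_newick(sub, tips_per_group, branch_length) for sub in layout
    ]
    return f"({','.join(parts)})100:{branch_length:g}"


def _resolve_tip_counts(
    groups: Iterable[str], tips_per_group: int | Mapping[str, int]
) -> dict[str, int]:
    counts = {
        g: (tips_per_group if isinstance(tips_per_group, int) else tips_per_group.get(g, 1))
        for g in groups
    }
    for g, n in counts.items():
        if n < 1:
            raise ValueError(f"group {g!r}: tips_per_group must be >= 1")
    return counts


def _layout_groups(layout) -> list[str]:
    if isinstance(layout, str):
        return [layout]
    out: list[str] = []
    for sub in layout:
        out.extend(_layout_groups(sub))
    return out


def species_tree_from_layout(
    layout,
    tips_per_group: int | Mapping[str, int] = 2,
    branch_length: float = 0.1,
) -> SupportTree:
    """Deterministic group-monophyletic species tree from a nested layout.

    *layout* is a nested tuple of group labels giving the rooted topology
    over groups; each group becomes a balanced clade of tips named
    ``GROUP_1 .. GROUP_n``.  All supports are 100 and all branch lengths
    *branch_length*.
    """
    groups = _layout_groups(layout)
    if len(groups) != len(set(groups)):
        raise ValueError("layout repeats a group")
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    counts = _resolve_tip_counts(groups, tips_per_group)
    newick = _layout_newick(layout, counts, branch_length) + ";"
    return SupportTree.from_string(newick)


def build_reference_species_tree(
    groups: Sequence[str],
    tips_per_group: int | Mapping[str, int] = 2,
    branch_length: float = 0.1,
) -> SupportTree:
    """Ladder (pectinate) species tree over *groups*, balanced within groups."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    layout = (groups[0], groups[1])
    for group in groups[2:]:
        layout = (layout, group)
    return species_tree_from_layout(layout, tips_per_group, branch_length)


def scheme_for_tips(
    tree_or_labels: SupportTree | Iterable[str],
    group_domains: Mapping[str, str] | None = None,
    extra: Mapping[str, str] | None = None,
) -> TaxonScheme:
    """Taxon scheme for generated tips named ``GROUP_i``.

    Domains default to Bacteria/Archaea for groups of those names and
    Eukaryota otherwise; *extra* maps additional leaf labels to groups.
    """
    labels = (
        tree_or_labels.leaf_labels
        if isinstance(tree_or_labels, SupportTree)
        else tuple(tree_or_labels)
    )
    domains = dict(DEFAULT_GROUP_DOMAINS)
    if group_domains:
        domains.update(group_domains)
    entries: dict[str, TaxonEntry] = {}

    def _domain(group: str) -> str:
        return domains.get(group, "Bacteria" if group == "Bacteria" else "Eukaryota")

    for label in labels:
        group = label.rsplit("_", 1)[0]
        entries[label] = TaxonEntry(label, group, _domain(group))
    for label, group in (extra or {}).items():
        entries[label] = TaxonEntry(label, group, _domain(group))
    return TaxonScheme(entries)


# ---------------------------------------------------------------------------
# gene trees with planted transfers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TreeSimConfig:
    """Study conditions for simulating discordant gene trees.

    With probability *p_egt* a gene's query tip is pruned and re-grafted
    as sister to a uniformly chosen tip of *donor_group* (a planted
    transfer); then ``Poisson(noise_rate)`` random nearest-neighbour
    interchange moves are applied, never detaching a planted query-donor
    cherry.  Supports are drawn uniformly from *support_resolved* for
    untouched edges and *support_perturbed* for edges touched by a move.
    """

    species_tree: SupportTree
    query_leaf: str
    donor_group: str
    n_genes: int
    p_egt: float
    noise_rate: float = 0.0
    support_resolved: tuple[float, float] = (100.0, 100.0)
    support_perturbed: tuple[float, float] = (60.0, 95.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_egt <= 1.0:
            raise ValueError("p_egt must be in [0, 1]")
        if self.noise_rate < 0:
            raise ValueError("noise_rate must be >= 0")
        for lo, hi in (self.support_resolved, self.support_perturbed):
            if not (0 <= lo <= hi <= 100):
                raise ValueError("support ranges must satisfy 0 <= lo <= hi <= 100")


def _find_leaf(tree: dendropy.Tree, label: str) -> dendropy.Node:
    for leaf in tree.leaf_node_iter():
        if leaf.taxon.label == label:
            return leaf
    raise ValueError(f"leaf {label!r} not found")


def _detach_leaf(tree: dendropy.Tree, leaf: dendropy.Node) -> None:
    parent = leaf.parent_node
    parent.remove_child(leaf)
    tree.suppress_unifurcations()


def _graft_sister(
    tree: dendropy.Tree,
    target: dendropy.Node,
    label: str,
    branch_length: float = 0.1,
) -> dendropy.Node:
    """Insert a new leaf as sister to *target*; returns the new cherry node."""
    parent = target.parent_node
    cherry = dendropy.Node()
    cherry.edge.length = branch_length
    parent.remove_child(target)
    parent.add_child(cherry)
    cherry.add_child(target)
    target.edge.length = branch_length
    taxon = dendropy.Taxon(label=label)
    tree.taxon_namespace.add_taxon(taxon)
    new_leaf = dendropy.Node(taxon=taxon)
    new_leaf.edge.length = branch_length
    cherry.add_child(new_leaf)
    return cherry


def _nni_candidates(
    tree: dendropy.Tree, forbidden: dendropy.Node | None
) -> list[dendropy.Node]:
    return [
        nd
        for nd in tree.preorder_internal_node_iter()
        if nd.parent_node is not None and nd is not forbidden
    ]


def _apply_nni(
    rng: np.random.Generator,
    tree: dendropy.Tree,
    forbidden: dendropy.Node | None,
) -> tuple[dendropy.Node, dendropy.Node] | None:
    candidates = _nni_candidates(tree, forbidden)
    if not candidates:
        return None
    child = candidates[rng.integers(len(candidates))]
    parent = child.parent_node
    siblings = [c for c in parent.child_nodes() if c is not child]
    sib = siblings[rng.integers(len(siblings))]
    kids = child.child_nodes()
    kid = kids[rng.integers(len(kids))]
    parent.remove_child(sib)
    child.remove_child(kid)
    parent.add_child(kid)
    child.add_child(sib)
    return child, parent


def simulate_gene_trees(
    config: TreeSimConfig,
    scheme: TaxonScheme,
) -> list[tuple[SupportTree, dict]]:
    """Simulate ``n_genes`` gene trees under the planted-transfer model.

    Returns ``(tree, truth)`` pairs where ``truth`` records whether the
    transfer was planted and, if so, onto which donor tip.  Fully
    reproducible from the config seed.
    """
    base_newick = config.species_tree.as_newick()
    donor_tips = [
        l
        for l in config.species_tree.leaf_labels
        if scheme.group_of(l) == config.donor_group
    ]
    if not donor_tips:
        raise ValueError(
            f"donor group {config.donor_group!r} absent from species tree"
        )
    if config.query_leaf not in config.species_tree.leaf_labels:
        raise ValueError(f"query leaf {config.query_leaf!r} absent from species tree")

    out: list[tuple[SupportTree, dict]] = []
    for index in range(config.n_genes):
        rng = np.random.default_rng([config.seed, index])
        st = SupportTree.from_string(base_newick)
        tree = st.tree
        planted = bool(rng.random() < config.p_egt)
        cherry = None
        donor_tip = None
        if planted:
            donor_tip = donor_tips[rng.integers(len(donor_tips))]
            leaf = _find_leaf(tree, config.query_leaf)
            _detach_leaf(tree, leaf)
            target = _find_leaf(tree, donor_tip)
            cherry = _graft_sister(tree, target, config.query_leaf)
        touched: set[int] = set()
        n_moves = int(rng.poisson(config.noise_rate))
        for _ in range(n_moves):
            moved = _apply_nni(rng, tree, cherry)
            if moved is None:
                break
            touched.update(id(nd) for nd in moved)
        lo_r, hi_r = config.support_resolved
        lo_p, hi_p = config.support_perturbed
        for nd in tree.preorder_internal_node_iter():
            if nd.parent_node is None:
                nd.support = None
                continue
            lo, hi = (lo_p, hi_p) if id(nd) in touched else (lo_r, hi_r)
            nd.support = float(lo) if lo == hi else float(rng.uniform(lo, hi))
        out.append(
            (
                SupportTree(tree, _normalized=True),
                {"planted": planted, "donor_tip": donor_tip},
            )
        )
    return out


# ---------------------------------------------------------------------------
# subset trees with known focal positions
# ---------------------------------------------------------------------------


def _clade_newick(group: str, n_tips: int, support: float = 100.0) -> str:
    tips = _tips_for(group, n_tips)
    if len(tips) == 1:
        return f"{tips[0]}:0.1"
    mid = len(tips) // 2
    return (
        f"({_balanced_clade(tips[:mid], 0.1)},"
        f"{_balanced_clade(tips[mid:], 0.1)}){support:g}:0.1"
    )


def _joint_clade(groups: Sequence[str], tips: Mapping[str, int]) -> str:
    core = _clade_newick(groups[0], tips[groups[0]])
    for group in groups[1:]:
        core = f"({core},{_clade_newick(group, tips[group])})100:0.1"
    return core


def _position_tree_newick(
    category: PositionCategory,
    focal_group: str,
    archaeplastida_groups: Sequence[str],
    background_groups: Sequence[str],
    tips: Mapping[str, int],
) -> str:
    arch = list(archaeplastida_groups)
    background = list(background_groups)
    focal = _clade_newick(focal_group, tips[focal_group])
    used: list[str] = []
    if category.kind == "sister_to":
        sister = _joint_clade(list(category.groups), tips)
        used = list(category.groups)
        core = f"({focal},{sister})100:0.1"
    elif category == SISTER_TO_MONOPHYLETIC_ARCHAEPLASTIDA:
        sister = _joint_clade(arch, tips)
        used = arch[:]
        core = f"({focal},{sister})100:0.1"
    elif category.kind == "non_archaeplastida":
        sister = _clade_newick(category.groups[0], tips[category.groups[0]])
        used = [category.groups[0]]
        core = f"({focal},{sister})100:0.1"
    elif category == WITHIN_ARCHAEPLASTIDA_OTHER:
        mixed = (
            f"({_clade_newick(arch[0], tips[arch[0]])},"
            f"{_clade_newick(background[0], tips[background[0]])})100:0.1"
        )
        used = [arch[0], background[0]]
        core = f"({focal},{mixed})100:0.1"
    elif category == FOCAL_NON_MONOPHYLETIC:
        if tips[focal_group] < 2:
            raise ValueError(
                "focal_non_monophyletic needs at least 2 focal tips"
            )
        f_tips = _tips_for(focal_group, tips[focal_group])
        used = [arch[0], background[0]]
        core = (
            f"(({f_tips[0]}:0.1,{_clade_newick(arch[0], tips[arch[0]])})100:0.1,"
            f"({_balanced_clade(f_tips[1:], 0.1)},"
            f"{_clade_newick(background[0], tips[background[0]])})100:0.1)100:0.1"
        )
    elif category == UNRESOLVED_POSITION:
        sister = _clade_newick(arch[0], tips[arch[0]], support=50.0)
        used = [arch[0]]
        core = f"({focal},{sister})50:0.1"
    else:
        raise ValueError(f"unreachable category {category!r}")
    leftovers = [g for g in arch + background if g not in used]
    for group in leftovers:
        core = f"({core},{_clade_newick(group, tips[group])})100:0.1"
    return core + ";"


def simulate_position_trees(
    distribution: Mapping[PositionCategory, float],
    n_trees: int,
    *,
    focal_group: str = "Cryptista",
    archaeplastida_groups: Sequence[str] = (
        "Viridiplantae",
        "Glaucophyta",
        "Rhodophyta",
    ),
    background_groups: Sequence[str] = ("Amoebozoa", "Opisthokonta"),
    tips_per_group: int | Mapping[str, int] = 2,
    seed: int = 0,
) -> list[tuple[SupportTree, PositionCategory]]:
    """Draw categories from *distribution* and build, for each draw, a tree
    that classifies to exactly that category (supports 100 except in the
    deliberately unresolved construction).

    Returns ``(tree, drawn_category)`` pairs; the drawn category is the
    truth flag downstream tallies are checked against.
    """
    categories = list(distribution)
    probs = np.array([distribution[c] for c in categories], dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("category probabilities must sum to 1")
    arch = list(archaeplastida_groups)
    background = list(background_groups)
    all_groups = [focal_group] + arch + background
    tips = _resolve_tip_counts(all_groups, tips_per_group)
    # validate reachability up front
    for cat in categories:
        if cat.kind == "sister_to":
            groups = set(cat.groups)
            if not groups or not groups <= set(arch):
                raise ValueError(
                    f"category {cat.label()} names groups outside Archaeplastida"
                )
            if groups == set(arch):
                raise ValueError(
                    "sister to the full archaeplastidal set is the "
                    "monophyletic-Archaeplastida category"
                )
        elif cat.kind == "non_archaeplastida":
            if cat.groups[0] not in background:
                raise ValueError(
                    f"category {cat.label()} names an absent background group"
                )
        elif cat not in (
            SISTER_TO_MONOPHYLETIC_ARCHAEPLASTIDA,
            WITHIN_ARCHAEPLASTIDA_OTHER,
            FOCAL_NON_MONOPHYLETIC,
            UNRESOLVED_POSITION,
        ):
            raise ValueError(f"unreachable category {cat!r}")

    rng = np.random.default_rng([seed, 0])
    draws = rng.choice(len(categories), size=n_trees, p=probs)
    out = []
    for idx in draws:
        category = categories[int(idx)]
        newick = _position_tree_newick(
            category, focal_group, arch, background, tips
        )
        out.append((SupportTree.from_string(newick), category))
    return out


# ---------------------------------------------------------------------------
# ranked hit tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HitSimConfig:
    """Study conditions for simulating ranked homology-hit tables.

    Each query's hit groups are drawn from a mixture
    ``purity * delta(origin) + (1 - purity) * background``; E-values grow
    strictly with rank as ``evalue_base * evalue_factor**(rank-1)``.
    """

    n_queries: int
    background: Mapping[str, float]
    hits_per_query: int = 10
    purity: float = 1.0
    origin_map: Mapping[str, str] | None = None
    evalue_base: float = 1e-60
    evalue_factor: float = 10.0
    group_domains: Mapping[str, str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.purity <= 1.0:
            raise ValueError("purity must be in [0, 1]")
        total = sum(self.background.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"background fractions sum to {total}, not 1")
        if self.evalue_factor <= 1.0:
            raise ValueError("evalue_factor must exceed 1 (strictly increasing)")


def simulate_hit_table(
    config: HitSimConfig,
) -> tuple[HitSet, TaxonScheme, dict[str, str]]:
    """Simulate a ranked hit table plus the taxon scheme covering it.

    Returns ``(hitset, scheme, truth)`` where ``truth`` maps each query to
    its planted origin group.
    """
    rng = np.random.default_rng([config.seed, 0])
    groups = list(config.background)
    probs = np.array([config.background[g] for g in groups], dtype=float)
    if config.origin_map is not None:
        queries = list(config.origin_map)
        origins = dict(config.origin_map)
    else:
        queries = [f"q{i:04d}" for i in range(1, config.n_queries + 1)]
        origins = {
            q: groups[int(rng.choice(len(groups), p=probs))] for q in queries
        }
    domains = dict(config.group_domains or {})

    def _domain(group: str) -> str:
        if group in domains:
            return domains[group]
        return DEFAULT_GROUP_DOMAINS.get(group, "Eukaryota")

    records: list[tuple[str, str, float, float]] = []
    entries: dict[str, TaxonEntry] = {}
    counter = 0
    for query in queries:
        origin = origins[query]
        if origin not in config.background:
            raise ValueError(
                f"origin group {origin!r} missing from background composition"
            )
        for rank in range(1, config.hits_per_query + 1):
            if rng.random() < config.purity:
                group = origin
            else:
                group = groups[int(rng.choice(len(groups), p=probs))]
            counter += 1
            subject = f"{group}_s{counter:06d}"
            entries[subject] = TaxonEntry(subject, group, _domain(group))
            evalue = config.evalue_base * config.evalue_factor ** (rank - 1)
            bitscore = max(10.0, 500.0 - 10.0 * (rank - 1))
            records.append((query, subject, evalue, bitscore))
    return HitSet.from_records(records), TaxonScheme(entries), origins
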