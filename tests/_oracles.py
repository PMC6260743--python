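"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the package's tree and graph machinery: the
sister-affinity oracle walks nested tuples, and the paralog oracle merges
groups pairwise to a fixpoint.  They exist so the production code paths
can be checked against a second, simpler derivation of the same rules.
"""

from __future__ import annotations

from itertools import combinations


# ---------------------------------------------------------------------------
# exhaustive rooted topologies over a fixed leaf set
# ---------------------------------------------------------------------------


def enumerate_rooted_trees(leaves):
    """All rooted binary topologies over *leaves* as nested tuples.

    Built by inserting each successive leaf on every edge (including above
    the root); yields (2n-3)!! trees for n leaves.
    """

    def insertions(tree, leaf):
        yield (tree, leaf)
        if isinstance(tree, tuple):
            a, b = tree
            for a2 in insertions(a, leaf):
                yield (a2, b)
            for b2 in insertions(b, leaf):
                yield (a, b2)

    trees = [leaves[0]]
    for leaf in leaves[1:]:
        trees = [t2 for t in trees for t2 in insertions(t, leaf)]
    return trees


def tuple_leaves(tree):
    if isinstance(tree, tuple):
        return tuple_leaves(tree[0]) + tuple_leaves(tree[1])
    return (tree,)


def tuple_to_newick(tree, support=100):
    """Newick with the given support on every internal node."""

    def rec(t):
        if isinstance(t, tuple):
            return f"({rec(t[0])},{rec(t[1])}){support}"
        return t

    return rec(tree) + ";"


def sister_affinity_oracle(
    tree,
    query,
    companion,
    group_of,
    archaeplastida,
    secondary,
):
    """Hand-derived sister-affinity call on a nested-tuple rooted tree.

    Mirrors the published sorting rules directly on set arithmetic: walk up
    from the query leaf; companion leaves in the sister set flag
    co-branching and are ignored; an empty effective sister set moves the
    reference clade up one level.  Returns
    (cobranching, sister_group_or_None, relationship).
    """

    def path_to(t, leaf):
        if t == leaf:
            return [t]
        if isinstance(t, tuple):
            for child in t:
                sub = path_to(child, leaf)
                if sub is not None:
                    return [t] + sub
        return None

    path = path_to(tree, query)
    assert path is not None
    cobranching = False
    # walk from the query leaf upward: path[-1] is the leaf
    for depth in range(len(path) - 2, -1, -1):
        node = path[depth]
        below = path[depth + 1]
        sister = set(tuple_leaves(node)) - set(tuple_leaves(below))
        comp = {l for l in sister if group_of(l) == companion}
        if comp:
            cobranching = True
        effective = sister - comp
        if not effective:
            continue
        groups = {group_of(l) for l in effective}
        arch = groups & archaeplastida
        if len(groups) == 1:
            return cobranching, next(iter(groups)), "exclusive"
        if (
            groups <= archaeplastida | secondary
            and len(arch) == 1
            and groups & secondary
        ):
            return cobranching, next(iter(arch)), "inclusive"
        return cobranching, None, "unresolved"
    return cobranching, None, "unresolved"


# ---------------------------------------------------------------------------
# paralog merging fixpoint
# ---------------------------------------------------------------------------


def merge_paralogs_fixpoint(hitsets, threshold, denominator="min"):
    """Repeatedly merge any two groups containing an over-threshold pair
    until no merge applies; returns a set of frozensets of queries."""

    def over(a, b):
        inter = len(hitsets[a] & hitsets[b])
        if denominator == "min":
            denom = min(len(hitsets[a]), len(hitsets[b]))
        elif denominator == "union":
            denom = len(hitsets[a] | hitsets[b])
        else:
            denom = (len(hitsets[a]) + len(hitsets[b])) / 2
        return inter / denom > threshold

    groups = [{q} for q in hitsets]
    changed = True
    while changed:
        changed = False
        for i, j in combinations(range(len(groups)), 2):
            if any(over(a, b) for a in groups[i] for b in groups[j]):
                groups[i] = groups[i] | groups[j]
                del groups[j]
                changed = True
                break
    return {frozenset(g) for g in groups}
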