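import itertools

import pytest

from egt_screen import (
    ARCHAEPLASTIDA_GROUPS,
    SECONDARY_PLASTID_GROUPS,
    SupportTree,
    TaxonEntry,
    TaxonScheme,
    background_comparison,
    classify_gene,
    classify_sister_signal,
    locate_query_clades,
    reduce_taxonomic_redundancy,
    root_tree,
    tally_signals,
)
from egt_screen.topology_classify import TopologyCall, UNRESOLVED

from _oracles import (
    enumerate_rooted_trees,
    sister_affinity_oracle,
    tuple_to_newick,
)


def scheme_for(mapping):
    return TaxonScheme(
        {
            leaf: TaxonEntry(leaf, group, "Bacteria" if group == "Bacteria" else "Eukaryota")
            for leaf, group in mapping.items()
        }
    )


FIVE_LEAF_GROUPS = {
    "q": "Goniomonadea",
    "c": "Cryptophyceae",
    "r": "Rhodophyta",
    "g": "Viridiplantae",
    "s": "Stramenopiles",
}
FIVE_LEAF_SCHEME = scheme_for(FIVE_LEAF_GROUPS)


class TestRootTree:
    def test_outgroup_rooting(self):
        t = SupportTree.from_string("((A:0.1,Bac:0.4)90:0.1,(B:0.1,C:0.1)80:0.1);")
        scheme = scheme_for({"A": "Alveolata", "B": "Alveolata", "C": "Rhizaria", "Bac": "Bacteria"})
        rooted = root_tree(t, scheme, {"Bacteria"})
        root_children = rooted.tree.seed_node.child_nodes()
        sides = [
            frozenset(l.taxon.label for l in c.leaf_iter()) for c in root_children
        ]
        assert frozenset({"Bac"}) in sides

    def test_supports_stay_on_their_splits(self):
        t = SupportTree.from_string(
            "(((A:0.1,B:0.1)90:0.1,C:0.1)70:0.1,(D:0.1,Bac:0.5)60:0.1);"
        )
        scheme = scheme_for(
            {"A": "Alveolata", "B": "Alveolata", "C": "Rhizaria", "D": "Haptista", "Bac": "Bacteria"}
        )
        rooted = root_tree(t, scheme, {"Bacteria"})
        supports = {}
        for nd in rooted.tree.preorder_internal_node_iter():
            if nd.parent_node is None or nd.support is None:
                continue
            supports[frozenset(l.taxon.label for l in nd.leaf_iter())] = nd.support
        assert supports[frozenset({"A", "B"})] == 90.0

    def test_midpoint_fallback_without_outgroup_leaves(self):
        t = SupportTree.from_string("((A:1,B:1):1,(C:1,D:10):1);")
        scheme = scheme_for({x: "Alveolata" for x in "ABCD"})
        rooted = root_tree(t, scheme, {"Bacteria"})
        # midpoint lies on D's long pendant edge
        sides = [
            frozenset(l.taxon.label for l in c.leaf_iter())
            for c in rooted.tree.seed_node.child_nodes()
        ]
        assert frozenset({"D"}) in sides

    def test_outgroup_covering_all_leaves_is_error(self):
        t = SupportTree.from_string("((A,B),C);")
        scheme = scheme_for({x: "Bacteria" for x in "ABC"})
        with pytest.raises(ValueError):
            root_tree(t, scheme, {"Bacteria"})

    def test_two_leaf_tree_is_error(self):
        t = SupportTree.from_string("(A,B);")
        scheme = scheme_for({"A": "Alveolata", "B": "Bacteria"})
        with pytest.raises(ValueError):
            root_tree(t, scheme, {"Bacteria"})


class TestReduceTaxonomicRedundancy:
    def test_oversized_group_clade_trimmed_by_length(self):
        t = SupportTree.from_string("(((S1,S2),(S3,(S4,S5))),(Q1,R1));")
        scheme = scheme_for(
            {f"S{i}": "Stramenopiles" for i in range(1, 6)}
            | {"Q1": "Goniomonadea", "R1": "Rhodophyta"}
        )
        lengths = {f"S{i}": i * 100 for i in range(1, 6)}
        drops = reduce_taxonomic_redundancy(t, scheme, 2, seq_lengths=lengths)
        assert drops == {"S1", "S2", "S3"}

    def test_one_leaf_per_group_drops_nothing(self):
        t = SupportTree.from_string("((A1,B1),(C1,D1));")
        scheme = scheme_for(
            {"A1": "Alveolata", "B1": "Rhizaria", "C1": "Haptista", "D1": "Rhodophyta"}
        )
        assert reduce_taxonomic_redundancy(t, scheme, 1) == set()

    def test_query_group_protected(self):
        t = SupportTree.from_string("(((Q1,Q2),(Q3,Q4)),R1);")
        scheme = scheme_for(
            {f"Q{i}": "Goniomonadea" for i in range(1, 5)} | {"R1": "Rhodophyta"}
        )
        drops = reduce_taxonomic_redundancy(
            t, scheme, 1, protected_groups={"Goniomonadea"}
        )
        assert drops == set()


class TestLocateQueryClades:
    def test_single_clade(self):
        t = SupportTree.from_string("((Q1,Q2),(R1,G1));")
        scheme = scheme_for(
            {"Q1": "Goniomonadea", "Q2": "Goniomonadea", "R1": "Rhodophyta", "G1": "Viridiplantae"}
        )
        assert locate_query_clades(t, scheme, "Goniomonadea") == [frozenset({"Q1", "Q2"})]

    def test_scattered_query_leaves_yield_singletons(self):
        t = SupportTree.from_string("((Q1,R1),(Q2,G1));")
        scheme = scheme_for(
            {"Q1": "Goniomonadea", "Q2": "Goniomonadea", "R1": "Rhodophyta", "G1": "Viridiplantae"}
        )
        assert locate_query_clades(t, scheme, "Goniomonadea") == [
            frozenset({"Q1"}),
            frozenset({"Q2"}),
        ]

    def test_absent_query_is_error(self):
        t = SupportTree.from_string("((R1,R2),G1);")
        scheme = scheme_for({"R1": "Rhodophyta", "R2": "Rhodophyta", "G1": "Viridiplantae"})
        with pytest.raises(ValueError, match="absent"):
            locate_query_clades(t, scheme, "Goniomonadea")


def _classify(newick, scheme=None, **kwargs):
    scheme = scheme or FIVE_LEAF_SCHEME
    tree = SupportTree.from_string(newick)
    clades = locate_query_clades(tree, scheme, "Goniomonadea")
    return classify_sister_signal(
        tree, clades[0], "Cryptophyceae", scheme, **kwargs
    )


class TestClassifySisterSignal:
    def test_exclusive_red_algal_affinity(self):
        scheme = scheme_for(
            {"Q": "Goniomonadea", "R1": "Rhodophyta", "R2": "Rhodophyta",
             "V1": "Viridiplantae", "V2": "Viridiplantae", "O": "Amoebozoa"}
        )
        call = _classify(
            "((Q,(R1,R2)100)100,((V1,V2)100,O)100);", scheme
        )
        assert (call.sister_group, call.relationship, call.support) == (
            "Rhodophyta", "exclusive", 100.0,
        )

    def test_support_at_threshold_is_unresolved(self):
        call = _classify("((q,(s,(r,g)100)100)70,c);")
        assert call.relationship == UNRESOLVED
        assert call.sister_group is None

    def test_inclusive_with_intervening_secondary_taxon(self):
        # two archaeplastidal groups in the sister set is mixed, hence unresolved
        call = _classify("((q,(s,(r,g)100)100)95,c);")
        assert call.relationship == UNRESOLVED
        # a single archaeplastidal lineage behind a secondary taxon is inclusive
        scheme = scheme_for({**FIVE_LEAF_GROUPS, "r2": "Rhodophyta"})
        call = _classify("((q,(s,(r,r2)100)100)95,c);", scheme)
        assert (call.sister_group, call.relationship, call.support) == (
            "Rhodophyta", "inclusive", 95.0,
        )

    def test_companion_in_sister_sets_cobranching_flag(self):
        call = _classify("((q,c)100,((r,g)100,s)100);")
        assert call.companion_cobranching is True

    def test_tree_without_supports_is_unresolved(self):
        call = _classify("((q,(r,r2)),((g,s),c));",
                         scheme_for({**FIVE_LEAF_GROUPS, "r2": "Rhodophyta"}))
        assert call.relationship == UNRESOLVED

    def test_query_clade_spanning_tree_is_error(self):
        t = SupportTree.from_string("(q1,q2);")
        scheme = scheme_for({"q1": "Goniomonadea", "q2": "Goniomonadea"})
        with pytest.raises(ValueError):
            classify_sister_signal(
                t, frozenset({"q1", "q2"}), "Cryptophyceae", scheme
            )

    def test_exhaustive_five_leaf_truth_table(self):
        """All 105 rooted topologies over {query, companion, red, green,
        secondary} with supports 100 match the independent oracle."""
        trees = enumerate_rooted_trees(["q", "c", "r", "g", "s"])
        assert len(trees) == 105
        group_of = FIVE_LEAF_GROUPS.__getitem__
        for tup in trees:
            expected = sister_affinity_oracle(
                tup, "q", "Cryptophyceae", lambda l: FIVE_LEAF_GROUPS[l],
                frozenset({"Rhodophyta", "Viridiplantae", "Glaucophyta"}),
                frozenset({"Cryptophyceae", "Stramenopiles"}),
            )
            tree = SupportTree.from_string(tuple_to_newick(tup))
            call = classify_sister_signal(
                tree, frozenset({"q"}), "Cryptophyceae", FIVE_LEAF_SCHEME
            )
            exp_group = {"Goniomonadea": None}.get(expected[1], expected[1])
            assert (
                call.companion_cobranching,
                call.sister_group,
                call.relationship,
            ) == (expected[0], exp_group, expected[2]), tup

    def test_raising_threshold_only_unresolves(self):
        newick = "((q,(r,g2)100)85,(c,(g,s)100)90);"
        scheme = scheme_for({**FIVE_LEAF_GROUPS, "g2": "Rhodophyta"})
        lo = _classify(newick, scheme, support_threshold=80.0)
        hi = _classify(newick, scheme, support_threshold=90.0)
        assert lo.relationship != UNRESOLVED
        assert hi.relationship == UNRESOLVED

    def test_invariant_to_child_rotation(self):
        scheme = scheme_for({**FIVE_LEAF_GROUPS, "r2": "Rhodophyta"})
        a = _classify("((q,(r,r2)100)95,(c,(g,s)100)90);", scheme)
        b = _classify("(((r2,r)100,q)95,((s,g)100,c)90);", scheme)
        assert (a.sister_group, a.relationship, a.support) == (
            b.sister_group, b.relationship, b.support,
        )


class TestTallyAndBackground:
    def _tally(self, spec_counts):
        calls = []
        for (cob, group, rel), n in spec_counts.items():
            sup = None if rel == UNRESOLVED else 100.0
            calls += [TopologyCall("g", cob, group, rel, sup)] * n
        return tally_signals(calls)

    def test_counts_conserved(self):
        tally = self._tally(
            {(False, "Rhodophyta", "exclusive"): 2, (False, None, UNRESOLVED): 1}
        )
        assert tally.total_trees == 3
        assert sum(tally.counts.values()) == 3

    def test_ratio_mirrors_published_contrast(self):
        tally = self._tally(
            {
                (False, "Rhodophyta", "exclusive"): 6,
                (False, "Amoebozoa", "exclusive"): 24,
                (False, None, UNRESOLVED): 255,
            }
        )
        ratio, p = background_comparison(tally, "Rhodophyta", "Amoebozoa")
        assert ratio == pytest.approx(0.25)
        assert p > 0.99  # 6 observed when 24/285 is the null rate

    def test_equal_counts_give_unity_and_half_tail(self):
        tally = self._tally(
            {
                (False, "Rhodophyta", "exclusive"): 10,
                (False, "Amoebozoa", "exclusive"): 10,
                (False, None, UNRESOLVED): 80,
            }
        )
        ratio, p = background_comparison(tally, "Rhodophyta", "Amoebozoa")
        assert ratio == 1.0
        assert 0.4 < p < 0.7

    def test_zero_hypothesis_count(self):
        tally = self._tally(
            {(False, "Amoebozoa", "exclusive"): 5, (False, None, UNRESOLVED): 5}
        )
        ratio, p = background_comparison(tally, "Rhodophyta", "Amoebozoa")
        assert ratio == 0.0
        assert p == 1.0

    def test_empty_call_list_is_error(self):
        with pytest.raises(ValueError):
            tally_signals([])
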