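"""Tree I/O, rerooting, Fitch/Hartigan vs brute force, rooting comparison,
event reconstruction and the distance/NJ pipeline."""

import itertools

import dendropy
import numpy as np
import pytest
from dendropy.calculate import treecompare

from phrkit.parsimony import (ActivityStates, cpf_clade_tree, compare_rootings,
                              fitch_count, nj_tree, parse_newick,
                              pdistance_matrix, reconstruct_events, reroot,
                              sankoff_cost, write_newick)
from phrkit.records import Msa


def random_binary_tree(rng, n_tips, prefix="t"):
    """Random rooted binary topology by recursive random bipartition."""
    labels = [f"{prefix}{i}" for i in range(n_tips)]
    rng.shuffle(labels)

    def build(group):
        if len(group) == 1:
            return group[0]
        cut = int(rng.integers(1, len(group)))
        return f"({build(group[:cut])},{build(group[cut:])})"

    return parse_newick(build(labels) + ";")


def brute_force_minimum(tree, states, alphabet):
    """Exhaustive enumeration over all internal-node labelings."""
    internals = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    best = None
    for combo in itertools.product(alphabet, repeat=len(internals)):
        assign = dict(zip(internals, combo))
        changes = 0
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            s = states[node.taxon.label] if node.is_leaf() else assign[node]
            p = assign[node.parent_node]
            changes += s != p
        best = changes if best is None else min(best, changes)
    return best


class TestNewickIO:
    def test_two_tip_tree(self):
        tree = parse_newick("(A,B);")
        assert {leaf.taxon.label for leaf in tree.leaf_node_iter()} == {"A", "B"}

    def test_round_trip_topology(self):
        text = "((A,B),(C,D));"
        tree = parse_newick(text)
        again = parse_newick(write_newick(tree))
        tns = dendropy.TaxonNamespace()
        a = dendropy.Tree.get(data=write_newick(tree), schema="newick", taxon_namespace=tns)
        b = dendropy.Tree.get(data=write_newick(again), schema="newick", taxon_namespace=tns)
        assert treecompare.symmetric_difference(a, b) == 0

    def test_polytomy_preserved(self):
        tree = parse_newick("(A,B,C,(D,E));")
        assert max(len(n.child_nodes()) for n in tree.preorder_node_iter()) >= 3
        assert "(D,E)" in write_newick(tree).replace(" ", "")

    def test_random_trees_round_trip(self, rng):
        for _ in range(25):
            tree = random_binary_tree(rng, int(rng.integers(4, 50)))
            text = write_newick(tree)
            tns = dendropy.TaxonNamespace()
            a = dendropy.Tree.get(data=text, schema="newick", taxon_namespace=tns)
            b = dendropy.Tree.get(data=write_newick(parse_newick(text)),
                                  schema="newick", taxon_namespace=tns)
            assert treecompare.symmetric_difference(a, b) == 0

    def test_malformed_rejected(self):
        with pytest.raises(ValueError, match="newick"):
            parse_newick("((A,B;")


class TestReroot:
    def test_tip_edge_becomes_root_child(self):
        tree = reroot(parse_newick("((A,B),(C,D));"), "C")
        root_children = tree.seed_node.child_nodes()
        assert any(c.is_leaf() and c.taxon.label == "C" for c in root_children)

    def test_reroot_twice_isomorphic(self):
        tree = parse_newick("((A,B),(C,D));")
        once = reroot(tree, "A")
        twice = reroot(once, "A")
        tns = dendropy.TaxonNamespace()
        a = dendropy.Tree.get(data=write_newick(once), schema="newick", taxon_namespace=tns)
        b = dendropy.Tree.get(data=write_newick(twice), schema="newick", taxon_namespace=tns)
        assert treecompare.symmetric_difference(a, b) == 0

    def test_unknown_edge_rejected(self):
        with pytest.raises(ValueError, match="no edge"):
            reroot(parse_newick("(A,B);"), "Z")

    def test_fitch_invariant_under_rerooting(self, rng):
        """Unordered parsimony scores do not depend on root placement."""
        for _ in range(100):
            n = int(rng.integers(4, 12))
            tree = random_binary_tree(rng, n)
            states = {f"t{i}": int(rng.integers(3)) for i in range(n)}
            base = fitch_count(tree, states)
            tip = f"t{int(rng.integers(n))}"
            assert fitch_count(reroot(tree, tip), states) == base


class TestFitch:
    def test_uniform_tips_zero_changes(self):
        tree = parse_newick("((A,B),(C,D));")
        assert fitch_count(tree, dict.fromkeys("ABCD", "CPD")) == 0

    def test_two_clades_one_change(self):
        tree = parse_newick("((A,B),(C,D));")
        states = {"A": "CPD", "B": "CPD", "C": "SIX4", "D": "SIX4"}
        assert fitch_count(tree, states) == 1
        assert brute_force_minimum(tree, states, ["CPD", "SIX4"]) == 1

    def test_equals_brute_force_on_random_trees(self, rng):
        for _ in range(200):
            n = int(rng.integers(3, 9))
            k = int(rng.integers(2, 5))
            tree = random_binary_tree(rng, n)
            states = {f"t{i}": int(rng.integers(k)) for i in range(n)}
            assert fitch_count(tree, states) == brute_force_minimum(
                tree, states, list(range(k)))

    def test_polytomy_handled(self):
        tree = parse_newick("(A,B,C,D);")
        assert fitch_count(tree, {"A": 0, "B": 0, "C": 1, "D": 2}) == 2

    def test_missing_tip_state_rejected(self):
        with pytest.raises(ValueError, match="t1"):
            fitch_count(parse_newick("(t0,t1);"), {"t0": 0})


class TestSankoff:
    def test_symmetric_unit_costs_match_fitch(self, rng):
        cost = {(a, b): float(a != b) for a in range(3) for b in range(3)}
        for _ in range(30):
            n = int(rng.integers(3, 9))
            tree = random_binary_tree(rng, n)
            states = {f"t{i}": int(rng.integers(3)) for i in range(n)}
            assert sankoff_cost(tree, states, cost) == fitch_count(tree, states)

    def test_origin_anchoring_charges_root_state(self):
        tree = parse_newick("(A,B);")
        cost = {(0, 0): 0.0, (1, 1): 0.0, (0, 1): 2.0, (1, 0): 1.0}
        states = {"A": 1, "B": 1}
        assert sankoff_cost(tree, states, cost) == 0.0
        assert sankoff_cost(tree, states, cost, origin_state=0) == 2.0


class TestRootingComparison:
    def test_single_candidate_is_argmin(self):
        tree, states = cpf_clade_tree()
        table, argmin = compare_rootings(tree, ["SPL"], states)
        assert argmin == ["SPL"] and len(table) == 1

    def test_empty_candidates_rejected(self):
        tree, states = cpf_clade_tree()
        with pytest.raises(ValueError):
            compare_rootings(tree, [], states)

    def test_rooting_inside_derived_clade_scores_higher(self):
        # Unrooted 4-taxon tree AB|CD; A repairs both lesions, B only 6-4,
        # C and D only CPD. Rooting at C needs one 6-4 gain on the AB stem
        # (cost 2) plus one free-rooted CPD loss on B (cost 1) = 3. Rooting
        # at A forces the 6-4 gain onto the root's own stem plus the same
        # losses, and the CPD trait loses its free root advantage: total 4.
        tree = parse_newick("((A,B),(C,D));")
        states = ActivityStates({"A": "DUAL", "B": "SIX4", "C": "CPD", "D": "CPD"})
        table, argmin = compare_rootings(tree, ["A", "C"], states)
        scores = dict(zip(table.root, table.score))
        assert scores["C"] == 3.0 and scores["A"] == 4.0
        assert argmin == ["C"]

    def test_spl_rooting_minimal_on_cpf_tree(self):
        tree, states = cpf_clade_tree()
        table, argmin = compare_rootings(
            tree, ["SPL", "FeS_BCP", "bifunctional"], states)
        assert argmin == ["SPL"]
        scores = dict(zip(table.root, table.score))
        assert scores["SPL"] < scores["FeS_BCP"]
        assert scores["SPL"] < scores["bifunctional"]


class TestEventReconstruction:
    def test_all_same_no_events(self):
        tree = parse_newick("((A,B),(C,D));")
        states = ActivityStates(dict.fromkeys("ABCD", "CPD"))
        report = reconstruct_events(tree, states)
        assert not report.events and report.total_score == 0

    def test_cpf_two_independent_loss_gain_events(self):
        tree, states = cpf_clade_tree()
        report = reconstruct_events(tree, states)
        assert report.gains["lost_cpd_gained_six4"] == 2
        branches = {b for t, b, _, _ in report.events if t == "lost_cpd_gained_six4"}
        assert branches == {"FeS_BCP", "eukaryotic_6_4"}

    def test_cpf_three_independent_six4_gains(self):
        tree, states = cpf_clade_tree()
        report = reconstruct_events(tree, states)
        assert report.gains["six4"] == 3
        branches = {b for t, b, f, s in report.events
                    if t == "six4" and (f, s) == (0, 1)}
        assert branches == {"FeS_BCP", "eukaryotic_6_4", "bifunctional"}

    def test_flip_totals_equal_fitch_minimum(self, rng):
        for _ in range(50):
            n = int(rng.integers(3, 10))
            tree = random_binary_tree(rng, n)
            tips = {f"t{i}": int(rng.integers(2)) for i in range(n)}
            report = reconstruct_events(
                tree, ActivityStates(dict.fromkeys(tips, "CPD")), traits={"x": tips})
            flips = sum(1 for t, *_ in report.events if t == "x")
            assert flips == report.fitch_minimum["x"] == fitch_count(tree, tips)


class TestDistanceNj:
    def test_identical_sequences_zero_matrix(self):
        msa = Msa(["a", "b", "c"], ["WAD", "WAD", "WAD"])
        assert not pdistance_matrix(msa).data.any()

    def test_pdistance_hand_value(self):
        msa = Msa(["a", "b", "c"], ["WWWW", "WW-D", "AAAA"])
        dm = pdistance_matrix(msa)
        assert dm["a", "b"] == pytest.approx(1 / 3)  # 3 shared columns, 1 mismatch
        assert dm["a", "c"] == 1.0

    def test_nj_recovers_additive_quartet(self):
        import skbio
        # additive distances from ((A:1,B:2):1,(C:3,D:4):1)
        dm = skbio.DistanceMatrix(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]],
            ids=list("ABCD"))
        tree = nj_tree(dm)
        tns = dendropy.TaxonNamespace()
        got = dendropy.Tree.get(data=write_newick(tree), schema="newick",
                                taxon_namespace=tns)
        want = dendropy.Tree.get(data="((A,B),(C,D));", schema="newick",
                                 taxon_namespace=tns)
        got.encode_bipartitions(); want.encode_bipartitions()
        assert treecompare.symmetric_difference(got, want) == 0

    def test_nj_recovers_planted_ten_tip_trees(self, rng):
        import skbio
        for _ in range(5):
            tree = random_binary_tree(rng, 10)
            for edge in tree.preorder_edge_iter():
                if edge.head_node.parent_node is not None:
                    edge.length = float(rng.uniform(0.5, 2.0))
            pdc = tree.phylogenetic_distance_matrix()
            taxa = list(tree.taxon_namespace)
            ids = [t.label for t in taxa]
            mat = [[pdc.distance(a, b) for b in taxa] for a in taxa]
            got = nj_tree(skbio.DistanceMatrix(np.array(mat), ids=ids))
            tns = dendropy.TaxonNamespace()
            a = dendropy.Tree.get(data=write_newick(got), schema="newick",
                                  taxon_namespace=tns)
            b = dendropy.Tree.get(data=write_newick(tree), schema="newick",
                                  taxon_namespace=tns)
            a.encode_bipartitions(); b.encode_bipartitions()
            assert treecompare.symmetric_difference(a, b, is_bipartitions_updated=True) == 0

    def test_asymmetric_matrix_rejected(self):
        import skbio
        msa = Msa(["a", "b", "c"], ["WW", "WA", "AA"])
        dm = pdistance_matrix(msa)
        bad = dm.data.copy()
        bad[0, 1] += 0.1
        with pytest.raises(Exception):
            nj_tree(skbio.DistanceMatrix(bad, ids=dm.ids))
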