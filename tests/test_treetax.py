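"""Order-cluster counting (with brute-force oracle), rOTU order assignment,
feeding-type transfer, concatenation comparison."""

import io

import numpy as np
import pytest
from skbio import TreeNode

from nemabar.phylo import bootstrap_support, pairwise_distance, root_at_outgroup
from nemabar.treetax import (
    assign_feeding_type,
    assign_rotu_order,
    compare_concatenations,
    count_order_clusters,
)

from oracles import brute_force_order_clusters, random_labeled_tree

NON_ORDERS = {"rOTU", "outgroup"}


def tree_of(newick: str) -> TreeNode:
    return TreeNode.read(io.StringIO(newick))


class TestCountOrderClusters:
    def test_monophyletic_caterpillar(self):
        t = tree_of("(((a1,a2),a3),b1);")
        labels = {"a1": "A", "a2": "A", "a3": "A", "b1": "B"}
        rep = count_order_clusters(t, labels)
        row = rep.table.set_index("order").loc["A"]
        assert row["n_clusters"] == 1 and row["max_cluster_size"] == 3

    def test_interleaved_orders_two_clusters(self):
        t = tree_of("((a1,b1),(a2,b2));")
        labels = {"a1": "A", "b1": "B", "a2": "A", "b2": "B"}
        rep = count_order_clusters(t, labels).table.set_index("order")
        assert rep.loc["A", "n_clusters"] == 2
        assert rep.loc["B", "n_clusters"] == 2

    def test_rotu_leaf_breaks_purity(self):
        t = tree_of("(((a1,q1),a2),b1);")
        labels = {"a1": "A", "q1": "rOTU", "a2": "A", "b1": "B"}
        rep = count_order_clusters(t, labels).table.set_index("order")
        assert rep.loc["A", "n_clusters"] == 2
        assert "rOTU" not in rep.index

    def test_single_species_order_flagged_omitted(self):
        t = tree_of("((a1,a2),b1);")
        rep = count_order_clusters(
            t, {"a1": "A", "a2": "A", "b1": "B"}).table.set_index("order")
        assert bool(rep.loc["B", "omitted"]) is True
        assert bool(rep.loc["A", "omitted"]) is False

    def test_unlabeled_leaf_rejected(self):
        t = tree_of("((a1,a2),b1);")
        with pytest.raises(ValueError):
            count_order_clusters(t, {"a1": "A", "a2": "A"})

    def test_cluster_sizes_partition_order_leaves(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            t, labels = random_labeled_tree(
                int(rng.integers(4, 31)), ["A", "B", "C"], rng)
            rep = count_order_clusters(t, labels)
            for order, clusters in rep.memberships.items():
                n_leaves = sum(1 for v in labels.values() if v == order)
                assert sum(len(c) for c in clusters) == n_leaves

    def test_brute_force_oracle_1000_random_trees(self):
        rng = np.random.default_rng(123)
        orders = ["A", "B", "C", "rOTU"]
        for _ in range(1000):
            n = int(rng.integers(4, 31))
            t, labels = random_labeled_tree(n, orders, rng)
            rep = count_order_clusters(t, labels)
            got = dict(zip(rep.table["order"], rep.table["n_clusters"]))
            expected = brute_force_order_clusters(t, labels, NON_ORDERS)
            for order in got:
                assert got[order] == expected.get(order, 0), (n, order)

    def test_all_monophyletic_means_all_ones(self, pipeline_bundle):
        # reference-only tree at default divergences: every order monophyletic
        _, _, bundle = pipeline_bundle
        references = bundle["references"]
        from nemabar.pipeline import build_region_sequences
        per, _ = build_region_sequences(references)
        seqs = {sp: "".join(per[sp][r].sequence for r in (1, 2, 3, 4))
                for sp in per}
        tree = bootstrap_support(seqs, n_replicates=0)
        rooted = root_at_outgroup(tree, "Tardigrada_outgroup")
        labels = {r.species_id: (r.order if not r.is_outgroup else "outgroup")
                  for r in references}
        rep = count_order_clusters(rooted, labels).table
        assert (rep["n_clusters"] == 1).all()
        assert (rep["max_cluster_size"] == rep["n_species"]).all()


class TestAssignOrder:
    def test_sister_to_pure_clade(self):
        t = tree_of("(((d1,d2),q1),(r1,r2));")
        labels = {"d1": "Dorylaimida", "d2": "Dorylaimida", "q1": "rOTU",
                  "r1": "Rhabditida", "r2": "Rhabditida"}
        order, size = assign_rotu_order(t, "q1", labels)
        assert order == "Dorylaimida" and size == 2

    def test_mixed_clade_majority(self):
        t = tree_of("(((d1,d2),(r1,q1)),(d3,d4));")
        labels = {"d1": "D", "d2": "D", "d3": "D", "d4": "D",
                  "r1": "R", "q1": "rOTU"}
        order, _ = assign_rotu_order(t, "q1", labels)
        # first informative clade is {r1}: unanimous R
        assert order == "R"

    def test_tie_defers_to_next_ancestor(self):
        t = tree_of("(((d1,r1),q1),(d2,d3));")
        labels = {"d1": "D", "r1": "R", "q1": "rOTU", "d2": "D", "d3": "D"}
        order, _ = assign_rotu_order(t, "q1", labels)
        assert order == "D"  # 1:1 tie at first clade; root clade majority D

    def test_no_references_rejected(self):
        t = tree_of("((q1,q2),q3);")
        labels = {"q1": "rOTU", "q2": "rOTU", "q3": "rOTU"}
        with pytest.raises(ValueError):
            assign_rotu_order(t, "q1", labels)

    def test_truth_recovery_on_pipeline(self, pipeline_bundle):
        _, _, bundle = pipeline_bundle
        truth = bundle["truth"]
        rotu_species = {r.rotu_id: truth.sample_species[r.members[0]]
                        for r in bundle["rotus"]}
        for row in bundle["assignments"].itertuples():
            assert row.order == truth.species_order[rotu_species[row.rotu]]


class TestAssignFeeding:
    def test_zero_distance_neighbor(self):
        t = tree_of("((q1:0.0,ref1:0.0):0.1,(ref2:0.2,ref3:0.3):0.1);")
        code, nearest, dist = assign_feeding_type(
            t, "q1", {"ref1": "2", "ref2": "3", "ref3": "5"})
        assert (code, nearest) == ("2", "ref1") and dist == 0.0

    def test_missing_annotation_named(self):
        t = tree_of("((q1:1,ref1:1):1,ref2:1);")
        with pytest.raises(ValueError, match="ref2"):
            assign_feeding_type(t, "q1", {"ref1": "2"},
                                reference_leaves=["ref1", "ref2"])

    def test_brute_force_patristic_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            t, _ = random_labeled_tree(12, ["x"], rng)
            for node in t.traverse():
                node.length = float(rng.uniform(0.1, 2.0))
            refs = [f"L{i}" for i in range(1, 12)]
            annotation = {r: str(i) for i, r in enumerate(refs)}
            code, nearest, dist = assign_feeding_type(t, "L0", annotation)
            # naive all-pairs check
            q = t.find("L0")
            exhaustive = {r: q.distance(t.find(r)) for r in refs}
            best = min(exhaustive.items(), key=lambda kv: (kv[1], kv[0]))
            assert abs(dist - best[1]) < 1e-9
            assert exhaustive[nearest] <= best[1] + 1e-9

    def test_feeding_truth_recovery_on_pipeline(self, pipeline_bundle):
        _, _, bundle = pipeline_bundle
        truth = bundle["truth"]
        rotu_species = {r.rotu_id: truth.sample_species[r.members[0]]
                        for r in bundle["rotus"]}
        for row in bundle["assignments"].itertuples():
            expected = truth.species_feeding[rotu_species[row.rotu]]
            assert row.feeding_code == expected


class TestCompareConcatenations:
    def test_identical_trees_identical_columns(self):
        t = tree_of("(((a1,a2),b1),b2);")
        labels = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        n_mat, m_mat = compare_concatenations(
            {"R1": (t, labels), "R2": (t.copy(), dict(labels))})
        assert (n_mat["R1"] == n_mat["R2"]).all()
        assert (m_mat["R1"] == m_mat["R2"]).all()

    def test_single_order_all_ones(self):
        t = tree_of("((a1,a2),(a3,a4));")
        labels = {f"a{i}": "A" for i in range(1, 5)}
        n_mat, _ = compare_concatenations({"R1": (t, labels)})
        assert (n_mat["R1"] == 1).all()

    def test_concatenation_improves_noisy_single_region(self):
        """Short, noisy single-region alignments fragment orders that the
        concatenated alignment recovers."""
        from nemabar.synthetic import SimulationConfig, simulate_reference_set
        from nemabar.pipeline import build_region_sequences
        cfg = SimulationConfig(seed=20, n_orders=5, species_per_order=6,
                               within_order_div=0.18, between_order_div=0.05)
        references, _ = simulate_reference_set(cfg)
        per, _ = build_region_sequences(references)
        labels = {r.species_id: (r.order if not r.is_outgroup else "outgroup")
                  for r in references}
        trees = {}
        for name, rs in (("R3", (3,)), ("R1_2_3_4", (1, 2, 3, 4))):
            seqs = {sp: "".join(per[sp][r].sequence for r in rs) for sp in per}
            tree = bootstrap_support(seqs, n_replicates=0)
            trees[name] = (root_at_outgroup(tree, "Tardigrada_outgroup"),
                           labels)
        n_mat, _ = compare_concatenations(trees)
        assert (n_mat["R1_2_3_4"] <= n_mat["R3"]).all()
        assert n_mat["R1_2_3_4"].sum() < n_mat["R3"].sum()
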