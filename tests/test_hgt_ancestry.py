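from itertools import chain, combinations

import pandas as pd
import pytest

from oracles import dollo_min_losses, to_newick, tuple_tree_leaves
from panagrokit import core_io, hgt_ancestry as anc, synthetic_data as sd
from panagrokit.core_io import node_label

TEN_LEAF_TREE = (
    "(((((L1,L2),L3),(L4,L5)),((L6,L7),L8)),(L9,L10));"
)


def _matrix(rows: dict[str, list[str]], species: list[str]) -> anc.PresenceMatrix:
    data = pd.DataFrame(
        {sp: [sp in rows[f] for f in rows] for sp in species},
        index=list(rows),
    )
    return anc.PresenceMatrix(data.astype(bool))


class TestInferGainNode:
    def test_single_leaf(self, quartet_tree):
        node = anc.infer_gain_node(quartet_tree, ["A"])
        assert node_label(node) == "A"

    def test_sisters(self, quartet_tree):
        assert node_label(anc.infer_gain_node(quartet_tree, ["A", "B"])) == "ab"

    def test_spanning_pair_hits_root(self, quartet_tree):
        assert node_label(anc.infer_gain_node(quartet_tree, ["A", "C"])) == "root"

    def test_unknown_leaf(self, quartet_tree):
        with pytest.raises(KeyError):
            anc.infer_gain_node(quartet_tree, ["A", "nope"])


class TestInferLosses:
    def test_full_clade_no_losses(self, quartet_tree):
        gain = core_io.find_node(quartet_tree, "root")
        assert anc.infer_losses(quartet_tree, gain, ["A", "B", "C", "D"]) == set()

    def test_alternating_pattern_two_leaf_losses(self, quartet_tree):
        gain = core_io.find_node(quartet_tree, "root")
        losses = anc.infer_losses(quartet_tree, gain, ["A", "C"])
        assert {node_label(n) for n in losses} == {"B", "D"}

    def test_whole_subtree_lost_as_one_event(self, quartet_tree):
        gain = core_io.find_node(quartet_tree, "root")
        losses = anc.infer_losses(quartet_tree, gain, ["A", "B"])
        assert {node_label(n) for n in losses} == {"cd"}

    def test_minimality_against_brute_force(self):
        """Loss counts equal the exhaustive single-gain minimum (<= 6 leaves)."""
        topologies = [
            ("A", ("B", "C")),
            (("A", "B"), ("C", "D")),
            ((("A", "B"), "C"), ("D", "E")),
            ((("A", "B"), ("C", "D")), ("E", "F")),
            (((("A", "B"), "C"), "D"), ("E", "F")),
        ]
        for topology in topologies:
            leaves = sorted(tuple_tree_leaves(topology))
            tree = core_io.read_tree(to_newick(topology) + ";")
            subsets = chain.from_iterable(
                combinations(leaves, r) for r in range(1, len(leaves) + 1)
            )
            for present in subsets:
                gain = anc.infer_gain_node(tree, list(present))
                losses = anc.infer_losses(tree, gain, list(present))
                expected = dollo_min_losses(topology, frozenset(present))
                assert len(losses) == expected, (topology, present)


class TestReconstruct:
    def test_ubiquitous_family(self, quartet_tree):
        matrix = _matrix({"f1": ["A", "B", "C", "D"]}, ["A", "B", "C", "D"])
        recon = anc.reconstruct(matrix, quartet_tree)
        assert recon.gain_node["f1"] == "root"
        assert recon.loss_edges["f1"] == frozenset()
        assert (recon.node_summary["cumulative_present"] == 1).all()

    def test_single_gain_per_family(self, quartet_tree):
        matrix = _matrix(
            {"f1": ["A"], "f2": ["A", "B"], "f3": ["B", "D"]},
            ["A", "B", "C", "D"],
        )
        recon = anc.reconstruct(matrix, quartet_tree)
        assert recon.node_summary["gains"].sum() == 3

    def test_leaf_states_match_input(self, quartet_tree):
        matrix = _matrix(
            {"f1": ["A", "C"], "f2": ["B"], "f3": ["A", "B", "D"]},
            ["A", "B", "C", "D"],
        )
        recon = anc.reconstruct(matrix, quartet_tree)
        # replay each family's gain/losses down the tree
        for family in matrix.families:
            present = set()
            gain = core_io.find_node(quartet_tree, recon.gain_node[family])
            lost = recon.loss_edges[family]

            def walk(node, alive):
                if node_label(node) in lost:
                    alive = False
                if node.is_leaf():
                    if alive:
                        present.add(node.taxon.label)
                    return
                for child in node.child_nodes():
                    walk(child, alive)

            walk(gain, True)
            assert present == set(matrix.present_species(family)), family

    def test_additivity_identity(self, species_tree):
        matrix, _ = sd.simulate_presence_matrix(
            sd.GainLossSimSpec(n_families=80, loss_rate=0.25, seed=3)
        )
        recon = anc.reconstruct(matrix, species_tree)
        summary = recon.node_summary
        for node in species_tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            row = summary.loc[node_label(node)]
            parent_row = summary.loc[node_label(node.parent_node)]
            assert (
                row["cumulative_present"] - parent_row["cumulative_present"]
                == row["gains"] - row["losses"]
            )

    def test_ancestral_content_sums_gains(self, species_tree):
        """7 root families + 49 gained at the congener crown -> 56 present."""
        leaves = core_io.leaf_labels(species_tree)
        crown = [
            l.taxon.label
            for l in core_io.find_node(species_tree, "panagro").leaf_iter()
        ]
        rows = {f"root_{i}": leaves for i in range(7)}
        rows.update({f"crown_{i}": crown for i in range(49)})
        recon = anc.reconstruct(_matrix(rows, leaves), species_tree)
        crown_row = recon.node_summary.loc["panagro"]
        assert crown_row["gains"] == 49
        assert crown_row["cumulative_present"] == 56


class TestRecovery:
    def test_exact_recovery_without_loss(self):
        spec = sd.GainLossSimSpec(
            TEN_LEAF_TREE, n_families=200, loss_rate=0.0, seed=21
        )
        matrix, truth = sd.simulate_presence_matrix(spec)
        recon = anc.reconstruct(matrix, core_io.read_tree(TEN_LEAF_TREE))
        assert all(
            recon.gain_node[f] == truth.gain_node[f] for f in matrix.families
        )

    def test_recovery_under_ten_percent_loss(self):
        spec = sd.GainLossSimSpec(
            TEN_LEAF_TREE, n_families=200, loss_rate=0.1, seed=21
        )
        matrix, truth = sd.simulate_presence_matrix(spec)
        tree = core_io.read_tree(TEN_LEAF_TREE)
        recon = anc.reconstruct(matrix, tree)
        recovered = sum(
            recon.gain_node[f] == truth.gain_node[f] for f in matrix.families
        )
        assert recovered >= 0.9 * len(matrix.families)

    def test_losses_shift_inferred_gain_tipward_only(self):
        """The inferred gain is always within the true gain's clade.

        Losing carriers shrinks the present set, so its MRCA can only move
        toward the tips relative to the simulated gain node, never above it.
        """
        spec = sd.GainLossSimSpec(
            TEN_LEAF_TREE, n_families=200, loss_rate=0.3, seed=5
        )
        matrix, truth = sd.simulate_presence_matrix(spec)
        tree = core_io.read_tree(TEN_LEAF_TREE)
        recon = anc.reconstruct(matrix, tree)
        for family in matrix.families:
            true_gain = core_io.find_node(tree, truth.gain_node[family])
            descendant_labels = {
                node_label(n) for n in true_gain.preorder_iter()
            }
            assert recon.gain_node[family] in descendant_labels
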