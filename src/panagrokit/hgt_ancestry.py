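"""Dollo-parsimony reconstruction of gene-family gain and loss on a tree.

Each horizontally acquired family is assumed to have entered the genome
exactly once (multiple independent acquisitions of the same family being
less parsimonious) and may subsequently be lost any number of times. Under
this Dollo model the most parsimonious gain node is the most recent common
ancestor of the species carrying the family, and the minimal loss set is
the set of maximal subtrees below the gain node that contain no carrier.
Per-node summaries report gains, losses (on the edge above the node) and
the cumulative number of families present.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy
import pandas as pd

from .core_io import leaf_labels, mrca, node_label


@dataclass(frozen=True)
class PresenceMatrix:
    """Family x species boolean presence/absence matrix."""

    data: pd.DataFrame  # index: family ids, columns: species ids, dtype bool

    def __post_init__(self) -> None:
        if not self.data.dtypes.map(lambda d: d == bool).all():
            raise ValueError("presence matrix must be boolean")
        empty = self.data.index[~self.data.any(axis=1)]
        if len(empty):
            raise ValueError(
                f"families present in no species: {list(empty[:5])}"
            )

    @property
    def families(self) -> list[str]:
        return list(self.data.index)

    @property
    def species(self) -> list[str]:
        return list(self.data.columns)

    def present_species(self, family: str) -> list[str]:
        row = self.data.loc[family]
        return list(row.index[row])

    @classmethod
    def from_tsv(cls, path) -> "PresenceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.astype(bool))

    def to_tsv(self, path) -> None:
        self.data.astype(int).to_csv(path, sep="\t")


@dataclass(frozen=True)
class AncestralReconstruction:
    """Per-family gains/losses plus per-node content summary.

    ``gain_node`` maps each family to the label of its inferred acquisition
    node; ``loss_edges`` to the labels of the child nodes whose parent edge
    lost the family. ``node_summary`` has one row per tree node with
    columns ``gains``, ``losses`` (on the edge above the node) and
    ``cumulative_present``.
    """

    gain_node: Mapping[str, str]
    loss_edges: Mapping[str, frozenset[str]]
    node_summary: pd.DataFrame


def infer_gain_node(
    tree: dendropy.Tree, present_leaves: Sequence[str]
) -> dendropy.Node:
    """Most parsimonious single gain node: the MRCA of the carriers."""
    if not present_leaves:
        raise ValueError("present_leaves must be non-empty")
    return mrca(tree, list(present_leaves))


def infer_losses(
    tree: dendropy.Tree,
    gain_node: dendropy.Node,
    present_leaves: Sequence[str],
) -> set[dendropy.Node]:
    """Minimal Dollo loss set below the gain node.

    Returns the child nodes of the lost edges: the roots of the maximal
    subtrees under ``gain_node`` containing no present leaf. Each such edge
    accounts for every absent leaf beneath it with a single loss, which is
    minimal because any valid loss set must cover those leaves and no
    smaller set can.
    """
    present = set(present_leaves)
    gained_leaves = {l.taxon.label for l in gain_node.leaf_iter()}
    if not present <= gained_leaves:
        raise ValueError("present leaves must descend from the gain node")

    losses: set[dendropy.Node] = set()

    def walk(node: dendropy.Node) -> None:
        for child in node.child_nodes():
            child_leaves = {l.taxon.label for l in child.leaf_iter()}
            if child_leaves & present:
                walk(child)
            else:
                losses.add(child)

    if gain_node.is_leaf():
        return losses
    walk(gain_node)
    return losses


def reconstruct(
    matrix: PresenceMatrix, tree: dendropy.Tree
) -> AncestralReconstruction:
    """Dollo reconstruction of every family on the species tree.

    The cumulative content of a node is its parent's cumulative content
    plus the gains at the node minus the losses on the edge above it; the
    root's cumulative content equals its gains.
    """
    tree_leaves = set(leaf_labels(tree))
    if set(matrix.species) != tree_leaves:
        raise ValueError(
            "species in matrix do not match tree leaves: "
            f"matrix-only={sorted(set(matrix.species) - tree_leaves)}, "
            f"tree-only={sorted(tree_leaves - set(matrix.species))}"
        )

    gain_of: dict[str, str] = {}
    losses_of: dict[str, frozenset[str]] = {}
    gains_at: dict[str, int] = {}
    losses_at: dict[str, int] = {}

    for family in matrix.families:
        present = matrix.present_species(family)
        gain = infer_gain_node(tree, present)
        loss_nodes = infer_losses(tree, gain, present)
        gain_label = node_label(gain)
        gain_of[family] = gain_label
        losses_of[family] = frozenset(node_label(n) for n in loss_nodes)
        gains_at[gain_label] = gains_at.get(gain_label, 0) + 1
        for n in loss_nodes:
            label = node_label(n)
            losses_at[label] = losses_at.get(label, 0) + 1

    rows = []
    cumulative: dict[int, int] = {}
    for node in tree.preorder_node_iter():
        label = node_label(node)
        gains = gains_at.get(label, 0)
        losses = losses_at.get(label, 0)
        if node.parent_node is None:
            cum = gains
        else:
            cum = cumulative[id(node.parent_node)] + gains - losses
        cumulative[id(node)] = cum
        rows.append(
            {
                "node": label,
                "is_leaf": node.is_leaf(),
                "gains": gains,
                "losses": losses,
                "cumulative_present": cum,
            }
        )
    summary = pd.DataFrame(rows).set_index("node")
    return AncestralReconstruction(gain_of, losses_of, summary)


def node_content_report(recon: AncestralReconstruction) -> pd.DataFrame:
    """One row per node: gains, losses on the edge above, cumulative content."""
    return recon.node_summary.copy()
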