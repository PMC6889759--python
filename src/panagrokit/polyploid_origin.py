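"""Allo- vs autopolyploid origin testing by duplication-loss reconciliation.

Parthenogenetic polyploids carry extra gene copies whose phylogenetic
position discriminates two scenarios: under autopolyploidy (within-lineage
whole-genome duplication) each extra copy should be sister to the copy of
its own species, while under allopolyploidy (hybrid origin) the extra
copies of all parthenogens should form a clade derived from a donor
lineage outside the sampled species.

The search grafts a hypothetical DONOR leaf midway onto every edge of the
species tree in turn, maps the extra copies to DONOR, and scores each
grafted tree against every gene tree by standard LCA duplication-loss
reconciliation (cost = duplications + losses). The graft edge minimising
the total cost identifies the donor position: a terminal edge of a
parthenogen, or an edge inside the parthenogen clade, reads as
autopolyploidy; an edge outside it reads as allopolyploidy. This
single-donor-leaf grafting is a deliberate simplification of full MUL-tree
reconciliation, sufficient to separate the two hypotheses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy

from .core_io import find_node, node_label, read_tree

logger = logging.getLogger("panagrokit")

DONOR_LABEL = "DONOR"

VERDICT_ALLO = "allo"
VERDICT_AUTO = "auto"
VERDICT_AMBIGUOUS = "ambiguous"


def parse_leaf_label(label: str) -> tuple[str, int]:
    """Split a ``SPECIES|copyN`` gene-tree leaf label; bare labels are copy 1."""
    if "|" in label:
        species, _, copy_part = label.partition("|")
        if not copy_part.startswith("copy"):
            raise ValueError(
                f"leaf label {label!r} does not follow SPECIES|copyN"
            )
        return species, int(copy_part[4:])
    return label, 1


class _TreeIndex:
    """Parent/depth index over a rooted tree for fast LCA queries."""

    def __init__(self, tree: dendropy.Tree):
        self.nodes = list(tree.preorder_node_iter())
        self.pos = {id(n): i for i, n in enumerate(self.nodes)}
        self.parent = [
            self.pos[id(n.parent_node)] if n.parent_node is not None else -1
            for n in self.nodes
        ]
        self.depth = [0] * len(self.nodes)
        for i, n in enumerate(self.nodes):
            if self.parent[i] >= 0:
                self.depth[i] = self.depth[self.parent[i]] + 1
        self.leaf_index = {
            n.taxon.label: i for i, n in enumerate(self.nodes) if n.is_leaf()
        }

    def lca(self, i: int, j: int) -> int:
        while self.depth[i] > self.depth[j]:
            i = self.parent[i]
        while self.depth[j] > self.depth[i]:
            j = self.parent[j]
        while i != j:
            i = self.parent[i]
            j = self.parent[j]
        return i


def lca_reconcile(
    gene_tree: dendropy.Tree,
    species_tree: dendropy.Tree,
    leaf_map: Mapping[str, str],
) -> tuple[int, int]:
    """Duplication and loss counts of the LCA reconciliation.

    Each gene leaf is mapped to its species leaf through ``leaf_map``;
    internal gene nodes map to the LCA of their children's images. A node
    is a duplication iff its image equals the image of one of its
    children. Losses follow standard counting: for each child edge the
    number of species edges skipped minus one, plus one more when the
    parent is a duplication that does not span down to the child's image.
    """
    sidx = _TreeIndex(species_tree)
    dups = 0
    losses = 0
    image: dict[int, int] = {}
    for node in gene_tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label
            if label not in leaf_map:
                raise KeyError(f"gene leaf {label!r} missing from leaf_map")
            species = leaf_map[label]
            if species not in sidx.leaf_index:
                raise KeyError(
                    f"species {species!r} (gene leaf {label!r}) "
                    "not in species tree"
                )
            image[id(node)] = sidx.leaf_index[species]
            continue
        children = node.child_nodes()
        m = image[id(children[0])]
        for child in children[1:]:
            m = sidx.lca(m, image[id(child)])
        image[id(node)] = m
        is_dup = any(image[id(c)] == m for c in children)
        if is_dup:
            dups += 1
        for child in children:
            d = sidx.depth[image[id(child)]] - sidx.depth[m]
            losses += max(d - 1, 0)
            if is_dup and image[id(child)] != m:
                losses += 1
    return dups, losses


def graft_candidates(
    species_tree: dendropy.Tree,
) -> list[tuple[str, dendropy.Tree]]:
    """One candidate tree per edge, with a DONOR leaf attached midway.

    Edges are identified by the label of their child node and enumerated
    in preorder; the root edge is excluded. The input tree is never
    modified.
    """
    newick = species_tree.as_string(schema="newick", suppress_rooting=True)
    candidates: list[tuple[str, dendropy.Tree]] = []
    edge_ids = [
        node_label(n)
        for n in species_tree.preorder_node_iter()
        if n.parent_node is not None
    ]
    for edge_id in edge_ids:
        grafted = read_tree(newick)
        child = find_node(grafted, edge_id)
        parent = child.parent_node
        parent.remove_child(child)
        joint = dendropy.Node()
        joint.label = f"graft_{edge_id}"
        parent.add_child(joint)
        joint.add_child(child)
        donor_taxon = grafted.taxon_namespace.require_taxon(DONOR_LABEL)
        joint.add_child(dendropy.Node(taxon=donor_taxon))
        candidates.append((edge_id, grafted))
    return candidates


@dataclass(frozen=True)
class PlacementResult:
    edge_scores: Mapping[str, int]  # aggregate dup+loss cost per graft edge
    per_tree_best: tuple[tuple[str, int, int], ...]  # (edge, dups, losses)
    best_edge: str | None
    verdict: str
    margin: int
    n_trees_used: int
    n_trees_skipped: int


def _auto_edge_ids(
    species_tree: dendropy.Tree, parthenogens: frozenset[str]
) -> frozenset[str]:
    """Edges whose graft reads as autopolyploidy.

    These are the edges inside (and at the crown of) the clade spanned by
    the parthenogen leaves: a donor placed there is indistinguishable from
    a within-lineage duplication. For a single parthenogen this is its
    terminal edge.
    """
    from .core_io import mrca

    crown = mrca(species_tree, sorted(parthenogens))
    labels = set()
    for node in crown.preorder_iter():
        labels.add(node_label(node))
    return frozenset(labels)


def score_placements(
    gene_trees: Sequence[dendropy.Tree],
    species_tree: dendropy.Tree,
    parthenogen_set: Sequence[str] | frozenset[str],
) -> PlacementResult:
    """Find the most parsimonious donor position for the extra gene copies.

    Extra copies (copy index >= 2 in a parthenogen species) from all
    parthenogens are mapped to a single DONOR leaf — the hypothesis of one
    polyploidisation event. Gene trees without extra copies are skipped
    with a warning. Ties between best edges of different verdict classes
    give an ``ambiguous`` verdict.
    """
    parthenogens = frozenset(parthenogen_set)
    candidates = graft_candidates(species_tree)
    edge_scores: dict[str, int] = {edge_id: 0 for edge_id, _ in candidates}
    per_tree_scores: list[dict[str, tuple[int, int]]] = []
    n_skipped = 0

    for gt in gene_trees:
        leaf_map: dict[str, str] = {}
        n_extra = 0
        for leaf in gt.leaf_node_iter():
            species, copy_index = parse_leaf_label(leaf.taxon.label)
            if species in parthenogens and copy_index >= 2:
                leaf_map[leaf.taxon.label] = DONOR_LABEL
                n_extra += 1
            else:
                leaf_map[leaf.taxon.label] = species
        if n_extra == 0:
            logger.warning("gene tree without extra parthenogen copies skipped")
            n_skipped += 1
            continue
        scores: dict[str, tuple[int, int]] = {}
        for edge_id, grafted in candidates:
            dups, losses = lca_reconcile(gt, grafted, leaf_map)
            scores[edge_id] = (dups, losses)
            edge_scores[edge_id] += dups + losses
        per_tree_scores.append(scores)

    if not per_tree_scores:
        return PlacementResult(
            edge_scores={}, per_tree_best=(), best_edge=None,
            verdict=VERDICT_AMBIGUOUS, margin=0,
            n_trees_used=0, n_trees_skipped=n_skipped,
        )

    per_tree_best = tuple(
        (lambda best: (best, *scores[best]))(
            min(scores, key=lambda e: (scores[e][0] + scores[e][1], e))
        )
        for scores in per_tree_scores
    )

    ordered = sorted(edge_scores.items(), key=lambda kv: (kv[1], kv[0]))
    best_edge, best_score = ordered[0]
    margin = (ordered[1][1] - best_score) if len(ordered) > 1 else 0

    auto_edges = _auto_edge_ids(species_tree, parthenogens)
    tied = [e for e, s in ordered if s == best_score]
    tied_classes = {
        VERDICT_AUTO if e in auto_edges else VERDICT_ALLO for e in tied
    }
    if len(tied_classes) > 1:
        verdict = VERDICT_AMBIGUOUS
    else:
        verdict = tied_classes.pop()
    return PlacementResult(
        edge_scores=edge_scores,
        per_tree_best=per_tree_best,
        best_edge=best_edge,
        verdict=verdict,
        margin=margin,
        n_trees_used=len(per_tree_scores),
        n_trees_skipped=n_skipped,
    )
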