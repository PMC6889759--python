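"""Independent brute-force oracles shared by the unit and acceptance tests.

Everything here is deliberately written from first principles (enumeration,
closed forms, exact combinatorics) and never calls the implementation
paths it is used to check.
"""

from __future__ import annotations

from itertools import combinations
from math import comb
from typing import Iterable, Sequence

# ---------------------------------------------------------------------------
# Tiny tuple-tree utilities: a tree is a leaf label (str) or a tuple of
# subtrees. Used by the Dollo and reconciliation oracles.
# ---------------------------------------------------------------------------

def tuple_tree_nodes(tree) -> list:
    """Postorder list of subtrees (each node identified by its subtree)."""
    out = []

    def walk(node):
        if isinstance(node, tuple):
            for child in node:
                walk(child)
        out.append(node)

    walk(tree)
    return out


def tuple_tree_leaves(tree) -> frozenset:
    if isinstance(tree, str):
        return frozenset([tree])
    out = frozenset()
    for child in tree:
        out |= tuple_tree_leaves(child)
    return out


def tuple_tree_edges(tree) -> list:
    """Edges as (parent subtree, child subtree) pairs."""
    edges = []

    def walk(node):
        if isinstance(node, tuple):
            for child in node:
                edges.append((node, child))
                walk(child)

    walk(tree)
    return edges


def to_newick(tree) -> str:
    if isinstance(tree, str):
        return tree
    return "(" + ",".join(to_newick(c) for c in tree) + ")"


# ---------------------------------------------------------------------------
# Dollo parsimony oracle: minimum loss count over all single-gain labelings
# ---------------------------------------------------------------------------

def dollo_min_losses(tree, present: frozenset) -> int:
    """Brute-force minimum number of loss edges for one gain, any gain node.

    Enumerates every node as gain candidate and every subset of edges below
    it as losses; a labeling is consistent when each present leaf descends
    from the gain with no loss on its path and each other leaf does not.
    """
    best = None
    for gain in tuple_tree_nodes(tree):
        gain_leaves = tuple_tree_leaves(gain)
        if not present <= gain_leaves:
            continue
        below = [e for e in tuple_tree_edges(gain)] if isinstance(gain, tuple) else []
        for r in range(len(below) + 1):
            if best is not None and r >= best:
                break
            for loss_set in combinations(below, r):
                lost_children = [child for _, child in loss_set]
                reached = set()
                for leaf in gain_leaves:
                    on_lost_path = any(
                        leaf in tuple_tree_leaves(c) for c in lost_children
                    )
                    if not on_lost_path:
                        reached.add(leaf)
                if reached == set(present):
                    best = r
                    break
            else:
                continue
            break
    assert best is not None, "no consistent Dollo labeling found"
    return best


# ---------------------------------------------------------------------------
# Duplication-loss reconciliation oracle over all valid mappings
# ---------------------------------------------------------------------------

class SpeciesIndexOracle:
    """Ancestor bookkeeping on a tuple species tree."""

    def __init__(self, tree):
        self.nodes = tuple_tree_nodes(tree)
        self.key = {id(n): i for i, n in enumerate(self.nodes)}
        # recompute by structural identity: map each subtree object once
        self.parent = {}
        self.depth = {}

        def walk(node, depth, parent):
            self.depth[self._k(node)] = depth
            self.parent[self._k(node)] = parent
            if isinstance(node, tuple):
                for child in node:
                    walk(child, depth + 1, self._k(node))

        self._keys = {}
        self._assign_keys(tree)
        walk(tree, 0, None)
        self.leaf_key = {
            n: self._k(n) for n in self.nodes if isinstance(n, str)
        }

    def _assign_keys(self, node):
        self._keys[id(node)] = len(self._keys)
        if isinstance(node, tuple):
            for child in node:
                self._assign_keys(child)

    def _k(self, node):
        return self._keys[id(node)]

    def ancestors_or_self(self, k):
        out = [k]
        while self.parent[k] is not None:
            k = self.parent[k]
            out.append(k)
        return out

    def lca(self, i, j):
        ai = set(self.ancestors_or_self(i))
        k = j
        while k not in ai:
            k = self.parent[k]
        return k


def reconcile_min_cost(gene_tree, species_tree, leaf_map) -> tuple[int, int, int]:
    """Exhaustive minimum of duplications + losses over valid mappings.

    A mapping assigns each internal gene node a species node that is an
    ancestor-or-self of the LCA of its children's images. Duplication:
    image equals a child's image. Losses: per child, skipped species edges
    minus one, plus one more under a duplication that does not reach the
    child's image. Returns (min_cost, dups, losses) of a cost-minimal map.
    """
    sp = SpeciesIndexOracle(species_tree)

    gene_internal = [
        n for n in tuple_tree_nodes(gene_tree) if isinstance(n, tuple)
    ]
    gene_children = {id(n): list(n) for n in gene_internal}

    best = [None]

    def assign(idx, images):
        if idx == len(gene_internal):
            dups = 0
            losses = 0
            for node in gene_internal:
                m = images[id(node)]
                child_images = [images[id(c)] if isinstance(c, tuple)
                                else sp.leaf_key[leaf_map[c]]
                                for c in gene_children[id(node)]]
                lca_children = child_images[0]
                for ci in child_images[1:]:
                    lca_children = sp.lca(lca_children, ci)
                # mapped above the children's LCA, both lineages descend
                # through one child of m: necessarily a duplication
                is_dup = m != lca_children or any(ci == m for ci in child_images)
                if is_dup:
                    dups += 1
                for ci in child_images:
                    d = sp.depth[ci] - sp.depth[m]
                    losses += max(d - 1, 0)
                    if is_dup and ci != m:
                        losses += 1
            cost = dups + losses
            if best[0] is None or cost < best[0][0]:
                best[0] = (cost, dups, losses)
            return
        node = gene_internal[idx]
        child_images = []
        ok = True
        for c in gene_children[id(node)]:
            if isinstance(c, tuple):
                if id(c) not in images:
                    ok = False
                    break
                child_images.append(images[id(c)])
            else:
                child_images.append(sp.leaf_key[leaf_map[c]])
        assert ok, "postorder violated"
        lca = child_images[0]
        for ci in child_images[1:]:
            lca = sp.lca(lca, ci)
        for m in sp.ancestors_or_self(lca):
            images[id(node)] = m
            assign(idx + 1, images)
        del images[id(node)]

    # order internal nodes postorder so children are assigned first
    assign(0, {})
    return best[0]


def all_binary_topologies(leaves: Sequence[str]):
    """All rooted binary tree shapes on an ordered leaf list (as tuples)."""
    if len(leaves) == 1:
        yield leaves[0]
        return
    first, rest = leaves[0], leaves[1:]
    n = len(rest)
    for mask in range(2 ** n):
        left = [first] + [rest[i] for i in range(n) if mask & (1 << i)]
        right = [rest[i] for i in range(n) if not mask & (1 << i)]
        if not right:
            continue
        for lt in all_binary_topologies(left):
            for rt in all_binary_topologies(right):
                yield (lt, rt)


# ---------------------------------------------------------------------------
# Exact two-sample KS p-value by label enumeration
# ---------------------------------------------------------------------------

def ks_exact_p(sample_a: Sequence[float], sample_b: Sequence[float]) -> float:
    """Permutation-exact KS p: share of label assignments with D >= observed."""

    def ks_d(xs, ys):
        points = sorted(set(xs) | set(ys))
        best = 0.0
        for t in points:
            fa = sum(1 for x in xs if x <= t) / len(xs)
            fb = sum(1 for y in ys if y <= t) / len(ys)
            best = max(best, abs(fa - fb))
        return best

    d_obs = ks_d(sample_a, sample_b)
    pooled = list(sample_a) + list(sample_b)
    n1 = len(sample_a)
    total = 0
    extreme = 0
    for labels in combinations(range(len(pooled)), n1):
        xs = [pooled[i] for i in labels]
        ys = [pooled[i] for i in range(len(pooled)) if i not in labels]
        total += 1
        if ks_d(xs, ys) >= d_obs - 1e-12:
            extreme += 1
    return extreme / total


# ---------------------------------------------------------------------------
# Exact one-sided Fisher p by hypergeometric tail summation
# ---------------------------------------------------------------------------

def fisher_greater_p(a: int, b: int, c: int, d: int) -> float:
    """P(X >= a) for X ~ Hypergeometric(N=a+b+c+d, K=a+b, n=a+c)."""
    N = a + b + c + d
    K = a + b
    n = a + c
    denom = comb(N, n)
    lo = max(0, n - (N - K))
    hi = min(K, n)
    return sum(comb(K, x) * comb(N - K, n - x) for x in range(a, hi + 1)) / denom
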