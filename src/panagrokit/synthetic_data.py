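"""Synthetic inputs with the statistical structure each stage assumes.

Every generator is a pure function of its spec (including the seed):
repeated calls give byte-identical output. The generators emulate

* read-count sampling at heterozygous sites under homozygous, diploid-
  heterozygous and triploid genotypes with symmetric sequencing error,
* best-hit tables mixing native genes, genuine horizontal transfers and
  contaminant sequences, together with the matching gene models and
  expression values,
* presence/absence matrices produced by a single gain plus independent
  edge losses on a species tree (the Dollo process),
* multi-copy gene trees under allo- vs autopolyploid scenarios with
  optional NNI topological noise,
* aligned sequence pairs at a designed Jukes-Cantor divergence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import dendropy
import numpy as np
import pandas as pd

from .core_io import (
    GeneModel,
    HitRecord,
    METAZOAN,
    NON_METAZOAN,
    VariantSite,
    ensure_internal_labels,
    find_node,
    node_label,
    read_tree,
)
from .hgt_ancestry import PresenceMatrix

PLOIDY_CLASSES = ("homozygous", "diploid_het", "triploid")

#: default study system: three parthenogenetic Panagrolaimus species, two
#: outcrossing congeners, and an outgroup.
DEFAULT_SPECIES_TREE = (
    "((((PS1159,PS1579)pp,DAW1)parth,(ES5,superbus)sex)panagro,JU765)root;"
)
DEFAULT_PARTHENOGENS = frozenset({"PS1159", "PS1579", "DAW1"})
#: edge above the clade containing both parthenogenetic and outcrossing
#: congeners — the donor position expected under a hybrid origin.
DEFAULT_DONOR_EDGE = "panagro"


# ---------------------------------------------------------------------------
# Variant-frequency simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PloidySimSpec:
    """Read-count sampling design at heterozygous (or error-only) sites.

    ``frac_two_thirds`` applies to the triploid class only: the fraction of
    divergent sites where the variant allele is carried by two of the three
    homeologous copies (the collapsed reference usually holds the majority
    allele, so most sites read at 1/3).
    """

    ploidy_class: str
    n_sites: int = 5000
    mean_depth: float = 50.0
    error_rate: float = 0.005
    frac_two_thirds: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ploidy_class not in PLOIDY_CLASSES:
            raise ValueError(
                f"ploidy_class must be one of {PLOIDY_CLASSES}, "
                f"got {self.ploidy_class!r}"
            )
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if not 0.0 <= self.error_rate <= 0.05:
            raise ValueError("error_rate must lie in [0, 0.05]")
        if not 0.0 <= self.frac_two_thirds <= 1.0:
            raise ValueError("frac_two_thirds must lie in [0, 1]")


def simulate_variants(spec: PloidySimSpec) -> list[VariantSite]:
    """Sample per-site allelic read counts under the given ploidy class.

    Site depth is Poisson(mean_depth) floored at 1; the alternative count
    is Binomial(depth, p') where p is 0 (homozygous), 1/2 (diploid
    heterozygote) or 1/3 vs 2/3 (triploid, the latter with probability
    ``frac_two_thirds``), blurred symmetrically by the error rate:
    p' = p(1-e) + (1-p)e.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_sites
    depth = np.maximum(rng.poisson(spec.mean_depth, size=n), 1)
    if spec.ploidy_class == "homozygous":
        p = np.zeros(n)
    elif spec.ploidy_class == "diploid_het":
        p = np.full(n, 0.5)
    else:
        two_thirds = rng.random(n) < spec.frac_two_thirds
        p = np.where(two_thirds, 2.0 / 3.0, 1.0 / 3.0)
    e = spec.error_rate
    p_eff = p * (1.0 - e) + (1.0 - p) * e
    alt = rng.binomial(depth, p_eff)
    ref = depth - alt
    # a site with zero reads of both alleles cannot occur (depth >= 1);
    # alt == depth leaves ref_count 0, a legal fixed-alternative site
    return [
        VariantSite("sim", i + 1, "A", "G", int(ref[i]), int(alt[i]))
        for i in range(n)
    ]


# ---------------------------------------------------------------------------
# HGT evidence simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HgtSimSpec:
    n_native: int = 10
    n_hgt: int = 5
    n_contaminant: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_native, self.n_hgt, self.n_contaminant) < 0:
            raise ValueError("class counts must be non-negative")


@dataclass(frozen=True)
class HgtFixture:
    """Joint output of the HGT evidence generator, plus the truth labels."""

    hits: tuple[HitRecord, ...]
    genes: tuple[GeneModel, ...]
    tpm: Mapping[str, float]
    pfam: Mapping[str, frozenset[str]]
    truth: Mapping[str, str]  # gene_id -> native | hgt | contaminant | anchor


def _exon_chain(start: int, n_exons: int) -> tuple[tuple[int, int], ...]:
    exons = []
    pos = start
    for _ in range(n_exons):
        exons.append((pos, pos + 199))
        pos += 400
    return tuple(exons)


def simulate_hit_evidence(spec: HgtSimSpec) -> HgtFixture:
    """Generate hit tables, gene models and expression for three gene classes.

    Native genes have a metazoan best hit far better than any non-metazoan
    one (AI < 0), introns and moderate expression. True transfers have a
    non-metazoan best hit at least e^30 better than the metazoan one
    (AI > 30), identity <= 70%, introns, strong expression (TPM > 100) and
    sit on contigs shared with metazoan-hitting genes — when no native
    genes are requested, dedicated anchor genes provide those neighbours.
    Contaminants have AI > 0, identity > 70%, no introns, no neighbours and
    near-zero expression.
    """
    rng = np.random.default_rng(spec.seed)
    hits: list[HitRecord] = []
    genes: list[GeneModel] = []
    tpm: dict[str, float] = {}
    pfam: dict[str, frozenset[str]] = {}
    truth: dict[str, str] = {}

    def add_native_like(gene_id: str, contig: str, offset: int, label: str) -> None:
        em_exp = rng.uniform(50, 120)  # best metazoan e-value 10^-em_exp
        en_exp = em_exp - rng.uniform(10, 40)  # non-metazoan hit much worse
        hits.append(
            HitRecord(gene_id, f"meta_subj_{gene_id}", METAZOAN,
                      10.0 ** -em_exp, rng.uniform(40, 70), 2 * em_exp)
        )
        if en_exp > 0:
            hits.append(
                HitRecord(gene_id, f"nonmeta_subj_{gene_id}", NON_METAZOAN,
                          10.0 ** -en_exp, rng.uniform(25, 55), 2 * en_exp)
            )
        genes.append(
            GeneModel(gene_id, contig, "+",
                      _exon_chain(offset, int(rng.integers(2, 6))))
        )
        tpm[gene_id] = float(rng.uniform(10, 200))
        pfam[gene_id] = frozenset({f"PF{10000 + int(rng.integers(0, 50)):05d}"})
        truth[gene_id] = label

    for i in range(spec.n_native):
        add_native_like(f"native_{i:03d}", f"ctg_{i:03d}", 1000, "native")

    for j in range(spec.n_hgt):
        gene_id = f"hgt_{j:03d}"
        if spec.n_native > 0:
            contig = f"ctg_{j % spec.n_native:03d}"
        else:
            contig = f"ctg_hgt_{j:03d}"
            add_native_like(f"anchor_{j:03d}", contig, 1000, "anchor")
        # exponents stay below the e^-200 AI floor so the designed e-value
        # gap (> e^30) survives the capped log transform
        en_exp = rng.uniform(45, 80)  # best non-metazoan e-value 10^-en_exp
        em_exp = en_exp - rng.uniform(15, 35)  # AI = gap * ln 10 > 30
        hits.append(
            HitRecord(gene_id, f"donor_subj_{gene_id}", NON_METAZOAN,
                      10.0 ** -en_exp, rng.uniform(35, 65), 2 * en_exp)
        )
        if em_exp > 0:
            hits.append(
                HitRecord(gene_id, f"meta_subj_{gene_id}", METAZOAN,
                          10.0 ** -em_exp, rng.uniform(25, 50), 2 * em_exp)
            )
        genes.append(
            GeneModel(gene_id, contig, "+",
                      _exon_chain(20000, int(rng.integers(2, 5))))
        )
        tpm[gene_id] = float(rng.uniform(150, 800))
        pfam[gene_id] = frozenset({f"PF{20000 + int(rng.integers(0, 30)):05d}"})
        truth[gene_id] = "hgt"

    for k in range(spec.n_contaminant):
        gene_id = f"contam_{k:03d}"
        contig = f"ctg_contam_{k:03d}"  # alone on its contig
        en_exp = rng.uniform(30, 80)
        hits.append(
            HitRecord(gene_id, f"bact_subj_{gene_id}", NON_METAZOAN,
                      10.0 ** -en_exp, rng.uniform(75, 95), 2 * en_exp)
        )
        genes.append(GeneModel(gene_id, contig, "+", _exon_chain(1000, 1)))
        tpm[gene_id] = float(rng.uniform(0, 5))
        truth[gene_id] = "contaminant"

    return HgtFixture(
        hits=tuple(hits), genes=tuple(genes), tpm=tpm, pfam=pfam, truth=truth
    )


# ---------------------------------------------------------------------------
# Presence/absence matrix simulation (Dollo process)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GainLossSimSpec:
    """Single-gain-plus-random-loss process on a fixed species tree."""

    species_tree: str = DEFAULT_SPECIES_TREE
    n_families: int = 200
    gain_node_weights: Mapping[str, float] | None = None  # None = uniform
    loss_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families < 1:
            raise ValueError("n_families must be >= 1")
        if not 0.0 <= self.loss_rate < 1.0:
            raise ValueError("loss_rate must lie in [0, 1)")


@dataclass(frozen=True)
class GainLossTruth:
    gain_node: Mapping[str, str]
    loss_edges: Mapping[str, frozenset[str]]  # child-node labels of lost edges


def simulate_presence_matrix(
    spec: GainLossSimSpec,
) -> tuple[PresenceMatrix, GainLossTruth]:
    """Simulate family presence by one gain and independent edge losses.

    Each family gains at a node drawn by weight (uniform by default over
    all nodes); every edge strictly below the gain node independently
    loses the family with ``loss_rate``; a leaf is present iff no loss
    occurred on its path from the gain node. Families absent from every
    leaf are re-drawn so the matrix satisfies the presence invariant.
    """
    tree = read_tree(spec.species_tree)
    nodes = list(tree.preorder_node_iter())
    labels = [node_label(n) for n in nodes]
    if spec.gain_node_weights is None:
        weights = np.ones(len(nodes))
    else:
        unknown = set(spec.gain_node_weights) - set(labels)
        if unknown:
            raise KeyError(f"unknown gain nodes in weights: {sorted(unknown)}")
        weights = np.array(
            [spec.gain_node_weights.get(l, 0.0) for l in labels], dtype=float
        )
        if weights.sum() <= 0:
            raise ValueError("gain node weights must sum to > 0")
    weights = weights / weights.sum()

    rng = np.random.default_rng(spec.seed)
    leaf_names = [l.taxon.label for l in tree.leaf_node_iter()]
    rows: dict[str, dict[str, bool]] = {}
    gain_of: dict[str, str] = {}
    losses_of: dict[str, frozenset[str]] = {}

    for i in range(spec.n_families):
        family = f"fam_{i:04d}"
        while True:
            gain = nodes[int(rng.choice(len(nodes), p=weights))]
            lost_edges: set[str] = set()
            present: dict[str, bool] = {name: False for name in leaf_names}

            def descend(node: dendropy.Node, alive: bool) -> None:
                if node.is_leaf():
                    present[node.taxon.label] = alive
                    return
                for child in node.child_nodes():
                    lost = bool(rng.random() < spec.loss_rate)
                    if lost:
                        lost_edges.add(node_label(child))
                    descend(child, alive and not lost)

            if gain.is_leaf():
                present[gain.taxon.label] = True
            else:
                descend(gain, True)
            if any(present.values()):
                break
        rows[family] = present
        gain_of[family] = node_label(gain)
        losses_of[family] = frozenset(lost_edges)

    matrix = PresenceMatrix(
        pd.DataFrame.from_dict(rows, orient="index")[leaf_names].astype(bool)
    )
    return matrix, GainLossTruth(gain_of, losses_of)


# ---------------------------------------------------------------------------
# Gene-tree simulation (allo vs auto polyploid origin)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OriginSimSpec:
    """Gene-tree generation design for the polyploid-origin test."""

    scenario: str  # "allo" | "auto"
    species_tree: str = DEFAULT_SPECIES_TREE
    parthenogens: frozenset[str] = DEFAULT_PARTHENOGENS
    donor_edge: str = DEFAULT_DONOR_EDGE  # used by the allo scenario
    n_trees: int = 100
    noise_nni: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in ("allo", "auto"):
            raise ValueError("scenario must be 'allo' or 'auto'")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.noise_nni < 0:
            raise ValueError("noise_nni must be >= 0")


def _induced_subtree_newick(
    tree: dendropy.Tree, keep: frozenset[str], suffix: str
) -> str:
    """Newick of the topology induced on ``keep`` leaves, labels suffixed."""

    def render(node: dendropy.Node) -> str | None:
        if node.is_leaf():
            if node.taxon.label in keep:
                return node.taxon.label + suffix
            return None
        parts = [p for p in (render(c) for c in node.child_nodes()) if p]
        if not parts:
            return None
        if len(parts) == 1:
            return parts[0]
        return "(" + ",".join(parts) + ")"

    rendered = render(tree.seed_node)
    if rendered is None:
        raise ValueError("no kept leaves in tree")
    return rendered


def _apply_nni(tree: dendropy.Tree, rng: np.random.Generator) -> None:
    """One random nearest-neighbour interchange on an internal edge."""
    candidates = [
        n for n in tree.preorder_node_iter()
        if n.parent_node is not None and not n.is_leaf()
    ]
    if not candidates:
        return
    v = candidates[int(rng.integers(len(candidates)))]
    parent = v.parent_node
    siblings = [x for x in parent.child_nodes() if x is not v]
    s = siblings[int(rng.integers(len(siblings)))]
    children = v.child_nodes()
    c = children[int(rng.integers(len(children)))]
    parent.remove_child(s)
    v.remove_child(c)
    parent.add_child(c)
    v.add_child(s)


def simulate_gene_trees(spec: OriginSimSpec) -> list[dendropy.Tree]:
    """Generate multi-copy gene trees under an allo- or autopolyploid origin.

    The base topology mirrors the species tree with leaves ``SP|copy1``.
    Each parthenogen contributes a second copy ``SP|copy2``: under ``auto``
    it attaches as sister to its own species' first copy; under ``allo``
    the second copies form a clade (mirroring the parthenogens' relative
    topology) grafted midway on the designated donor edge. ``noise_nni``
    random NNI moves then perturb each tree.
    """
    species_tree = read_tree(spec.species_tree)
    unknown = spec.parthenogens - set(
        l.taxon.label for l in species_tree.leaf_node_iter()
    )
    if unknown:
        raise KeyError(f"parthenogens not in species tree: {sorted(unknown)}")

    base = read_tree(spec.species_tree)
    for leaf in base.leaf_node_iter():
        leaf.taxon = base.taxon_namespace.require_taxon(
            leaf.taxon.label + "|copy1"
        )

    rng = np.random.default_rng(spec.seed)
    trees: list[dendropy.Tree] = []
    for _ in range(spec.n_trees):
        gt = read_tree(base.as_string(schema="newick", suppress_rooting=True))
        if spec.scenario == "auto":
            for parthenogen in sorted(spec.parthenogens):
                leaf = find_node(gt, parthenogen + "|copy1")
                parent = leaf.parent_node
                parent.remove_child(leaf)
                cherry = dendropy.Node()
                parent.add_child(cherry)
                cherry.add_child(leaf)
                extra = dendropy.Node(
                    taxon=gt.taxon_namespace.require_taxon(
                        parthenogen + "|copy2"
                    )
                )
                cherry.add_child(extra)
        else:
            donor_child_label = (
                spec.donor_edge + "|copy1"
                if find_leaf_safe(gt, spec.donor_edge + "|copy1")
                else spec.donor_edge
            )
            attach = find_node(gt, donor_child_label)
            parent = attach.parent_node
            if parent is None:
                raise ValueError(
                    f"donor edge {spec.donor_edge!r} is the root edge"
                )
            parent.remove_child(attach)
            joint = dendropy.Node()
            parent.add_child(joint)
            joint.add_child(attach)
            extra_clade = dendropy.Tree.get(
                data=_induced_subtree_newick(
                    species_tree, spec.parthenogens, "|copy2"
                ) + ";",
                schema="newick",
                preserve_underscores=True,
                taxon_namespace=gt.taxon_namespace,
            )
            joint.add_child(extra_clade.seed_node)
        for _ in range(spec.noise_nni):
            _apply_nni(gt, rng)
        ensure_internal_labels(gt)
        trees.append(gt)
    return trees


def find_leaf_safe(tree: dendropy.Tree, label: str) -> bool:
    return any(l.taxon.label == label for l in tree.leaf_node_iter())


# ---------------------------------------------------------------------------
# Aligned sequence pairs at designed divergence
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def simulate_aligned_pair(
    length: int, jc_distance: float, seed: int = 0
) -> tuple[str, str]:
    """Two aligned sequences at a designed Jukes-Cantor distance.

    The expected mismatch fraction is p = (3/4)(1 - exp(-4d/3)); each site
    of the copy mutates to one of the three other bases with probability p.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if jc_distance < 0:
        raise ValueError("distance must be non-negative")
    rng = np.random.default_rng(seed)
    p = 0.75 * (1.0 - math.exp(-4.0 * jc_distance / 3.0))
    seq_a = rng.integers(0, 4, size=length)
    mutate = rng.random(length) < p
    shift = rng.integers(1, 4, size=length)
    seq_b = np.where(mutate, (seq_a + shift) % 4, seq_a)
    return "".join(_BASES[seq_a]), "".join(_BASES[seq_b])
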