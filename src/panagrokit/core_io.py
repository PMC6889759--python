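"""Readers and writers for the standard formats every pipeline stage touches.

Variant tables arrive as VCF 4.x (per-sample allelic depths in the ``AD``
FORMAT field) or as plain TSV; best-hit tables as BLAST ``outfmt 6``-like
TSV partitioned into metazoan vs non-metazoan subjects; gene models as
GFF3; trees as Newick. Coordinates are 1-based inclusive on I/O, matching
the VCF/GFF3 conventions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy

logger = logging.getLogger("panagrokit")

METAZOAN = "metazoan"
NON_METAZOAN = "non_metazoan"
EXCLUDED = "excluded"

_VALID_PARTITIONS = frozenset({METAZOAN, NON_METAZOAN})

#: column order of BLAST tabular output (outfmt 6); a 13th column may carry
#: either a subject taxon id or a partition label directly.
OUTFMT6_COLUMNS = (
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
)


@dataclass(frozen=True)
class VariantSite:
    """A biallelic SNV with raw per-allele read depths."""

    contig: str
    pos: int
    ref_allele: str
    alt_allele: str
    ref_count: int
    alt_count: int

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref_count < 0 or self.alt_count < 0:
            raise ValueError("allele depths must be non-negative")
        if self.ref_count + self.alt_count < 1:
            raise ValueError("total depth must be >= 1")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")

    @property
    def depth(self) -> int:
        return self.ref_count + self.alt_count

    @property
    def alt_fraction(self) -> float:
        return self.alt_count / self.depth


@dataclass(frozen=True)
class HitRecord:
    """One database hit of a query gene, tagged with its taxon partition."""

    query_id: str
    subject_id: str
    taxon_partition: str
    evalue: float
    percent_identity: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"evalue must be >= 0, got {self.evalue}")
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError("percent_identity must lie in [0, 100]")
        if self.taxon_partition not in _VALID_PARTITIONS:
            raise ValueError(
                f"taxon_partition must be one of {sorted(_VALID_PARTITIONS)}, "
                f"got {self.taxon_partition!r}"
            )


@dataclass(frozen=True)
class GeneModel:
    """A gene with its exon structure; intron count is n_exons - 1."""

    gene_id: str
    contig: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"gene {self.gene_id} has no exons")
        prev_end = 0
        for start, end in self.exons:
            if start > end:
                raise ValueError(
                    f"gene {self.gene_id}: exon ({start},{end}) start > end"
                )
            if start <= prev_end:
                raise ValueError(
                    f"gene {self.gene_id}: exons overlap or are unsorted"
                )
            prev_end = end

    @property
    def intron_count(self) -> int:
        return len(self.exons) - 1

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


# ---------------------------------------------------------------------------
# Variant tables
# ---------------------------------------------------------------------------

VARIANT_TSV_COLUMNS = ("contig", "pos", "ref", "alt", "ref_count", "alt_count")


def read_variant_table(
    path: str | Path,
    format: str = "tsv",
    min_depth: int = 1,
) -> list[VariantSite]:
    """Read biallelic SNVs with total read depth >= ``min_depth``.

    ``format='vcf'`` takes allelic depths from the AD field of the first
    sample (raw read evidence, independent of the caller's AF); records
    without AD are skipped with a warning. Triallelic sites and indels are
    excluded in both formats, since frequency semantics assume a single
    alternative allele. Input order is preserved.
    """
    path = Path(path)
    if format == "tsv":
        return _read_variant_tsv(path, min_depth)
    if format == "vcf":
        return _read_variant_vcf(path, min_depth)
    raise ValueError(f"unknown variant table format: {format!r}")


def _read_variant_tsv(path: Path, min_depth: int) -> list[VariantSite]:
    sites: list[VariantSite] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != VARIANT_TSV_COLUMNS:
            raise ValueError(
                f"{path}: line 1: expected header {VARIANT_TSV_COLUMNS}, "
                f"got {tuple(header)}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(VARIANT_TSV_COLUMNS):
                raise ValueError(
                    f"{path}: line {lineno}: expected "
                    f"{len(VARIANT_TSV_COLUMNS)} columns, got {len(fields)}"
                )
            try:
                contig, pos, ref, alt = fields[0], int(fields[1]), fields[2], fields[3]
                ref_count, alt_count = int(fields[4]), int(fields[5])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
            if len(ref) != 1 or len(alt) != 1:
                continue  # indel or multi-nucleotide record
            if ref_count + alt_count < min_depth:
                continue
            sites.append(VariantSite(contig, pos, ref, alt, ref_count, alt_count))
    return sites


def _read_variant_vcf(path: Path, min_depth: int) -> list[VariantSite]:
    from cyvcf2 import VCF

    sites: list[VariantSite] = []
    vcf = VCF(str(path))
    for rec in vcf:
        if len(rec.ALT) != 1:
            continue  # triallelic
        ref, alt = rec.REF, rec.ALT[0]
        if len(ref) != 1 or len(alt) != 1:
            continue  # indel
        ad = rec.format("AD")
        if ad is None:
            logger.warning(
                "%s: record %s:%d has no AD field; skipped", path, rec.CHROM, rec.POS
            )
            continue
        ref_count, alt_count = int(ad[0][0]), int(ad[0][1])
        if ref_count < 0 or alt_count < 0:  # cyvcf2 encodes missing AD as < 0
            logger.warning(
                "%s: record %s:%d has missing AD values; skipped",
                path, rec.CHROM, rec.POS,
            )
            continue
        if ref_count + alt_count < min_depth:
            continue
        sites.append(VariantSite(rec.CHROM, rec.POS, ref, alt, ref_count, alt_count))
    return sites


def write_variant_table(sites: Iterable[VariantSite], path: str | Path) -> None:
    """Write variants as TSV readable by :func:`read_variant_table`."""
    with open(path, "w") as fh:
        fh.write("\t".join(VARIANT_TSV_COLUMNS) + "\n")
        for s in sites:
            fh.write(
                f"{s.contig}\t{s.pos}\t{s.ref_allele}\t{s.alt_allele}"
                f"\t{s.ref_count}\t{s.alt_count}\n"
            )


# ---------------------------------------------------------------------------
# Best-hit tables
# ---------------------------------------------------------------------------

def read_hit_table(
    path: str | Path,
    partition_map: Mapping[str, str] | None = None,
) -> list[HitRecord]:
    """Read a BLAST outfmt-6-like TSV into partition-tagged hit records.

    The subject taxon is taken from the 13th column when present, else from
    the subject id. ``partition_map`` assigns each taxon to ``metazoan``,
    ``non_metazoan`` or ``excluded`` (self-hits / skip set); hits to
    excluded taxa are dropped. When the 13th column already carries a
    partition label no map is needed. Unmapped taxa raise an error listing
    the offending ids, so silent misclassification is impossible.
    """
    path = Path(path)
    records: list[HitRecord] = []
    unmapped: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ValueError(
                    f"{path}: line {lineno}: expected >= 12 columns, got {len(fields)}"
                )
            try:
                qseqid, sseqid = fields[0], fields[1]
                pident = float(fields[2])
                evalue = float(fields[10])
                bitscore = float(fields[11])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
            taxon_key = fields[12] if len(fields) >= 13 else sseqid
            if taxon_key in _VALID_PARTITIONS or taxon_key == EXCLUDED:
                partition = taxon_key
            elif partition_map is not None and taxon_key in partition_map:
                partition = partition_map[taxon_key]
            else:
                unmapped.add(taxon_key)
                continue
            if partition == EXCLUDED:
                continue
            records.append(
                HitRecord(qseqid, sseqid, partition, evalue, pident, bitscore)
            )
    if unmapped:
        raise ValueError(
            f"{path}: taxa without partition assignment: {sorted(unmapped)}"
        )
    return records


def write_hit_table(hits: Iterable[HitRecord], path: str | Path) -> None:
    """Write hits as 13-column outfmt-6-like TSV (partition in column 13).

    Alignment coordinate columns not carried by :class:`HitRecord` are
    written as zeros; they are ignored on re-read.
    """
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.percent_identity}\t0\t0\t0"
                f"\t0\t0\t0\t0\t{h.evalue:g}\t{h.bitscore}\t{h.taxon_partition}\n"
            )


# ---------------------------------------------------------------------------
# Gene models (GFF3)
# ---------------------------------------------------------------------------

def read_gene_models(path_gff3: str | Path) -> list[GeneModel]:
    """Read GFF3 gene/mRNA/exon features into :class:`GeneModel` records.

    For multi-isoform genes the isoform with the most exons represents the
    gene (intron presence is what downstream screens consume). Coordinates
    stay 1-based inclusive. An exon whose Parent cannot be resolved is an
    error.
    """
    import gffutils

    db = gffutils.create_db(
        str(path_gff3), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    known_ids = {f.id for f in db.all_features()}
    for exon in db.features_of_type("exon"):
        for parent_id in exon.attributes.get("Parent", []):
            if parent_id not in known_ids:
                raise ValueError(
                    f"{path_gff3}: exon at {exon.seqid}:{exon.start}-{exon.end} "
                    f"has unresolvable Parent {parent_id!r}"
                )

    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        best_exons: list[tuple[int, int]] = []
        for mrna in db.children(gene, featuretype="mRNA"):
            exons = sorted(
                (e.start, e.end) for e in db.children(mrna, featuretype="exon")
            )
            if len(exons) > len(best_exons):
                best_exons = exons
        if not best_exons:  # exons attached directly to the gene
            best_exons = sorted(
                (e.start, e.end) for e in db.children(gene, featuretype="exon")
            )
        if not best_exons:
            logger.warning("gene %s has no exons; skipped", gene.id)
            continue
        genes.append(
            GeneModel(gene.id, gene.seqid, gene.strand or ".", tuple(best_exons))
        )
    return genes


def write_gene_models(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models as minimal GFF3 (gene, mRNA, exon features)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            lo, hi = g.span
            fh.write(
                f"{g.contig}\tpanagrokit\tgene\t{lo}\t{hi}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            mrna_id = f"{g.gene_id}.t1"
            fh.write(
                f"{g.contig}\tpanagrokit\tmRNA\t{lo}\t{hi}\t.\t{g.strand}\t.\t"
                f"ID={mrna_id};Parent={g.gene_id}\n"
            )
            for i, (start, end) in enumerate(g.exons, start=1):
                fh.write(
                    f"{g.contig}\tpanagrokit\texon\t{start}\t{end}\t.\t{g.strand}"
                    f"\t.\tID={mrna_id}.exon{i};Parent={mrna_id}\n"
                )


# ---------------------------------------------------------------------------
# Expression tables
# ---------------------------------------------------------------------------

def read_expression_table(path: str | Path) -> dict[str, float]:
    """Read a two-column ``gene_id<TAB>tpm`` table (header optional)."""
    tpm: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 columns")
            if lineno == 1 and fields[0].lower() in {"gene_id", "gene", "id"}:
                continue
            tpm[fields[0]] = float(fields[1])
    return tpm


def write_expression_table(tpm: Mapping[str, float], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\ttpm\n")
        for gene_id, value in tpm.items():
            fh.write(f"{gene_id}\t{value:g}\n")


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

def read_tree(source: str | Path) -> dendropy.Tree:
    """Read a rooted Newick tree, keeping underscores, and label internals.

    Internal nodes without a label are auto-named ``n<postorder index>``
    deterministically so gains/losses and graft edges can be reported by
    node id.
    """
    if isinstance(source, Path) or (
        isinstance(source, str) and "(" not in source
    ):
        tree = dendropy.Tree.get(
            path=str(source), schema="newick", preserve_underscores=True,
        )
    else:
        tree = dendropy.Tree.get(
            data=source, schema="newick", preserve_underscores=True,
        )
    tree.is_rooted = True
    ensure_internal_labels(tree)
    return tree


def ensure_internal_labels(tree: dendropy.Tree) -> dendropy.Tree:
    """Assign deterministic ``n<i>`` labels to unlabeled internal nodes."""
    seen = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    for i, node in enumerate(tree.postorder_node_iter()):
        if node.is_leaf():
            continue
        if not node.label or node.label in seen:
            label = f"n{i}"
            while label in seen:
                label = "n" + label
            node.label = label
        seen.add(node.label)
    return tree


def node_label(node: dendropy.Node) -> str:
    """Canonical label of a node: taxon label for leaves, node label inside."""
    if node.is_leaf():
        return node.taxon.label
    return node.label


def find_node(tree: dendropy.Tree, label: str) -> dendropy.Node:
    for node in tree.preorder_node_iter():
        if node_label(node) == label:
            return node
    raise KeyError(f"no node labeled {label!r} in tree")


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def mrca(tree: dendropy.Tree, labels: Sequence[str]) -> dendropy.Node:
    """Most recent common ancestor of the named leaves."""
    known = set(leaf_labels(tree))
    missing = set(labels) - known
    if missing:
        raise KeyError(f"unknown leaves: {sorted(missing)}")
    if len(set(labels)) == 1:
        return find_node(tree, next(iter(labels)))
    node = tree.mrca(taxon_labels=list(set(labels)))
    if node is None:  # pragma: no cover - defensive
        raise RuntimeError("MRCA lookup failed")
    return node


# ---------------------------------------------------------------------------
# Flat config files
# ---------------------------------------------------------------------------

def load_config(path: str | Path) -> dict[str, str]:
    """Parse a flat ``key = value`` config file (TOML-style scalars).

    Quotes around values are stripped; sections and nesting are not
    supported — each key mirrors a CLI flag.
    """
    config: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("["):
                continue
            if "=" not in line:
                raise ValueError(f"{path}: line {lineno}: expected key = value")
            key, _, value = line.partition("=")
            config[key.strip()] = value.strip().strip("\"'")
    return config


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
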