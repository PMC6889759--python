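"""Alien-Index screening for horizontally transferred genes.

The Alien Index (AI) of a gene compares its best metazoan database hit
against its best non-metazoan one on a log e-value scale:

    AI = ln(E_metazoan + e^-200) - ln(E_non_metazoan + e^-200)

with missing hits encoded as e-value 1 and e-values capped into [0, 1].
AI > 0 means the non-metazoan hit is better (a possible horizontal
acquisition); AI > 30 corresponds to roughly an e^30 e-value gap and marks
strong candidates. Candidates whose best non-metazoan hit exceeds 70%
identity are flagged as likely contaminant sequences rather than anciently
integrated transfers. Genomic-integration evidence (spliceosomal introns,
metazoan-hitting neighbours on the same contig, RNA-seq expression) then
tiers the surviving candidates; those with introns and TPM > 100 are the
most reliable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .core_io import METAZOAN, NON_METAZOAN, GeneModel, HitRecord

logger = logging.getLogger("panagrokit")

STATUS_NOT_CANDIDATE = "not_candidate"
STATUS_CONTAMINANT = "contaminant"
STATUS_AI0 = "candidate_ai0"
STATUS_AI30 = "candidate_ai30"
STATUS_HIGH = "high_confidence"


@dataclass(frozen=True)
class ScreenThresholds:
    """Cut-offs of the candidate / contamination / confidence screens."""

    ai_candidate: float = 0.0
    ai_strong: float = 30.0
    contaminant_identity: float = 70.0  # percent
    tpm_tiers: tuple[float, ...] = (10.0, 100.0, 1000.0)
    evalue_floor_exponent: float = 200.0
    missing_hit_evalue: float = 1.0


DEFAULT_THRESHOLDS = ScreenThresholds()


@dataclass(frozen=True)
class AlienIndexRecord:
    gene_id: str
    best_meta_evalue: float
    best_nonmeta_evalue: float
    ai: float
    best_nonmeta_identity: float | None
    donor_hint: str | None


@dataclass(frozen=True)
class HgtEvidence:
    gene_id: str
    intron_count: int
    on_multigene_contig: bool
    has_metazoan_neighbor: bool
    tpm: float
    pfam_domains: frozenset[str] = frozenset()


@dataclass(frozen=True)
class HgtClassification:
    gene_id: str
    status: str
    tier_reasons: tuple[str, ...]


def alien_index(
    best_meta_evalue: float,
    best_nonmeta_evalue: float,
    thresholds: ScreenThresholds = DEFAULT_THRESHOLDS,
) -> float:
    """AI = ln(E_meta + floor) - ln(E_nonmeta + floor), floor = e^-200.

    E-values above 1 are capped to 1, bounding |AI| by 200 + ln 2. Positive
    AI means the best non-metazoan hit beats the best metazoan hit.
    """
    if best_meta_evalue < 0 or best_nonmeta_evalue < 0:
        raise ValueError("e-values must be non-negative")
    floor = math.exp(-thresholds.evalue_floor_exponent)
    em = min(best_meta_evalue, 1.0)
    en = min(best_nonmeta_evalue, 1.0)
    return math.log(em + floor) - math.log(en + floor)


def _best_hit(hits: Sequence[HitRecord]) -> HitRecord | None:
    """Lowest e-value; ties broken by highest bitscore, then subject id."""
    if not hits:
        return None
    return min(hits, key=lambda h: (h.evalue, -h.bitscore, h.subject_id))


def summarize_hits(
    hits: Iterable[HitRecord],
    thresholds: ScreenThresholds = DEFAULT_THRESHOLDS,
) -> list[AlienIndexRecord]:
    """Reduce a partitioned hit table to one Alien-Index record per query.

    Per query the best hit of each partition is selected; a partition with
    no hit contributes the missing-hit e-value (1). The identity and donor
    hint come from the best non-metazoan hit. Output is sorted by query id
    for determinism.
    """
    by_query: dict[str, dict[str, list[HitRecord]]] = {}
    for hit in hits:
        by_query.setdefault(hit.query_id, {METAZOAN: [], NON_METAZOAN: []})[
            hit.taxon_partition
        ].append(hit)

    records: list[AlienIndexRecord] = []
    for query_id in sorted(by_query):
        best_meta = _best_hit(by_query[query_id][METAZOAN])
        best_non = _best_hit(by_query[query_id][NON_METAZOAN])
        em = best_meta.evalue if best_meta else thresholds.missing_hit_evalue
        en = best_non.evalue if best_non else thresholds.missing_hit_evalue
        records.append(
            AlienIndexRecord(
                gene_id=query_id,
                best_meta_evalue=em,
                best_nonmeta_evalue=en,
                ai=alien_index(em, en, thresholds),
                best_nonmeta_identity=(
                    best_non.percent_identity if best_non else None
                ),
                donor_hint=best_non.subject_id if best_non else None,
            )
        )
    return records


def collect_evidence(
    genes: Sequence[GeneModel],
    ai_records: Sequence[AlienIndexRecord],
    expression: Mapping[str, float],
    pfam: Mapping[str, Iterable[str]] | None = None,
) -> list[HgtEvidence]:
    """Assemble genomic-integration evidence for every AI record.

    ``on_multigene_contig`` is true when at least two annotated genes share
    the contig. ``has_metazoan_neighbor`` is true when some *other* gene on
    the same contig has AI < 0, i.e. its best hit is metazoan — the
    operational reading of "neighbours hitting Metazoa". Genes absent from
    the expression table get TPM 0; genes absent from the annotation get
    default evidence and a warning.
    """
    gene_by_id = {g.gene_id: g for g in genes}
    ai_by_id = {r.gene_id: r for r in ai_records}
    contig_members: dict[str, list[str]] = {}
    for g in genes:
        contig_members.setdefault(g.contig, []).append(g.gene_id)

    evidence: list[HgtEvidence] = []
    for record in ai_records:
        gene = gene_by_id.get(record.gene_id)
        domains = frozenset(pfam.get(record.gene_id, ())) if pfam else frozenset()
        tpm = float(expression.get(record.gene_id, 0.0))
        if gene is None:
            logger.warning(
                "gene %s has hits but no annotation; default evidence used",
                record.gene_id,
            )
            evidence.append(
                HgtEvidence(record.gene_id, 0, False, False, tpm, domains)
            )
            continue
        neighbors = [
            other for other in contig_members[gene.contig]
            if other != record.gene_id
        ]
        has_meta_neighbor = any(
            ai_by_id[n].ai < 0 for n in neighbors if n in ai_by_id
        )
        evidence.append(
            HgtEvidence(
                gene_id=record.gene_id,
                intron_count=gene.intron_count,
                on_multigene_contig=len(neighbors) > 0,
                has_metazoan_neighbor=has_meta_neighbor,
                tpm=tpm,
                pfam_domains=domains,
            )
        )
    return evidence


def classify_candidates(
    ai_records: Sequence[AlienIndexRecord],
    evidence: Sequence[HgtEvidence],
    thresholds: ScreenThresholds = DEFAULT_THRESHOLDS,
) -> list[HgtClassification]:
    """Tier genes through the candidate / contaminant / confidence cascade.

    AI <= 0: not a candidate. AI > 0 with best non-metazoan identity above
    the contaminant cut-off (70%): contaminant — the identity rule wins
    over any integration evidence, and the reasons trail records what else
    was seen. Otherwise AI > 30 with at least one intron and TPM > 100 is
    high confidence; AI > 30 alone is a strong candidate; residual AI > 0
    genes are weak candidates.
    """
    ev_by_id = {e.gene_id: e for e in evidence}
    out: list[HgtClassification] = []
    for record in ai_records:
        ev = ev_by_id.get(record.gene_id)
        if ev is None:
            raise ValueError(f"no evidence record for gene {record.gene_id}")
        reasons: list[str] = []
        if record.ai <= thresholds.ai_candidate:
            out.append(HgtClassification(record.gene_id, STATUS_NOT_CANDIDATE, ()))
            continue
        reasons.append(f"ai>{thresholds.ai_candidate:g}")
        identity = record.best_nonmeta_identity
        if identity is not None and identity > thresholds.contaminant_identity:
            reasons.append(f"identity>{thresholds.contaminant_identity:g}")
            if ev.intron_count >= 1:
                reasons.append("has_introns_despite_identity")
            out.append(
                HgtClassification(record.gene_id, STATUS_CONTAMINANT, tuple(reasons))
            )
            continue
        if record.ai > thresholds.ai_strong:
            reasons.append(f"ai>{thresholds.ai_strong:g}")
            if ev.intron_count >= 1 and ev.tpm > thresholds.tpm_tiers[1]:
                reasons.extend(["introns", f"tpm>{thresholds.tpm_tiers[1]:g}"])
                status = STATUS_HIGH
            else:
                status = STATUS_AI30
        else:
            status = STATUS_AI0
        out.append(HgtClassification(record.gene_id, status, tuple(reasons)))
    return out


def tier_report(
    classifications: Sequence[HgtClassification],
    evidence: Sequence[HgtEvidence],
    tpm_tiers: tuple[float, ...] = DEFAULT_THRESHOLDS.tpm_tiers,
) -> pd.Series:
    """Per-species summary counts in the style of an HGT screen table.

    Candidate feature counts (contig sharing, metazoan neighbours, introns,
    expression tiers, Pfam) are tallied over the strong candidates
    (AI > 30, contaminants excluded), the set the evidence screens target.
    """
    ev_by_id = {e.gene_id: e for e in evidence}
    status = {c.gene_id: c.status for c in classifications}
    ai_pos = [g for g, s in status.items() if s != STATUS_NOT_CANDIDATE]
    contaminants = [g for g, s in status.items() if s == STATUS_CONTAMINANT]
    strong = [g for g, s in status.items() if s in (STATUS_AI30, STATUS_HIGH)]
    strong_ev = [ev_by_id[g] for g in strong if g in ev_by_id]

    counts: dict[str, int] = {
        "possible_candidates_ai0": len(ai_pos),
        "contaminants": len(contaminants),
        "candidates_ai30": len(strong),
        "high_confidence": sum(
            1 for g, s in status.items() if s == STATUS_HIGH
        ),
        "on_multigene_contig": sum(1 for e in strong_ev if e.on_multigene_contig),
        "with_metazoan_neighbor": sum(
            1 for e in strong_ev if e.has_metazoan_neighbor
        ),
        "with_introns": sum(1 for e in strong_ev if e.intron_count >= 1),
    }
    for tier in tpm_tiers:
        counts[f"tpm_gt_{tier:g}"] = sum(1 for e in strong_ev if e.tpm > tier)
    with_pfam = [e for e in strong_ev if e.pfam_domains]
    counts["with_pfam_domains"] = len(with_pfam)
    counts["total_pfam_annotations"] = sum(len(e.pfam_domains) for e in with_pfam)
    distinct: set[str] = set()
    for e in with_pfam:
        distinct |= e.pfam_domains
    counts["distinct_pfam_domains"] = len(distinct)
    return pd.Series(counts, name="count")


def classifications_to_frame(
    ai_records: Sequence[AlienIndexRecord],
    evidence: Sequence[HgtEvidence],
    classifications: Sequence[HgtClassification],
) -> pd.DataFrame:
    """Join AI, evidence and status into one per-gene table for output."""
    ai_by_id = {r.gene_id: r for r in ai_records}
    ev_by_id = {e.gene_id: e for e in evidence}
    rows = []
    for c in classifications:
        r, e = ai_by_id[c.gene_id], ev_by_id[c.gene_id]
        rows.append(
            {
                "gene_id": c.gene_id,
                "ai": r.ai,
                "best_meta_evalue": r.best_meta_evalue,
                "best_nonmeta_evalue": r.best_nonmeta_evalue,
                "best_nonmeta_identity": r.best_nonmeta_identity,
                "donor_hint": r.donor_hint,
                "intron_count": e.intron_count,
                "on_multigene_contig": e.on_multigene_contig,
                "has_metazoan_neighbor": e.has_metazoan_neighbor,
                "tpm": e.tpm,
                "status": c.status,
                "tier_reasons": ";".join(c.tier_reasons),
            }
        )
    return pd.DataFrame(rows)
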