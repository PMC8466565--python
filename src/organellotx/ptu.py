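"""Polycistronic transcription unit (PTU) inference from multi-gene
transcripts.

A transcript nominates a candidate PTU when it fully covers the exonic
length of two or more same-strand genes (``coverage_fraction`` of exonic
bases, default 1.0).  Candidates are merged by transitive closure under
"same strand and (shared gene or overlapping genomic span)"; the merged gene
list is the position-ordered union.  Transcripts that join the segments of a
trans-spliced gene to neighbouring genes are products of trans-splicing, not
read-through transcription, and are flagged and excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .model import (GeneModel, GeneType, SpliceClass, TranscriptAlignment)
from .splicing import detect_trans_splicing


@dataclass
class PTU:
    ptu_id: str
    strand: str
    gene_ids: list[str]
    span: tuple[int, int]
    supporting_transcripts: list[str]
    partial_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.gene_ids) < 2:
            raise ValueError(f"{self.ptu_id}: a PTU needs >= 2 genes")


def _exonic_coverage(aln: TranscriptAlignment, gene: GeneModel) -> float:
    covered = 0
    for exon in gene.exons:
        for bs, be in aln.blocks:
            covered += max(0, min(be, exon.end) - max(bs, exon.start))
    return covered / gene.exonic_length


def candidate_ptus(alignments: Iterable[TranscriptAlignment],
                   genes: Sequence[GeneModel],
                   coverage_fraction: float = 1.0,
                   partial_fraction: float = 0.5,
                   ) -> tuple[list[PTU], list[str]]:
    """Per-transcript candidate PTUs plus the ids of transcripts excluded
    because they join trans-spliced gene segments to downstream genes."""
    if not 0.0 < coverage_fraction <= 1.0:
        raise ValueError("coverage_fraction must be in (0, 1]")
    candidates: list[PTU] = []
    excluded: list[str] = []
    for aln in alignments:
        full, partial = [], []
        for gene in genes:
            if gene.strand != aln.strand:
                continue
            frac = _exonic_coverage(aln, gene)
            if frac >= coverage_fraction:
                full.append(gene)
            elif frac >= partial_fraction:
                partial.append(gene)
        if len(full) < 2:
            continue
        trans_joined = any(
            detect_trans_splicing(aln, gene)
            for gene in full
            if any(i.splice_class is SpliceClass.TRANS for i in gene.introns))
        if trans_joined:
            excluded.append(aln.transcript_id)
            continue
        ordered = sorted(full, key=lambda g: g.span[0],
                         reverse=(aln.strand == "-"))
        span = (min(g.span[0] for g in full), max(g.span[1] for g in full))
        candidates.append(PTU(
            ptu_id=f"cand_{aln.transcript_id}", strand=aln.strand,
            gene_ids=[g.gene_id for g in ordered], span=span,
            supporting_transcripts=[aln.transcript_id],
            partial_genes=[g.gene_id for g in partial]))
    return candidates, excluded


def merge_ptus(candidates: Sequence[PTU],
               genes: Sequence[GeneModel]) -> list[PTU]:
    """Transitive closure under same strand and (shared gene or span
    overlap); idempotent and input-order invariant."""
    if not candidates:
        return []
    n = len(candidates)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        parent[find(i)] = find(j)

    def linked(a: PTU, b: PTU) -> bool:
        if a.strand != b.strand:
            return False
        if set(a.gene_ids) & set(b.gene_ids):
            return True
        return a.span[0] < b.span[1] and b.span[0] < a.span[1]

    for i in range(n):
        for j in range(i + 1, n):
            if linked(candidates[i], candidates[j]):
                union(i, j)

    groups: dict[int, list[PTU]] = {}
    for i, cand in enumerate(candidates):
        groups.setdefault(find(i), []).append(cand)
    gene_by_id = {g.gene_id: g for g in genes}
    merged = []
    for members in groups.values():
        strand = members[0].strand
        gene_ids = sorted({g for m in members for g in m.gene_ids},
                          key=lambda gid: gene_by_id[gid].span[0],
                          reverse=(strand == "-"))
        span = (min(m.span[0] for m in members),
                max(m.span[1] for m in members))
        support = sorted({t for m in members
                          for t in m.supporting_transcripts})
        partial = sorted({g for m in members for g in m.partial_genes}
                         - set(gene_ids))
        merged.append(PTU("", strand, gene_ids, span, support, partial))
    merged.sort(key=lambda p: p.span[0])
    for k, p in enumerate(merged):
        p.ptu_id = f"PTU{k + 1}"
    return merged


def postulate_operons(ptus: Sequence[PTU]) -> list[dict]:
    """Each merged PTU (all members share a transcription direction by
    construction) is postulated as one operon."""
    return [{"operon_id": f"operon_{p.ptu_id}", "strand": p.strand,
             "gene_ids": list(p.gene_ids), "n_genes": len(p.gene_ids)}
            for p in ptus]


def cotranscription_stats(ptus: Sequence[PTU],
                          genes: Sequence[GeneModel]) -> dict:
    """Fraction of protein-coding genes found in any PTU.  tRNA/rRNA genes
    can be PTU members but are excluded from the denominator; partial
    members are listed, not counted."""
    protein = {g.gene_id for g in genes if g.gene_type is GeneType.PROTEIN}
    in_ptu = {gid for p in ptus for gid in p.gene_ids} & protein
    fraction = len(in_ptu) / len(protein) if protein else 0.0
    return {"n_protein_genes": len(protein),
            "n_cotranscribed": len(in_ptu),
            "fraction_cotranscribed": fraction}
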