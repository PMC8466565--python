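"""Per-transcript intron splice-state classification and derived reports.

An intron is called SPLICED on a transcript when an inter-block gap of the
alignment matches the annotated intron interval within a junction tolerance
``tolerance`` (bp); UNSPLICED when the alignment covers the full intron
interior with no gap touching it; UNCOVERED when the alignment does not reach
the intron; AMBIGUOUS when a gap overlaps the intron but violates the
tolerance.  A trans intron is never UNSPLICED on a single molecule — segment
precursors contribute UNCOVERED, and trans intron retention is a
population-level inference.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from .model import (GeneModel, IntronModel, Source, SpliceClass, SpliceState,
                    TranscriptAlignment)

DEFAULT_TOLERANCE = 0
DISCREPANCY_WINDOW = 10


@dataclass
class SpliceStateVector:
    transcript_id: str
    gene_id: str
    source: Source
    states: list[SpliceState]

    def pattern(self) -> tuple[str, ...]:
        return tuple(s.value for s in self.states)


@dataclass
class TransSpliceEvent:
    transcript_id: str
    intron_id: str
    segments: tuple[str, str]


@dataclass
class JunctionDiscrepancy:
    gene_id: str
    intron_id: str
    side: str                      # "donor" | "acceptor"
    annotated: int
    consensus: int
    offset: int
    support: int


def _interval_overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def _covers_interval(blocks: Sequence[tuple[int, int]],
                     interval: tuple[int, int]) -> bool:
    lo, hi = interval
    covered = lo
    for s, e in blocks:
        if s > covered:
            break
        if e > covered:
            covered = e
        if covered >= hi:
            return True
    return covered >= hi


def _classify_intron(alignment: TranscriptAlignment, intron: IntronModel,
                     tolerance: int) -> SpliceState:
    interval = intron.interval
    for gs, ge in alignment.gaps():
        if (abs(gs - interval[0]) <= tolerance
                and abs(ge - interval[1]) <= tolerance):
            return SpliceState.SPLICED
    overlapping = [g for g in alignment.gaps()
                   if _interval_overlap(g, interval) > 0]
    if overlapping:
        return SpliceState.AMBIGUOUS
    if intron.splice_class is SpliceClass.TRANS:
        # single molecules never retain a trans intron
        return SpliceState.UNCOVERED
    if _covers_interval(alignment.blocks, interval):
        return SpliceState.UNSPLICED
    return SpliceState.UNCOVERED


def classify_splice_states(alignment: TranscriptAlignment, gene: GeneModel,
                           tolerance: int = DEFAULT_TOLERANCE,
                           ) -> SpliceStateVector:
    """Classify every intron of ``gene`` on one alignment."""
    if alignment.strand != gene.strand:
        raise ValueError(
            f"{alignment.transcript_id}: strand {alignment.strand} does not "
            f"match gene {gene.gene_id} ({gene.strand})")
    states = [_classify_intron(alignment, intron, tolerance)
              for intron in gene.introns]
    return SpliceStateVector(alignment.transcript_id, gene.gene_id,
                             alignment.source, states)


def classify_all(alignments: Iterable[TranscriptAlignment],
                 genes: Sequence[GeneModel],
                 tolerance: int = DEFAULT_TOLERANCE,
                 ) -> list[SpliceStateVector]:
    """Classify each alignment against every same-strand gene it overlaps."""
    vectors = []
    for aln in alignments:
        a_lo, a_hi = aln.span
        for gene in genes:
            if gene.strand != aln.strand or not gene.introns:
                continue
            g_lo, g_hi = gene.span
            if a_lo < g_hi and g_lo < a_hi:
                vectors.append(classify_splice_states(aln, gene, tolerance))
    return vectors


def enumerate_intermediates(vectors: Iterable[SpliceStateVector],
                            gene: GeneModel,
                            require_complete: bool = True,
                            ) -> dict[tuple[str, ...], int]:
    """Distinct splice-state patterns and their transcript counts.

    With ``require_complete`` (default) only transcripts whose every intron is
    SPLICED or UNSPLICED are counted, so the pattern space is the 2^k products
    of a k-intron gene.
    """
    counts: Counter = Counter()
    decided = {SpliceState.SPLICED, SpliceState.UNSPLICED}
    for vec in vectors:
        if vec.gene_id != gene.gene_id:
            continue
        if require_complete and any(s not in decided for s in vec.states):
            continue
        counts[vec.pattern()] += 1
    return dict(counts)


def detect_trans_splicing(alignment: TranscriptAlignment, gene: GeneModel,
                          tolerance: int = DEFAULT_TOLERANCE,
                          ) -> list[TransSpliceEvent]:
    """Direct trans-splicing evidence: a gap joining exons of two different
    gene segments at the trans intron's boundaries."""
    if len(gene.segments) < 2:
        return []
    events = []
    for intron in gene.introns:
        if intron.splice_class is not SpliceClass.TRANS:
            continue
        if _classify_intron(alignment, intron, tolerance) is not SpliceState.SPLICED:
            continue
        # flanking exons must actually be present on both sides of the gap
        up_exon = gene.exon_by_rank(intron.rank)
        down_exon = gene.exon_by_rank(intron.rank + 1)
        if any(_interval_overlap(b, (up_exon.start, up_exon.end)) > 0
               for b in alignment.blocks) and \
           any(_interval_overlap(b, (down_exon.start, down_exon.end)) > 0
               for b in alignment.blocks):
            events.append(TransSpliceEvent(
                alignment.transcript_id, intron.intron_id,
                (intron.upstream_segment_id, intron.downstream_segment_id)))
    return events


def splice_order_events(vectors: Iterable[SpliceStateVector],
                        gene: GeneModel) -> dict[str, list[str]]:
    """Mixed-order molecules in a gene with both cis and trans introns:
    trans-before-cis (trans spliced while a cis intron is retained) and
    cis-before-trans (a cis intron spliced within an unjoined segment
    precursor)."""
    cis_idx = [i for i, intr in enumerate(gene.introns)
               if intr.splice_class is SpliceClass.CIS]
    trans_idx = [i for i, intr in enumerate(gene.introns)
                 if intr.splice_class is SpliceClass.TRANS]
    if not cis_idx or not trans_idx:
        return {"trans_before_cis": [], "cis_before_trans": []}
    report: dict[str, list[str]] = {"trans_before_cis": [],
                                    "cis_before_trans": []}
    for vec in vectors:
        if vec.gene_id != gene.gene_id:
            continue
        trans_spliced = any(vec.states[i] is SpliceState.SPLICED
                            for i in trans_idx)
        cis_unspliced = any(vec.states[i] is SpliceState.UNSPLICED
                            for i in cis_idx)
        cis_spliced = any(vec.states[i] is SpliceState.SPLICED
                          for i in cis_idx)
        if trans_spliced and cis_unspliced:
            report["trans_before_cis"].append(vec.transcript_id)
        if cis_spliced and not trans_spliced and \
                all(vec.states[i] is SpliceState.UNCOVERED for i in trans_idx):
            report["cis_before_trans"].append(vec.transcript_id)
    return report


def intron_support_table(genes: Sequence[GeneModel],
                         alignments_by_source: dict[Source, list[TranscriptAlignment]],
                         tolerance: int = DEFAULT_TOLERANCE) -> pd.DataFrame:
    """Per-intron detection matrix over evidence sources: an intron counts as
    detected for a source when >=1 transcript shows it SPLICED (for trans
    introns, a trans-splice event)."""
    rows = []
    for gene in genes:
        detected: dict[str, dict[Source, bool]] = defaultdict(
            lambda: {s: False for s in alignments_by_source})
        for source, alns in alignments_by_source.items():
            for aln in alns:
                if aln.strand != gene.strand:
                    continue
                a_lo, a_hi = aln.span
                g_lo, g_hi = gene.span
                if not (a_lo < g_hi and g_lo < a_hi):
                    continue
                vec = classify_splice_states(aln, gene, tolerance)
                for intron, state in zip(gene.introns, vec.states):
                    if intron.splice_class is SpliceClass.CIS:
                        if state is SpliceState.SPLICED:
                            detected[intron.intron_id][source] = True
                for ev in detect_trans_splicing(aln, gene, tolerance):
                    detected[ev.intron_id][source] = True
        for intron in gene.introns:
            row = {"gene_id": gene.gene_id, "intron_id": intron.intron_id,
                   "splice_class": intron.splice_class.value}
            for source in alignments_by_source:
                row[source.value] = detected[intron.intron_id][source]
            rows.append(row)
    return pd.DataFrame(rows)


def junction_discrepancies(alignments: Iterable[TranscriptAlignment],
                           genes: Sequence[GeneModel],
                           min_support: int = 3,
                           window: int = DISCREPANCY_WINDOW,
                           ) -> list[JunctionDiscrepancy]:
    """Compare the modal transcript gap coordinate at each intron side with
    the annotation; report non-zero offsets with enough transcript support."""
    gaps_by_intron: dict[str, tuple[GeneModel, IntronModel,
                                    list[tuple[int, int]]]] = {}
    for gene in genes:
        for intron in gene.introns:
            gaps_by_intron[intron.intron_id] = (gene, intron, [])
    for aln in alignments:
        for gene in genes:
            if gene.strand != aln.strand:
                continue
            for intron in gene.introns:
                for gs, ge in aln.gaps():
                    if (abs(gs - intron.start) <= window
                            and abs(ge - intron.end) <= window):
                        gaps_by_intron[intron.intron_id][2].append((gs, ge))
    report = []
    for intron_id, (gene, intron, gaps) in gaps_by_intron.items():
        if not gaps:
            continue
        for side, annotated, observed in (
                ("donor", intron.start, [g[0] for g in gaps]),
                ("acceptor", intron.end, [g[1] for g in gaps])):
            mode, support = Counter(observed).most_common(1)[0]
            if mode != annotated and support >= min_support:
                report.append(JunctionDiscrepancy(
                    gene.gene_id, intron_id, side, annotated, mode,
                    mode - annotated, support))
    return report


# ---------------------------------------------------------------------------
# TSV-facing helpers (CLI)
# ---------------------------------------------------------------------------

def vectors_to_frame(vectors: Iterable[SpliceStateVector],
                     genes: Sequence[GeneModel]) -> pd.DataFrame:
    gene_by_id = {g.gene_id: g for g in genes}
    rows = []
    for vec in vectors:
        gene = gene_by_id[vec.gene_id]
        for intron, state in zip(gene.introns, vec.states):
            rows.append({"transcript_id": vec.transcript_id,
                         "gene_id": vec.gene_id,
                         "source": vec.source.value,
                         "intron_id": intron.intron_id,
                         "state": state.value})
    return pd.DataFrame(rows)
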