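"""Splice-dependent editing: exonic sites editable only on molecules whose
adjacent intron has been spliced.

For every accepted exonic site near a junction, transcripts covering the
site are cross-tabulated as {edited, unedited} x {adjacent intron SPLICED,
UNSPLICED}; a spliced-edited event is flagged when the unspliced class is
(nearly) never edited while the spliced class is edited in at least a
configurable fraction, with an optional Fisher exact test reported alongside.
Distances use the convention that the first exonic base adjacent to the
junction is 1 (so a site "6 bp downstream" of an intron is the sixth exonic
base after the acceptor).  For trans introns the SPLICED class comes from
trans-splice events and the UNSPLICED class from segment precursors.
Intronic sites are annotated with their distance but never tested — their
presence on unspliced molecules is expected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd
from scipy.stats import fisher_exact

from .editing_call import EditingSite
from .model import (FeatureContext, GeneModel, SpliceClass, SpliceState,
                    TranscriptAlignment)
from .splicing import classify_splice_states

logger = logging.getLogger("organellotx")

DEFAULT_WINDOW = 50


@dataclass
class JointStateTable:
    position: int
    intron_id: str
    edited_spliced: int = 0
    unedited_spliced: int = 0
    edited_unspliced: int = 0
    unedited_unspliced: int = 0

    @property
    def n_spliced(self) -> int:
        return self.edited_spliced + self.unedited_spliced

    @property
    def n_unspliced(self) -> int:
        return self.edited_unspliced + self.unedited_unspliced

    @property
    def total(self) -> int:
        return self.n_spliced + self.n_unspliced


@dataclass
class SplicedEditedEvent:
    position: int
    intron_id: str
    side: Optional[str]
    distance: Optional[int]
    edited_fraction_spliced: float
    edited_fraction_unspliced: float
    flag: bool
    p_value: Optional[float] = None


def distance_to_junction(position: int, gene: GeneModel
                         ) -> tuple[str, str, int]:
    """(intron_id, side, distance) of the nearest junction in transcript
    orientation.  Exonic sites get side UPSTREAM/DOWNSTREAM of the nearest
    intron; intronic sites get side INTERNAL with the distance to the nearer
    exon boundary.  Distance 1 = the base adjacent to the junction."""
    if not gene.introns:
        raise ValueError(f"{gene.gene_id} has no introns")
    cds_idx = gene.cds_index_of(position)
    if cds_idx is not None:
        offsets = gene.junction_offsets()
        best: Optional[tuple[int, str, str]] = None
        for intron, off in zip(gene.introns, offsets):
            if cds_idx >= off:   # intron upstream of the site
                dist, side = cds_idx - off + 1, "DOWNSTREAM"
            else:
                dist, side = off - cds_idx, "UPSTREAM"
            # ties break toward the upstream intron (the DOWNSTREAM side)
            key = (dist, 0 if side == "DOWNSTREAM" else 1)
            if best is None or key < (best[0], 0 if best[1] == "DOWNSTREAM" else 1):
                best = (dist, side, intron.intron_id)
            elif key == (best[0], 0 if best[1] == "DOWNSTREAM" else 1):
                logger.info("pos %d: junction-distance tie kept at %s",
                            position + 1, best[2])
        assert best is not None
        return best[2], best[1], best[0]
    # intronic: distance to the nearer exon boundary
    for intron in gene.introns:
        intervals = intron.transcribed_intervals()
        if intron.splice_class is SpliceClass.CIS:
            intervals = [intron.interval]
        for s, e in intervals:
            if s <= position < e:
                d = min(position - s + 1, e - position)
                return intron.intron_id, "INTERNAL", d
    raise ValueError(f"position {position} not inside gene {gene.gene_id}")


def _precursor_state(aln: TranscriptAlignment, gene: GeneModel,
                     intron) -> bool:
    """True when the alignment is a segment precursor for a trans intron:
    it overlaps exactly one of the two adjacent segments."""
    up = gene.segment_of_rank(intron.rank).span
    down = gene.segment_of_rank(intron.rank + 1).span
    lo, hi = aln.span
    hits = sum(1 for s, e in (up, down) if lo < e and s < hi)
    return hits == 1


def joint_states(site: EditingSite, intron_id: str,
                 alignments: Iterable[TranscriptAlignment], gene: GeneModel,
                 tolerance: int = 0) -> JointStateTable:
    """Tally {edited, unedited} x {SPLICED, UNSPLICED} over transcripts that
    cover the site and have a decided intron state; UNCOVERED/AMBIGUOUS
    molecules are excluded (for trans introns, segment precursors stand in
    for the UNSPLICED class)."""
    intron = gene.intron_by_id(intron_id)
    alt = "T" if site.strand == "+" else "A"
    table = JointStateTable(site.position, intron_id)
    idx = gene.introns.index(intron)
    for aln in alignments:
        if aln.strand != gene.strand:
            continue
        base = aln.base_at(site.position)
        if base is None:
            continue
        state = classify_splice_states(aln, gene, tolerance).states[idx]
        if intron.splice_class is SpliceClass.TRANS:
            if state is SpliceState.UNCOVERED and \
                    _precursor_state(aln, gene, intron):
                state = SpliceState.UNSPLICED
        if state not in (SpliceState.SPLICED, SpliceState.UNSPLICED):
            continue
        edited = base == alt
        if state is SpliceState.SPLICED:
            if edited:
                table.edited_spliced += 1
            else:
                table.unedited_spliced += 1
        else:
            if edited:
                table.edited_unspliced += 1
            else:
                table.unedited_unspliced += 1
    return table


def detect_spliced_edited(table: JointStateTable, min_per_class: int = 5,
                          eps: float = 0.05, delta: float = 0.5,
                          exact_test: bool = True,
                          side: Optional[str] = None,
                          distance: Optional[int] = None,
                          ) -> SplicedEditedEvent:
    """Flag a spliced-edited event when both classes are covered and editing
    is (nearly) absent among UNSPLICED but common among SPLICED molecules."""
    frac_spliced = (table.edited_spliced / table.n_spliced
                    if table.n_spliced else 0.0)
    frac_unspliced = (table.edited_unspliced / table.n_unspliced
                      if table.n_unspliced else 0.0)
    flag = (table.n_spliced >= min_per_class
            and table.n_unspliced >= min_per_class
            and frac_unspliced <= eps
            and frac_spliced >= delta)
    p_value = None
    if exact_test and table.total > 0:
        _, p_value = fisher_exact(
            [[table.edited_spliced, table.unedited_spliced],
             [table.edited_unspliced, table.unedited_unspliced]],
            alternative="two-sided")
    return SplicedEditedEvent(table.position, table.intron_id, side, distance,
                              frac_spliced, frac_unspliced, flag, p_value)


def interplay_report(sites: Iterable[EditingSite],
                     genes: Sequence[GeneModel],
                     alignments: Sequence[TranscriptAlignment],
                     window: int = DEFAULT_WINDOW,
                     tolerance: int = 0,
                     min_per_class: int = 5,
                     eps: float = 0.05,
                     delta: float = 0.5,
                     exact_test: bool = True) -> pd.DataFrame:
    """Test every exonic accepted site within ``window`` exonic bases of a
    junction; annotate intronic sites without testing."""
    gene_by_id = {g.gene_id: g for g in genes}
    rows = []
    for site in sites:
        gene = gene_by_id.get(site.gene_id)
        if gene is None or not gene.introns:
            continue
        intron_id, side, distance = distance_to_junction(site.position, gene)
        intron = gene.intron_by_id(intron_id)
        row = {"position": site.position, "gene_id": gene.gene_id,
               "intron_id": intron_id,
               "splice_class": intron.splice_class.value,
               "side": side, "distance": distance,
               "n_spliced": None, "n_unspliced": None,
               "frac_edited_spliced": None, "frac_edited_unspliced": None,
               "flag": None, "p_value": None}
        if side != "INTERNAL" and distance <= window:
            table = joint_states(site, intron_id, alignments, gene, tolerance)
            event = detect_spliced_edited(table, min_per_class, eps, delta,
                                          exact_test, side, distance)
            row.update({"n_spliced": table.n_spliced,
                        "n_unspliced": table.n_unspliced,
                        "frac_edited_spliced": event.edited_fraction_spliced,
                        "frac_edited_unspliced": event.edited_fraction_unspliced,
                        "flag": event.flag, "p_value": event.p_value})
        rows.append(row)
    return pd.DataFrame(rows)
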