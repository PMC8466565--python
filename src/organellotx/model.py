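"""Domain types and coordinate conventions for organelle transcript analysis.

All internal coordinates are 0-based half-open on the reference genome;
conversion from the 1-based inclusive conventions of GFF3/VCF happens at the
I/O boundary only.  Exon ``rank`` is 1-based in transcription order, so for a
minus-strand gene exon 1 is the genomically rightmost exon.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
PYRIMIDINES = frozenset("CT")
PURINES = frozenset("AG")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


class SpliceClass(str, Enum):
    CIS = "CIS"
    TRANS = "TRANS"


class GeneType(str, Enum):
    PROTEIN = "PROTEIN"
    TRNA = "TRNA"
    RRNA = "RRNA"


class Source(str, Enum):
    LONGREAD = "LONGREAD"
    ASSEMBLY = "ASSEMBLY"


class SpliceState(str, Enum):
    SPLICED = "SPLICED"
    UNSPLICED = "UNSPLICED"
    UNCOVERED = "UNCOVERED"
    AMBIGUOUS = "AMBIGUOUS"


class FeatureContext(str, Enum):
    CDS = "CDS"
    INTRON = "INTRON"
    UTR = "UTR"
    INTERGENIC = "INTERGENIC"
    TRNA = "TRNA"
    RRNA = "RRNA"


class SiteStatus(str, Enum):
    ACCEPTED = "ACCEPTED"
    REMOVED_SNP = "REMOVED_SNP"
    REMOVED_NO_ASSEMBLY = "REMOVED_NO_ASSEMBLY"
    REMOVED_FILTER = "REMOVED_FILTER"
    RECOVERED = "RECOVERED"


@dataclass
class OrganelleGenome:
    """A single organelle reference sequence (plastome or mitogenome)."""

    genome_id: str
    sequence: str
    circular: bool = False

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError("genome sequence is empty")
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(f"non-IUPAC-DNA characters in genome: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ExonInterval:
    start: int
    end: int
    rank: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty exon interval [{self.start}, {self.end})")
        if self.rank < 1:
            raise ValueError("exon rank must be >= 1")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class IntronModel:
    """One intron, numbered by the rank of its transcription-upstream exon.

    ``start``/``end`` delimit the genomic interval between the two flanking
    exons.  For a TRANS intron that interval spans everything between the two
    gene segments; the transcribed intron halves (e.g. ``nad1-i1a``/``i1b``)
    may be given explicitly as ``donor_half``/``acceptor_half`` intervals.
    """

    intron_id: str
    splice_class: SpliceClass
    start: int
    end: int
    rank: int
    upstream_segment_id: Optional[str] = None
    downstream_segment_id: Optional[str] = None
    donor_half: Optional[tuple[int, int]] = None
    acceptor_half: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if self.splice_class is SpliceClass.CIS and self.start >= self.end:
            raise ValueError(f"{self.intron_id}: CIS intron needs start < end")
        if self.splice_class is SpliceClass.TRANS:
            if self.upstream_segment_id is None or self.downstream_segment_id is None:
                raise ValueError(f"{self.intron_id}: TRANS intron needs two segments")
            if self.upstream_segment_id == self.downstream_segment_id:
                raise ValueError(f"{self.intron_id}: TRANS segments must differ")

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)

    def transcribed_intervals(self) -> list[tuple[int, int]]:
        """Genomic intervals that are part of the precursor transcript."""
        if self.splice_class is SpliceClass.CIS:
            return [(self.start, self.end)]
        halves = [h for h in (self.donor_half, self.acceptor_half) if h is not None]
        return halves


@dataclass
class GeneSegment:
    """A contiguously transcribed piece of a (possibly trans-spliced) gene."""

    segment_id: str
    gene_id: str
    strand: str
    exon_ranks: list[int]
    span: tuple[int, int]

    def __post_init__(self) -> None:
        ranks = self.exon_ranks
        if ranks != list(range(ranks[0], ranks[0] + len(ranks))):
            raise ValueError(f"segment {self.segment_id}: exon ranks not contiguous")


@dataclass
class GeneModel:
    gene_id: str
    gene_type: GeneType
    strand: str
    exons: list[ExonInterval]
    introns: list[IntronModel] = field(default_factory=list)
    segments: list[GeneSegment] = field(default_factory=list)
    utr5: Optional[tuple[int, int]] = None
    utr3: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        ranks = sorted(e.rank for e in self.exons)
        if ranks != list(range(1, len(self.exons) + 1)):
            raise ValueError(f"{self.gene_id}: exon ranks must be 1..n")
        by_pos = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(by_pos, by_pos[1:]):
            if b.start < a.end:
                raise ValueError(f"{self.gene_id}: overlapping exons")
        if len(self.introns) != len(self.exons) - 1:
            raise ValueError(
                f"{self.gene_id}: intron count must equal exon count - 1"
            )
        if not self.segments:
            span = (min(e.start for e in self.exons), max(e.end for e in self.exons))
            self.segments = [
                GeneSegment(f"{self.gene_id}.seg1", self.gene_id, self.strand,
                            sorted(e.rank for e in self.exons), span)
            ]

    # -- geometry helpers -------------------------------------------------

    def exon_by_rank(self, rank: int) -> ExonInterval:
        for e in self.exons:
            if e.rank == rank:
                return e
        raise KeyError(rank)

    def intron_by_id(self, intron_id: str) -> IntronModel:
        for i in self.introns:
            if i.intron_id == intron_id:
                return i
        raise KeyError(intron_id)

    @property
    def exonic_length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        starts = [e.start for e in self.exons]
        ends = [e.end for e in self.exons]
        for i in self.introns:
            for s, e in i.transcribed_intervals():
                starts.append(s)
                ends.append(e)
        return (min(starts), max(ends))

    def exons_in_order(self) -> list[ExonInterval]:
        return sorted(self.exons, key=lambda e: e.rank)

    def segment_of_rank(self, rank: int) -> GeneSegment:
        for seg in self.segments:
            if rank in seg.exon_ranks:
                return seg
        raise KeyError(rank)

    def cds_index_of(self, position: int) -> Optional[int]:
        """Spliced-transcript index (0-based) of a genomic position, or None
        if the position is not exonic."""
        offset = 0
        for exon in self.exons_in_order():
            if exon.start <= position < exon.end:
                if self.strand == "+":
                    return offset + (position - exon.start)
                return offset + (exon.end - 1 - position)
            offset += len(exon)
        return None

    def junction_offsets(self) -> list[int]:
        """Spliced-coordinate position of each inter-exon junction: junction k
        (after exon rank k) sits between spliced indices off-1 and off."""
        offsets = []
        total = 0
        for exon in self.exons_in_order()[:-1]:
            total += len(exon)
            offsets.append(total)
        return offsets


@dataclass
class TranscriptAlignment:
    """One gapped alignment of a full-length transcript to the genome.

    ``blocks`` give the reference geometry (deletions merged, skips opening
    gaps); ``match_segments`` keep the fine-grained (ref_start, ref_end,
    query_start) mapping of aligned bases so the transcript base under any
    reference position can be recovered.
    """

    transcript_id: str
    source: Source
    strand: str
    genome_id: str
    blocks: list[tuple[int, int]]
    match_segments: list[tuple[int, int, int]] = field(default_factory=list)
    query: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError(f"{self.transcript_id}: alignment has no blocks")
        for (s1, e1), (s2, e2) in zip(self.blocks, self.blocks[1:]):
            if s2 <= e1:
                raise ValueError(f"{self.transcript_id}: blocks not increasing")
        for s, e in self.blocks:
            if s >= e:
                raise ValueError(f"{self.transcript_id}: empty block")

    @property
    def span(self) -> tuple[int, int]:
        return (self.blocks[0][0], self.blocks[-1][1])

    def gaps(self) -> list[tuple[int, int]]:
        return [(e1, s2) for (_, e1), (s2, _) in zip(self.blocks, self.blocks[1:])]

    def covers(self, position: int) -> bool:
        i = bisect.bisect_right(self.blocks, (position, float("inf"))) - 1
        return i >= 0 and self.blocks[i][0] <= position < self.blocks[i][1]

    def base_at(self, position: int) -> Optional[str]:
        """Reference-orientation transcript base aligned to ``position``,
        or None when the position is not covered by an aligned base."""
        if self.query is None or not self.match_segments:
            return None
        lo, hi = self.span
        if not (lo <= position < hi):
            return None
        i = bisect.bisect_right(self.match_segments, (position, float("inf"), 0)) - 1
        if i < 0:
            return None
        rs, re, qs = self.match_segments[i]
        if rs <= position < re:
            return self.query[qs + (position - rs)]
        return None


@dataclass
class PileupSite:
    """Stranded per-base counts at one reference position (0-based)."""

    position: int
    ref_base: str
    counts_fwd: dict[str, int]
    counts_rev: dict[str, int]
    QUAL: float = 0.0
    DP: int = 0

    def __post_init__(self) -> None:
        if self.ref_base not in "ACGT":
            raise ValueError(f"pos {self.position}: ref base {self.ref_base!r} "
                             "not in {A,C,G,T}")
        for counts in (self.counts_fwd, self.counts_rev):
            for base, n in counts.items():
                if n < 0:
                    raise ValueError(f"pos {self.position}: negative count for {base}")
        self.DP = sum(self.counts_fwd.values()) + sum(self.counts_rev.values())
        if self.QUAL < 0:
            raise ValueError(f"pos {self.position}: negative QUAL")

    def count(self, base: str, strand: str) -> int:
        counts = self.counts_fwd if strand == "+" else self.counts_rev
        return counts.get(base, 0)


class GenomicSnpSet:
    """DNA-level variant positions used to veto RNA-editing calls."""

    def __init__(self, snps: set[tuple[int, str, str]] | None = None):
        self.snps: set[tuple[int, str, str]] = set(snps or ())
        self._positions = {p for p, _, _ in self.snps}

    def add(self, position: int, ref: str, alt: str) -> None:
        self.snps.add((position, ref, alt))
        self._positions.add(position)

    def __contains__(self, position: int) -> bool:
        return position in self._positions

    def __len__(self) -> int:
        return len(self.snps)
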