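"""Readers and writers for the standard formats the pipeline touches.

FASTA via Biopython, SAM via pysam, GFF3 via gffutils, VCF via pysam, and a
documented stranded-pileup TSV dialect via pandas.  All conversions between
the 1-based inclusive file conventions (GFF3, VCF, pileup TSV) and the
package-internal 0-based half-open coordinates happen here and only here.

Pileup TSV dialect (tab-separated, header row required)::

    pos  ref  A+  C+  G+  T+  A-  C-  G-  T-  qual  [dp]

``pos`` is 1-based; ``X+``/``X-`` are base counts from forward/reverse-strand
reads; ``dp`` is optional and, when it disagrees with the count sum, the
counts win (with a warning).
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional

import gffutils
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq

from .model import (
    ExonInterval,
    GeneModel,
    GeneSegment,
    GeneType,
    GenomicSnpSet,
    IntronModel,
    OrganelleGenome,
    PileupSite,
    Source,
    SpliceClass,
    TranscriptAlignment,
    revcomp,
)

logger = logging.getLogger("organellotx")

PILEUP_COLUMNS = ["pos", "ref", "A+", "C+", "G+", "T+", "A-", "C-", "G-", "T-", "qual"]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_genome(path: str) -> OrganelleGenome:
    """Read a single-record FASTA; 'circular' in the header sets the flag."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"expected 1 record, found {len(records)}")
    rec = records[0]
    circular = "circular" in rec.description.lower()
    return OrganelleGenome(rec.id, str(rec.seq).upper(), circular=circular)


def write_genome(genome: OrganelleGenome, path: str) -> None:
    with open(path, "w") as fh:
        header = genome.genome_id + (" circular" if genome.circular else "")
        fh.write(f">{header}\n")
        seq = genome.sequence
        for i in range(0, len(seq), 70):
            fh.write(seq[i:i + 70] + "\n")


# ---------------------------------------------------------------------------
# GFF3 annotation
# ---------------------------------------------------------------------------

def _derive_introns(gene_id: str, strand: str,
                    exons: list[ExonInterval],
                    rank_segment: dict[int, str],
                    half_features: dict[tuple[str, str], tuple[int, int]],
                    ) -> list[IntronModel]:
    """Introns are the inter-exon gaps, CIS within one segment and TRANS at
    segment boundaries.  Intron k joins exon ranks k and k+1."""
    ordered = sorted(exons, key=lambda e: e.rank)
    introns = []
    for up, down in zip(ordered, ordered[1:]):
        k = up.rank
        intron_id = f"{gene_id}-i{k}"
        if strand == "+":
            start, end = up.end, down.start
        else:
            start, end = down.end, up.start
        if start >= end:
            raise ValueError(f"{intron_id}: exons abut or overlap, no intron gap")
        seg_up, seg_down = rank_segment[up.rank], rank_segment[down.rank]
        if seg_up == seg_down:
            introns.append(IntronModel(intron_id, SpliceClass.CIS, start, end, rank=k))
        else:
            introns.append(IntronModel(
                intron_id, SpliceClass.TRANS, start, end, rank=k,
                upstream_segment_id=seg_up, downstream_segment_id=seg_down,
                donor_half=half_features.get((intron_id, "donor")),
                acceptor_half=half_features.get((intron_id, "acceptor")),
            ))
    return introns


def read_annotation(path: str, genome: Optional[OrganelleGenome] = None) -> list[GeneModel]:
    """Parse a GFF3 annotation into GeneModels.

    Expected features: ``gene`` (attributes ``ID``, optional ``gene_type``),
    ``exon`` (``Parent``, ``rank``, optional ``segment_id``), optional
    ``intron`` features carrying the transcribed halves of trans introns
    (``intron_id``, ``part=donor|acceptor``), optional ``five_prime_UTR`` /
    ``three_prime_UTR``.
    """
    db = gffutils.create_db(str(path), ":memory:", force=True, keep_order=True,
                            merge_strategy="create_unique")
    genes: list[GeneModel] = []
    for gf in db.features_of_type("gene"):
        gene_id = gf.id
        gene_type = GeneType(gf.attributes.get("gene_type", ["PROTEIN"])[0])
        strand = gf.strand
        exons: list[ExonInterval] = []
        rank_segment: dict[int, str] = {}
        half_features: dict[tuple[str, str], tuple[int, int]] = {}
        utr5 = utr3 = None
        for child in db.children(gf):
            iv = (child.start - 1, child.end)  # 1-based inclusive -> half-open
            if child.featuretype == "exon":
                rank = int(child.attributes["rank"][0])
                exons.append(ExonInterval(iv[0], iv[1], rank))
                seg = child.attributes.get("segment_id", [f"{gene_id}.seg1"])[0]
                rank_segment[rank] = seg
            elif child.featuretype == "intron":
                iid = child.attributes["intron_id"][0]
                part = child.attributes["part"][0]
                half_features[(iid, part)] = iv
            elif child.featuretype == "five_prime_UTR":
                utr5 = iv
            elif child.featuretype == "three_prime_UTR":
                utr3 = iv
        if not exons:
            raise ValueError(f"{gene_id}: gene without exons")
        introns = _derive_introns(gene_id, strand, exons, rank_segment, half_features)
        segments = _build_segments(gene_id, strand, exons, rank_segment)
        if any(i.splice_class is SpliceClass.TRANS for i in introns) and len(segments) < 2:
            raise ValueError(f"{gene_id}: trans-spliced gene needs >=2 segments")
        gene = GeneModel(gene_id, gene_type, strand, exons, introns, segments,
                         utr5=utr5, utr3=utr3)
        if gene_type is GeneType.PROTEIN and gene.exonic_length % 3 != 0:
            raise ValueError(
                f"{gene_id}: spliced CDS length {gene.exonic_length} "
                "is not a multiple of 3")
        genes.append(gene)
    return genes


def _build_segments(gene_id: str, strand: str, exons: list[ExonInterval],
                    rank_segment: dict[int, str]) -> list[GeneSegment]:
    segments: list[GeneSegment] = []
    order: list[str] = []
    by_seg: dict[str, list[int]] = {}
    for e in sorted(exons, key=lambda x: x.rank):
        seg = rank_segment[e.rank]
        if seg not in by_seg:
            by_seg[seg] = []
            order.append(seg)
        by_seg[seg].append(e.rank)
    exon_by_rank = {e.rank: e for e in exons}
    for seg in order:
        ranks = by_seg[seg]
        span = (min(exon_by_rank[r].start for r in ranks),
                max(exon_by_rank[r].end for r in ranks))
        segments.append(GeneSegment(seg, gene_id, strand, ranks, span))
    return segments


def write_annotation(genes: Iterable[GeneModel], genome: OrganelleGenome,
                     path: str) -> None:
    """Write GeneModels back to GFF3 (inverse of :func:`read_annotation`)."""
    lines = ["##gff-version 3",
             f"##sequence-region {genome.genome_id} 1 {len(genome)}"]
    for gene in sorted(genes, key=lambda g: g.span[0]):
        gs, ge = gene.span
        lines.append("\t".join([
            genome.genome_id, "organellotx", "gene", str(gs + 1), str(ge),
            ".", gene.strand, ".",
            f"ID={gene.gene_id};gene_type={gene.gene_type.value}"]))
        rank_segment = {r: seg.segment_id for seg in gene.segments
                        for r in seg.exon_ranks}
        for exon in gene.exons_in_order():
            lines.append("\t".join([
                genome.genome_id, "organellotx", "exon",
                str(exon.start + 1), str(exon.end), ".", gene.strand, ".",
                f"ID={gene.gene_id}.e{exon.rank};Parent={gene.gene_id};"
                f"rank={exon.rank};segment_id={rank_segment[exon.rank]}"]))
        for intron in gene.introns:
            if intron.splice_class is not SpliceClass.TRANS:
                continue
            for part, half, seg in (("donor", intron.donor_half,
                                     intron.upstream_segment_id),
                                    ("acceptor", intron.acceptor_half,
                                     intron.downstream_segment_id)):
                if half is None:
                    continue
                lines.append("\t".join([
                    genome.genome_id, "organellotx", "intron",
                    str(half[0] + 1), str(half[1]), ".", gene.strand, ".",
                    f"ID={intron.intron_id}{'a' if part == 'donor' else 'b'};"
                    f"Parent={gene.gene_id};intron_id={intron.intron_id};"
                    f"part={part};splice_class=trans;segment_id={seg}"]))
        for kind, iv in (("five_prime_UTR", gene.utr5),
                         ("three_prime_UTR", gene.utr3)):
            if iv is not None:
                lines.append("\t".join([
                    genome.genome_id, "organellotx", kind,
                    str(iv[0] + 1), str(iv[1]), ".", gene.strand, ".",
                    f"ID={gene.gene_id}.{kind};Parent={gene.gene_id}"]))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# SAM alignments
# ---------------------------------------------------------------------------

_CIGAR_MATCH = {0, 7, 8}  # M, =, X


def _blocks_from_cigar(cigartuples, ref_start: int):
    blocks: list[tuple[int, int]] = []
    segs: list[tuple[int, int, int]] = []
    rpos, qpos = ref_start, 0
    block_start = rpos
    for op, ln in cigartuples:
        if op in _CIGAR_MATCH:
            segs.append((rpos, rpos + ln, qpos))
            rpos += ln
            qpos += ln
        elif op == 1:      # insertion
            qpos += ln
        elif op == 2:      # deletion extends the reference block
            rpos += ln
        elif op == 3:      # skip closes the block and opens a splice gap
            if rpos > block_start:
                blocks.append((block_start, rpos))
            rpos += ln
            block_start = rpos
        elif op == 4:      # soft clip
            qpos += ln
        elif op in (5, 6):  # hard clip / pad
            pass
        else:
            raise ValueError(f"unsupported CIGAR op {op}")
    if rpos > block_start:
        blocks.append((block_start, rpos))
    return blocks, segs


def read_alignments(path: str, source: Source | str) -> list[TranscriptAlignment]:
    """Parse transcript alignments from a text SAM file.

    Unmapped records are skipped (and counted in the log); insertions and
    clips do not contribute reference geometry; N skips open splice gaps.
    """
    source = Source(source)
    alignments: list[TranscriptAlignment] = []
    skipped = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        it = enumerate(sam, start=1)
        while True:
            try:
                n, rec = next(it)
            except StopIteration:
                break
            except Exception as exc:  # malformed record
                raise ValueError(f"{path}: malformed SAM record "
                                 f"near record {skipped + len(alignments) + 1}: {exc}")
            if rec.is_unmapped:
                skipped += 1
                continue
            try:
                blocks, segs = _blocks_from_cigar(rec.cigartuples,
                                                  rec.reference_start)
            except ValueError as exc:
                raise ValueError(f"{path}: record {n} ({rec.query_name}): {exc}")
            alignments.append(TranscriptAlignment(
                transcript_id=rec.query_name,
                source=source,
                strand="-" if rec.is_reverse else "+",
                genome_id=rec.reference_name or "",
                blocks=blocks,
                match_segments=segs,
                query=rec.query_sequence,
            ))
    if skipped:
        logger.info("read_alignments(%s): skipped %d unmapped records",
                    path, skipped)
    return alignments


def write_sam(alignments: Iterable[TranscriptAlignment],
              genome: OrganelleGenome, path: str) -> None:
    """Write alignments as text SAM (M/N CIGARs reconstructed from blocks)."""
    header = pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": genome.genome_id, "LN": len(genome)}],
    })
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for aln in sorted(alignments, key=lambda a: a.span[0]):
            rec = pysam.AlignedSegment(header)
            rec.query_name = aln.transcript_id
            rec.flag = 16 if aln.strand == "-" else 0
            rec.reference_id = 0
            rec.reference_start = aln.blocks[0][0]
            rec.mapping_quality = 60
            cig = []
            for i, (s, e) in enumerate(aln.blocks):
                if i:
                    cig.append((3, s - aln.blocks[i - 1][1]))
                cig.append((0, e - s))
            rec.cigartuples = cig
            if aln.query is not None:
                rec.query_sequence = aln.query
                rec.query_qualities = None
            out.write(rec)


# ---------------------------------------------------------------------------
# Pileups and genomic SNPs
# ---------------------------------------------------------------------------

def read_pileup(path: str) -> list[PileupSite]:
    """Read the stranded pileup TSV dialect (see module docstring)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in PILEUP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing pileup columns {missing}")
    sites = []
    for row in df.itertuples(index=False):
        # column names contain +/-, so index positionally
        vals = dict(zip(df.columns, row))
        fwd = {b: int(vals[f"{b}+"]) for b in "ACGT"}
        rev = {b: int(vals[f"{b}-"]) for b in "ACGT"}
        site = PileupSite(position=int(vals["pos"]) - 1,
                          ref_base=str(vals["ref"]),
                          counts_fwd=fwd, counts_rev=rev,
                          QUAL=float(vals["qual"]))
        if "dp" in df.columns and int(vals["dp"]) != site.DP:
            logger.warning("pileup pos %d: declared dp=%s but counts sum to %d; "
                           "using counts", site.position + 1, vals["dp"], site.DP)
        sites.append(site)
    return sites


def write_pileup(sites: Iterable[PileupSite], path: str) -> None:
    rows = []
    for s in sorted(sites, key=lambda x: x.position):
        rows.append([s.position + 1, s.ref_base,
                     *(s.counts_fwd.get(b, 0) for b in "ACGT"),
                     *(s.counts_rev.get(b, 0) for b in "ACGT"),
                     s.QUAL])
    pd.DataFrame(rows, columns=PILEUP_COLUMNS).to_csv(path, sep="\t", index=False)


def read_genomic_snps(path: str) -> GenomicSnpSet:
    """Read a (plain-text) VCF of DNA-level SNPs."""
    snps = GenomicSnpSet()
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if rec.alts is None:
                continue
            for alt in rec.alts:
                if len(rec.ref) == 1 and len(alt) == 1:
                    snps.add(rec.pos - 1, rec.ref, alt)
    return snps


def write_genomic_snps(snps: GenomicSnpSet, genome: OrganelleGenome,
                       path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={genome.genome_id},length={len(genome)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for pos, ref, alt in sorted(snps.snps):
            fh.write(f"{genome.genome_id}\t{pos + 1}\t.\t{ref}\t{alt}\t"
                     f"100\tPASS\t.\n")


# ---------------------------------------------------------------------------
# Spliced CDS extraction and translation
# ---------------------------------------------------------------------------

def extract_spliced_cds(gene: GeneModel, genome: OrganelleGenome) -> str:
    """Exons concatenated in transcription order, minus-strand genes
    reverse-complemented per exon."""
    parts = []
    for exon in gene.exons_in_order():
        seq = genome.sequence[exon.start:exon.end]
        parts.append(revcomp(seq) if gene.strand == "-" else seq)
    return "".join(parts)


def translate(cds: str) -> str:
    """Standard genetic code (table 1); stop rendered '*'.  An internal stop
    in the reference CDS warns only — editing may create or remove stops."""
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} not a multiple of 3")
    protein = str(Seq(cds).translate(table=1))
    if "*" in protein[:-1]:
        logger.warning("internal stop codon in reference CDS")
    return protein
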