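"""Synthetic organelle genomes, annotations, transcripts and pileups with
known truth.

The generator emulates the statistical structure of full-length organelle
transcript data: per-intron Bernoulli splicing (cis and trans), per-site
C-to-U editing efficiencies sampled binomially at a configured depth, a
configurable pyrimidine bias at the -1 (5'-adjacent) position, splice-gated
editing (a site that can only be edited once a given intron is spliced),
polycistronic read-through transcripts, DNA-level SNPs, and a uniform
sequencing-error rate applied after editing.

One global seed drives independent per-stage generator streams (genome,
transcripts, pileups), so regenerating one stage does not perturb the others.
QUAL in the simulated pileup is ``min(60, 3 * alternate_count)`` — an
arbitrary but monotone stand-in for a caller's site quality.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .io import (_derive_introns, write_annotation, write_genome,
                 write_genomic_snps, write_pileup, write_sam)
from .model import (ExonInterval, FeatureContext, GeneModel, GeneSegment,
                    GeneType, GenomicSnpSet, IntronModel, OrganelleGenome,
                    PileupSite, Source, SpliceClass, TranscriptAlignment,
                    revcomp)

QUAL_CAP = 60.0
QUAL_PER_ALT = 3.0


def qual_model(alt_count: int) -> float:
    """Deterministic, monotone pileup quality: min(60, 3 * alt_count)."""
    return min(QUAL_CAP, QUAL_PER_ALT * alt_count)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class IntronSpec:
    length: int = 60
    splice_class: str = "cis"          # "cis" | "trans"
    splice_prob: float = 0.5


@dataclass
class GeneSpec:
    gene_id: str
    exon_lengths: list[int]
    introns: list[IntronSpec] = field(default_factory=list)
    strand: str = "+"
    gene_type: str = "PROTEIN"
    start: Optional[int] = None        # explicit placement (else auto-layout)


@dataclass
class SiteSpec:
    """One planted C-to-U editing site.

    Exonic sites give ``exon`` (1-based rank) and ``offset`` (0-based exonic
    offset in transcription orientation); intronic sites give ``intron``
    (1-based rank, offset from the donor side); intergenic sites give
    neither (placed in the intergenic tail) and carry their own ``strand``.
    """

    site_id: str
    gene_id: Optional[str] = None
    exon: Optional[int] = None
    intron: Optional[int] = None
    offset: int = 3
    efficiency: float = 0.8
    dependency_intron: Optional[int] = None   # 1-based intron rank gating editing
    minus1_pyrimidine_prob: float = 0.93
    strand: str = "+"
    depth: Optional[int] = None


@dataclass
class SimulationConfig:
    seed: int = 0
    genes: list[GeneSpec] = field(default_factory=list)
    editing_sites: list[SiteSpec] = field(default_factory=list)
    depth: int = 100
    error_rate: float = 0.0
    n_longread: int = 20
    n_assembly: int = 20
    n_site_transcripts: int = 10       # transcripts over each intergenic site
    intergenic_spacer: int = 150
    tail_length: int = 300
    operons: list[list[str]] = field(default_factory=list)
    n_operon_transcripts: int = 5
    snp_site_ids: list[str] = field(default_factory=list)
    n_random_snps: int = 0
    n_error_positions: int = 0
    genome_id: str = "sim_organelle"
    circular: bool = False

    def validate(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate must be in [0, 1]")
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            raise ValueError("gene ids must be unique")
        for g in self.genes:
            if len(g.introns) != len(g.exon_lengths) - 1:
                raise ValueError(f"{g.gene_id}: need exon count - 1 introns")
            if any(l <= 0 for l in g.exon_lengths):
                raise ValueError(f"{g.gene_id}: exon lengths must be positive")
            if g.gene_type == "PROTEIN" and sum(g.exon_lengths) % 3 != 0:
                raise ValueError(f"{g.gene_id}: CDS length not a multiple of 3")
            for i in g.introns:
                if not 0.0 <= i.splice_prob <= 1.0:
                    raise ValueError(f"{g.gene_id}: splice_prob outside [0, 1]")
        for s in self.editing_sites:
            if not 0.0 <= s.efficiency <= 1.0:
                raise ValueError(f"{s.site_id}: efficiency outside [0, 1]")
            if not 0.0 <= s.minus1_pyrimidine_prob <= 1.0:
                raise ValueError(f"{s.site_id}: -1 bias outside [0, 1]")

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        genes = [GeneSpec(**{**g, "introns": [IntronSpec(**i)
                                              for i in g.get("introns", [])]})
                 for g in d.get("genes", [])]
        sites = [SiteSpec(**s) for s in d.get("editing_sites", [])]
        rest = {k: v for k, v in d.items() if k not in ("genes", "editing_sites")}
        return cls(genes=genes, editing_sites=sites, **rest)

    @classmethod
    def from_yaml(cls, path: str) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# Truth
# ---------------------------------------------------------------------------

@dataclass
class SiteTruth:
    site_id: str
    position: int                       # 0-based genomic
    strand: str                         # transcript sense
    gene_id: Optional[str]
    context: str                        # FeatureContext value
    intron_id: Optional[str]
    efficiency: float
    dependency_intron_id: Optional[str]
    gating_marginal: float              # splice prob of gate, 1.0 if ungated
    minus1_sense_base: str
    depth: int


@dataclass
class TranscriptTruth:
    gene_id: Optional[str]
    source: str
    states: list[str]                   # SPLICED/UNSPLICED per intron rank
    record_ids: list[str]
    edited_sites: list[str]


@dataclass
class TruthTable:
    sites: dict[str, SiteTruth] = field(default_factory=dict)
    transcripts: dict[str, TranscriptTruth] = field(default_factory=dict)
    ptu_transcripts: dict[str, list[str]] = field(default_factory=dict)
    operons: list[list[str]] = field(default_factory=list)
    snps: list[tuple[int, str, str]] = field(default_factory=list)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


@dataclass
class SimulationResult:
    config: SimulationConfig
    genome: OrganelleGenome
    genes: list[GeneModel]
    truth: TruthTable
    alignments: dict[Source, list[TranscriptAlignment]]
    pileup: list[PileupSite]
    snps: GenomicSnpSet


# ---------------------------------------------------------------------------
# Stage 1: genome and annotation
# ---------------------------------------------------------------------------

def _layout_gene(spec: GeneSpec, start: int, spacer: int):
    """Lay out one gene in local transcription coordinates, then map to the
    genome (minus-strand genes are mirrored so exon rank 1 is rightmost)."""
    n_exons = len(spec.exon_lengths)
    local: dict[str, tuple[int, int]] = {}
    cursor = 0
    for k in range(n_exons):
        local[f"e{k + 1}"] = (cursor, cursor + spec.exon_lengths[k])
        cursor += spec.exon_lengths[k]
        if k < n_exons - 1:
            intr = spec.introns[k]
            if intr.splice_class == "cis":
                local[f"i{k + 1}"] = (cursor, cursor + intr.length)
                cursor += intr.length
            else:
                da = intr.length // 2
                local[f"i{k + 1}a"] = (cursor, cursor + da)
                cursor += da + spacer
                local[f"i{k + 1}b"] = (cursor, cursor + (intr.length - da))
                cursor += intr.length - da
    total = cursor

    def to_genomic(iv: tuple[int, int]) -> tuple[int, int]:
        if spec.strand == "+":
            return (start + iv[0], start + iv[1])
        return (start + total - iv[1], start + total - iv[0])

    exons = [ExonInterval(*to_genomic(local[f"e{k + 1}"]), rank=k + 1)
             for k in range(n_exons)]
    halves = {}
    seg_idx, rank_segment = 1, {}
    rank_segment[1] = f"{spec.gene_id}.seg1"
    for k in range(1, n_exons):
        if spec.introns[k - 1].splice_class == "trans":
            seg_idx += 1
        rank_segment[k + 1] = f"{spec.gene_id}.seg{seg_idx}"
    for k in range(n_exons - 1):
        if spec.introns[k].splice_class == "trans":
            iid = f"{spec.gene_id}-i{k + 1}"
            halves[(iid, "donor")] = to_genomic(local[f"i{k + 1}a"])
            halves[(iid, "acceptor")] = to_genomic(local[f"i{k + 1}b"])
    introns = _derive_introns(spec.gene_id, spec.strand, exons,
                              rank_segment, halves)
    # attach configured splice probabilities by rank for the later stages
    probs = {k + 1: spec.introns[k].splice_prob for k in range(n_exons - 1)}
    segments = []
    for j in range(1, seg_idx + 1):
        ranks = [r for r, s in rank_segment.items()
                 if s == f"{spec.gene_id}.seg{j}"]
        ebr = {e.rank: e for e in exons}
        span = (min(ebr[r].start for r in ranks), max(ebr[r].end for r in ranks))
        segments.append(GeneSegment(f"{spec.gene_id}.seg{j}", spec.gene_id,
                                    spec.strand, sorted(ranks), span))
    gene = GeneModel(spec.gene_id, GeneType(spec.gene_type), spec.strand,
                     exons, introns, segments)
    return gene, probs, start + total


def _site_position(site: SiteSpec, gene: GeneModel) -> tuple[int, str, Optional[str]]:
    """Resolve a genic site spec to (genomic position, context, intron_id)."""
    if site.exon is not None:
        exon = gene.exon_by_rank(site.exon)
        if site.offset >= len(exon):
            raise ValueError(f"{site.site_id}: offset beyond exon")
        pos = (exon.start + site.offset if gene.strand == "+"
               else exon.end - 1 - site.offset)
        ctx = {GeneType.PROTEIN: FeatureContext.CDS,
               GeneType.TRNA: FeatureContext.TRNA,
               GeneType.RRNA: FeatureContext.RRNA}[gene.gene_type]
        return pos, ctx.value, None
    if site.intron is not None:
        intron = gene.introns[site.intron - 1]
        ivs = intron.transcribed_intervals()
        if not ivs:
            raise ValueError(f"{site.site_id}: trans intron without halves")
        iv = ivs[0]  # donor-side interval
        if gene.strand == "+":
            pos = iv[0] + site.offset
        else:
            pos = iv[1] - 1 - site.offset
        return pos, FeatureContext.INTRON.value, intron.intron_id
    raise ValueError(f"{site.site_id}: genic site needs exon or intron")


def simulate_genome_and_annotation(config: SimulationConfig,
                                   rng: Optional[np.random.Generator] = None,
                                   ) -> tuple[OrganelleGenome, list[GeneModel],
                                              TruthTable]:
    config.validate()
    if rng is None:
        rng = np.random.default_rng([config.seed, 0])
    spacer = config.intergenic_spacer
    genes: list[GeneModel] = []
    probs_by_gene: dict[str, dict[int, float]] = {}
    cursor = spacer
    for spec in config.genes:
        start = spec.start if spec.start is not None else cursor
        gene, probs, end = _layout_gene(spec, start, spacer)
        for prev in genes:
            ps, pe = prev.span
            gs, ge = gene.span
            if gs < pe and ps < ge:
                raise ValueError(f"planted genes {prev.gene_id} and "
                                 f"{gene.gene_id} overlap")
        genes.append(gene)
        probs_by_gene[gene.gene_id] = probs
        cursor = max(cursor, end) + spacer
    tail_start = cursor
    genome_len = tail_start + config.tail_length
    seq = rng.choice(list("ACGT"), size=genome_len)

    truth = TruthTable()
    gene_by_id = {g.gene_id: g for g in genes}
    n_intergenic = 0
    for site in config.editing_sites:
        if site.gene_id is not None:
            gene = gene_by_id[site.gene_id]
            pos, ctx, intron_id = _site_position(site, gene)
            strand = gene.strand
        else:
            pos = tail_start + 10 + 5 * n_intergenic
            n_intergenic += 1
            if pos >= genome_len - 2:
                raise ValueError("tail_length too small for intergenic sites")
            ctx, intron_id, strand = FeatureContext.INTERGENIC.value, None, site.strand
        # plant a sense-strand C and the biased -1 base
        seq[pos] = "C" if strand == "+" else "G"
        if rng.random() < site.minus1_pyrimidine_prob:
            m1 = "C" if rng.random() < 0.5 else "T"
        else:
            m1 = "A" if rng.random() < 0.5 else "G"
        if strand == "+":
            if pos > 0:
                seq[pos - 1] = m1
        else:
            seq[pos + 1] = revcomp(m1)
        gate_id, marginal = None, 1.0
        if site.dependency_intron is not None:
            gate_id = f"{site.gene_id}-i{site.dependency_intron}"
            marginal = probs_by_gene[site.gene_id][site.dependency_intron]
        truth.sites[site.site_id] = SiteTruth(
            site.site_id, int(pos), strand, site.gene_id, ctx, intron_id,
            site.efficiency, gate_id, marginal, m1,
            site.depth if site.depth is not None else config.depth)

    # DNA-level SNPs: at chosen editing sites, plus random intergenic ones
    site_positions = {t.position for t in truth.sites.values()}
    for sid in config.snp_site_ids:
        t = truth.sites[sid]
        ref = "C" if t.strand == "+" else "G"
        alt = "T" if t.strand == "+" else "A"
        truth.snps.append((t.position, ref, alt))
    placed = 0
    while placed < config.n_random_snps:
        pos = int(rng.integers(tail_start + 10 + 5 * n_intergenic + 5,
                               genome_len - 2))
        if pos in site_positions or any(p == pos for p, _, _ in truth.snps):
            continue
        seq[pos] = "C"
        truth.snps.append((pos, "C", "T"))
        placed += 1

    truth.operons = [list(op) for op in config.operons]
    genome = OrganelleGenome(config.genome_id, "".join(seq),
                             circular=config.circular)
    return genome, genes, truth


# ---------------------------------------------------------------------------
# Stage 2: transcripts
# ---------------------------------------------------------------------------

def _segment_chain_intervals(gene: GeneModel) -> list[dict]:
    """Per segment (transcription order): exon intervals, cis-intron intervals
    by rank, and adjacent trans-intron halves."""
    chains = []
    for seg in gene.segments:
        exons = [gene.exon_by_rank(r) for r in seg.exon_ranks]
        cis = {}
        for intron in gene.introns:
            if (intron.splice_class is SpliceClass.CIS
                    and intron.rank in seg.exon_ranks
                    and intron.rank + 1 in seg.exon_ranks):
                cis[intron.rank] = intron.interval
        chains.append({"segment": seg,
                       "exons": [(e.start, e.end) for e in exons],
                       "cis": cis})
    return chains


def _molecule_records(gene: GeneModel, states: dict[int, bool]
                      ) -> list[list[tuple[int, int]]]:
    """Block lists for the molecule(s) a splice-state draw produces; an
    unspliced trans intron splits the molecule into separate precursors."""
    chains = _segment_chain_intervals(gene)
    trans = {i.rank: i for i in gene.introns
             if i.splice_class is SpliceClass.TRANS}
    # group consecutive segments joined by spliced trans introns
    groups: list[list[int]] = [[0]]
    trans_after: list[Optional[IntronModel]] = []
    for j in range(len(chains) - 1):
        last_rank = chains[j]["segment"].exon_ranks[-1]
        intr = trans.get(last_rank)
        trans_after.append(intr)
        if intr is not None and states.get(intr.rank, False):
            groups[-1].append(j + 1)
        else:
            groups.append([j + 1])
    records = []
    for grp in groups:
        ivs: list[tuple[int, int]] = []
        for j in grp:
            ivs.extend(chains[j]["exons"])
            for rank, iv in chains[j]["cis"].items():
                if not states.get(rank, False):
                    ivs.append(iv)
            # retained trans halves at unspliced boundaries
            if j > 0:
                intr = trans_after[j - 1]
                if intr is not None and not states.get(intr.rank, False) \
                        and intr.acceptor_half is not None:
                    ivs.append(intr.acceptor_half)
            if j < len(chains) - 1:
                intr = trans_after[j]
                if intr is not None and not states.get(intr.rank, False) \
                        and intr.donor_half is not None:
                    ivs.append(intr.donor_half)
        ivs.sort()
        merged: list[list[int]] = []
        for s, e in ivs:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        records.append([(s, e) for s, e in merged])
    return records


def _render_record(tid: str, source: Source, strand: str, genome_seq: str,
                   genome_id: str, blocks: list[tuple[int, int]],
                   edits: dict[int, str], error_rate: float,
                   rng: np.random.Generator) -> TranscriptAlignment:
    parts, segs, qpos = [], [], 0
    for s, e in blocks:
        chunk = bytearray(genome_seq[s:e], "ascii")
        for pos, alt in edits.items():
            if s <= pos < e:
                chunk[pos - s] = ord(alt)
        if error_rate > 0:
            mask = rng.random(e - s) < error_rate
            for idx in np.flatnonzero(mask):
                cur = chr(chunk[idx])
                others = [b for b in "ACGT" if b != cur]
                chunk[idx] = ord(others[int(rng.integers(3))])
        parts.append(chunk.decode())
        segs.append((s, e, qpos))
        qpos += e - s
    return TranscriptAlignment(tid, source, strand, genome_id, list(blocks),
                               segs, "".join(parts))


def simulate_transcripts(config: SimulationConfig, genome: OrganelleGenome,
                         genes: list[GeneModel], truth: TruthTable,
                         rng: Optional[np.random.Generator] = None,
                         ) -> dict[Source, list[TranscriptAlignment]]:
    if rng is None:
        rng = np.random.default_rng([config.seed, 1])
    out: dict[Source, list[TranscriptAlignment]] = {Source.LONGREAD: [],
                                                    Source.ASSEMBLY: []}
    gene_by_id = {g.gene_id: g for g in genes}
    probs = {g.gene_id: {i.rank: spec.introns[i.rank - 1].splice_prob
                         for i in g.introns}
             for g, spec in zip(genes, config.genes)}
    sites_by_gene: dict[str, list[SiteTruth]] = {}
    for t in truth.sites.values():
        if t.gene_id is not None:
            sites_by_gene.setdefault(t.gene_id, []).append(t)

    for gene in genes:
        for source, n in ((Source.LONGREAD, config.n_longread),
                          (Source.ASSEMBLY, config.n_assembly)):
            for i in range(n):
                tid = f"{gene.gene_id}.{source.value.lower()}.{i}"
                states = {intr.rank: bool(rng.random() < probs[gene.gene_id][intr.rank])
                          for intr in gene.introns}
                records = _molecule_records(gene, states)
                edits: dict[int, str] = {}
                edited_ids = []
                for st in sites_by_gene.get(gene.gene_id, []):
                    on_molecule = any(s <= st.position < e
                                      for blocks in records for s, e in blocks)
                    if not on_molecule:
                        continue
                    gated_ok = True
                    if st.dependency_intron_id is not None:
                        rank = gene.intron_by_id(st.dependency_intron_id).rank
                        gated_ok = states.get(rank, False)
                    if gated_ok and rng.random() < st.efficiency:
                        edits[st.position] = "T" if st.strand == "+" else "A"
                        edited_ids.append(st.site_id)
                record_ids = []
                for j, blocks in enumerate(records):
                    rid = tid if len(records) == 1 else f"{tid}/seg{j + 1}"
                    record_ids.append(rid)
                    out[source].append(_render_record(
                        rid, source, gene.strand, genome.sequence,
                        genome.genome_id, blocks, edits,
                        config.error_rate, rng))
                truth.transcripts[tid] = TranscriptTruth(
                    gene.gene_id, source.value,
                    ["SPLICED" if states[i.rank] else "UNSPLICED"
                     for i in gene.introns],
                    record_ids, sorted(edited_ids))

    # transcripts over intergenic sites (strand per site, no splicing)
    for st in truth.sites.values():
        if st.gene_id is not None:
            continue
        lo = max(0, st.position - 100)
        hi = min(len(genome), st.position + 100)
        for source in (Source.LONGREAD, Source.ASSEMBLY):
            for i in range(config.n_site_transcripts):
                tid = f"{st.site_id}.{source.value.lower()}.{i}"
                edits = {}
                edited = bool(rng.random() < st.efficiency)
                if edited:
                    edits[st.position] = "T" if st.strand == "+" else "A"
                out[source].append(_render_record(
                    tid, source, st.strand, genome.sequence, genome.genome_id,
                    [(lo, hi)], edits, config.error_rate, rng))
                truth.transcripts[tid] = TranscriptTruth(
                    None, source.value, [], [tid],
                    [st.site_id] if edited else [])

    # polycistronic read-through transcripts (unspliced precursors)
    for k, operon in enumerate(config.operons):
        members = [gene_by_id[g] for g in operon]
        lo = min(g.span[0] for g in members)
        hi = max(g.span[1] for g in members)
        for i in range(config.n_operon_transcripts):
            tid = f"ptu{k + 1}.{i}"
            edits = {}
            for g in members:
                for st in sites_by_gene.get(g.gene_id, []):
                    if st.dependency_intron_id is None \
                            and rng.random() < st.efficiency:
                        edits[st.position] = "T" if st.strand == "+" else "A"
            out[Source.LONGREAD].append(_render_record(
                tid, Source.LONGREAD, members[0].strand, genome.sequence,
                genome.genome_id, [(lo, hi)], edits, config.error_rate, rng))
            truth.ptu_transcripts[tid] = list(operon)
    return out


# ---------------------------------------------------------------------------
# Stage 3: pileups and genomic SNPs
# ---------------------------------------------------------------------------

def simulate_pileups(config: SimulationConfig, genome: OrganelleGenome,
                     truth: TruthTable,
                     rng: Optional[np.random.Generator] = None,
                     ) -> tuple[list[PileupSite], GenomicSnpSet]:
    if rng is None:
        rng = np.random.default_rng([config.seed, 2])
    eps = config.error_rate
    pileup: list[PileupSite] = []
    for st in truth.sites.values():
        depth = st.depth
        e_eff = st.efficiency * st.gating_marginal
        k = int(rng.binomial(depth, e_eff))
        sense_bases = ["T"] * k + ["C"] * (depth - k)
        if eps > 0:
            mask = rng.random(depth) < eps
            for idx in np.flatnonzero(mask):
                others = [b for b in "ACGT" if b != sense_bases[idx]]
                sense_bases[idx] = others[int(rng.integers(3))]
        counts: dict[str, int] = {b: 0 for b in "ACGT"}
        for b in sense_bases:
            counts[b] += 1
        if st.strand == "+":
            fwd, rev = counts, {b: 0 for b in "ACGT"}
            ref, alt_n = "C", counts["T"]
        else:
            fwd = {b: 0 for b in "ACGT"}
            rev = {revcomp(b): n for b, n in counts.items()}
            ref, alt_n = "G", counts["T"]
        pileup.append(PileupSite(st.position, ref, fwd, rev,
                                 QUAL=qual_model(alt_n)))

    snp_set = GenomicSnpSet()
    site_positions = {t.position for t in truth.sites.values()}
    for pos, ref, alt in truth.snps:
        snp_set.add(pos, ref, alt)
        if pos not in site_positions:
            # homozygous DNA variant: RNA reads all show the alternate base
            fwd = {b: 0 for b in "ACGT"}
            fwd[alt] = config.depth
            pileup.append(PileupSite(pos, ref, fwd, {b: 0 for b in "ACGT"},
                                     QUAL=qual_model(config.depth)))

    if config.n_error_positions > 0 and eps > 0:
        used = site_positions | {p for p, _, _ in truth.snps}
        placed = 0
        while placed < config.n_error_positions:
            pos = int(rng.integers(1, len(genome) - 1))
            if pos in used:
                continue
            used.add(pos)
            placed += 1
            ref = genome.sequence[pos]
            if ref == "N":
                continue
            n_err = int(rng.binomial(config.depth, eps))
            fwd = {b: 0 for b in "ACGT"}
            fwd[ref] = config.depth - n_err
            others = [b for b in "ACGT" if b != ref]
            for _ in range(n_err):
                fwd[others[int(rng.integers(3))]] += 1
            alt_n = max(fwd[b] for b in others)
            pileup.append(PileupSite(pos, ref, fwd, {b: 0 for b in "ACGT"},
                                     QUAL=qual_model(alt_n)))
    pileup.sort(key=lambda s: s.position)
    return pileup, snp_set


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def run_simulation(config: SimulationConfig) -> SimulationResult:
    """Run all stages with per-stage generator streams derived from the seed."""
    genome, genes, truth = simulate_genome_and_annotation(
        config, np.random.default_rng([config.seed, 0]))
    alignments = simulate_transcripts(
        config, genome, genes, truth, np.random.default_rng([config.seed, 1]))
    pileup, snps = simulate_pileups(
        config, genome, truth, np.random.default_rng([config.seed, 2]))
    return SimulationResult(config, genome, genes, truth, alignments,
                            pileup, snps)


def save_simulation(result: SimulationResult, outdir: str) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_genome(result.genome, out / "genome.fa")
    write_annotation(result.genes, result.genome, out / "annotation.gff3")
    write_sam(result.alignments[Source.LONGREAD], result.genome,
              out / "longread.sam")
    write_sam(result.alignments[Source.ASSEMBLY], result.genome,
              out / "assembly.sam")
    write_pileup(result.pileup, out / "pileup.tsv")
    write_genomic_snps(result.snps, result.genome, out / "gdna.vcf")
    result.truth.to_json(out / "truth.json")
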