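"""Characterization of accepted C-to-U editing sites.

Covers feature-context assignment (precedence CDS > tRNA/rRNA exon > intron >
UTR > intergenic), codon effects of the C->U substitution under the standard
genetic code, hydropathy shifts on the Kyte-Doolittle scale and the IMGT
hydrophobicity ranking, the -1 (5'-adjacent, transcript orientation)
nucleotide preference, per-region editing-efficiency summaries, and
cross-sample shared-site counting.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from .aa_tables import IMGT_RANK, KYTE_DOOLITTLE
from .io import extract_spliced_cds, translate
from .model import (FeatureContext, GeneModel, GeneType, OrganelleGenome,
                    PYRIMIDINES, SpliceClass, revcomp)

EFFICIENT_VAF = 0.6   # threshold for an "efficiently edited" site


@dataclass
class CodonEffect:
    position: int
    gene_id: str
    codon_position: int          # 1..3
    ref_codon: str
    alt_codon: str
    aa_from: str
    aa_to: str
    synonymous: bool
    stop_gained: bool


@dataclass
class HydropathyChange:
    aa_from: str
    aa_to: str
    delta_kd: float
    imgt_rank_from: int
    imgt_rank_to: int
    direction: str               # INCREASE | DECREASE | NONE


_CONTEXT_PRECEDENCE = {FeatureContext.CDS: 0, FeatureContext.TRNA: 1,
                       FeatureContext.RRNA: 1, FeatureContext.INTRON: 2,
                       FeatureContext.UTR: 3, FeatureContext.INTERGENIC: 4}


def _gene_context(position: int, gene: GeneModel
                  ) -> Optional[tuple[FeatureContext, Optional[str]]]:
    for exon in gene.exons:
        if exon.start <= position < exon.end:
            ctx = {GeneType.PROTEIN: FeatureContext.CDS,
                   GeneType.TRNA: FeatureContext.TRNA,
                   GeneType.RRNA: FeatureContext.RRNA}[gene.gene_type]
            return ctx, None
    for intron in gene.introns:
        for s, e in intron.transcribed_intervals():
            if s <= position < e:
                return FeatureContext.INTRON, intron.intron_id
        if intron.splice_class is SpliceClass.CIS:
            s, e = intron.interval
            if s <= position < e:
                return FeatureContext.INTRON, intron.intron_id
    for iv in (gene.utr5, gene.utr3):
        if iv is not None and iv[0] <= position < iv[1]:
            return FeatureContext.UTR, None
    return None


def assign_feature_context(position: int, genes: Sequence[GeneModel],
                           strand: Optional[str] = None,
                           ) -> tuple[FeatureContext, Optional[str], Optional[str]]:
    """(context, gene_id, intron_id) for a genomic position.  Overlapping
    genes are resolved by context precedence, then by sense-strand match."""
    hits = []
    for gene in genes:
        res = _gene_context(position, gene)
        if res is not None:
            ctx, intron_id = res
            strand_match = 0 if (strand is None or gene.strand == strand) else 1
            hits.append((_CONTEXT_PRECEDENCE[ctx], strand_match,
                         ctx, gene.gene_id, intron_id))
    if not hits:
        return FeatureContext.INTERGENIC, None, None
    hits.sort(key=lambda h: (h[0], h[1]))
    _, _, ctx, gene_id, intron_id = hits[0]
    return ctx, gene_id, intron_id


def codon_effect(position: int, gene: GeneModel,
                 genome: OrganelleGenome) -> CodonEffect:
    """Effect of editing the sense-strand C at ``position`` in a CDS."""
    cds_idx = gene.cds_index_of(position)
    if cds_idx is None:
        raise ValueError(f"position {position} is not exonic in {gene.gene_id}")
    cds = extract_spliced_cds(gene, genome)
    if cds[cds_idx] != "C":
        raise ValueError(f"position {position}: sense base is {cds[cds_idx]}, "
                         "not C")
    codon_start = (cds_idx // 3) * 3
    codon_pos = cds_idx % 3 + 1
    ref_codon = cds[codon_start:codon_start + 3]
    alt_codon = (ref_codon[:codon_pos - 1] + "T" + ref_codon[codon_pos:])
    aa_from = translate(ref_codon)
    aa_to = translate(alt_codon)
    return CodonEffect(position, gene.gene_id, codon_pos, ref_codon,
                       alt_codon, aa_from, aa_to,
                       synonymous=(aa_from == aa_to),
                       stop_gained=(aa_to == "*" and aa_from != "*"))


def hydropathy_change(aa_from: str, aa_to: str) -> HydropathyChange:
    """Kyte-Doolittle delta and IMGT rank shift for one substitution; stops
    are excluded from hydropathy statistics by the caller."""
    for aa in (aa_from, aa_to):
        if aa not in KYTE_DOOLITTLE:
            raise ValueError(f"non-standard residue {aa!r}")
    delta = KYTE_DOOLITTLE[aa_to] - KYTE_DOOLITTLE[aa_from]
    direction = "INCREASE" if delta > 0 else ("DECREASE" if delta < 0 else "NONE")
    return HydropathyChange(aa_from, aa_to, delta,
                            IMGT_RANK[aa_from], IMGT_RANK[aa_to], direction)


def minus_one_base(position: int, strand: str,
                   genome: OrganelleGenome) -> Optional[str]:
    """Base immediately 5' of the edited C in transcript orientation, or None
    at the genome edge of a linear genome."""
    if strand == "+":
        if position == 0:
            if genome.circular:
                return genome.sequence[-1]
            return None
        return genome.sequence[position - 1]
    if position == len(genome) - 1:
        if genome.circular:
            return revcomp(genome.sequence[0])
        return None
    return revcomp(genome.sequence[position + 1])


def minus_one_context(sites: Iterable, genome: OrganelleGenome) -> pd.DataFrame:
    """Per-site -1 base (transcript orientation) for objects exposing
    ``position`` and ``strand``; use :func:`pyrimidine_fraction` to summarise."""
    rows = []
    for site in sites:
        base = minus_one_base(site.position, site.strand, genome)
        rows.append({"position": site.position, "strand": site.strand,
                     "minus1": base,
                     "pyrimidine": (base in PYRIMIDINES) if base else None})
    return pd.DataFrame(rows)


def pyrimidine_fraction(minus1: pd.DataFrame) -> float:
    defined = minus1.dropna(subset=["minus1"])
    if defined.empty:
        raise ValueError("no sites with a defined -1 base")
    return float(defined["pyrimidine"].mean())


def region_efficiency_summary(sites: Iterable) -> pd.DataFrame:
    """Per-context mean VAF, site count, and fraction of sites with
    VAF > 0.6, for objects exposing ``feature_context`` and ``VAF``."""
    rows = [{"context": str(getattr(s.feature_context, "value",
                                    s.feature_context)),
             "VAF": s.VAF} for s in sites]
    if not rows:
        raise ValueError("no sites to summarise")
    df = pd.DataFrame(rows)
    out = df.groupby("context")["VAF"].agg(
        mean_vaf="mean", n="count",
        fraction_efficient=lambda v: float((v > EFFICIENT_VAF).mean()))
    return out.reset_index()


def codon_position_distribution(effects: Iterable[CodonEffect]) -> dict[int, int]:
    counts = Counter(e.codon_position for e in effects)
    return {p: counts.get(p, 0) for p in (1, 2, 3)}


def shared_sites(site_sets: dict[str, set[tuple[str, int]]]) -> pd.DataFrame:
    """Per-gene shared/exclusive counts across samples.  Keys of
    ``site_sets`` are sample names; members are (gene_id, spliced-CDS
    coordinate) pairs expressed in a common per-gene frame."""
    samples = list(site_sets)
    genes = sorted({g for s in site_sets.values() for g, _ in s})
    rows = []
    for gene in genes:
        per_sample = {name: {c for g, c in sites if g == gene}
                      for name, sites in site_sets.items()}
        shared = set.intersection(*per_sample.values()) if samples else set()
        row = {"gene_id": gene,
               "shared": len(shared)}
        for name in samples:
            row[f"n_{name}"] = len(per_sample[name])
            row[f"exclusive_{name}"] = len(
                per_sample[name] - set.union(*(per_sample[o] for o in samples
                                               if o != name))
                if len(samples) > 1 else per_sample[name])
        rows.append(row)
    return pd.DataFrame(rows)
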