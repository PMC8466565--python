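"""C-to-U RNA-editing site identification from stranded pileups.

The caller combines three evidence paths and reconciles them:

* variant path — site-level thresholds on the pileup (DP >= 20, AD >= 5,
  QUAL >= 30 by default), aimed at intron/intergenic sites;
* CDS-confirmation path — a depth/edited-count check (DP >= 30, AD >= 5)
  for sites inside CDS/tRNA/rRNA features;
* transcript support — counts of long-read and assembly transcripts whose
  aligned base at the site is the edited (sense T) base; "more than
  two/three/five" transcripts are read literally as >= 3 / >= 4 / >= 6, and
  "more than half" as a strict majority.

Reconciliation order is fixed: genomic-SNP exclusion dominates everything;
CDS-confirmed sites need at least one covering assembly transcript;
variant-only sites need an assembly majority; assembly-supported sites
missing from the variant path are recovered only inside protein-coding
sequence.  Editing efficiency is the variant allele frequency VAF = AD/DP.
Only C-to-U (sense) changes are called; sense G->A candidates (reverse
U-to-C) are tallied for diagnostics and dropped.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import yaml

from .editing_annotate import assign_feature_context
from .model import (FeatureContext, GeneModel, GenomicSnpSet,
                    OrganelleGenome, PileupSite, SiteStatus, Source,
                    TranscriptAlignment)

logger = logging.getLogger("organellotx")

_GENIC = {FeatureContext.CDS, FeatureContext.TRNA, FeatureContext.RRNA}


@dataclass
class FilterConfig:
    # variant path (bcftools-style site filter)
    min_dp: int = 20
    min_ad: int = 5
    min_qual: float = 30.0
    # CDS/tRNA/rRNA confirmation path
    cds_min_depth: int = 30
    cds_min_edited: int = 5
    # transcript support ("more than two/three/five", "more than half")
    longread_min_cds: int = 3
    longread_min_nongenic: int = 4
    assembly_min: int = 6
    assembly_majority: float = 0.5

    def __post_init__(self) -> None:
        for name, val in self.__dict__.items():
            if val < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def from_yaml(cls, path: str) -> "FilterConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


@dataclass
class EditingSite:
    """A candidate (and possibly accepted) C-to-U editing event; ``position``
    is 0-based, strand is the transcript sense, AD counts the sense-strand
    edited base."""

    position: int
    strand: str
    DP: int
    AD: int
    QUAL: float
    feature_context: FeatureContext
    gene_id: Optional[str] = None
    intron_id: Optional[str] = None
    longread_edited: int = 0
    longread_covering: int = 0
    assembly_edited: int = 0
    assembly_covering: int = 0
    evidence: dict = field(default_factory=dict)
    status: Optional[SiteStatus] = None

    @property
    def VAF(self) -> float:
        return compute_vaf(self)

    @property
    def assembly_majority_fraction(self) -> float:
        if self.assembly_covering == 0:
            return 0.0
        return self.assembly_edited / self.assembly_covering


def compute_vaf(site) -> float:
    """Editing efficiency VAF = AD / DP."""
    if site.DP <= 0:
        raise ValueError("VAF undefined at zero depth")
    return site.AD / site.DP


# ---------------------------------------------------------------------------
# Candidate extraction
# ---------------------------------------------------------------------------

def candidate_sites(pileups: Iterable[PileupSite], genes: Sequence[GeneModel],
                    genome: OrganelleGenome,
                    ) -> tuple[list[EditingSite], Counter]:
    """Extract sense C->T mismatches as candidates; everything else is
    tallied and dropped.  Sense strand comes from the gene for genic sites
    and from the read-orientation majority for intergenic ones (ties are
    uninformative and dropped)."""
    candidates: list[EditingSite] = []
    tally: Counter = Counter()
    for site in pileups:
        ctx, gene_id, intron_id = assign_feature_context(site.position, genes)
        if ctx is FeatureContext.INTERGENIC:
            fwd = sum(site.counts_fwd.values())
            rev = sum(site.counts_rev.values())
            if fwd == rev:
                tally["strand_tie"] += 1
                logger.info("pos %d: intergenic strand tie, dropped",
                            site.position + 1)
                continue
            strand = "+" if fwd > rev else "-"
        else:
            gene = next(g for g in genes if g.gene_id == gene_id)
            strand = gene.strand
        if strand == "+":
            ref_needed, alt_base = "C", "T"
        else:
            ref_needed, alt_base = "G", "A"
        if site.ref_base != ref_needed:
            # not a C in the sense orientation; classify for diagnostics
            sense_ref = site.ref_base if strand == "+" else \
                site.ref_base.translate(str.maketrans("ACGT", "TGCA"))
            alts = {b: site.count(b, strand) for b in "ACGT"
                    if b != site.ref_base}
            if any(alts.values()):
                major = max(alts, key=alts.get)
                sense_alt = major if strand == "+" else \
                    major.translate(str.maketrans("ACGT", "TGCA"))
                tally[f"{sense_ref}>{sense_alt}"] += 1
            continue
        ad = site.count(alt_base, strand)
        candidates.append(EditingSite(
            position=site.position, strand=strand, DP=site.DP, AD=ad,
            QUAL=site.QUAL, feature_context=ctx, gene_id=gene_id,
            intron_id=intron_id))
    return candidates, tally


# ---------------------------------------------------------------------------
# Filter paths
# ---------------------------------------------------------------------------

def filter_variant_path(candidates: Iterable[EditingSite],
                        cfg: FilterConfig = FilterConfig(),
                        ) -> list[EditingSite]:
    """bcftools-style site filter: DP, AD and QUAL thresholds (inclusive)."""
    return [s for s in candidates
            if s.DP >= cfg.min_dp and s.AD >= cfg.min_ad
            and s.QUAL >= cfg.min_qual]


def cds_confirm(candidates: Iterable[EditingSite],
                cfg: FilterConfig = FilterConfig()) -> list[EditingSite]:
    """Depth/edited-count confirmation for CDS/tRNA/rRNA sites only;
    non-genic sites are out of this path's scope."""
    return [s for s in candidates
            if s.feature_context in _GENIC
            and s.DP >= cfg.cds_min_depth and s.AD >= cfg.cds_min_edited]


def transcript_support(site: EditingSite,
                       alignments_by_source: dict[Source, list[TranscriptAlignment]],
                       ) -> EditingSite:
    """Fill per-source covering/edited transcript counts for one site.  A
    transcript is edited at the site when its aligned base is the sense
    alternate (reference-orientation T on '+', A on '-')."""
    alt = "T" if site.strand == "+" else "A"
    for source, attr in ((Source.LONGREAD, "longread"),
                         (Source.ASSEMBLY, "assembly")):
        covering = edited = 0
        for aln in alignments_by_source.get(source, []):
            base = aln.base_at(site.position)
            if base is None:
                continue
            covering += 1
            if base == alt:
                edited += 1
        setattr(site, f"{attr}_covering", covering)
        setattr(site, f"{attr}_edited", edited)
    return site


def evaluate_evidence(site: EditingSite,
                      cfg: FilterConfig = FilterConfig()) -> dict:
    """Evidence flags derived from the stored counts."""
    genic = site.feature_context in _GENIC
    longread_min = cfg.longread_min_cds if genic else cfg.longread_min_nongenic
    evidence = {
        "variant_path": (site.DP >= cfg.min_dp and site.AD >= cfg.min_ad
                         and site.QUAL >= cfg.min_qual),
        "cds_confirmed": (genic and site.DP >= cfg.cds_min_depth
                          and site.AD >= cfg.cds_min_edited),
        "longread_support": site.longread_edited >= longread_min,
        "assembly_support": site.assembly_edited >= cfg.assembly_min,
        "assembly_majority": site.assembly_majority_fraction,
    }
    site.evidence = evidence
    return evidence


# ---------------------------------------------------------------------------
# Reconciliation
# ---------------------------------------------------------------------------

def reconcile(sites: Iterable[EditingSite], snps: GenomicSnpSet,
              cfg: FilterConfig = FilterConfig()) -> list[EditingSite]:
    """Assign a final status to every candidate.

    Rule order (fixed): (1) genomic-SNP positions are removed outright;
    (2) CDS-confirmed sites with no covering assembly transcript are removed,
    otherwise accepted; (3) variant-path sites outside the confirmation path
    are accepted only on an assembly majority; (4) assembly-supported sites
    missing from the variant path are recovered only in CDS; (5) everything
    else fails the filters.
    """
    out = []
    for site in sites:
        ev = evaluate_evidence(site, cfg)
        if site.position in snps:
            site.status = SiteStatus.REMOVED_SNP
        elif ev["cds_confirmed"]:
            if site.assembly_covering == 0:
                site.status = SiteStatus.REMOVED_NO_ASSEMBLY
            else:
                site.status = SiteStatus.ACCEPTED
        elif ev["variant_path"]:
            if ev["assembly_majority"] > cfg.assembly_majority:
                site.status = SiteStatus.ACCEPTED
            else:
                site.status = SiteStatus.REMOVED_FILTER
        elif ev["assembly_support"] and site.feature_context is FeatureContext.CDS:
            site.status = SiteStatus.RECOVERED
        else:
            site.status = SiteStatus.REMOVED_FILTER
        out.append(site)
    return out


def call_editing_sites(pileups: Iterable[PileupSite],
                       genes: Sequence[GeneModel],
                       genome: OrganelleGenome,
                       alignments_by_source: dict[Source, list[TranscriptAlignment]],
                       snps: GenomicSnpSet,
                       cfg: FilterConfig = FilterConfig(),
                       ) -> tuple[list[EditingSite], Counter]:
    """Full cascade: candidates -> transcript support -> reconciliation.
    Returns all candidates with statuses plus the dropped-mismatch tally."""
    candidates, tally = candidate_sites(pileups, genes, genome)
    for site in candidates:
        transcript_support(site, alignments_by_source)
    reconcile(candidates, snps, cfg)
    return candidates, tally


def accepted_sites(sites: Iterable[EditingSite]) -> list[EditingSite]:
    return [s for s in sites
            if s.status in (SiteStatus.ACCEPTED, SiteStatus.RECOVERED)]
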