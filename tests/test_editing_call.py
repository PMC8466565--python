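"""Editing caller: candidate extraction, filter paths, transcript support,
reconciliation (vs. an exhaustive truth-table oracle), and parameter
recovery on clean simulations."""

import itertools

import numpy as np
import pytest

from organellotx.editing_call import (EditingSite, FilterConfig,
                                      accepted_sites, call_editing_sites,
                                      candidate_sites, cds_confirm,
                                      compute_vaf, filter_variant_path,
                                      reconcile, transcript_support)
from organellotx.model import (FeatureContext, GenomicSnpSet, OrganelleGenome,
                               PileupSite, SiteStatus, Source)
from organellotx.simulate import (GeneSpec, SimulationConfig, SiteSpec,
                                  run_simulation)
from tests.conftest import make_alignment, make_cis_gene


def _pileup(pos, ref, qual=60, **counts):
    fwd = {b: counts.get(f"{b}f", 0) for b in "ACGT"}
    rev = {b: counts.get(f"{b}r", 0) for b in "ACGT"}
    return PileupSite(pos, ref, fwd, rev, QUAL=qual)


@pytest.fixture()
def plus_gene_setup():
    gene = make_cis_gene("g", n_introns=0, exon_len=90, start=100)
    genome = OrganelleGenome("chr", "A" * 100 + "C" * 90 + "A" * 60)
    return gene, genome


def test_candidate_arithmetic_plus_strand(plus_gene_setup):
    gene, genome = plus_gene_setup
    sites, _ = candidate_sites([_pileup(110, "C", Cf=7, Tf=13)],
                               [gene], genome)
    (s,) = sites
    assert (s.AD, s.DP) == (13, 20)
    assert compute_vaf(s) == pytest.approx(0.65)
    assert s.feature_context is FeatureContext.CDS


def test_candidate_minus_strand_is_sense_c_to_u():
    gene = make_cis_gene("g", n_introns=0, exon_len=90, start=100,
                         strand="-")
    genome = OrganelleGenome("chr", "A" * 250)
    sites, _ = candidate_sites([_pileup(110, "G", Gr=10, Ar=10)],
                               [gene], genome)
    (s,) = sites
    assert (s.strand, s.AD, s.DP) == ("-", 10, 20)


def test_non_c_to_u_mismatch_dropped(plus_gene_setup):
    gene, genome = plus_gene_setup
    sites, tally = candidate_sites([_pileup(110, "A", Af=10, Gf=10)],
                                   [gene], genome)
    assert sites == []
    assert tally["A>G"] == 1


def test_intergenic_strand_from_read_majority_and_tie_dropped():
    genome = OrganelleGenome("chr", "A" * 250)
    sites, _ = candidate_sites([_pileup(10, "C", Cf=8, Tf=12)], [], genome)
    assert sites[0].strand == "+"
    sites, tally = candidate_sites([_pileup(10, "C", Cf=10, Tr=10)],
                                   [], genome)
    assert sites == []
    assert tally["strand_tie"] == 1


def _site(dp, ad, qual, ctx=FeatureContext.CDS, pos=0, **kw):
    return EditingSite(position=pos, strand="+", DP=dp, AD=ad, QUAL=qual,
                       feature_context=ctx, **kw)


def test_variant_path_toy_table():
    """(DP, AD, QUAL) over five sites under DP>=20 & AD>=5 & QUAL>=30."""
    rows = [(25, 6, 40), (19, 6, 40), (25, 4, 40), (25, 6, 20), (30, 10, 60)]
    kept = filter_variant_path([_site(*r, pos=i) for i, r in enumerate(rows)])
    assert [(s.DP, s.AD, s.QUAL) for s in kept] == [(25, 6, 40), (30, 10, 60)]
    # boundary inclusivity
    assert filter_variant_path([_site(100, 5, 30)])
    assert not filter_variant_path([_site(19, 10, 60)])


def test_cds_confirmation_scope_and_boundaries():
    assert not cds_confirm([_site(29, 10, 60)])
    assert cds_confirm([_site(35, 5, 60)])
    # non-genic sites are out of this path's scope
    assert not cds_confirm([_site(100, 50, 60, ctx=FeatureContext.INTRON)])


def test_transcript_support_thresholds():
    genome = OrganelleGenome("chr", "C" * 200)
    site = _site(100, 50, 60, pos=50)

    def reads(n_edited, n_ref, source):
        alns = []
        for i in range(n_edited):
            alns.append(make_alignment([(0, 100)], tid=f"e{i}", source=source,
                                       genome=genome, edits={50: "T"}))
        for i in range(n_ref):
            alns.append(make_alignment([(0, 100)], tid=f"r{i}", source=source,
                                       genome=genome))
        return alns

    transcript_support(site, {Source.LONGREAD: reads(3, 2, Source.LONGREAD)})
    assert site.longread_edited == 3 and site.longread_covering == 5

    cfg = FilterConfig()
    from organellotx.editing_call import evaluate_evidence
    ev = evaluate_evidence(site, cfg)
    assert ev["longread_support"]          # CDS needs >= 3

    nongenic = _site(100, 50, 60, pos=50, ctx=FeatureContext.INTERGENIC)
    transcript_support(nongenic,
                       {Source.LONGREAD: reads(3, 2, Source.LONGREAD)})
    assert not evaluate_evidence(nongenic, cfg)["longread_support"]  # needs >= 4

    asm_site = _site(100, 50, 60, pos=50)
    transcript_support(asm_site,
                       {Source.ASSEMBLY: reads(6, 4, Source.ASSEMBLY)})
    ev = evaluate_evidence(asm_site, cfg)
    assert ev["assembly_support"]
    assert ev["assembly_majority"] == pytest.approx(0.6)


def test_uncovered_site_has_zero_support():
    site = _site(100, 50, 60, pos=500)
    genome = OrganelleGenome("chr", "C" * 200)
    transcript_support(site, {Source.LONGREAD: [
        make_alignment([(0, 100)], genome=genome)]})
    assert site.longread_covering == 0 and site.assembly_covering == 0


# ---------------------------------------------------------------------------
# Reconciliation
# ---------------------------------------------------------------------------

def test_reconcile_spec_cases():
    no_snps = GenomicSnpSet()
    # confirmed CDS site, no covering assembly transcript
    s1 = _site(50, 20, 60)
    (r1,) = reconcile([s1], no_snps)
    assert r1.status is SiteStatus.REMOVED_NO_ASSEMBLY
    # variant-kept intronic site with assembly majority 0.6
    s2 = _site(50, 20, 60, ctx=FeatureContext.INTRON,
               assembly_edited=6, assembly_covering=10)
    (r2,) = reconcile([s2], no_snps)
    assert r2.status is SiteStatus.ACCEPTED
    # assembly-supported CDS site missing from the variant path
    s3 = _site(10, 3, 5, assembly_edited=6, assembly_covering=10)
    (r3,) = reconcile([s3], no_snps)
    assert r3.status is SiteStatus.RECOVERED
    # same evidence outside CDS is not recovered
    s4 = _site(10, 3, 5, ctx=FeatureContext.INTRON,
               assembly_edited=6, assembly_covering=10)
    (r4,) = reconcile([s4], no_snps)
    assert r4.status is SiteStatus.REMOVED_FILTER


def test_snp_exclusion_is_absolute():
    snps = GenomicSnpSet({(0, "C", "T")})
    # overwhelming evidence cannot rescue a genomic SNP position
    s = _site(500, 400, 60, assembly_edited=50, assembly_covering=50)
    (r,) = reconcile([s], snps)
    assert r.status is SiteStatus.REMOVED_SNP


def _oracle_status(variant_kept, confirmed, asm_support, majority_gt_half,
                   snp, context, asm_covering):
    """Documented reconciliation rules, written independently."""
    if snp:
        return SiteStatus.REMOVED_SNP
    if confirmed:
        return (SiteStatus.REMOVED_NO_ASSEMBLY if asm_covering == 0
                else SiteStatus.ACCEPTED)
    if variant_kept:
        return (SiteStatus.ACCEPTED if majority_gt_half
                else SiteStatus.REMOVED_FILTER)
    if asm_support and context is FeatureContext.CDS:
        return SiteStatus.RECOVERED
    return SiteStatus.REMOVED_FILTER


def test_reconcile_matches_truth_table_oracle():
    """All 2^5 evidence combinations x feature contexts."""
    contexts = [FeatureContext.CDS, FeatureContext.INTRON,
                FeatureContext.INTERGENIC]
    for ctx in contexts:
        for bits in itertools.product([False, True], repeat=5):
            variant_kept, confirmed, asm_support, majority, snp = bits
            if confirmed and ctx not in (FeatureContext.CDS,
                                         FeatureContext.TRNA,
                                         FeatureContext.RRNA):
                continue   # confirmation path only applies to genic sites
            # DP/AD/QUAL chosen so the derived flags match the intent:
            # confirmation needs DP >= 30 (genic), the variant path needs
            # DP >= 20 & AD >= 5 & QUAL >= 30
            if confirmed and variant_kept:
                dp, ad, qual = 50, 20, 60
            elif confirmed:
                dp, ad, qual = 30, 5, 10
            elif variant_kept:
                dp, ad, qual = 25, 10, 60
            else:
                dp, ad, qual = 19, 4, 10
            if asm_support:
                asm_edit, asm_cov = 6, (10 if majority else 20)
            else:
                asm_edit, asm_cov = (4, 6) if majority else (0, 10)
            site = _site(dp, ad, qual, ctx=ctx, pos=7,
                         assembly_edited=asm_edit,
                         assembly_covering=asm_cov)
            snps = GenomicSnpSet({(7, "C", "T")} if snp else set())
            (res,) = reconcile([site], snps)
            expect = _oracle_status(
                variant_kept, confirmed, asm_support,
                site.assembly_majority_fraction > 0.5, snp, ctx,
                site.assembly_covering)
            assert res.status is expect, (bits, ctx)


def test_threshold_monotonicity(rng):
    """Raising any threshold never increases the accepted-site count."""
    sites_raw = []
    for i in range(1000):
        sites_raw.append(dict(
            dp=int(rng.integers(1, 80)), ad=int(rng.integers(0, 40)),
            qual=float(rng.integers(0, 70)),
            ctx=FeatureContext.CDS if rng.random() < 0.5
            else FeatureContext.INTRON,
            asm_edit=int(rng.integers(0, 12)),
            asm_cov_extra=int(rng.integers(0, 12))))

    def count_accepted(cfg):
        sites = [
            _site(r["dp"], min(r["ad"], r["dp"]), r["qual"], ctx=r["ctx"],
                  pos=i, assembly_edited=r["asm_edit"],
                  assembly_covering=r["asm_edit"] + r["asm_cov_extra"])
            for i, r in enumerate(sites_raw)]
        return len(accepted_sites(reconcile(sites, GenomicSnpSet(), cfg)))

    base = FilterConfig()
    n0 = count_accepted(base)
    for change in (dict(min_dp=30), dict(min_ad=8), dict(min_qual=45),
                   dict(cds_min_depth=40), dict(cds_min_edited=8),
                   dict(assembly_min=8), dict(assembly_majority=0.7)):
        n1 = count_accepted(FilterConfig(**change))
        assert n1 <= n0, change


# ---------------------------------------------------------------------------
# End-to-end parameter recovery
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def clean_call_sim():
    rng = np.random.default_rng(77)
    genes, sites = [], []
    for g in range(6):
        gid = f"g{g}"
        genes.append(GeneSpec(gid, [300], []))
        for k in range(10):
            sites.append(SiteSpec(f"{gid}_s{k}", gid, exon=1, offset=2 + 6 * k,
                                  efficiency=float(rng.uniform(0.3, 1.0))))
    cfg = SimulationConfig(seed=78, genes=genes, editing_sites=sites,
                           depth=120, error_rate=0.003,
                           n_longread=10, n_assembly=10,
                           n_error_positions=60)
    res = run_simulation(cfg)
    called, _ = call_editing_sites(res.pileup, res.genes, res.genome,
                                   res.alignments, res.snps)
    return res, called


def test_precision_and_recall_on_clean_simulation(clean_call_sim):
    res, called = clean_call_sim
    truth_pos = {t.position for t in res.truth.sites.values()}
    accepted = {s.position for s in accepted_sites(called)}
    tp = len(accepted & truth_pos)
    precision = tp / len(accepted)
    recall = tp / len(truth_pos)
    assert precision >= 0.95
    assert recall >= 0.95


def test_vaf_estimates_unbiased(clean_call_sim):
    res, called = clean_call_sim
    truth_by_pos = {t.position: t.efficiency
                    for t in res.truth.sites.values()}
    errs = [s.VAF - truth_by_pos[s.position]
            for s in accepted_sites(called) if s.position in truth_by_pos]
    errs = np.array(errs)
    se = np.sqrt(0.25 / 120 / len(errs))   # conservative binomial SE bound
    assert abs(errs.mean()) < 3 * se


def test_compute_vaf_degenerate_cases():
    assert compute_vaf(_site(50, 0, 60)) == 0.0
    assert compute_vaf(_site(50, 50, 60)) == 1.0
    with pytest.raises(ValueError, match="zero depth"):
        compute_vaf(EditingSite(position=0, strand="+", DP=0, AD=0, QUAL=0,
                                feature_context=FeatureContext.CDS))
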