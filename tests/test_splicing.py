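"""Splice-state classification, intermediates, trans events, support table,
junction discrepancies — with a brute-force interval oracle."""

import numpy as np
import pytest

from organellotx.model import Source, SpliceClass, SpliceState
from organellotx.simulate import (GeneSpec, IntronSpec, SimulationConfig,
                                  run_simulation)
from organellotx.splicing import (classify_splice_states,
                                  detect_trans_splicing,
                                  enumerate_intermediates,
                                  intron_support_table,
                                  junction_discrepancies,
                                  splice_order_events)
from tests.conftest import make_alignment, make_cis_gene

S, U, C, A = (SpliceState.SPLICED, SpliceState.UNSPLICED,
              SpliceState.UNCOVERED, SpliceState.AMBIGUOUS)


def test_partial_splicing_pattern():
    """Gaps at introns 1 and 3 with a block across intron 2 give
    (SPLICED, UNSPLICED, SPLICED)."""
    gene = make_cis_gene(n_introns=3, exon_len=30, intron_len=20, start=100)
    i1, i2, i3 = [i.interval for i in gene.introns]
    blocks = [(100, i1[0]), (i1[1], i3[0]), (i3[1], 300)]
    vec = classify_splice_states(make_alignment(blocks), gene, 0)
    assert vec.states == [S, U, S]


def test_single_block_is_all_unspliced():
    gene = make_cis_gene(n_introns=3)
    vec = classify_splice_states(make_alignment([gene.span]), gene, 0)
    assert vec.states == [U, U, U]


def test_tolerance_boundary():
    gene = make_cis_gene(n_introns=1)
    (intron,) = gene.introns
    s, e = intron.interval
    off = make_alignment([(gene.span[0], s + 1), (e, gene.span[1])])
    assert classify_splice_states(off, gene, 0).states == [A]
    assert classify_splice_states(off, gene, 2).states == [S]


def test_partial_intron_dip_is_uncovered_not_unspliced():
    gene = make_cis_gene(n_introns=1, exon_len=30, intron_len=20, start=100)
    (intron,) = gene.introns
    # alignment ends a few bases into the intron
    aln = make_alignment([(100, intron.start + 5)])
    assert classify_splice_states(aln, gene, 0).states == [C]


def test_strand_mismatch_rejected():
    gene = make_cis_gene(n_introns=1)
    with pytest.raises(ValueError, match="strand"):
        classify_splice_states(make_alignment([gene.span], strand="-"),
                               gene, 0)


# ---------------------------------------------------------------------------
# Intermediates
# ---------------------------------------------------------------------------

def test_all_eight_intermediates_recovered():
    cfg = SimulationConfig(
        seed=21, genes=[GeneSpec("g", [30, 30, 30, 30],
                                 [IntronSpec(20, "cis", 0.5)] * 3)],
        n_longread=200, n_assembly=0)
    res = run_simulation(cfg)
    (gene,) = res.genes
    vecs = [classify_splice_states(a, gene, 0)
            for a in res.alignments[Source.LONGREAD]]
    patterns = enumerate_intermediates(vecs, gene)
    assert len(patterns) == 8
    assert sum(patterns.values()) == 200


def test_zero_intron_gene_single_empty_pattern():
    gene = make_cis_gene(n_introns=0, exon_len=30)
    vecs = [classify_splice_states(make_alignment([gene.span], tid=f"t{i}"),
                                   gene, 0) for i in range(5)]
    patterns = enumerate_intermediates(vecs, gene)
    assert patterns == {(): 5}


def test_pattern_count_bounded_by_two_to_k(nad4_like_sim):
    res = nad4_like_sim
    (gene,) = res.genes
    vecs = [classify_splice_states(a, gene, 0)
            for a in res.alignments[Source.LONGREAD]]
    patterns = enumerate_intermediates(vecs, gene)
    assert len(patterns) <= 2 ** len(gene.introns)
    eligible = sum(1 for v in vecs
                   if all(s in (S, U) for s in v.states))
    assert sum(patterns.values()) == eligible


# ---------------------------------------------------------------------------
# Trans splicing and splice order
# ---------------------------------------------------------------------------

def test_trans_event_detection(nad5_like_sim):
    res = nad5_like_sim
    (gene,) = res.genes
    trans_ids = {i.intron_id for i in gene.introns
                 if i.splice_class is SpliceClass.TRANS}
    assert trans_ids == {"nad5-i2", "nad5-i3"}
    for tid, tt in res.truth.transcripts.items():
        alns = [a for a in res.alignments[Source(tt.source)]
                if a.transcript_id in tt.record_ids]
        detected = {e.intron_id for a in alns
                    for e in detect_trans_splicing(a, gene)}
        expected = {i.intron_id for i, st in zip(gene.introns, tt.states)
                    if i.splice_class is SpliceClass.TRANS and st == "SPLICED"}
        assert detected == expected


def test_segment_confined_transcript_yields_no_event(nad5_like_sim):
    res = nad5_like_sim
    (gene,) = res.genes
    seg1 = gene.segments[0]
    aln = make_alignment([seg1.span], strand=gene.strand)
    assert detect_trans_splicing(aln, gene) == []


def test_mature_trans_with_retained_cis_intron():
    """Trans introns spliced while cis intron 1 is retained: two trans
    events plus a state vector showing the retention."""
    cfg = SimulationConfig(
        seed=22, genes=[GeneSpec(
            "nad5", [60, 60, 60, 63],
            [IntronSpec(50, "cis", 0.0), IntronSpec(60, "trans", 1.0),
             IntronSpec(60, "trans", 1.0)])],
        n_longread=1, n_assembly=0)
    res = run_simulation(cfg)
    (gene,) = res.genes
    (aln,) = res.alignments[Source.LONGREAD]
    events = detect_trans_splicing(aln, gene)
    assert {e.intron_id for e in events} == {"nad5-i2", "nad5-i3"}
    vec = classify_splice_states(aln, gene, 0)
    assert vec.states == [U, S, S]
    report = splice_order_events([vec], gene)
    assert aln.transcript_id in report["trans_before_cis"]
    assert report["cis_before_trans"] == []


def test_cis_before_trans_precursor():
    cfg = SimulationConfig(
        seed=23, genes=[GeneSpec(
            "nad1", [60, 60, 60], [IntronSpec(50, "cis", 1.0),
                                   IntronSpec(60, "trans", 0.0)])],
        n_longread=1, n_assembly=0)
    res = run_simulation(cfg)
    (gene,) = res.genes
    alns = res.alignments[Source.LONGREAD]
    assert len(alns) == 2      # two precursor records
    vecs = [classify_splice_states(a, gene, 0) for a in alns]
    report = splice_order_events(vecs, gene)
    ids = {a.transcript_id for a in alns}
    # the precursor carrying the spliced cis intron is in the class
    assert set(report["cis_before_trans"]) <= ids
    assert len(report["cis_before_trans"]) == 1
    assert report["trans_before_cis"] == []


def test_fully_spliced_transcript_in_neither_order_class():
    cfg = SimulationConfig(
        seed=24, genes=[GeneSpec(
            "g", [60, 60, 60], [IntronSpec(50, "cis", 1.0),
                                IntronSpec(60, "trans", 1.0)])],
        n_longread=1, n_assembly=0)
    res = run_simulation(cfg)
    (gene,) = res.genes
    vecs = [classify_splice_states(a, gene, 0)
            for a in res.alignments[Source.LONGREAD]]
    report = splice_order_events(vecs, gene)
    assert report == {"trans_before_cis": [], "cis_before_trans": []}


# ---------------------------------------------------------------------------
# Support table
# ---------------------------------------------------------------------------

def test_support_table_definitions():
    gene = make_cis_gene(n_introns=1, exon_len=30, intron_len=20, start=100)
    (intron,) = gene.introns
    spliced = make_alignment([(100, intron.start), (intron.end, 180)],
                             source=Source.LONGREAD)
    df = intron_support_table(
        [gene], {Source.LONGREAD: [spliced], Source.ASSEMBLY: []})
    row = df.iloc[0]
    assert bool(row["LONGREAD"]) and not bool(row["ASSEMBLY"])

    df_empty = intron_support_table(
        [gene], {Source.LONGREAD: [], Source.ASSEMBLY: []})
    row = df_empty.iloc[0]
    assert not bool(row["LONGREAD"]) and not bool(row["ASSEMBLY"])


def test_support_table_monotone_in_transcripts(nad4_like_sim):
    res = nad4_like_sim
    lr = res.alignments[Source.LONGREAD]
    prev = None
    for n in (5, 20, len(lr)):
        df = intron_support_table(res.genes,
                                  {Source.LONGREAD: lr[:n]})
        cur = df["LONGREAD"].tolist()
        if prev is not None:
            assert all(not p or c for p, c in zip(prev, cur))
        prev = cur


# ---------------------------------------------------------------------------
# Junction discrepancies
# ---------------------------------------------------------------------------

def test_junction_discrepancy_offset_reported():
    gene = make_cis_gene(n_introns=1, exon_len=30, intron_len=20, start=100)
    (intron,) = gene.introns
    s, e = intron.interval
    shifted = [make_alignment([(100, s + 2), (e, 180)], tid=f"t{i}")
               for i in range(5)]
    (disc,) = junction_discrepancies(shifted, [gene], min_support=3)
    assert (disc.side, disc.offset, disc.support) == ("donor", 2, 5)


def test_junction_discrepancy_clean_annotation_empty():
    gene = make_cis_gene(n_introns=1)
    (intron,) = gene.introns
    s, e = intron.interval
    alns = [make_alignment([(gene.span[0], s), (e, gene.span[1])],
                           tid=f"t{i}") for i in range(5)]
    assert junction_discrepancies(alns, [gene]) == []


def test_junction_discrepancy_needs_support():
    gene = make_cis_gene(n_introns=1)
    (intron,) = gene.introns
    s, e = intron.interval
    one = [make_alignment([(gene.span[0], s + 2), (e, gene.span[1])])]
    assert junction_discrepancies(one, [gene], min_support=3) == []


# ---------------------------------------------------------------------------
# Oracle equivalence and full recovery
# ---------------------------------------------------------------------------

def _oracle_state(blocks, intron, tolerance):
    """Direct interval comparison over every (gap, intron) pair."""
    gaps = [(e1, s2) for (_, e1), (s2, _) in zip(blocks, blocks[1:])]
    for gs, ge in gaps:
        if abs(gs - intron.start) <= tolerance and \
                abs(ge - intron.end) <= tolerance:
            return S
    if any(min(ge, intron.end) - max(gs, intron.start) > 0
           for gs, ge in gaps):
        return A
    if intron.splice_class is SpliceClass.TRANS:
        return C
    interior = set(range(intron.start, intron.end))
    covered = set()
    for bs, be in blocks:
        covered.update(range(max(bs, intron.start), min(be, intron.end)))
    return U if interior <= covered else C


def test_classification_equals_brute_force_oracle(rng):
    gene = make_cis_gene(n_introns=3, exon_len=30, intron_len=20, start=100)
    lo, hi = gene.span
    for tol in (0, 2):
        for _ in range(1000):
            # random alignment: random breakpoints within the gene span
            cuts = sorted(rng.integers(lo - 10, hi + 10, size=6).tolist())
            blocks = []
            for s, e in zip(cuts[::2], cuts[1::2]):
                if e > s and (not blocks or s > blocks[-1][1]):
                    blocks.append((s, e))
            if not blocks:
                continue
            vec = classify_splice_states(make_alignment(blocks), gene, tol)
            expect = [_oracle_state(blocks, i, tol) for i in gene.introns]
            assert vec.states == expect


def test_perfect_recovery_on_clean_simulation():
    """With no sequencing error and zero tolerance, classification matches
    the generator's truth for every one of >= 1000 cis transcripts."""
    cfg = SimulationConfig(
        seed=25, genes=[GeneSpec("g", [40, 40, 40, 42],
                                 [IntronSpec(30, "cis", 0.5)] * 3)],
        n_longread=600, n_assembly=600, error_rate=0.0)
    res = run_simulation(cfg)
    (gene,) = res.genes
    by_id = {a.transcript_id: a
             for alns in res.alignments.values() for a in alns}
    checked = 0
    for tid, tt in res.truth.transcripts.items():
        vec = classify_splice_states(by_id[tid], gene, 0)
        assert [s.value for s in vec.states] == tt.states
        checked += 1
    assert checked >= 1000
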