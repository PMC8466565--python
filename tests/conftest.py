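"""Shared fixtures: small hand-built gene models and standard simulations."""

import numpy as np
import pytest

from organellotx.model import (ExonInterval, GeneModel, GeneType, IntronModel,
                               OrganelleGenome, SpliceClass, Source,
                               TranscriptAlignment)
from organellotx.simulate import (GeneSpec, IntronSpec, SimulationConfig,
                                  SiteSpec, run_simulation)


def make_alignment(blocks, tid="t1", source=Source.LONGREAD, strand="+",
                   genome=None, edits=None):
    """Alignment whose query is the reference slice with optional edits."""
    query = None
    segs = []
    if genome is not None:
        parts, qpos = [], 0
        for s, e in blocks:
            chunk = bytearray(genome.sequence[s:e], "ascii")
            for pos, alt in (edits or {}).items():
                if s <= pos < e:
                    chunk[pos - s] = ord(alt)
            parts.append(chunk.decode())
            segs.append((s, e, qpos))
            qpos += e - s
        query = "".join(parts)
    else:
        qpos = 0
        for s, e in blocks:
            segs.append((s, e, qpos))
            qpos += e - s
    return TranscriptAlignment(tid, source, strand, "chr", list(blocks),
                               segs, query)


def make_cis_gene(gene_id="g", exon_len=30, intron_len=20, n_introns=3,
                  start=100, strand="+", gene_type=GeneType.PROTEIN):
    """Equal-sized exon/intron ladder; plus-strand layout regardless of
    strand label (rank follows transcription order only for '+')."""
    exons, introns = [], []
    pos = start
    n_exons = n_introns + 1
    for k in range(n_exons):
        rank = k + 1 if strand == "+" else n_exons - k
        exons.append(ExonInterval(pos, pos + exon_len, rank))
        pos += exon_len
        if k < n_introns:
            pos += intron_len
    exons.sort(key=lambda e: e.rank)
    for k in range(n_introns):
        up = next(e for e in exons if e.rank == k + 1)
        down = next(e for e in exons if e.rank == k + 2)
        s, e = ((up.end, down.start) if strand == "+"
                else (down.end, up.start))
        introns.append(IntronModel(f"{gene_id}-i{k + 1}", SpliceClass.CIS,
                                   s, e, rank=k + 1))
    return GeneModel(gene_id, gene_type, strand, exons, introns)


@pytest.fixture(scope="session")
def nad4_like_sim():
    """Three cis introns spliced independently at p=0.5, two editing sites
    in the last exon (one gated by intron 3), moderate depth."""
    cfg = SimulationConfig(
        seed=101,
        genes=[GeneSpec("nad4", [99, 120, 90, 150],
                        [IntronSpec(80, "cis", 0.5),
                         IntronSpec(70, "cis", 0.5),
                         IntronSpec(60, "cis", 0.5)])],
        editing_sites=[
            SiteSpec("gated", "nad4", exon=4, offset=5, efficiency=0.9,
                     dependency_intron=3),
            SiteSpec("free", "nad4", exon=4, offset=33, efficiency=0.9)],
        depth=300, n_longread=100, n_assembly=100)
    return run_simulation(cfg)


@pytest.fixture(scope="session")
def nad5_like_sim():
    """Mixed cis/trans gene (trans i2, i3) for trans-splicing tests."""
    cfg = SimulationConfig(
        seed=103,
        genes=[GeneSpec("nad5", [60, 60, 60, 60, 63],
                        [IntronSpec(50, "cis", 0.5),
                         IntronSpec(60, "trans", 0.5),
                         IntronSpec(60, "trans", 0.5),
                         IntronSpec(40, "cis", 0.5)])],
        n_longread=50, n_assembly=50)
    return run_simulation(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
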