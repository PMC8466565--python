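# Methods

## Coordinate and annotation model

All internal coordinates are 0-based half-open on the reference; GFF3, VCF
and the pileup TSV (all 1-based inclusive) are converted at the I/O boundary
only.  Exon `rank` is 1-based in transcription order, so exon 1 of a
minus-strand gene is the genomically rightmost exon.  Introns are not read
from the annotation but derived as inter-exon gaps: intron *k* joins exon
ranks *k* and *k*+1.  A trans-spliced gene is modelled as one gene with
multiple `GeneSegment`s (contiguously transcribed exon runs); the gap
between two segments is a TRANS intron, whose transcribed halves (the
`-i1a`/`-i1b` pieces flanking the fragmentation point) may be annotated as
explicit `intron` features and are then treated as intronic sequence for
feature-context assignment and as precursor-transcript sequence in the
simulator.  Multi-copy introns (e.g. inverted-repeat duplicates) are simply
introns of distinct gene copies and never conflated.

Circular genomes are handled by linearization; the only circular-aware
operation is the −1 base lookup at the origin.  Spliced CDS extraction
concatenates exons in rank order, reverse-complementing minus-strand genes,
and translates with the standard genetic code (table 1, standard for plant
organelles; an internal reference stop only warns, since editing may create
or remove stops).

## Splice-state classification

An intron is **SPLICED** on a transcript when some inter-block gap of the
alignment matches the intron interval with both endpoints within a tolerance
τ (bp); **UNSPLICED** when the blocks cover the full intron interior and no
gap touches the intron; **UNCOVERED** when the alignment does not reach the
intron — including when it only dips partially into an intron end, which
avoids calling retention from terminal alignment fray; **AMBIGUOUS** when a
gap overlaps the intron but violates τ.  τ defaults to 0 (synthetic data);
2–3 bp is appropriate for real long-read alignments.  A trans intron is
never UNSPLICED on a single molecule: no physical precursor contains it, so
segment-confined alignments contribute UNCOVERED and trans-intron retention
is inferred only at the population level (the `cis_before_trans` splice-order
class and the interplay module's precursor class).

Intermediate enumeration counts distinct state patterns over transcripts
whose every intron is decided (SPLICED/UNSPLICED); the pattern space is
bounded by 2^k.  Junction-discrepancy reporting relaxes τ to a window
(default 10 bp), takes the modal transcript gap coordinate per intron side,
and reports non-zero offsets supported by a configurable number of
transcripts (default 3) — an automated replacement for manual boundary
curation.

## PTU inference

A transcript nominates a candidate PTU when ≥ 2 same-strand genes each have
≥ `coverage_fraction` (default 1.0, i.e. full coverage) of their exonic
length inside its blocks; genes reaching 0.5 but not the threshold are
listed as `partial` members and excluded from statistics.  Transcripts that
join segments of a trans-spliced gene to neighbouring genes are products of
trans-splicing rather than read-through transcription and are excluded (and
reported).  Candidates merge by transitive closure under "same strand ∧
(shared gene ∨ span overlap ≥ 1 bp)"; merging is idempotent and
input-order invariant, and conserves the gene set.  Each merged PTU — whose
members share one transcription direction by construction — is postulated
as one operon.  The co-transcription fraction counts protein-coding genes
only in its denominator; tRNA/rRNA genes may be PTU members but are not
counted.

## Editing-site identification

Candidates are sense C→U mismatches only: reference C with T alternate for
plus-sense positions, reference G with A alternate for minus-sense.  Sense
orientation comes from the annotated gene for genic sites and from the
read-strand majority for intergenic sites (the data are strand-specific);
ties are uninformative and dropped with a log message.  Reverse (U-to-C)
events are not called — they are essentially absent in angiosperm
organelles — but sense G→A candidates are tallied for diagnostics.

Three evidence paths feed a fixed-order reconciliation:

1. **Genomic-SNP exclusion** dominates everything: a site at a DNA-level
   variant position is removed regardless of other evidence.
2. **Confirmation path** (CDS/tRNA/rRNA sites): DP ≥ 30 and edited count
   ≥ 5.  Confirmed sites with *no* covering assembly transcript are removed;
   otherwise they are accepted.  The variant path is not additionally
   required here: the site-level filter exists for regions the confirmation
   path does not cover.
3. **Variant path** (DP ≥ 20 ∧ AD ≥ 5 ∧ QUAL ≥ 30, boundaries inclusive):
   non-confirmed sites passing it are accepted only on a strict assembly
   majority (> 0.5 of covering assembly transcripts edited).
4. **Recovery** (last): assembly-supported sites (≥ 6 edited transcripts)
   missing from the variant path are recovered only inside protein-coding
   sequence.

"More than two/three/five" transcript thresholds are read literally as
≥ 3 / ≥ 4 / ≥ 6 and "more than half" as strictly > 0.5; all thresholds live
in `FilterConfig` and are overridable.  Whether the non-genic long-read
threshold counts edited or merely covering transcripts is ambiguous in
common usage; this package counts *edited* transcripts.  QUAL is carried
opaque and only thresholded — callers define it differently and the
pipeline does not model it.  Editing efficiency is VAF = AD/DP, with AD the
sense-strand edited-base count.

Raising any threshold never increases the accepted-site count (verified by
property test), and accepted/recovered sites never coincide with genomic
SNPs.

## Editing characterization

Feature context uses the precedence CDS > tRNA/rRNA exon > intron > UTR >
intergenic, breaking remaining ties by sense-strand match.  Codon effects
apply the C→T substitution at the site's spliced-CDS offset and re-translate;
by construction the edited protein differs at exactly the affected residue
(or nowhere, for synonymous changes), and position-3 edits of a C are always
synonymous under the standard code (verified exhaustively over all 64
codons).  Hydropathy uses the bundled Kyte–Doolittle scale and the IMGT
hydrophobicity ranking (I most hydrophobic … R least, with the three-class
partition hydrophobic I–A / neutral W–H / hydrophilic N–R); stop-gaining
changes are reported but excluded from hydropathy statistics, since stops
have no hydropathy value.  The −1 base is the genome base immediately 5′ of
the edited C in transcript orientation (reverse-complemented for minus-sense
sites); sites at the edge of a linear genome have no defined −1 base and are
excluded from the pyrimidine fraction.  Cross-sample shared-site counting is
a per-gene set intersection over (gene, spliced-CDS coordinate) pairs; the
caller is responsible for expressing coordinates in a common frame
(cross-species alignment is out of scope).

## Splice-dependent editing

Distances to junctions are counted in exonic bases with the first exonic
base adjacent to the junction equal to 1 — chosen so that "6 bp downstream
of the intron" denotes the sixth exonic base after the acceptor.  Ties
between two equidistant introns break toward the upstream intron.  Every
accepted exonic site within a window (default 50 bp, comfortably above the
longest splice-dependent distance the test data produce) of a junction is
tested: transcripts covering the site with a decided intron state form a
2×2 table {edited, unedited} × {SPLICED, UNSPLICED}.  A spliced-edited
event is flagged when both classes hold ≥ `min_per_class` (5) molecules,
the unspliced edited fraction is ≤ `eps` (0.05) and the spliced edited
fraction is ≥ `delta` (0.5); a two-sided Fisher exact test is reported
alongside but does not gate the flag.  This rule is this package's
formalization of what is otherwise assessed by inspection; all parameters
are exposed.  For trans introns the SPLICED class comes from trans-splice
events and the UNSPLICED class from segment precursors (alignments covering
the site but confined to one segment); no inference is made about the order
of segment assembly and splicing.  Intronic sites are annotated with their
distance but never tested — their presence on unspliced molecules is
expected, as intronic editing typically *enables* splicing.

## Synthetic data generator

The generator emulates the statistical structure of full-length organelle
transcript data rather than its sequence content:

* **Splicing**: each intron of each simulated molecule splices independently
  with probability p (default 0.5 — a modelling choice; per-intron splice
  probabilities are not established quantities).  Unspliced trans introns
  split the molecule into separate precursor records sharing an id prefix,
  mirroring how unspliced trans pre-RNAs appear as separate molecules.
* **Editing**: each site has a true efficiency e ∈ [0, 1]; on transcripts,
  a site is edited with probability e when its gating intron (if any) is
  spliced on that molecule and never otherwise; in pileups the edited count
  is Binomial(depth, e·m) with m the gate's marginal splice probability.
  Editing is applied before sequencing error, so errors can also revert
  edited bases.
* **Sequence context**: site reference bases are forced to sense-strand C
  and the −1 base is drawn as a pyrimidine with a configurable probability
  (default 0.93).
* **Noise and confounders**: a uniform per-base error rate ε (default 0),
  error-only pileup rows, DNA-level SNPs emitted both to the genomic VCF and
  as near-fixed RNA mismatches, and polycistronic read-through transcripts
  over configured operons.
* **QUAL** is `min(60, 3·alt_count)` — arbitrary but deterministic and
  monotone, so threshold behaviour is testable; it does not reproduce any
  caller's quality model, and QUAL-threshold behaviour on real data is not
  claimed.

One global seed drives separate numpy Generator streams per stage (genome,
transcripts, pileups), so regenerating one stage leaves the others
unchanged; identical configurations produce byte-identical outputs.

What the generator does *not* emulate: alignment artefacts (indels,
soft-clips, multi-mapping), coverage heterogeneity along transcripts,
basecall-quality strings, or realistic sequence composition.  Passing tests
therefore demonstrate the correctness of the classification/filtering logic
under the stated generative model, not performance on real libraries —
junction tolerance, depth filters and QUAL behaviour in particular will
differ on real alignments.

## Problem sizes and numerical choices

The test suite and the acceptance script run simulations of desk scale —
hundreds to a few thousand sites at depths 100–2000, tens to hundreds of
transcripts per gene — chosen so the binomial sampling error of each
recovered quantity is several times smaller than the tolerance asserted on
it (e.g. a single site at efficiency 0.935 and depth 2000 has SE ≈ 0.006).
Degenerate inputs are handled explicitly: zero-depth sites are an error for
VAF; empty contexts are omitted from summaries; intergenic strand ties and
junction-distance ties are logged; genes without introns are rejected by the
distance computation.
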