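# Methods

## Scope and data model

`aimchip` implements the downstream, post-peak-calling half of a
multi-experiment transcription-factor ChIP-seq study together with its
companion expression and repeat analyses. It consumes called peaks
(ENCODE narrowPeak or the MACS2 `peaks.xls` dialect), a genome FASTA and
a gene-level GFF3; it does not map reads or call peaks.

All intervals are 0-based half-open internally; GFF3 and MACS2 `.xls`
coordinates (1-based inclusive) are converted only at the I/O boundary,
and q-values are stored on probability scale (the −log10 form is an I/O
detail). MACS2 run with `--call-summits` emits one row per summit; rows
sharing coordinates are merged into one peak carrying several summit
offsets. The narrowPeak "no summit" sentinel (point source −1) maps to
an empty summit list, and a −log10(q) of −1 ("not available") maps to
q = 1 rather than breaking the q ∈ [0, 1] invariant. In the `.xls`
dialect both `start` and `abs_summit` are 1-based, so the summit offset
is `abs_summit − start`, the same value MACS2 writes to the narrowPeak
point-source column.

## Consensus detection

Peaks are filtered at fold enrichment ≥ 4 over the matched control
(inclusive). Two filter modes exist: `column` (default) trusts the
fold-enrichment column the peak caller produced; `control` divides each
peak's value by the best overlapping control peak's value first. A peak
associates with gene G when it overlaps the intergenic window adjacent
to G's 5′ end — from the 5′ boundary to the nearest annotated gene
boundary, capped at `max_distance` (default 3000 bp, wide enough for
multi-kb peaks while bounding spurious association; annotation-based
promoter windows are not otherwise derivable since UTRs are not
modelled) — or overlaps G's body. A peak wholly between two divergent
genes therefore reports both.

The consensus is computed on **gene lists**, not intervals, because the
question asked is "which genes are bound in every experiment": per
experiment the associated-gene sets are formed, the union is partitioned
into Venn membership classes by per-gene membership, and peaks sharing
an identical associated-gene set across all experiments form one
consensus locus. An interval mode (single-linkage clustering at ≥ 1 bp
overlap) is provided for generality and is oracle-tested against an
all-pairs overlap search.

## Orientation and promoters

A locus is classed by the median of its member-peak summits (summits
are the unit of binding localisation; a locus straddling a gene edge is
classed by where it summits). A summit inside a gene body is
`intragenic`; otherwise the flanking genes decide: a left neighbour on
the − strand or a right neighbour on the + strand faces the locus with
its 5′ end. Two facing 5′ ends → `divergent_pair` (both genes
returned), one → `single_gene`, none → `tail_to_tail` (no genes
returned; flagged for exclusion from promoter analyses since such a
region is a promoter for neither flanking gene). Contig-edge loci with
one flank degrade to the single-flank case.

Promoter extraction returns the full intergenic interval abutting the
gene's 5′ boundary, with the sequence reported on the gene's sense
strand so motif positions convert to "bp upstream of the start codon"
(gene models are anchored at the start codon; UTRs are not modelled). A
motif's upstream offset is the distance from its proximal edge to the
5′ boundary.

## Motif scanning and concordance

The AIM is the 13 bp degenerate pattern CGG-N7-CGG. Scanning uses
overlap-tolerant regex lookahead on the uppercased sequence; both
strands are scanned by default (the motif is not its own reverse
complement and strandedness of binding is unknown), with minus-strand
hits being CCG-N7-CCG occurrences on the forward strand. `N` in the
subject never matches a pattern literal, so masked sequence cannot
produce hits. The repeat-associated conserved 14-mer is scanned as an
IUPAC-degenerate consensus with a mismatch budget (default 1) by a
sliding Hamming comparison; the consensus itself must be supplied by
the user (it is not hard-coded; the simulator carries its own synthetic
14-mer, `TCATGACGTCATGA`, inside the repeat ITRs).

A locus is motif–summit **concordant** when some hit's midpoint lies
within `window` bp of some summit of any member peak. The window
defaults to 50 bp — typical summit resolution — and is a parameter;
reported results state it. Loci without motifs are `no_motif`; loci
with motifs but no summit within the window (or no summits at all) are
`motif_without_summit_match`.

## Repeat family and RIP census

Copy search is seed-and-extend: exact 12-mers of the seed (both
orientations) are located in the genome, hits are clustered by implied
unit start within a 16 bp band, and each candidate window is aligned
glocally to the seed (match +1, mismatch −1, gap open −4, gap
extend −1; window/seed overhangs free) with Biopython's
`PairwiseAligner`. Identity is matches / alignment columns × 100 over
the aligned core; candidates pass at ≥ 75% identity over ≥ 80% of the
seed length, and overlapping candidates merge keeping the best. The
scoring's stiff gap-open favours the contiguous 1–2 bp indels real
RIP'd families show. The search is deterministic and is oracle-tested
against exhaustive window alignment on toy genomes.

ITR detection compares the unit position-wise against its own reverse
complement and takes the maximal-scoring prefix (+1 per complementary
match, −3 per mismatch): terminal self-complementarity scores upward
until the boundary, after which random sequence (expected 25% matches)
drives the score down at slope −2, so the argmax sits at the planted
boundary. A detection requires length ≥ 20 bp and identity ≥ 80%; the
statistic is exactly symmetric under reverse complement. Gapped ITRs
are a known limitation: an indel inside an ITR shifts the positional
comparison and can shorten the reported length.

Copies are star-aligned: each member is globally aligned to the
reference copy and projected onto reference columns; insertions
relative to the reference are recorded as events, not columns. The
census counts a column as variant when ≥ 1 member differs there.
Substitution columns are classed transition (A↔G, C↔T) or transversion
by the majority of differing member bases, ties to transversion (a
conservative choice; multi-class columns are rare at realistic copy
numbers). Contiguous gap runs count as one deletion event each, with a
run shared identically by several members counted once. The invariant
transitions + transversions = substitution columns is enforced by test.

## ΔΔCt quantification and classification

Technical replicates are averaged per biological replicate;
ΔCt = Ct_target − Ct_reference; ΔΔCt subtracts the mean baseline ΔCt
(baseline: control strain, non-inducing condition); per-replicate
fold = 2^(−ΔΔCt). The reported fold is the arithmetic mean over
biological replicates, then renormalised so the baseline cell reads
exactly 1 (the published convention of setting the uninduced control to
one); SEM is on the fold scale. A geometric-mean mode is available
since arithmetic aggregation of ratios carries a small convexity bias.
Replicates lacking a reference measurement are dropped with a warning.

Contrasts use Welch's t-test on per-replicate log2 folds (a robust
default; the classic pooled-variance form is available via
`equal_var=True`), checked against a label-permutation oracle.

Classification applies twofold rules to mean folds, with mutant effects
taken as ratios against the matched-condition control: "greater than
twofold decreased" is strict (< 0.5×), "twofold or greater increase" is
inclusive (≥ 2×). Precedence: decreases in every available
mutant × condition cell → `positive_2_and_5`; any increase with no
decreases → `negative`; no mutant effect but a ≥ 2× inducer effect in
the control → `cm_only`; nothing at threshold → `no_effect`; anything
else → `mixed`, with the triggering comparisons listed. Missing cells
are skipped and the call flagged incomplete. No multiple-testing
correction is applied by default (matching common qPCR practice at this
scale); Benjamini–Hochberg is available in the enrichment module where
many categories are tested.

## Category enrichment

One-sided Fisher exact per category — the hypergeometric upper tail
P(X ≥ k) for k query hits among n query genes, K category members in a
background of N annotated genes — with BH adjustment across tested
categories (minimum category size 2). Query genes without any category
annotation are dropped and counted. Web annotation services implement
unpublished variants of this test, so results are comparable in kind
(which categories are over-represented), not guaranteed identical in
p-value.

## The synthetic study

The generator emulates the study design end to end from one seeded
NumPy generator drawn in fixed order (genome → motif plants → repeat
family → peaks → Ct tables), so a seed reproduces byte-identical
fixture files.

**Genome.** 9 contigs × 20 genes (≈ 325 kb), gene lengths 900–1500 bp,
intergenic gaps 400–800 bp, strands following the repeating pattern
`++--` so single-gene, divergent and tail-to-tail gap configurations
all occur. One AIM is planted per promoter gap at 170 bp upstream of an
anchor gene's start codon. After assembly the contigs are scanned and
every AIM occurrence outside a planted footprint is destroyed by
mutating a CGG-core base, so the background is provably motif-free:
a genome-wide scan returns exactly the planted motifs.

**Peaks.** Four treatment experiments (two factors × two growth
conditions) share a planted core of 70 loci — 32 single-gene, 33
divergent, 5 tail-to-tail — mirroring the attrition a four-way
consensus analysis narrates (70 → 65 promoter loci → 32/33 split).
Core peaks span their gap (tail-to-tail peaks extend 30 bp into each
flanking gene body, which is how such loci acquire gene associations in
real data), carry fold enrichment drawn uniformly in [4, 30), q-values
log-uniform in [1e−8, 2.2e−3], and summit exactly on the planted motif
midpoint (summit jitter defaults to 0 so plant/recover is exact; a
jitter parameter exists). Ten extra loci per experiment are drawn from
the leftover promoter pool to populate partial Venn classes; matched
controls carry only background peaks with fold < 4.

**Repeat family.** A 310 bp master unit X + core + revcomp(X) with
|X| = 78 (ITR), the synthetic 14-mer at the unit's outer ends, planted
in 11 tail-to-tail gaps (copy 0 unmutated, odd copies
reverse-complemented). Non-reference copies receive C:G→T:A transitions
at 0.04 per C:G site, transversions at 0.005 per site, and indels at
0.0007 per site — chosen by expectation arithmetic so an 11-copy family
yields a census of the same order as a RIP'd fungal repeat family: tens
of variant columns with transitions dominating roughly 4:1 and rare
1–2 bp indels. An optional CpA/TpG-context mode restricts transitions
to the dinucleotide context biological RIP prefers. Every introduced
change is recorded in the truth table; copies are redrawn if mutation
happens to create an AIM.

**Ct tables.** 4 biological × 3 technical replicates per
gene × strain × condition. The reference gene's Ct is constant (plus
noise); a target's Ct is baseline − log2(fold) plus per-measurement
Gaussian noise (sd 0.2 cycles by default, a realistic qPCR replicate
spread). Planted genes cover one regulatory archetype each: an AOX-like
gene (18-fold inducer response, collapse in either knockout), a
factor-dependent but inducer-blind gene, a negatively regulated gene,
an inducer-only gene and a null gene.

**What the simulation does not emulate.** Read-level artefacts
(mappability, GC bias, fragment-size effects), peak-caller behaviour
(the fold-enrichment and q columns are planted, not re-derived from
coverage), overlapping genes and UTRs, repeat copies inside gene
bodies, amplification-efficiency differences between qPCR assays, and
biological replicate effects beyond i.i.d. Gaussian Ct noise. Passing
plant/recover therefore validates the downstream logic, not the peak
caller or the wet-lab pipeline.

## Problem sizes and numerics

Default analyses run on the ≈ 325 kb / 180-gene study (seconds on one
CPU); oracle tests use toy genomes of 4–8 kb where exhaustive window
alignment is feasible, and Monte-Carlo recovery uses 200 seeded Ct
tables and 20 seeded mutation runs. The permutation oracle for the
Welch test uses 20,000 shuffles with a matching Monte-Carlo tolerance.
Ties in the ITR score take the shortest maximal prefix; the master
unit's construction guarantees the base past the ITR breaks
self-complementarity so the planted length is well defined. Peaks with
equal coordinates are merged at read time; all writers sort output so
runs are byte-reproducible.
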