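"""Orientation classification of binding loci and promoter extraction.

A consensus binding locus in an intergenic region is classed by which
flanking gene ends face it: one facing 5' end makes it a candidate
promoter for a single gene; two facing 5' ends put it upstream of a
divergently transcribed pair (either or both genes may be its target);
two facing 3' ends (tail-to-tail) make it a promoter for neither flanking
gene, and such loci are flagged for exclusion from promoter-centric
analyses.  Loci whose summit falls inside a gene body are intragenic.

The summit is the unit of binding localisation: a locus partially
overlapping a gene body but summitting in the intergenic region is
classed by the summit position.
"""

from __future__ import annotations

import warnings

from aimchip.models import (
    BindingLocus,
    GeneModel,
    GenomeSequence,
    OrientationClass,
    PromoterRegion,
)
from aimchip.motifs import revcomp


def _sorted_by_contig(annotation: list[GeneModel]) -> dict[str, list[GeneModel]]:
    by_contig: dict[str, list[GeneModel]] = {}
    for g in annotation:
        by_contig.setdefault(g.contig_id, []).append(g)
    for genes in by_contig.values():
        genes.sort(key=lambda g: g.start)
    return by_contig


def _reference_point(locus: BindingLocus) -> int:
    """Summit consensus position: median of member summits, else midpoint."""
    summits = locus.summits
    if summits:
        return summits[len(summits) // 2]
    return (locus.start + locus.end) // 2


def classify_locus(
    locus: BindingLocus, annotation: list[GeneModel]
) -> tuple[OrientationClass, list[GeneModel]]:
    """Class a locus by orientation and return the genes it can drive.

    Returns (class, genes in correct orientation): the host gene for
    intragenic loci, the facing gene for single-gene loci, both genes for
    divergent pairs, and no genes for tail-to-tail loci.
    """
    genes = _sorted_by_contig(annotation).get(locus.contig_id, [])
    point = _reference_point(locus)
    for g in genes:
        if g.start <= point < g.end:
            return OrientationClass.INTRAGENIC, [g]
    left = None
    right = None
    for g in genes:
        if g.end <= point:
            left = g
        elif g.start > point and right is None:
            right = g
            break
    oriented: list[GeneModel] = []
    if left is not None and left.strand == "-":
        oriented.append(left)
    if right is not None and right.strand == "+":
        oriented.append(right)
    if len(oriented) == 2:
        return OrientationClass.DIVERGENT_PAIR, oriented
    if len(oriented) == 1:
        return OrientationClass.SINGLE_GENE, oriented
    return OrientationClass.TAIL_TO_TAIL, []


def extract_promoter(
    gene: GeneModel,
    annotation: list[GeneModel],
    genome: list[GenomeSequence],
) -> tuple[PromoterRegion, str]:
    """Return the full upstream intergenic region and its sense-strand sequence.

    The region runs from the gene's 5' boundary to the nearest annotated
    gene boundary on that side (or the contig end).  For a minus-strand
    gene the sequence is reverse-complemented so motif positions read as
    distances upstream of the start codon.  A zero-length region is
    returned (with a warning) when the neighbouring gene abuts directly.
    """
    contig = next((c for c in genome if c.contig_id == gene.contig_id), None)
    if contig is None:
        raise KeyError(f"contig {gene.contig_id!r} not in genome")
    neighbours = _sorted_by_contig(annotation).get(gene.contig_id, [])
    if gene.strand == "+":
        left_bound = 0
        for g in neighbours:
            if g.gene_id != gene.gene_id and g.end <= gene.start:
                left_bound = max(left_bound, g.end)
        start, end = left_bound, gene.start
    else:
        right_bound = len(contig)
        for g in neighbours:
            if g.gene_id != gene.gene_id and g.start >= gene.end:
                right_bound = min(right_bound, g.start)
        start, end = gene.end, right_bound
    if start >= end:
        warnings.warn(f"gene {gene.gene_id!r}: zero-length upstream intergenic region")
        start = end
    region = PromoterRegion(gene.gene_id, gene.contig_id, start, end, gene.strand)
    seq = contig.sequence[start:end]
    if gene.strand == "-":
        seq = revcomp(seq)
    return region, seq


def upstream_offset(hit_start: int, hit_end: int, gene: GeneModel) -> int:
    """Distance from a motif's proximal edge to the gene's start codon.

    A motif "170 bp upstream of the predicted start codon" ends 170 bp
    before the 5' boundary on the gene's sense strand.
    """
    if gene.strand == "+":
        return gene.start - hit_end
    return hit_start - gene.end
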