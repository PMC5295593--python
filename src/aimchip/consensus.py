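"""Fold-enrichment filtering, gene association and multi-experiment consensus.

The study design behind this module: four ChIP experiments (two factors x
two growth conditions) each yield a MACS2 peak set; peaks with at least
fourfold enrichment over the matched control are kept, associated with
nearby genes, and the gene lists are intersected across all four
experiments.  Loci present in every experiment form the consensus most
likely to be authentic heterodimer binding sites.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

from intervaltree import IntervalTree

from aimchip.models import BindingLocus, GeneModel, Peak

logger = logging.getLogger(__name__)

DEFAULT_ENRICHMENT_THRESHOLD = 4.0
DEFAULT_MAX_DISTANCE = 3000


def filter_by_enrichment(
    peaks: list[Peak], threshold: float = DEFAULT_ENRICHMENT_THRESHOLD
) -> list[Peak]:
    """Keep peaks with fold enrichment >= threshold ("fourfold or higher"
    is inclusive).  Order is preserved; the operation is monotone in the
    threshold."""
    kept = [p for p in peaks if p.fold_enrichment >= threshold]
    logger.info(
        "enrichment filter >= %.3g: %d of %d peaks retained",
        threshold,
        len(kept),
        len(peaks),
    )
    return kept


@dataclass
class ExperimentPeakSet:
    """One experiment's peaks after filtering, plus its gene list."""

    experiment_id: str
    peaks: list[Peak]
    associations: dict[int, frozenset[str]] = field(default_factory=dict)

    @property
    def associated_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for genes in self.associations.values():
            out.update(genes)
        return frozenset(out)


def _promoter_intervals(
    annotation: list[GeneModel],
    contig_lengths: dict[str, int] | None,
    max_distance: int,
) -> dict[str, IntervalTree]:
    """Per contig: interval tree of 5'-adjacent intergenic windows.

    A gene's promoter window runs from its 5' boundary to the nearest
    annotated gene boundary (or contig end), capped at ``max_distance``.
    """
    trees: dict[str, IntervalTree] = {}
    by_contig: dict[str, list[GeneModel]] = {}
    for g in annotation:
        by_contig.setdefault(g.contig_id, []).append(g)
    for contig_id, genes in by_contig.items():
        tree = IntervalTree()
        ordered = sorted(genes, key=lambda g: g.start)
        for i, g in enumerate(ordered):
            if g.strand == "+":
                left_bound = ordered[i - 1].end if i > 0 else 0
                start = max(left_bound, g.start - max_distance)
                end = g.start
            else:
                right_bound = (
                    ordered[i + 1].start
                    if i + 1 < len(ordered)
                    else (contig_lengths or {}).get(contig_id, g.end + max_distance)
                )
                start = g.end
                end = min(right_bound, g.end + max_distance)
            if start < end:
                tree[start:end] = g.gene_id
        trees[contig_id] = tree
    return trees


def _body_intervals(annotation: list[GeneModel]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for g in annotation:
        trees.setdefault(g.contig_id, IntervalTree())[g.start : g.end] = g.gene_id
    return trees


def associate_peaks_to_genes(
    peaks: list[Peak],
    annotation: list[GeneModel],
    max_distance: int = DEFAULT_MAX_DISTANCE,
    contig_lengths: dict[str, int] | None = None,
) -> dict[int, frozenset[str]]:
    """Map each peak (by list index) to the set of genes it is tied to.

    A peak is associated with gene G if it overlaps the intergenic window
    adjacent to G's 5' end (within ``max_distance``) or overlaps G's body.
    A peak wholly between two divergent genes therefore reports both; a
    peak on a contig with no annotated genes reports an empty set with a
    warning.
    """
    promoter_trees = _promoter_intervals(annotation, contig_lengths, max_distance)
    body_trees = _body_intervals(annotation)
    result: dict[int, frozenset[str]] = {}
    for i, peak in enumerate(peaks):
        if peak.contig_id not in promoter_trees:
            warnings.warn(
                f"peak {peak.name!r} on contig {peak.contig_id!r} absent from annotation"
            )
            result[i] = frozenset()
            continue
        genes: set[str] = set()
        for iv in promoter_trees[peak.contig_id].overlap(peak.start, peak.end):
            genes.add(iv.data)
        for iv in body_trees[peak.contig_id].overlap(peak.start, peak.end):
            genes.add(iv.data)
        result[i] = frozenset(genes)
    return result


def venn_partition(gene_sets: dict[str, set]) -> dict[frozenset[str], set]:
    """Partition the union of 2-8 named sets into membership classes.

    Keys are frozensets of set names; the class keyed by all names is the
    consensus.  Classes are disjoint and cover the union (empty classes
    are included so callers can tabulate full Venn counts).
    """
    if not (2 <= len(gene_sets) <= 8):
        raise ValueError(f"venn_partition needs 2-8 sets, got {len(gene_sets)}")
    names = sorted(gene_sets)
    partition: dict[frozenset[str], set] = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            partition[frozenset(combo)] = set()
    universe = set().union(*gene_sets.values())
    for item in universe:
        members = frozenset(n for n in names if item in gene_sets[n])
        partition[members].add(item)
    return partition


def _cluster_by_overlap(peaks: list[Peak]) -> list[list[Peak]]:
    """Single-linkage clustering of peaks by >=1 bp interval overlap."""
    clusters: list[list[Peak]] = []
    for contig in sorted({p.contig_id for p in peaks}):
        ordered = sorted(
            (p for p in peaks if p.contig_id == contig), key=lambda p: (p.start, p.end)
        )
        current: list[Peak] = []
        current_end = -1
        for p in ordered:
            if current and p.start < current_end:
                current.append(p)
                current_end = max(current_end, p.end)
            else:
                if current:
                    clusters.append(current)
                current = [p]
                current_end = p.end
        if current:
            clusters.append(current)
    return clusters


def build_consensus_loci(
    experiment_sets: list[ExperimentPeakSet],
    mode: str = "gene",
    require_all: bool = True,
) -> list[BindingLocus]:
    """Group peaks across experiments into binding loci.

    ``gene`` mode (the default, matching how the published Venn was
    computed on gene lists): peaks sharing an identical associated gene
    set form one locus.  ``interval`` mode: single-linkage clustering by
    >=1 bp interval overlap.  With ``require_all`` only loci present in
    every experiment (the consensus) are returned; otherwise all loci are
    returned and callers can inspect ``experiments_present``.
    """
    all_ids = frozenset(s.experiment_id for s in experiment_sets)
    loci: list[BindingLocus] = []
    if mode == "gene":
        grouped: dict[tuple[str, frozenset[str]], dict[str, list[Peak]]] = {}
        for eset in experiment_sets:
            for i, peak in enumerate(eset.peaks):
                genes = eset.associations.get(i, frozenset())
                if not genes:
                    continue
                key = (peak.contig_id, genes)
                grouped.setdefault(key, {}).setdefault(eset.experiment_id, []).append(peak)
        for n, ((contig, genes), members) in enumerate(
            sorted(grouped.items(), key=lambda kv: (kv[0][0], min(p.start for ps in kv[1].values() for p in ps)))
        ):
            all_peaks = [p for ps in members.values() for p in ps]
            loci.append(
                BindingLocus(
                    locus_id=f"locus_{n + 1:04d}",
                    contig_id=contig,
                    start=min(p.start for p in all_peaks),
                    end=max(p.end for p in all_peaks),
                    member_peaks=members,
                    associated_genes=genes,
                )
            )
    elif mode == "interval":
        tagged: list[Peak] = []
        gene_lookup: dict[int, frozenset[str]] = {}
        for eset in experiment_sets:
            for i, peak in enumerate(eset.peaks):
                gene_lookup[id(peak)] = eset.associations.get(i, frozenset())
                tagged.append(peak)
        for n, cluster in enumerate(_cluster_by_overlap(tagged)):
            members: dict[str, list[Peak]] = {}
            genes: set[str] = set()
            for p in cluster:
                members.setdefault(p.experiment_id, []).append(p)
                genes.update(gene_lookup[id(p)])
            loci.append(
                BindingLocus(
                    locus_id=f"locus_{n + 1:04d}",
                    contig_id=cluster[0].contig_id,
                    start=min(p.start for p in cluster),
                    end=max(p.end for p in cluster),
                    member_peaks=members,
                    associated_genes=frozenset(genes),
                )
            )
    else:
        raise ValueError(f"unknown consensus mode {mode!r}")

    if require_all:
        loci = [l for l in loci if l.experiments_present == all_ids]
    logger.info("consensus (%s mode): %d loci", mode, len(loci))
    return loci


def build_experiment_sets(
    peak_lists: dict[str, list[Peak]],
    annotation: list[GeneModel],
    threshold: float = DEFAULT_ENRICHMENT_THRESHOLD,
    max_distance: int = DEFAULT_MAX_DISTANCE,
    contig_lengths: dict[str, int] | None = None,
) -> list[ExperimentPeakSet]:
    """Filter each experiment's peaks and associate them to genes."""
    out = []
    for exp_id in sorted(peak_lists):
        kept = filter_by_enrichment(peak_lists[exp_id], threshold)
        assoc = associate_peaks_to_genes(kept, annotation, max_distance, contig_lengths)
        out.append(ExperimentPeakSet(exp_id, kept, assoc))
    return out
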