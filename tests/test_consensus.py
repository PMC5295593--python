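"""Enrichment filter, gene association, Venn partition and consensus loci."""

import itertools

import numpy as np
import pytest

from aimchip.consensus import (
    associate_peaks_to_genes,
    build_consensus_loci,
    build_experiment_sets,
    filter_by_enrichment,
    venn_partition,
)
from aimchip.models import GeneModel, Peak


def _peak(start, end, fe=8.0, contig="c1", exp="e1", summit=None):
    offsets = (summit - start,) if summit is not None else ()
    return Peak(contig, start, end, offsets, fe, 1e-4, exp, name=f"p{start}")


class TestFilter:
    def test_counts(self):
        peaks = [_peak(i * 1000, i * 1000 + 100, fe) for i, fe in enumerate([2.0, 4.0, 4.5, 8.0, 3.9])]
        assert len(filter_by_enrichment(peaks, 4.0)) == 3

    def test_fourfold_is_inclusive(self):
        assert filter_by_enrichment([_peak(0, 100, 4.0)], 4.0)

    def test_threshold_zero_is_identity(self):
        peaks = [_peak(0, 100, 0.5), _peak(200, 300, 9.0)]
        assert filter_by_enrichment(peaks, 0.0) == peaks

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(2)
        peaks = [_peak(i * 200, i * 200 + 100, float(rng.uniform(0, 10))) for i in range(50)]
        kept = [len(filter_by_enrichment(peaks, t)) for t in np.linspace(0, 10, 21)]
        assert kept == sorted(kept, reverse=True)


class TestAssociation:
    GENES = [
        GeneModel("gL", "c1", 1000, 2000, "-"),  # 5' end at 2000, faces right
        GeneModel("gR", "c1", 3000, 4000, "+"),  # 5' end at 3000, faces left
        GeneModel("gF", "c1", 5000, 6000, "+"),
    ]

    def test_divergent_peak_reports_both_genes(self):
        peaks = [_peak(2300, 2700)]
        assoc = associate_peaks_to_genes(peaks, self.GENES)
        assert assoc[0] == frozenset({"gL", "gR"})

    def test_intragenic_peak_reports_host_gene(self):
        peaks = [_peak(3200, 3400)]
        assoc = associate_peaks_to_genes(peaks, self.GENES)
        assert "gR" in assoc[0]

    def test_unknown_contig_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="absent"):
            assoc = associate_peaks_to_genes([_peak(0, 100, contig="cX")], self.GENES)
        assert assoc[0] == frozenset()

    def test_matches_brute_force_oracle(self):
        """Association equals an exhaustive per-gene interval check."""
        rng = np.random.default_rng(9)
        max_distance = 3000
        genes, pos = [], 0
        for i in range(30):
            w = int(rng.integers(200, 1500))
            genes.append(
                GeneModel(f"g{i}", "c1", pos, pos + w, "+-"[int(rng.integers(0, 2))])
            )
            pos += w + int(rng.integers(0, 2500))
        contig_len = pos + 1000
        peaks = []
        for i in range(60):
            s = int(rng.integers(0, contig_len - 100))
            peaks.append(_peak(s, s + int(rng.integers(50, 2000))))
        assoc = associate_peaks_to_genes(
            peaks, genes, max_distance, {"c1": contig_len}
        )
        ordered = sorted(genes, key=lambda g: g.start)
        for i, p in enumerate(peaks):
            expected = set()
            for j, g in enumerate(ordered):
                # body overlap
                if p.start < g.end and g.start < p.end:
                    expected.add(g.gene_id)
                # 5'-adjacent intergenic window, capped at max_distance
                if g.strand == "+":
                    left = ordered[j - 1].end if j > 0 else 0
                    ws, we = max(left, g.start - max_distance), g.start
                else:
                    right = ordered[j + 1].start if j + 1 < len(ordered) else contig_len
                    ws, we = g.end, min(right, g.end + max_distance)
                if ws < we and p.start < we and ws < p.end:
                    expected.add(g.gene_id)
            assert assoc[i] == expected, f"peak {i}"


class TestVennPartition:
    def test_all_present_class(self):
        sets = {"A": {"g1", "g2"}, "B": {"g1"}, "C": {"g1", "g3"}, "D": {"g1"}}
        part = venn_partition(sets)
        assert part[frozenset("ABCD")] == {"g1"}

    def test_disjoint_sets_have_empty_core(self):
        part = venn_partition({"A": {"x"}, "B": {"y"}})
        assert part[frozenset("AB")] == set()

    def test_matches_membership_enumeration_and_conserves(self):
        rng = np.random.default_rng(4)
        universe = [f"g{i}" for i in range(40)]
        sets = {
            name: {g for g in universe if rng.random() < 0.4} for name in "ABCD"
        }
        part = venn_partition(sets)
        # disjoint and conservative
        union = set().union(*sets.values())
        seen = set()
        for items in part.values():
            assert not (items & seen)
            seen |= items
        assert seen == union
        # per-item enumeration oracle
        for item in union:
            members = frozenset(n for n in sets if item in sets[n])
            assert item in part[members]

    def test_rejects_wrong_arity(self):
        with pytest.raises(ValueError):
            venn_partition({"A": set()})


def _experiment_sets(peak_lists, genes, contig_len=100000):
    return build_experiment_sets(
        peak_lists, genes, threshold=4.0, contig_lengths={"c1": contig_len}
    )


class TestConsensusLoci:
    GENES = [
        GeneModel("gA", "c1", 1000, 2000, "-"),
        GeneModel("gB", "c1", 3000, 4000, "+"),
        GeneModel("gC", "c1", 9000, 10000, "-"),
        GeneModel("gD", "c1", 11000, 12000, "+"),
    ]

    def _four_experiments(self, drop_locus2_from=None):
        lists = {}
        for exp in ["e1", "e2", "e3", "e4"]:
            peaks = [_peak(2300, 2700, exp=exp)]
            if exp != drop_locus2_from:
                peaks.append(_peak(10300, 10700, exp=exp))
            lists[exp] = peaks
        return lists

    def test_locus_in_all_four_recovered(self):
        sets = _experiment_sets(self._four_experiments(), self.GENES)
        loci = build_consensus_loci(sets)
        assert len(loci) == 2

    def test_missing_in_one_experiment_excluded_but_in_three_way_class(self):
        sets = _experiment_sets(self._four_experiments(drop_locus2_from="e3"), self.GENES)
        loci = build_consensus_loci(sets)
        assert len(loci) == 1
        part = venn_partition({s.experiment_id: set(s.associated_genes) for s in sets})
        assert part[frozenset({"e1", "e2", "e4"})] == {"gC", "gD"}

    def test_interval_mode_agrees_with_gene_mode_on_one_to_one_fixtures(self):
        sets = _experiment_sets(self._four_experiments(), self.GENES)
        gene_loci = build_consensus_loci(sets, mode="gene")
        interval_loci = build_consensus_loci(sets, mode="interval")
        assert {(l.start, l.end) for l in gene_loci} == {
            (l.start, l.end) for l in interval_loci
        }

    def test_interval_mode_matches_brute_force_overlap_clustering(self):
        """Interval-mode loci equal an all-pairs overlap component search."""
        rng = np.random.default_rng(17)
        lists = {}
        for exp in ["e1", "e2", "e3", "e4"]:
            peaks = []
            for _ in range(40):
                s = int(rng.integers(0, 50000))
                peaks.append(_peak(s, s + int(rng.integers(100, 1500)), exp=exp))
            lists[exp] = peaks
        sets = _experiment_sets(lists, self.GENES)
        loci = build_consensus_loci(sets, mode="interval", require_all=False)
        # brute force: union-find over all-pairs overlap
        allp = [p for s in sets for p in s.peaks]
        parent = list(range(len(allp)))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i, j in itertools.combinations(range(len(allp)), 2):
            a, b = allp[i], allp[j]
            if a.contig_id == b.contig_id and a.start < b.end and b.start < a.end:
                parent[find(i)] = find(j)
        comps = {}
        for i in range(len(allp)):
            comps.setdefault(find(i), []).append(allp[i])
        expected = {
            (min(p.start for p in c), max(p.end for p in c), len(c))
            for c in comps.values()
        }
        got = {
            (l.start, l.end, sum(len(ps) for ps in l.member_peaks.values()))
            for l in loci
        }
        assert got == expected


def test_plant_recover_small_study(small_study):
    """Consensus recovers exactly the planted core loci of the simulator."""
    ann = small_study.genes
    clens = {c.contig_id: len(c) for c in small_study.contigs}
    sets = build_experiment_sets(small_study.treatments, ann, 4.0, 3000, clens)
    loci = build_consensus_loci(sets)
    assert len(loci) == len(small_study.peak_truth.core_loci)
    planted_gene_sets = {frozenset(l.genes) for l in small_study.peak_truth.core_loci}
    assert {l.associated_genes for l in loci} == planted_gene_sets


def test_controls_all_fall_below_fourfold(small_study):
    for peaks in small_study.controls.values():
        assert filter_by_enrichment(peaks, 4.0) == []
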