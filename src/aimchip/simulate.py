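"""Synthetic study generator with fully known planted structure.

Emulates the data a four-experiment transcription-factor ChIP-seq study
produces downstream of peak calling: a toy multi-contig genome whose genes
alternate strands so single-gene, divergent and tail-to-tail intergenic
configurations all occur; AIM motifs (CGG-N7-CGG) planted at known offsets
upstream of start codons; a multi-copy ~310 bp repeat element with inverted
terminal repeats carrying a conserved 14-mer, mutated by a transition-biased
(RIP-like) process; four treatment + four matched-control peak sets sharing
a planted consensus core; and qPCR Ct tables with planted fold-change
effects under a 4 biological x 3 technical replicate design.

Everything is driven by one seeded NumPy generator drawn from in a fixed
order (genome -> motif plants -> repeat family -> peaks -> Ct tables), so a
seed reproduces byte-identical fixture files.  Every planted feature is
recorded in a truth table so each downstream stage can be checked by
plant/recover.

Background sequence is guaranteed AIM-free: after assembly the contigs are
scanned and any occurrence outside a planted footprint is destroyed by
mutating one of its CGG/CCG core bases, so a genome-wide scan returns
exactly the planted motifs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from aimchip import io as aio
from aimchip.models import ConfigError, GeneModel, GenomeSequence, Peak
from aimchip.motifs import AIM_LENGTH, revcomp, scan_aim

_BASES = np.array(list("ACGT"))
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "C": "AG", "G": "CT", "T": "AG"}

#: default conserved 14-mer carried at the outer ends of the repeat's
#: inverted terminal repeats (synthetic stand-in for the AOD2-associated
#: consensus, which is supplied by the user when scanning real data)
DEFAULT_CONSENSUS14 = "TCATGACGTCATGA"


@dataclass(frozen=True)
class RepeatSpec:
    """Architecture and mutation model of the planted repeat family.

    Defaults mirror a RIP'd fungal repeat family: a 310 bp unit with 78 bp
    inverted terminal repeats, present in 11 genomic copies, each
    non-reference copy hit by C:G->T:A transitions at a per-site rate that
    dominates transversions roughly 4:1 in the resulting column census.
    """

    unit_length: int = 310
    itr_length: int = 78
    n_copies: int = 11
    transition_rate: float = 0.04
    transversion_rate: float = 0.005
    indel_rate: float = 0.0007
    consensus14: str = DEFAULT_CONSENSUS14
    context_mode: str = "uniform"  # or "cpa": transitions only at CpA/TpG

    def __post_init__(self) -> None:
        if self.itr_length >= self.unit_length / 2:
            raise ConfigError("itr_length must be < unit_length / 2")
        for r in (self.transition_rate, self.transversion_rate, self.indel_rate):
            if not (0.0 <= r <= 1.0):
                raise ConfigError(f"mutation rate {r} outside [0, 1]")
        if self.context_mode not in ("uniform", "cpa"):
            raise ConfigError(f"unknown context_mode {self.context_mode!r}")


@dataclass(frozen=True)
class PeakSpec:
    """Design of the simulated ChIP experiments.

    Four treatment experiments (two factors x two growth conditions, as in
    the study design) share ``core_single + core_divergent`` promoter loci
    plus ``core_tail_to_tail`` loci between gene 3' ends, all with fold
    enrichment >= 4 over the matched control; each experiment additionally
    carries ``extra_loci_per_experiment`` loci drawn from a shared pool so
    partial Venn classes are populated.  Controls hold only background
    peaks with fold enrichment < 4.
    """

    n_experiments: int = 4
    core_single: int = 32
    core_divergent: int = 33
    core_tail_to_tail: int = 5
    extra_loci_per_experiment: int = 10
    core_fold_range: tuple[float, float] = (4.0, 30.0)
    extra_fold_range: tuple[float, float] = (4.0, 15.0)
    control_fold_range: tuple[float, float] = (1.0, 3.9)
    n_control_peaks: int = 20
    peak_inset: int = 10
    summit_jitter: int = 0
    q_range: tuple[float, float] = (1e-8, 2.2e-3)

    @property
    def shared_core_loci(self) -> int:
        return self.core_single + self.core_divergent + self.core_tail_to_tail

    @property
    def experiment_ids(self) -> tuple[str, ...]:
        labels = ["AOD2_plusCm", "AOD5_plusCm", "AOD2_minusCm", "AOD5_minusCm"]
        return tuple(labels[: self.n_experiments])


@dataclass(frozen=True)
class CtSpec:
    """Planted qPCR effects under the replicate design of the study.

    ``planted_folds`` maps gene -> (strain, condition) -> expression fold
    relative to the (control, -Cm) baseline.  Defaults plant one gene per
    regulatory archetype: an AOX-like gene induced 18-fold by Cm and
    dependent on both factors, a factor-dependent but Cm-blind gene, a
    negatively regulated gene, a Cm-only gene and a no-effect gene.
    """

    biological_reps: int = 4
    technical_reps: int = 3
    ct_noise_sd: float = 0.2
    reference_gene: str = "tub"
    reference_ct: float = 20.0
    baseline_ct: float = 24.0
    strains: tuple[str, ...] = ("control", "aod2KO", "aod5KO")
    conditions: tuple[str, ...] = ("minusCm", "plusCm")
    planted_folds: dict[str, dict[tuple[str, str], float]] | None = None

    def effective_folds(self) -> dict[str, dict[tuple[str, str], float]]:
        if self.planted_folds is not None:
            return self.planted_folds
        return {
            # AOX-like: Cm-induced, both factors required
            "gene_pos_cm": {
                ("control", "minusCm"): 1.0,
                ("control", "plusCm"): 18.0,
                ("aod2KO", "minusCm"): 0.1,
                ("aod2KO", "plusCm"): 0.1,
                ("aod5KO", "minusCm"): 0.1,
                ("aod5KO", "plusCm"): 0.1,
            },
            # factor-dependent, unaffected by Cm
            "gene_pos_nocm": {
                ("control", "minusCm"): 1.0,
                ("control", "plusCm"): 1.2,
                ("aod2KO", "minusCm"): 0.2,
                ("aod2KO", "plusCm"): 0.2,
                ("aod5KO", "minusCm"): 0.2,
                ("aod5KO", "plusCm"): 0.2,
            },
            # negatively regulated (up in mutants with Cm)
            "gene_neg": {
                ("control", "minusCm"): 1.0,
                ("control", "plusCm"): 1.0,
                ("aod2KO", "minusCm"): 1.0,
                ("aod2KO", "plusCm"): 3.0,
                ("aod5KO", "minusCm"): 1.0,
                ("aod5KO", "plusCm"): 3.0,
            },
            # Cm effect independent of the factors
            "gene_cm_only": {
                ("control", "minusCm"): 1.0,
                ("control", "plusCm"): 3.0,
                ("aod2KO", "minusCm"): 1.0,
                ("aod2KO", "plusCm"): 3.0,
                ("aod5KO", "minusCm"): 1.0,
                ("aod5KO", "plusCm"): 3.0,
            },
            "gene_no_effect": {
                (s, c): 1.0 for s in self.strains for c in self.conditions
            },
        }


@dataclass(frozen=True)
class SimulationConfig:
    rng_seed: int = 1
    n_contigs: int = 9
    genes_per_contig: int = 20
    gene_length_range: tuple[int, int] = (900, 1500)
    intergenic_length_range: tuple[int, int] = (400, 800)
    strand_pattern: str = "++--"
    aim_offset: int = 170
    plant_aims: bool = True
    aim_plant_spec: tuple[tuple[str, int], ...] | None = None
    repeat_spec: RepeatSpec = field(default_factory=RepeatSpec)
    peak_spec: PeakSpec = field(default_factory=PeakSpec)
    ct_spec: CtSpec = field(default_factory=CtSpec)

    def __post_init__(self) -> None:
        if min(self.n_contigs, self.genes_per_contig) <= 0:
            raise ConfigError("contig and gene counts must be positive")
        lo, hi = self.intergenic_length_range
        if self.plant_aims and lo < self.aim_offset + AIM_LENGTH + 20:
            raise ConfigError(
                "intergenic regions too short to plant AIMs at the requested offset"
            )
        if set(self.strand_pattern) - {"+", "-"}:
            raise ConfigError("strand_pattern must consist of '+'/'-'")


# ---------------------------------------------------------------------------
# gap bookkeeping


@dataclass
class IntergenicGap:
    """An internal intergenic interval with its flanking genes."""

    contig_id: str
    start: int
    end: int
    left_gene: GeneModel
    right_gene: GeneModel

    @property
    def gap_id(self) -> str:
        return f"{self.contig_id}:{self.start}-{self.end}"

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def facing_genes(self) -> list[GeneModel]:
        """Genes whose 5' end faces into this gap."""
        out = []
        if self.left_gene.strand == "-":  # 5' at right boundary of left gene
            out.append(self.left_gene)
        if self.right_gene.strand == "+":
            out.append(self.right_gene)
        return out

    @property
    def orientation(self) -> str:
        n = len(self.facing_genes)
        return {0: "tail_to_tail", 1: "single_gene", 2: "divergent_pair"}[n]


def intergenic_gaps(genes: list[GeneModel]) -> list[IntergenicGap]:
    """Internal gaps between consecutive genes, per contig, sorted."""
    gaps: list[IntergenicGap] = []
    by_contig: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_contig.setdefault(g.contig_id, []).append(g)
    for contig_id in sorted(by_contig):
        ordered = sorted(by_contig[contig_id], key=lambda g: g.start)
        for left, right in zip(ordered, ordered[1:]):
            if right.start > left.end:
                gaps.append(IntergenicGap(contig_id, left.end, right.start, left, right))
    return gaps


# ---------------------------------------------------------------------------
# genome generation


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _clean_aims(
    seq_list: list[str], protected: set[int], cap: int = 200
) -> None:
    """Destroy every AIM occurrence whose footprint is not protected.

    Mutates one CGG/CCG core base per offending hit to 'A' (or 'T' when
    the base already is 'A').  Protected positions (planted motifs, repeat
    copies) are never touched; by construction every spurious hit has at
    least one unprotected core base.
    """
    core_offsets = (0, 1, 2, 10, 11, 12)
    for _ in range(cap):
        seq = "".join(seq_list)
        dirty = [
            h
            for h in scan_aim(seq)
            if not all(p in protected for p in range(h.start, h.end))
        ]
        if not dirty:
            return
        for h in dirty:
            for off in core_offsets:
                pos = h.start + off
                if pos not in protected:
                    seq_list[pos] = "A" if seq_list[pos] != "A" else "T"
                    break
            else:  # pragma: no cover - impossible by construction
                raise RuntimeError("AIM hit with fully protected cores")
    raise RuntimeError("AIM cleaning did not converge")  # pragma: no cover


@dataclass
class AimPlant:
    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    upstream_offset: int
    gap_id: str


@dataclass
class GenomeTruth:
    aim_plants: list[AimPlant]
    gaps: list[IntergenicGap]

    def protected_positions(self, contig_id: str) -> set[int]:
        out: set[int] = set()
        for p in self.aim_plants:
            if p.contig_id == contig_id:
                out.update(range(p.start, p.end))
        return out


def generate_genome(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[list[GenomeSequence], list[GeneModel], GenomeTruth]:
    """Generate the toy genome, gene models, and planted AIM truth.

    Genes alternate strands following ``config.strand_pattern`` so single,
    divergent and tail-to-tail gap configurations all occur.  With
    ``plant_aims`` one AIM is planted per single/divergent gap at
    ``aim_offset`` bp upstream of the start codon of an anchor gene (the
    facing gene; for divergent gaps, the one with the lower coordinate
    among the two is chosen on alternating gaps).  ``aim_plant_spec``
    overrides auto-planting with explicit (gene_id, offset) pairs.
    """
    rng = np.random.default_rng(config.rng_seed) if rng is None else rng
    lo_g, hi_g = config.gene_length_range
    lo_i, hi_i = config.intergenic_length_range
    if hi_g <= lo_g or hi_i <= lo_i:
        raise ConfigError("length ranges must have low < high")

    contig_seqs: dict[str, list[str]] = {}
    genes: list[GeneModel] = []
    pattern = config.strand_pattern
    gene_no = 0
    for c in range(config.n_contigs):
        contig_id = f"contig_{c + 1}"
        parts: list[str] = []
        pos = 0
        seq_genes: list[GeneModel] = []
        parts.append(_random_dna(rng, int(rng.integers(lo_i, hi_i))))
        pos = len(parts[-1])
        for _ in range(config.genes_per_contig):
            glen = int(rng.integers(lo_g, hi_g))
            strand = pattern[gene_no % len(pattern)]
            gene_no += 1
            seq_genes.append(
                GeneModel(f"g{gene_no:04d}", contig_id, pos, pos + glen, strand)
            )
            parts.append(_random_dna(rng, glen))
            pos += glen
            ilen = int(rng.integers(lo_i, hi_i))
            parts.append(_random_dna(rng, ilen))
            pos += ilen
        contig_seqs[contig_id] = list("".join(parts))
        genes.extend(seq_genes)

    gaps = intergenic_gaps(genes)
    genes_by_id = {g.gene_id: g for g in genes}
    gap_by_facing: dict[str, IntergenicGap] = {}
    for gap in gaps:
        for g in gap.facing_genes:
            gap_by_facing[g.gene_id] = gap

    # decide what to plant
    plants: list[AimPlant] = []
    if config.aim_plant_spec is not None:
        to_plant = list(config.aim_plant_spec)
    elif config.plant_aims:
        to_plant = []
        flip = 0
        for gap in gaps:
            facing = gap.facing_genes
            if not facing:
                continue
            if len(facing) == 2:
                anchor = sorted(facing, key=lambda g: g.start)[flip % 2]
                flip += 1
            else:
                anchor = facing[0]
            to_plant.append((anchor.gene_id, config.aim_offset))
    else:
        to_plant = []

    for gene_id, offset in to_plant:
        gene = genes_by_id[gene_id]
        seq_list = contig_seqs[gene.contig_id]
        spacer = _random_dna(rng, 7)
        if gene.strand == "+":
            start = gene.start - offset - AIM_LENGTH
            motif = "CGG" + spacer + "CGG"
        else:
            start = gene.end + offset
            motif = revcomp("CGG" + spacer + "CGG")
        end = start + AIM_LENGTH
        gap = gap_by_facing.get(gene_id)
        if gap is None or start < gap.start or end > gap.end:
            raise ConfigError(
                f"AIM for {gene_id} at offset {offset} does not fit its "
                f"upstream intergenic region"
            )
        seq_list[start:end] = list(motif)
        plants.append(
            AimPlant(gene_id, gene.contig_id, start, end, gene.strand, offset, gap.gap_id)
        )

    truth = GenomeTruth(aim_plants=plants, gaps=gaps)
    for contig_id, seq_list in contig_seqs.items():
        _clean_aims(seq_list, truth.protected_positions(contig_id))

    contigs = [
        GenomeSequence(cid, "".join(seq)) for cid, seq in sorted(contig_seqs.items())
    ]
    return contigs, genes, truth


# ---------------------------------------------------------------------------
# repeat family


@dataclass
class RepeatCopyTruth:
    contig_id: str
    start: int
    end: int
    strand: str
    substitutions: list[dict]  # {unit_pos, kind, ref, alt}
    indels: list[dict]  # {unit_pos, kind, length, seq}


@dataclass
class RepeatTruth:
    master_unit: str
    itr_length: int
    consensus14: str
    copies: list[RepeatCopyTruth]

    @property
    def n_transitions(self) -> int:
        return sum(
            1 for c in self.copies for s in c.substitutions if s["kind"] == "transition"
        )

    @property
    def n_transversions(self) -> int:
        return sum(
            1 for c in self.copies for s in c.substitutions if s["kind"] == "transversion"
        )


def build_master_unit(spec: RepeatSpec, rng: np.random.Generator) -> str:
    """Construct the repeat unit: ITR + core + revcomp(ITR), AIM-free.

    The conserved 14-mer sits at the very start of the ITR (and hence, as
    reverse complement, at the unit's far end).
    """
    if len(spec.consensus14) != 14:
        raise ConfigError("consensus14 must be 14 bp")
    core_len = spec.unit_length - 2 * spec.itr_length
    for _ in range(200):
        itr = spec.consensus14 + _random_dna(rng, spec.itr_length - 14)
        core = _random_dna(rng, core_len)
        unit = itr + core + revcomp(itr)
        # the base just past the ITR must not extend the terminal
        # self-complementarity, so the planted ITR length is well defined
        rc = revcomp(unit)
        if unit[spec.itr_length] == rc[spec.itr_length]:
            continue
        if not scan_aim(unit):
            return unit
    raise RuntimeError("could not build AIM-free repeat unit")  # pragma: no cover


def mutate_unit(
    unit: str, spec: RepeatSpec, rng: np.random.Generator
) -> tuple[str, list[dict], list[dict]]:
    """Apply the RIP-like mutation process to one copy of the unit.

    Transitions hit C:G sites at ``transition_rate`` (in ``cpa`` mode only
    cytosines in CpA context or guanines in TpG context, the dinucleotide
    preference of biological RIP); transversions and indels hit any site.
    Returns (sequence, substitution records, indel records) with unit
    coordinates.  Redrawn wholesale if the mutated copy acquires an AIM.
    """
    for _ in range(100):
        bases = list(unit)
        subs: list[dict] = []
        indels: list[dict] = []
        u_sub = rng.random(len(unit))
        u_tv = rng.random(len(unit))
        u_ind = rng.random(len(unit))
        for i, ref in enumerate(unit):
            eligible = ref in "CG"
            if eligible and spec.context_mode == "cpa":
                nxt = unit[i + 1] if i + 1 < len(unit) else ""
                prv = unit[i - 1] if i > 0 else ""
                eligible = (ref == "C" and nxt == "A") or (ref == "G" and prv == "T")
            if eligible and u_sub[i] < spec.transition_rate:
                alt = _TRANSITION[ref]
                bases[i] = alt
                subs.append({"unit_pos": i, "kind": "transition", "ref": ref, "alt": alt})
            elif u_tv[i] < spec.transversion_rate:
                alt = _TRANSVERSIONS[ref][int(rng.integers(0, 2))]
                bases[i] = alt
                subs.append(
                    {"unit_pos": i, "kind": "transversion", "ref": ref, "alt": alt}
                )
        # indels applied right-to-left so earlier unit positions stay valid
        for i in range(len(unit) - 1, -1, -1):
            if u_ind[i] < spec.indel_rate:
                if rng.random() < 0.5:
                    indels.append(
                        {"unit_pos": i, "kind": "del", "length": 1, "seq": unit[i]}
                    )
                    del bases[i]
                else:
                    ins = _random_dna(rng, int(rng.integers(1, 3)))
                    indels.append(
                        {"unit_pos": i, "kind": "ins", "length": len(ins), "seq": ins}
                    )
                    bases[i:i] = list(ins)
        seq = "".join(bases)
        if not scan_aim(seq):
            return seq, subs, sorted(indels, key=lambda d: d["unit_pos"])
    raise RuntimeError("could not mutate copy without creating an AIM")  # pragma: no cover


def plant_repeat_family(
    contig_seqs: dict[str, list[str]],
    gaps: list[IntergenicGap],
    spec: RepeatSpec,
    rng: np.random.Generator,
) -> RepeatTruth:
    """Plant the repeat family into tail-to-tail gaps, mutating copies.

    Copy 0 is the unmutated reference.  Copies are centred in their gaps;
    odd-indexed copies are inserted reverse-complemented.  The contig
    sequences are modified in place; the returned truth records every
    introduced change in unit coordinates.
    """
    usable = [
        g
        for g in gaps
        if g.orientation == "tail_to_tail" and g.length >= spec.unit_length + 20
    ]
    if len(usable) < spec.n_copies:
        raise ConfigError(
            f"need {spec.n_copies} tail-to-tail gaps >= {spec.unit_length + 20} bp, "
            f"found {len(usable)}"
        )
    chosen_idx = rng.choice(len(usable), size=spec.n_copies, replace=False)
    chosen = [usable[i] for i in sorted(chosen_idx)]
    master = build_master_unit(spec, rng)
    copies: list[RepeatCopyTruth] = []
    for i, gap in enumerate(chosen):
        if i == 0:
            seq, subs, indels = master, [], []
        else:
            seq, subs, indels = mutate_unit(master, spec, rng)
        strand = "+" if i % 2 == 0 else "-"
        placed = seq if strand == "+" else revcomp(seq)
        start = gap.start + (gap.length - len(placed)) // 2
        end = start + len(placed)
        contig_seqs[gap.contig_id][start:end] = list(placed)
        copies.append(
            RepeatCopyTruth(gap.contig_id, start, end, strand, subs, indels)
        )
    return RepeatTruth(master, spec.itr_length, spec.consensus14, copies)


# ---------------------------------------------------------------------------
# peak simulation


@dataclass
class LocusTruth:
    gap_id: str
    contig_id: str
    start: int
    end: int
    orientation: str
    genes: tuple[str, ...]  # genes the locus should associate with
    summit: int
    experiments: tuple[str, ...]


@dataclass
class PeakTruth:
    core_loci: list[LocusTruth]
    extra_loci: list[LocusTruth]

    def genes_per_experiment(self, experiment_ids: tuple[str, ...]) -> dict[str, set]:
        out: dict[str, set] = {e: set() for e in experiment_ids}
        for locus in [*self.core_loci, *self.extra_loci]:
            for e in locus.experiments:
                out[e].update(locus.genes)
        return out


def _locus_interval(gap: IntergenicGap, spec: PeakSpec) -> tuple[int, int]:
    if gap.orientation == "tail_to_tail":
        # extend slightly into both gene bodies so gene association via
        # body overlap mirrors how such loci surface in real peak sets
        return gap.start - 30, gap.end + 30
    return gap.start + spec.peak_inset, gap.end - spec.peak_inset


def _gap_gene_ids(gap: IntergenicGap) -> tuple[str, ...]:
    if gap.orientation == "tail_to_tail":
        return tuple(sorted((gap.left_gene.gene_id, gap.right_gene.gene_id)))
    return tuple(sorted(g.gene_id for g in gap.facing_genes))


def simulate_peak_files(
    genome_truth: GenomeTruth,
    repeat_gaps: set[str],
    spec: PeakSpec,
    rng: np.random.Generator,
):
    """Build 4 treatment + 4 control peak lists with planted consensus.

    Core loci (present in all experiments, fold >= 4) are drawn from
    single-gene, divergent and tail-to-tail gaps per the ``PeakSpec`` counts; each
    promoter core locus is a gap that carries a planted AIM, and its
    summit sits on the motif midpoint (jittered by at most
    ``summit_jitter``).  Extra loci appear in random subsets of the
    experiments.  Control peaks all have fold < 4.

    Returns (treatments, controls, truth): dicts experiment_id -> list of
    Peak.
    """
    aim_by_gap = {p.gap_id: p for p in genome_truth.aim_plants}
    # without planted motifs (a motif-free background run) any promoter
    # gap can host a core locus; summits then sit at gap centres
    need_aim = bool(aim_by_gap)
    singles, divergents, t2ts = [], [], []
    for gap in genome_truth.gaps:
        if gap.gap_id in repeat_gaps:
            continue
        if gap.orientation == "single_gene" and (not need_aim or gap.gap_id in aim_by_gap):
            singles.append(gap)
        elif gap.orientation == "divergent_pair" and (not need_aim or gap.gap_id in aim_by_gap):
            divergents.append(gap)
        elif gap.orientation == "tail_to_tail":
            t2ts.append(gap)

    if (
        len(singles) < spec.core_single
        or len(divergents) < spec.core_divergent
        or len(t2ts) < spec.core_tail_to_tail
    ):
        raise ConfigError(
            "genome too small for the requested core locus design: "
            f"have {len(singles)} single / {len(divergents)} divergent / "
            f"{len(t2ts)} tail-to-tail candidate gaps"
        )

    def pick(pool, k):
        idx = rng.choice(len(pool), size=k, replace=False)
        keep = [pool[i] for i in sorted(idx)]
        rest = [g for j, g in enumerate(pool) if j not in set(idx.tolist())]
        return keep, rest

    core_s, rest_s = pick(singles, spec.core_single)
    core_d, rest_d = pick(divergents, spec.core_divergent)
    core_t, _ = pick(t2ts, spec.core_tail_to_tail)
    experiment_ids = spec.experiment_ids

    def summit_for(gap: IntergenicGap) -> int:
        plant = aim_by_gap.get(gap.gap_id)
        if plant is not None:
            base = (plant.start + plant.end) // 2
        else:
            base = (gap.start + gap.end) // 2
        if spec.summit_jitter > 0:
            base += int(rng.integers(-spec.summit_jitter, spec.summit_jitter + 1))
        return base

    core_loci: list[LocusTruth] = []
    for gap in [*core_s, *core_d, *core_t]:
        start, end = _locus_interval(gap, spec)
        core_loci.append(
            LocusTruth(
                gap.gap_id,
                gap.contig_id,
                start,
                end,
                gap.orientation,
                _gap_gene_ids(gap),
                summit_for(gap),
                experiment_ids,
            )
        )

    # extra loci: per-experiment draws from the leftover promoter pool
    pool = [*rest_s, *rest_d]
    membership: dict[str, set[str]] = {}
    pool_by_id = {g.gap_id: g for g in pool}
    for exp in experiment_ids:
        k = min(spec.extra_loci_per_experiment, len(pool))
        idx = rng.choice(len(pool), size=k, replace=False)
        for i in sorted(idx):
            membership.setdefault(pool[i].gap_id, set()).add(exp)
    extra_loci: list[LocusTruth] = []
    for gap_id in sorted(membership):
        exps = tuple(sorted(membership[gap_id]))
        if set(exps) == set(experiment_ids):
            continue  # would contaminate the planted consensus count
        gap = pool_by_id[gap_id]
        start, end = _locus_interval(gap, spec)
        extra_loci.append(
            LocusTruth(
                gap.gap_id,
                gap.contig_id,
                start,
                end,
                gap.orientation,
                _gap_gene_ids(gap),
                summit_for(gap),
                exps,
            )
        )

    lo_q, hi_q = np.log10(spec.q_range[0]), np.log10(spec.q_range[1])

    def make_peak(locus: LocusTruth, exp: str, fold_range, tag: str) -> Peak:
        fold = float(rng.uniform(*fold_range))
        q = float(10 ** rng.uniform(lo_q, hi_q))
        return Peak(
            contig_id=locus.contig_id,
            start=locus.start,
            end=locus.end,
            summit_offsets=(locus.summit - locus.start,),
            fold_enrichment=round(fold, 5),
            q_value=q,
            name=f"{tag}_{locus.gap_id}",
            experiment_id=exp,
        )

    treatments: dict[str, list[Peak]] = {e: [] for e in experiment_ids}
    for locus in core_loci:
        for exp in experiment_ids:
            treatments[exp].append(make_peak(locus, exp, spec.core_fold_range, "core"))
    for locus in extra_loci:
        for exp in locus.experiments:
            treatments[exp].append(make_peak(locus, exp, spec.extra_fold_range, "extra"))
    for exp in experiment_ids:
        treatments[exp].sort(key=lambda p: (p.contig_id, p.start))

    controls: dict[str, list[Peak]] = {}
    used = {l.gap_id for l in core_loci} | set(membership) | repeat_gaps
    bg_pool = [g for g in genome_truth.gaps if g.gap_id not in used]
    for exp in experiment_ids:
        ctrl = []
        k = min(spec.n_control_peaks, len(bg_pool))
        idx = rng.choice(len(bg_pool), size=k, replace=False)
        for i in sorted(idx):
            gap = bg_pool[i]
            fold = float(rng.uniform(*spec.control_fold_range))
            ctrl.append(
                Peak(
                    contig_id=gap.contig_id,
                    start=gap.start,
                    end=gap.end,
                    summit_offsets=((gap.end - gap.start) // 2,),
                    fold_enrichment=round(fold, 5),
                    q_value=float(10 ** rng.uniform(-3, -1.31)),
                    name=f"bg_{gap.gap_id}",
                    experiment_id=f"{exp}_control",
                )
            )
        controls[f"{exp}_control"] = ctrl
    return treatments, controls, PeakTruth(core_loci, extra_loci)


# ---------------------------------------------------------------------------
# Ct tables


def simulate_ct_table(
    spec: CtSpec, rng: np.random.Generator
) -> tuple[pd.DataFrame, dict]:
    """Emit a long-format Ct table with planted fold changes.

    The reference gene's Ct is constant (plus noise); a target gene's Ct
    in a cell with planted fold f is ``baseline_ct - log2(f)`` plus
    per-measurement Gaussian noise, so the ddCt pipeline recovers f
    exactly at noise 0.
    """
    folds = spec.effective_folds()
    rows = []
    for gene in sorted(folds):
        cells = folds[gene]
        for strain in spec.strains:
            for condition in spec.conditions:
                f = cells[(strain, condition)]
                if f <= 0:
                    raise ConfigError(f"planted fold for {gene} must be > 0, got {f}")
                for b in range(1, spec.biological_reps + 1):
                    for t in range(1, spec.technical_reps + 1):
                        noise = float(rng.normal(0, spec.ct_noise_sd)) if spec.ct_noise_sd else 0.0
                        rows.append(
                            (gene, strain, condition, b, t,
                             spec.baseline_ct - float(np.log2(f)) + noise)
                        )
    # reference gene measurements for every (strain, condition, bio_rep)
    for strain in spec.strains:
        for condition in spec.conditions:
            for b in range(1, spec.biological_reps + 1):
                for t in range(1, spec.technical_reps + 1):
                    noise = float(rng.normal(0, spec.ct_noise_sd)) if spec.ct_noise_sd else 0.0
                    rows.append(
                        (spec.reference_gene, strain, condition, b, t,
                         spec.reference_ct + noise)
                    )
    df = pd.DataFrame(
        rows, columns=["gene", "strain", "condition", "bio_rep", "tech_rep", "ct"]
    )
    truth = {
        "planted_folds": {
            gene: {f"{s}|{c}": f for (s, c), f in cells.items()}
            for gene, cells in folds.items()
        },
        "reference_gene": spec.reference_gene,
    }
    return df, truth


# ---------------------------------------------------------------------------
# orchestration


@dataclass
class SimulatedStudy:
    config: SimulationConfig
    contigs: list[GenomeSequence]
    genes: list[GeneModel]
    genome_truth: GenomeTruth
    repeat_truth: RepeatTruth | None
    treatments: dict
    controls: dict
    peak_truth: PeakTruth
    ct_table: pd.DataFrame
    ct_truth: dict

    def truth_json(self) -> dict:
        rt = self.repeat_truth
        return {
            "aim_plants": [dataclasses.asdict(p) for p in self.genome_truth.aim_plants],
            "repeat": None
            if rt is None
            else {
                "master_unit": rt.master_unit,
                "itr_length": rt.itr_length,
                "consensus14": rt.consensus14,
                "copies": [dataclasses.asdict(c) for c in rt.copies],
            },
            "core_loci": [dataclasses.asdict(l) for l in self.peak_truth.core_loci],
            "extra_loci": [dataclasses.asdict(l) for l in self.peak_truth.extra_loci],
            "ct": self.ct_truth,
        }

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write FASTA, GFF3, 8 narrowPeak files, Ct TSV and truth JSON."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        paths["fasta"] = outdir / "genome.fa"
        aio.write_fasta(self.contigs, paths["fasta"])
        paths["gff3"] = outdir / "genes.gff3"
        aio.write_gff3(self.genes, paths["gff3"])
        for exp, peaks in sorted(self.treatments.items()):
            p = outdir / f"{exp}.narrowPeak"
            aio.write_narrowpeak(peaks, p)
            paths[exp] = p
        for exp, peaks in sorted(self.controls.items()):
            p = outdir / f"{exp}.narrowPeak"
            aio.write_narrowpeak(peaks, p)
            paths[exp] = p
        paths["ct"] = outdir / "ct_table.tsv"
        self.ct_table.to_csv(paths["ct"], sep="\t", index=False, float_format="%.6f")
        paths["truth"] = outdir / "truth.json"
        with open(paths["truth"], "w") as fh:
            json.dump(self.truth_json(), fh, indent=1, sort_keys=True)
            fh.write("\n")
        return paths


def generate_fixture(
    config: SimulationConfig | None = None, plant_repeats: bool = True
) -> SimulatedStudy:
    """Run the full generator: genome -> repeats -> peaks -> Ct tables.

    One RNG, seeded once from ``config.rng_seed``, is passed through the
    stages in that fixed order, so the entire fixture set is reproducible
    byte for byte from the seed.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.rng_seed)
    contigs, genes, genome_truth = generate_genome(config, rng)

    contig_seqs = {c.contig_id: list(c.sequence) for c in contigs}
    repeat_truth = None
    repeat_gaps: set[str] = set()
    if plant_repeats:
        repeat_truth = plant_repeat_family(
            contig_seqs, genome_truth.gaps, config.repeat_spec, rng
        )
        for copy in repeat_truth.copies:
            for gap in genome_truth.gaps:
                if gap.contig_id == copy.contig_id and gap.start <= copy.start < gap.end:
                    repeat_gaps.add(gap.gap_id)
                    break
        # re-clean: repeat/flank junctions may have formed AIM cores
        for contig_id, seq_list in contig_seqs.items():
            protected = genome_truth.protected_positions(contig_id)
            for copy in repeat_truth.copies:
                if copy.contig_id == contig_id:
                    protected.update(range(copy.start, copy.end))
            _clean_aims(seq_list, protected)

    contigs = [GenomeSequence(cid, "".join(s)) for cid, s in sorted(contig_seqs.items())]
    treatments, controls, peak_truth = simulate_peak_files(
        genome_truth, repeat_gaps, config.peak_spec, rng
    )
    ct_table, ct_truth = simulate_ct_table(config.ct_spec, rng)
    return SimulatedStudy(
        config=config,
        contigs=contigs,
        genes=genes,
        genome_truth=genome_truth,
        repeat_truth=repeat_truth,
        treatments=treatments,
        controls=controls,
        peak_truth=peak_truth,
        ct_table=ct_table,
        ct_truth=ct_truth,
    )
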