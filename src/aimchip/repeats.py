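"""Repeat-family discovery, inverted terminal repeats, and RIP census.

Fungal genomes mutate duplicated sequence through repeat-induced point
mutation (RIP), which leaves a distinctive excess of C:G->T:A transitions
among the differences between repeat copies.  This module finds genomic
copies of a seed repeat unit by exact k-mer seeding followed by banded
global alignment (a deterministic, dependency-free stand-in for a BLASTN
search), detects inverted terminal repeats (ITRs) at the unit's ends,
star-aligns the copies against a reference copy, and tallies a
column-level mutation census (transitions, transversions, indel events).

Pairwise alignments use match +1 / mismatch -1 / gap open -4 / gap
extend -1, which favours the contiguous short indels observed in RIP'd
families.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from Bio import Align

from aimchip.models import GenomeSequence, MutationCensus, RepeatCopy, RepeatFamily
from aimchip.motifs import revcomp

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def _make_aligner(free_target_ends: bool = False) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -4
    aligner.extend_gap_score = -1
    if free_target_ends:
        # glocal: overhangs of the candidate window (and, at contig
        # edges, of the seed) are not penalized
        try:
            aligner.end_deletion_score = 0.0
            aligner.end_insertion_score = 0.0
        except AttributeError:  # Biopython < 1.88 naming
            aligner.query_end_gap_score = 0.0
            aligner.target_end_gap_score = 0.0
    return aligner


def _alignment_stats(alignment) -> tuple[int, int, int, int, int, int]:
    """(matches, columns, t_first, t_last, q_first, q_last) over the aligned core."""
    t_blocks, q_blocks = alignment.aligned
    target = str(alignment.target)
    query = str(alignment.query)
    matches = 0
    block_len = 0
    internal_gaps = 0
    prev_te = prev_qe = None
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        for a, b in zip(target[ts:te], query[qs:qe]):
            if a == b:
                matches += 1
        block_len += te - ts
        if prev_te is not None:
            internal_gaps += (ts - prev_te) + (qs - prev_qe)
        prev_te, prev_qe = te, qe
    if not len(t_blocks):
        return 0, 0, 0, 0, 0, 0
    columns = block_len + internal_gaps
    return (
        matches,
        columns,
        int(t_blocks[0][0]),
        int(t_blocks[-1][1]),
        int(q_blocks[0][0]),
        int(q_blocks[-1][1]),
    )


# ---------------------------------------------------------------------------
# seed-and-extend copy search


def _kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        index.setdefault(seq[i : i + k], []).append(i)
    return index


@dataclass
class _Candidate:
    contig_id: str
    start: int
    end: int
    strand: str
    identity: float
    coverage: float


def _cluster_seed_hits(
    hits: list[tuple[int, int]], seed_len: int, band: int
) -> list[tuple[int, int]]:
    """Cluster (contig_pos, seed_pos) hits into candidate window starts.

    Hits whose implied unit start (contig_pos - seed_pos) falls within
    ``band`` of a cluster's running start estimate join that cluster.
    Returns (window_start, window_end) per cluster with a small pad.
    """
    if not hits:
        return []
    diags = sorted(cpos - spos for cpos, spos in hits)
    clusters: list[list[int]] = [[diags[0]]]
    for d in diags[1:]:
        if d - clusters[-1][-1] <= band:
            clusters[-1].append(d)
        else:
            clusters.append([d])
    pad = band
    windows = []
    for cl in clusters:
        windows.append((min(cl) - pad, max(cl) + seed_len + pad))
    return windows


def find_repeat_copies(
    genome: list[GenomeSequence],
    seed_sequence: str,
    min_identity: float = 75.0,
    min_coverage: float = 0.8,
    k: int = 12,
    band: int = 16,
) -> list[RepeatCopy]:
    """Find genomic copies of ``seed_sequence`` on both strands.

    Exact ``k``-mer seeding proposes candidate windows, each aligned
    globally against the seed (window end gaps free, so the seed may sit
    anywhere in the window).  Copies with identity >= ``min_identity``
    over >= ``min_coverage`` of the seed length are reported; overlapping
    candidates are merged keeping the best identity.  Identity is
    matches / alignment columns x 100 over the aligned core.
    """
    seed = seed_sequence.upper()
    if len(seed) < 50:
        raise ValueError("seed sequence must be >= 50 bp")
    aligner = _make_aligner(free_target_ends=True)
    indices = {"+": _kmer_index(seed, k), "-": _kmer_index(revcomp(seed), k)}
    candidates: list[_Candidate] = []
    for contig in genome:
        seq = contig.sequence
        hits: dict[str, list[tuple[int, int]]] = {"+": [], "-": []}
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            for strand, index in indices.items():
                for spos in index.get(kmer, ()):
                    hits[strand].append((i, spos))
        for strand in "+-":
            for ws, we in _cluster_seed_hits(hits[strand], len(seed), band):
                ws, we = max(0, ws), min(len(seq), we)
                window = seq[ws:we]
                oriented = window if strand == "+" else revcomp(window)
                alignment = aligner.align(oriented, seed)[0]
                matches, columns, t0, t1, q0, q1 = _alignment_stats(alignment)
                if columns == 0:
                    continue
                identity = 100.0 * matches / columns
                coverage = (q1 - q0) / len(seed)
                if identity < min_identity or coverage < min_coverage:
                    continue
                if strand == "+":
                    g_start, g_end = ws + t0, ws + t1
                else:
                    g_start, g_end = ws + len(window) - t1, ws + len(window) - t0
                candidates.append(
                    _Candidate(contig.contig_id, g_start, g_end, strand, identity, coverage)
                )
    # merge overlapping candidates, keep best identity
    merged: list[_Candidate] = []
    for cand in sorted(candidates, key=lambda c: (c.contig_id, c.start, c.end)):
        if (
            merged
            and merged[-1].contig_id == cand.contig_id
            and cand.start < merged[-1].end
        ):
            if cand.identity > merged[-1].identity:
                merged[-1] = cand
        else:
            merged.append(cand)
    return [
        RepeatCopy(c.contig_id, c.start, c.end, c.strand, round(c.identity, 4))
        for c in merged
    ]


def copy_sequence(copy: RepeatCopy, genome: list[GenomeSequence]) -> str:
    """Unit-oriented sequence of a repeat copy."""
    contig = next(c for c in genome if c.contig_id == copy.contig_id)
    seq = contig.sequence[copy.start : copy.end]
    return seq if copy.strand == "+" else revcomp(seq)


# ---------------------------------------------------------------------------
# inverted terminal repeats


def detect_inverted_terminal_repeats(
    unit_sequence: str,
    min_itr: int = 20,
    min_identity: float = 80.0,
    mismatch_penalty: float = 3.0,
) -> tuple[int, float | None]:
    """Find the inverted terminal repeat of a unit sequence.

    Compares the unit position-wise against its own reverse complement
    and takes the maximal-scoring prefix (+1 per complementary match,
    -``mismatch_penalty`` per mismatch), which locates the boundary where
    terminal self-complementarity decays into background.  Returns
    (length, percent identity), or (0, None) when no prefix of at least
    ``min_itr`` bp reaches ``min_identity``.  Symmetric under reverse
    complement of the input.
    """
    unit = unit_sequence.upper()
    rc = revcomp(unit)
    half = len(unit) // 2
    if half < min_itr:
        return 0, None
    best_len, best_score, best_matches = 0, float("-inf"), 0
    matches = 0
    for i in range(half):
        if unit[i] == rc[i]:
            matches += 1
        score = matches - mismatch_penalty * (i + 1 - matches)
        if score > best_score:
            best_score, best_len, best_matches = score, i + 1, matches
    identity = 100.0 * best_matches / best_len if best_len else 0.0
    if best_len >= min_itr and identity >= min_identity:
        return best_len, round(identity, 4)
    return 0, None


def build_family(
    genome: list[GenomeSequence],
    seed_sequence: str,
    min_identity: float = 75.0,
    min_coverage: float = 0.8,
    min_itr: int = 20,
) -> RepeatFamily:
    """Find all copies of the seed and annotate the family's ITR.

    The reference copy is the one with the highest identity to the seed
    (the seed's own locus when the seed was lifted from the genome).
    """
    copies = find_repeat_copies(genome, seed_sequence, min_identity, min_coverage)
    if not copies:
        raise ValueError("no repeat copies found for the given seed")
    reference = max(copies, key=lambda c: (c.percent_identity, -c.start))
    members = [c for c in copies if c is not reference]
    itr_len, itr_ident = detect_inverted_terminal_repeats(seed_sequence, min_itr)
    return RepeatFamily(reference, members, itr_len, itr_ident)


# ---------------------------------------------------------------------------
# star alignment and mutation census


@dataclass
class StarAlignment:
    """Member copies projected onto reference coordinates.

    ``rows[name][i]`` is the member base aligned to reference position
    ``i`` ('-' for a deletion); insertions relative to the reference are
    events, not columns.
    """

    reference: str
    rows: dict[str, list[str]] = field(default_factory=dict)
    insertions: list[tuple[str, int, str]] = field(default_factory=list)


def star_align_copies(
    reference: str, members: dict[str, str], min_member_identity: float = 50.0
) -> StarAlignment:
    """Pairwise-align each member to the reference and project columns.

    Members below ``min_member_identity`` percent identity are excluded
    with a warning (they are unlikely to be true family members).
    """
    aligner = _make_aligner()
    out = StarAlignment(reference=reference)
    for name in sorted(members):
        member = members[name].upper()
        alignment = aligner.align(reference, member)[0]
        matches, columns, *_ = _alignment_stats(alignment)
        identity = 100.0 * matches / columns if columns else 0.0
        if identity < min_member_identity:
            warnings.warn(
                f"member {name!r} identity {identity:.1f}% < {min_member_identity}%; excluded"
            )
            continue
        row = ["-"] * len(reference)
        t_blocks, q_blocks = alignment.aligned
        prev_te = prev_qe = None
        for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
            if prev_qe is not None and qs > prev_qe:
                out.insertions.append((name, int(ts), member[prev_qe:qs]))
            for i in range(te - ts):
                row[ts + i] = member[qs + i]
            prev_te, prev_qe = te, qe
        out.rows[name] = row
    return out


def mutation_census(alignment: StarAlignment) -> MutationCensus:
    """Column-level census of changes relative to the reference.

    A column is variant when at least one member differs from the
    reference there.  Substitution columns are classed transition
    (A<->G, C<->T) or transversion by the majority of differing member
    bases (ties break to transversion).  Contiguous gap runs count as one
    deletion event each (a run shared identically by several members
    counts once); insertions likewise.
    """
    ref = alignment.reference
    n_transitions = n_transversions = 0
    sub_columns = 0
    for i, r in enumerate(ref):
        diffs = [
            row[i]
            for row in alignment.rows.values()
            if row[i] != "-" and row[i] != r
        ]
        if not diffs:
            continue
        sub_columns += 1
        ts = sum(1 for b in diffs if (r, b) in _TRANSITIONS)
        tv = len(diffs) - ts
        if ts > tv:
            n_transitions += 1
        else:
            n_transversions += 1
    # deletion runs, unique per (start, end)
    del_runs: set[tuple[int, int]] = set()
    for row in alignment.rows.values():
        start = None
        for i, b in enumerate([*row, "x"]):  # sentinel flushes trailing run
            if b == "-" and start is None:
                start = i
            elif b != "-" and start is not None:
                del_runs.add((start, i))
                start = None
    ins_events = {(pos, seq) for (_name, pos, seq) in alignment.insertions}
    indel_lengths = tuple(
        sorted(
            [e - s for s, e in del_runs] + [len(seq) for _pos, seq in ins_events]
        )
    )
    return MutationCensus(
        n_variant_columns=sub_columns + len(del_runs) + len(ins_events),
        n_transitions=n_transitions,
        n_transversions=n_transversions,
        indel_lengths=indel_lengths,
    )


def census_for_family(
    genome: list[GenomeSequence], family: RepeatFamily
) -> tuple[StarAlignment, MutationCensus]:
    """Align a found family's members to its reference copy and census it."""
    ref_seq = copy_sequence(family.reference, genome)
    members = {
        f"{c.contig_id}:{c.start}-{c.end}({c.strand})": copy_sequence(c, genome)
        for c in family.members
    }
    alignment = star_align_copies(ref_seq, members)
    return alignment, mutation_census(alignment)
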