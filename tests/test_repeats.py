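"""Repeat-copy search, ITR detection, star alignment and RIP census."""

import numpy as np
import pytest

from aimchip.models import GenomeSequence
from aimchip.motifs import revcomp
from aimchip.repeats import (
    _make_aligner,
    census_for_family,
    build_family,
    copy_sequence,
    detect_inverted_terminal_repeats,
    find_repeat_copies,
    mutation_census,
    star_align_copies,
    StarAlignment,
)
from aimchip.simulate import _random_dna


def _rng(seed=0):
    return np.random.default_rng(seed)


def _genome_with_copies(seed_seq, positions, rng, length=6000, strands=None):
    """Background genome with the seed planted verbatim at given positions."""
    seq = list(_random_dna(rng, length))
    strands = strands or ["+"] * len(positions)
    for pos, strand in zip(positions, strands):
        unit = seed_seq if strand == "+" else revcomp(seed_seq)
        seq[pos : pos + len(unit)] = list(unit)
    return [GenomeSequence("c1", "".join(seq))]


class TestFindRepeatCopies:
    def test_three_verbatim_copies_found_at_100_percent(self):
        rng = _rng(1)
        seed = _random_dna(rng, 200)
        genome = _genome_with_copies(seed, [500, 2000, 4000], rng, strands=["+", "-", "+"])
        copies = find_repeat_copies(genome, seed)
        assert [(c.start, c.strand) for c in copies] == [
            (500, "+"),
            (2000, "-"),
            (4000, "+"),
        ]
        assert all(c.percent_identity == 100.0 for c in copies)

    def test_mutated_copy_identity_reflects_mutation_load(self):
        rng = _rng(2)
        seed = _random_dna(rng, 200)
        mutated = list(seed)
        for pos in rng.choice(len(seed), size=20, replace=False):
            alts = [b for b in "ACGT" if b != seed[pos]]
            mutated[pos] = alts[int(rng.integers(0, 3))]
        genome = _genome_with_copies("".join(mutated), [1000], rng)
        copies = find_repeat_copies(genome, seed, min_identity=75)
        assert len(copies) == 1
        assert copies[0].percent_identity == pytest.approx(90.0, abs=1.5)

    def test_monotone_in_min_identity(self):
        rng = _rng(3)
        seed = _random_dna(rng, 150)
        genome = _genome_with_copies(seed, [800, 3000], rng)
        prev = None
        for ident in (60.0, 75.0, 90.0, 99.0):
            n = len(find_repeat_copies(genome, seed, min_identity=ident))
            if prev is not None:
                assert n <= prev
            prev = n

    def test_matches_exhaustive_window_alignment_oracle(self):
        """Seeded search equals brute-force alignment of the seed against
        every seed-length window of a toy genome."""
        rng = _rng(4)
        seed = _random_dna(rng, 80)
        # plant two exact copies and one with scattered substitutions
        noisy = list(seed)
        for pos in rng.choice(len(seed), size=8, replace=False):
            alts = [b for b in "ACGT" if b != seed[pos]]
            noisy[pos] = alts[int(rng.integers(0, 3))]
        seq = list(_random_dna(rng, 4000))
        seq[300 : 300 + 80] = list(seed)
        seq[1500 : 1500 + 80] = list(revcomp(seed))
        seq[3000 : 3000 + 80] = noisy
        genome = [GenomeSequence("c1", "".join(seq))]
        got = {(c.start, c.strand) for c in find_repeat_copies(genome, seed, 80.0)}

        # oracle: gapless Hamming identity of every window, both strands,
        # then merge contiguous window runs to their best-scoring start
        s = genome[0].sequence
        best: dict[int, tuple[float, str]] = {}
        for i in range(len(s) - 80 + 1):
            window = s[i : i + 80]
            for strand, w in (("+", window), ("-", revcomp(window))):
                ident = 100.0 * sum(a == b for a, b in zip(w, seed)) / 80
                if ident >= 80.0 and ident > best.get(i, (0, ""))[0]:
                    best[i] = (ident, strand)
        expected = set()
        run: list[int] = []
        for i in sorted(best):
            if run and i - run[-1] > 1:
                top = max(run, key=lambda j: best[j][0])
                expected.add((top, best[top][1]))
                run = []
            run.append(i)
        if run:
            top = max(run, key=lambda j: best[j][0])
            expected.add((top, best[top][1]))
        assert got == expected

    def test_short_seed_rejected(self):
        with pytest.raises(ValueError):
            find_repeat_copies([GenomeSequence("c1", "ACGT" * 100)], "ACGT" * 5)


class TestInvertedTerminalRepeats:
    def test_construction_identity(self):
        rng = _rng(5)
        x = _random_dna(rng, 78)
        y = _random_dna(rng, 154)
        unit = x + y + revcomp(x)
        # guard the construction: the planted boundary must be sharp
        if unit[78] == revcomp(unit)[78]:
            y = "A" + y[1:] if y[0] != "A" else "C" + y[1:]
            unit = x + y + revcomp(x)
        length, identity = detect_inverted_terminal_repeats(unit)
        assert (length, identity) == (78, 100.0)

    def test_symmetric_under_reverse_complement(self):
        rng = _rng(6)
        x = _random_dna(rng, 40)
        unit = x + _random_dna(rng, 150) + revcomp(x)
        assert detect_inverted_terminal_repeats(unit) == detect_inverted_terminal_repeats(
            revcomp(unit)
        )

    def test_random_sequence_rarely_reports_an_itr(self):
        """False-positive rate below a few percent on ITR-free sequence."""
        rng = _rng(7)
        false_pos = sum(
            detect_inverted_terminal_repeats(_random_dna(rng, 310))[0] > 0
            for _ in range(100)
        )
        assert false_pos <= 2

    def test_too_short_unit(self):
        assert detect_inverted_terminal_repeats("ACGTACGT") == (0, None)


class TestStarAlignment:
    def test_identical_copies_have_zero_variant_columns(self):
        ref = _random_dna(_rng(8), 200)
        aln = star_align_copies(ref, {"m1": ref, "m2": ref})
        census = mutation_census(aln)
        assert census.n_variant_columns == 0

    def test_single_substitution_is_one_column_at_position(self):
        ref = _random_dna(_rng(9), 200)
        member = list(ref)
        member[100] = "T" if ref[100] != "T" else "C"
        aln = star_align_copies(ref, {"m1": "".join(member)})
        assert aln.rows["m1"][100] == member[100]
        assert mutation_census(aln).n_variant_columns == 1

    def test_low_identity_member_excluded_with_warning(self):
        rng = _rng(10)
        ref = _random_dna(rng, 200)
        with pytest.warns(UserWarning, match="excluded"):
            aln = star_align_copies(ref, {"junk": _random_dna(rng, 200)})
        assert aln.rows == {}

    def test_deletion_and_insertion_projection(self):
        ref = _random_dna(_rng(11), 120)
        member = ref[:50] + ref[52:]  # 2 bp deletion at 50
        aln = star_align_copies(ref, {"m": member})
        assert aln.rows["m"][50] == "-" and aln.rows["m"][51] == "-"
        member2 = ref[:60] + "AC" + ref[60:]  # 2 bp insertion at 60
        aln2 = star_align_copies(ref, {"m": member2})
        assert ("m", 60, "AC") in aln2.insertions


class TestMutationCensus:
    @pytest.mark.parametrize(
        "ref_base,alt,expected",
        [
            ("C", "T", "transition"),
            ("C", "G", "transversion"),
            ("A", "G", "transition"),
            ("A", "C", "transversion"),
            ("A", "T", "transversion"),
            ("G", "A", "transition"),
        ],
    )
    def test_substitution_classes(self, ref_base, alt, expected):
        ref = "A" * 10 + ref_base + "A" * 10
        row = list(ref)
        row[10] = alt
        aln = StarAlignment(reference=ref, rows={"m": row})
        census = mutation_census(aln)
        assert census.n_transitions == (1 if expected == "transition" else 0)
        assert census.n_transversions == (1 if expected == "transversion" else 0)

    def test_tie_breaks_to_transversion(self):
        ref = "A" * 10 + "C" + "A" * 10
        rows = {"m1": list(ref), "m2": list(ref)}
        rows["m1"][10] = "T"  # transition
        rows["m2"][10] = "G"  # transversion
        census = mutation_census(StarAlignment(reference=ref, rows=rows))
        assert (census.n_transitions, census.n_transversions) == (0, 1)

    def test_shared_deletion_counts_once(self):
        ref = "ACGTACGTACGTACGTACGT"
        row = list(ref)
        row[5] = row[6] = "-"
        census = mutation_census(StarAlignment(reference=ref, rows={"a": row, "b": list(row)}))
        assert census.n_indel_events == 1
        assert census.indel_lengths == (2,)

    def test_conservation_invariant(self, small_study):
        """transitions + transversions = substitution-variant columns."""
        fam = build_family(small_study.contigs, small_study.repeat_truth.master_unit)
        aln, census = census_for_family(small_study.contigs, fam)
        sub_columns = 0
        for i, r in enumerate(aln.reference):
            if any(row[i] not in ("-", r) for row in aln.rows.values()):
                sub_columns += 1
        assert census.n_transitions + census.n_transversions == sub_columns


def test_family_census_matches_truth_columns(small_study):
    """Plant/recover: the alignment census equals a column census derived
    directly from the simulator's truth table (defaults have rare indels,
    so substitution columns not adjacent to an indel must agree)."""
    truth = small_study.repeat_truth
    fam = build_family(small_study.contigs, truth.master_unit)
    assert len(fam.members) + 1 == len(truth.copies)
    _aln, census = census_for_family(small_study.contigs, fam)

    # expected column census from the truth table (majority, tie -> tv)
    by_col: dict[int, list[str]] = {}
    for copy in truth.copies:
        for s in copy.substitutions:
            by_col.setdefault(s["unit_pos"], []).append(s["kind"])
    exp_ts = exp_tv = 0
    for kinds in by_col.values():
        ts = kinds.count("transition")
        if ts > len(kinds) - ts:
            exp_ts += 1
        else:
            exp_tv += 1
    n_indels = sum(len(c.indels) for c in truth.copies)
    assert census.n_transitions == exp_ts
    assert census.n_transversions == exp_tv
    assert census.n_indel_events == n_indels
    assert census.n_variant_columns == exp_ts + exp_tv + n_indels
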