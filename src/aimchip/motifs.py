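"""Degenerate motif scanning and motif-summit concordance.

The central pattern is the alternative oxidase induction motif (AIM): two
CGG triplets separated by any seven nucleotides (CGG-N7-CGG, 13 bp),
bound by the AOD2/AOD5 zinc-cluster heterodimer.  The motif is not its
own reverse complement, so both strands are scanned by default; a minus
strand hit is an occurrence of CCG-N7-CCG on the forward strand.  ``N``
in the subject sequence never matches a pattern literal.
"""

from __future__ import annotations

import enum
import re
from typing import Iterable, Sequence

from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import Seq

from aimchip.models import BindingLocus, ConfigError, MotifHit

AIM_LENGTH = 13

# lookahead so overlapping occurrences are all reported; N excluded
_AIM_FWD = re.compile(r"(?=(CGG[ACGT]{7}CGG))")
_AIM_REV = re.compile(r"(?=(CCG[ACGT]{7}CCG))")


def revcomp(sequence: str) -> str:
    return str(Seq(sequence).reverse_complement())


def scan_aim(
    sequence: str,
    contig_id: str = "",
    offset: int = 0,
    both_strands: bool = True,
) -> list[MotifHit]:
    """Find all AIM (CGG-N7-CGG) occurrences in ``sequence``.

    ``offset`` shifts reported coordinates so hits can be expressed in
    genomic space when scanning a slice.  Overlapping hits are all
    reported; hits are sorted by start then strand.
    """
    seq = sequence.upper()
    hits = [
        MotifHit(contig_id, offset + m.start(), offset + m.start() + AIM_LENGTH, "+", m.group(1))
        for m in _AIM_FWD.finditer(seq)
    ]
    if both_strands:
        hits.extend(
            MotifHit(contig_id, offset + m.start(), offset + m.start() + AIM_LENGTH, "-", m.group(1))
            for m in _AIM_REV.finditer(seq)
        )
    return sorted(hits, key=lambda h: (h.start, h.strand))


def scan_genome_aim(contigs, both_strands: bool = True) -> list[MotifHit]:
    """Scan every contig of a genome for AIM occurrences."""
    out: list[MotifHit] = []
    for contig in contigs:
        out.extend(scan_aim(contig.sequence, contig.contig_id, 0, both_strands))
    return out


class ConcordanceVerdict(str, enum.Enum):
    CONCORDANT = "concordant"
    MOTIF_WITHOUT_SUMMIT_MATCH = "motif_without_summit_match"
    NO_MOTIF = "no_motif"


def summit_concordance(
    hits: Sequence[MotifHit],
    locus: BindingLocus,
    window: int = 50,
) -> ConcordanceVerdict:
    """Judge whether any motif hit sits at or near any peak summit.

    Concordant iff some hit's midpoint lies within ``window`` bp of some
    summit of any member peak.  A locus without summits can never be
    concordant; with motifs present it is reported as
    ``motif_without_summit_match``.
    """
    if not hits:
        return ConcordanceVerdict.NO_MOTIF
    summits = locus.summits
    if not summits:
        return ConcordanceVerdict.MOTIF_WITHOUT_SUMMIT_MATCH
    for hit in hits:
        mid = hit.midpoint
        if any(abs(mid - s) <= window for s in summits):
            return ConcordanceVerdict.CONCORDANT
    return ConcordanceVerdict.MOTIF_WITHOUT_SUMMIT_MATCH


# ---------------------------------------------------------------------------
# Degenerate consensus scanning (the repeat-associated 14-mer)


def _iupac_sets(consensus: str) -> list[frozenset[str]]:
    sets = []
    for ch in consensus.upper():
        if ch not in ambiguous_dna_values:
            raise ConfigError(f"invalid IUPAC code {ch!r} in consensus")
        sets.append(frozenset(ambiguous_dna_values[ch]))
    return sets


def scan_consensus(
    sequence: str,
    consensus: str,
    max_mismatches: int = 1,
    contig_id: str = "",
    offset: int = 0,
    both_strands: bool = True,
    expected_length: int | None = 14,
) -> list[MotifHit]:
    """Sliding scan for an IUPAC-degenerate consensus with mismatches.

    Reports every window matching ``consensus`` with at most
    ``max_mismatches`` mismatching positions, on both strands by default.
    An ``N`` in the subject matches nothing (conservative handling of
    masked sequence).  ``expected_length`` guards the repeat-associated
    14-mer use case; pass ``None`` to scan arbitrary-length consensi.
    """
    if expected_length is not None and len(consensus) != expected_length:
        raise ConfigError(
            f"consensus length {len(consensus)} != required {expected_length}"
        )
    seq = sequence.upper()
    L = len(consensus)
    targets = [("+", _iupac_sets(consensus))]
    if both_strands:
        targets.append(("-", _iupac_sets(revcomp(consensus))))
    hits: list[MotifHit] = []
    for strand, sets in targets:
        for i in range(len(seq) - L + 1):
            window = seq[i : i + L]
            mism = sum(1 for base, allowed in zip(window, sets) if base not in allowed)
            if mism <= max_mismatches:
                hits.append(
                    MotifHit(contig_id, offset + i, offset + i + L, strand, window, mism)
                )
    return sorted(hits, key=lambda h: (h.start, h.strand))


def scan_consensus14(
    sequence: str,
    consensus: str,
    max_mismatches: int = 1,
    **kwargs,
) -> list[MotifHit]:
    """Scan for the conserved 14 bp repeat-associated consensus."""
    return scan_consensus(sequence, consensus, max_mismatches, expected_length=14, **kwargs)


def hits_in_interval(hits: Iterable[MotifHit], start: int, end: int) -> list[MotifHit]:
    """Hits whose interval lies wholly within [start, end)."""
    return [h for h in hits if h.start >= start and h.end <= end]
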