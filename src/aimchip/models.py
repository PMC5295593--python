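"""Domain types shared across the pipeline.

Every interval is 0-based half-open on the forward strand of its contig.
Types validate their invariants on construction and fail loudly; nothing is
silently clamped.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

_DNA_ALPHABET = frozenset("ACGTN")


class ParseError(ValueError):
    """A record in an input file could not be parsed."""


class SchemaError(ParseError):
    """An input file is missing required columns."""


class ValidationError(ValueError):
    """A parsed or constructed value violates a type invariant."""


class ConfigError(ValueError):
    """A configuration value is inconsistent or infeasible."""


@dataclass(frozen=True)
class GenomeSequence:
    """One contig of a genome, uppercase DNA over {A,C,G,T,N}."""

    contig_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError(f"contig {self.contig_id!r}: empty sequence")
        extra = set(self.sequence) - _DNA_ALPHABET
        if extra:
            raise ValidationError(
                f"contig {self.contig_id!r}: non-DNA characters {sorted(extra)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneModel:
    """A gene feature anchored at its start codon (no UTR modelling)."""

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"gene {self.gene_id!r}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id!r}: strand {self.strand!r}")

    @property
    def five_prime(self) -> int:
        """Genomic coordinate of the 5' boundary (start codon position)."""
        return self.start if self.strand == "+" else self.end


@dataclass(frozen=True)
class Peak:
    """A called binding interval with optional summit(s).

    ``fold_enrichment`` is the treatment/control signal ratio; ``q_value``
    is stored on probability scale (the -log10 form used by MACS2 and
    narrowPeak is an I/O detail).  MACS2 run with ``--call-summits`` emits
    one row per summit; readers merge rows sharing coordinates into one
    Peak carrying several summit offsets.
    """

    contig_id: str
    start: int
    end: int
    summit_offsets: tuple[int, ...] = ()
    fold_enrichment: float = 0.0
    q_value: float = 1.0
    experiment_id: str = ""
    name: str = "."
    p_value: float = 1.0

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(
                f"peak {self.name!r}: invalid interval [{self.start}, {self.end})"
            )
        if self.start < 0:
            raise ValidationError(f"peak {self.name!r}: negative start {self.start}")
        width = self.end - self.start
        for off in self.summit_offsets:
            if not (0 <= off < width):
                raise ValidationError(
                    f"peak {self.name!r}: summit offset {off} outside [0, {width})"
                )
        if self.fold_enrichment < 0:
            raise ValidationError(
                f"peak {self.name!r}: fold_enrichment {self.fold_enrichment} < 0"
            )
        if not (0.0 <= self.q_value <= 1.0):
            raise ValidationError(f"peak {self.name!r}: q_value {self.q_value}")

    @property
    def summits(self) -> tuple[int, ...]:
        """Absolute genomic summit positions."""
        return tuple(self.start + off for off in self.summit_offsets)

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


class OrientationClass(str, enum.Enum):
    """Position of a binding locus relative to its flanking genes."""

    SINGLE_GENE = "single_gene"
    DIVERGENT_PAIR = "divergent_pair"
    TAIL_TO_TAIL = "tail_to_tail"
    INTRAGENIC = "intragenic"


@dataclass
class BindingLocus:
    """A consensus binding site grouping peaks from several experiments."""

    locus_id: str
    contig_id: str
    start: int
    end: int
    member_peaks: dict[str, list[Peak]] = field(default_factory=dict)
    associated_genes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(
                f"locus {self.locus_id!r}: invalid interval [{self.start}, {self.end})"
            )
        if not self.member_peaks:
            raise ValidationError(f"locus {self.locus_id!r}: no member peaks")

    @property
    def experiments_present(self) -> frozenset[str]:
        return frozenset(self.member_peaks)

    @property
    def summits(self) -> tuple[int, ...]:
        out: list[int] = []
        for peaks in self.member_peaks.values():
            for p in peaks:
                out.extend(p.summits)
        return tuple(sorted(out))


@dataclass(frozen=True)
class PromoterRegion:
    """The intergenic interval abutting a gene's 5' boundary."""

    gene_id: str
    contig_id: str
    start: int
    end: int
    gene_strand: str

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class MotifHit:
    """One occurrence of a motif, genomic forward-strand coordinates."""

    contig_id: str
    start: int
    end: int
    strand: str
    matched: str
    mismatches: int = 0
    upstream_offset: int | None = None

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2


@dataclass(frozen=True)
class RepeatCopy:
    """One genomic copy of a repeat element."""

    contig_id: str
    start: int
    end: int
    strand: str
    percent_identity: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.percent_identity <= 100.0):
            raise ValidationError(
                f"repeat copy identity {self.percent_identity} outside [0, 100]"
            )


@dataclass
class RepeatFamily:
    """A reference repeat unit plus its genomic copies."""

    reference: RepeatCopy
    members: list[RepeatCopy]
    itr_length: int = 0
    itr_identity: float | None = None


@dataclass(frozen=True)
class MutationCensus:
    """Column-level census of differences within an aligned repeat family."""

    n_variant_columns: int
    n_transitions: int
    n_transversions: int
    indel_lengths: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if min(self.n_variant_columns, self.n_transitions, self.n_transversions) < 0:
            raise ValidationError("census counts must be non-negative")

    @property
    def n_indel_events(self) -> int:
        return len(self.indel_lengths)

    @property
    def transition_fraction(self) -> float:
        n_sub = self.n_transitions + self.n_transversions
        return self.n_transitions / n_sub if n_sub else float("nan")


@dataclass(frozen=True)
class ExpressionResult:
    """ddCt outcome for one gene x strain x condition cell."""

    gene_id: str
    strain: str
    condition: str
    fold_change: float
    sem: float
    n_bio_reps: int
    log2_folds: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.fold_change <= 0:
            raise ValidationError("fold_change must be positive")
        if self.sem < 0:
            raise ValidationError("sem must be non-negative")


@dataclass(frozen=True)
class EnrichmentResult:
    """One category's over-representation test."""

    category: str
    k: int
    n: int
    K: int
    N: int
    p_value: float
    q_value: float

    def __post_init__(self) -> None:
        if self.k > min(self.n, self.K):
            raise ValidationError(
                f"category {self.category!r}: k={self.k} exceeds min(n, K)"
            )
        if not (0.0 < self.p_value <= 1.0):
            raise ValidationError(f"category {self.category!r}: p={self.p_value}")
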