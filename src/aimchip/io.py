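"""Readers and writers for the file formats the pipeline touches.

Internal coordinates are 0-based half-open everywhere; GFF3 and the MACS2
``.xls`` dialect are converted at this boundary (both are 1-based
inclusive), ENCODE narrowPeak is already half-open.  q- and p-values are
converted between the files' -log10 form and the probability scale stored
on :class:`~aimchip.models.Peak`.  All writers emit deterministic, sorted
output.
"""

from __future__ import annotations

import math
from collections import OrderedDict
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from aimchip.models import (
    GeneModel,
    GenomeSequence,
    ParseError,
    Peak,
    SchemaError,
    ValidationError,
)

# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[GenomeSequence]:
    """Read a FASTA file; sequences are case-normalized to upper."""
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValidationError(f"duplicate contig id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(GenomeSequence(rec.id, str(rec.seq).upper()))
    return records


def write_fasta(sequences: Iterable[GenomeSequence], path: str | Path) -> None:
    recs = [
        SeqRecord(Seq(s.sequence), id=s.contig_id, description="")
        for s in sorted(sequences, key=lambda s: s.contig_id)
    ]
    SeqIO.write(recs, str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3 (1-based inclusive on disk)


def read_gff3(path: str | Path, feature_type: str = "gene") -> list[GeneModel]:
    """Read gene features from a GFF3 file into half-open coordinates."""
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 columns, got {len(fields)}")
            contig, _source, ftype, start_s, end_s, _score, strand, _phase, attrs = fields
            if ftype != feature_type:
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if end1 < start1:
                raise ValidationError(f"{path}:{lineno}: end {end1} < start {start1}")
            attr_map = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            gene_id = attr_map.get("ID") or attr_map.get("Name")
            if gene_id is None:
                raise ParseError(f"{path}:{lineno}: feature without ID attribute")
            if gene_id in seen:
                raise ValidationError(f"{path}:{lineno}: duplicate gene id {gene_id!r}")
            seen.add(gene_id)
            genes.append(GeneModel(gene_id, contig, start1 - 1, end1, strand))
    return genes


def write_gff3(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.contig_id, g.start, g.gene_id)):
            fh.write(
                f"{g.contig_id}\taimchip\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# ENCODE narrowPeak (BED6+4, 0-based half-open on disk)


def _neg_log10_to_prob(value: float) -> float:
    # narrowPeak uses -1 for "not available"
    if value < 0:
        return 1.0
    return 10.0 ** (-value)


def _prob_to_neg_log10(value: float) -> float:
    return -math.log10(max(value, 1e-300))


def read_narrowpeak(path: str | Path, experiment_id: str = "") -> list[Peak]:
    """Read an ENCODE narrowPeak file.

    Rows sharing (contig, start, end) are merged into one
    :class:`~aimchip.models.Peak` carrying several summit offsets (MACS2
    ``--call-summits`` emits one row per summit).  Column 10 (point
    source) is the summit offset from ``start``; -1 means no summit.
    """
    merged: "OrderedDict[tuple, dict]" = OrderedDict()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(
                    f"{path}:{lineno}: narrowPeak needs >=6 tab-separated columns"
                )
            try:
                contig = fields[0]
                start, end = int(fields[1]), int(fields[2])
                name = fields[3]
                signal = float(fields[6]) if len(fields) > 6 else 0.0
                neg_log_p = float(fields[7]) if len(fields) > 7 else -1.0
                neg_log_q = float(fields[8]) if len(fields) > 8 else -1.0
                point = int(fields[9]) if len(fields) > 9 else -1
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: malformed field ({exc})") from exc
            if start < 0:
                raise ValidationError(f"{path}:{lineno}: negative start {start}")
            key = (contig, start, end)
            entry = merged.setdefault(
                key,
                {
                    "name": name,
                    "summits": [],
                    "fe": signal,
                    "p": _neg_log10_to_prob(neg_log_p),
                    "q": _neg_log10_to_prob(neg_log_q),
                    "line": lineno,
                },
            )
            if point >= 0:
                if point not in entry["summits"]:
                    entry["summits"].append(point)
    peaks = []
    for (contig, start, end), e in merged.items():
        try:
            peaks.append(
                Peak(
                    contig_id=contig,
                    start=start,
                    end=end,
                    summit_offsets=tuple(sorted(e["summits"])),
                    fold_enrichment=e["fe"],
                    q_value=e["q"],
                    p_value=e["p"],
                    name=e["name"].split("_summit")[0] if "_summit" in e["name"] else e["name"],
                    experiment_id=experiment_id,
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}:{e['line']}: {exc}") from exc
    return peaks


def write_narrowpeak(peaks: Sequence[Peak], path: str | Path) -> None:
    """Write peaks as narrowPeak; one row per summit (or one row, -1)."""
    with open(path, "w") as fh:
        for pk in sorted(peaks, key=lambda p: (p.contig_id, p.start, p.end)):
            score = min(1000, int(round(pk.fold_enrichment * 10)))
            base = (
                f"{pk.contig_id}\t{pk.start}\t{pk.end}\t{{name}}\t{score}\t.\t"
                f"{pk.fold_enrichment:.6g}\t{_prob_to_neg_log10(pk.p_value):.6f}\t"
                f"{_prob_to_neg_log10(pk.q_value):.6f}\t{{point}}\n"
            )
            if pk.summit_offsets:
                for i, off in enumerate(pk.summit_offsets):
                    name = pk.name if len(pk.summit_offsets) == 1 else f"{pk.name}_summit{i + 1}"
                    fh.write(base.format(name=name, point=off))
            else:
                fh.write(base.format(name=pk.name, point=-1))


# ---------------------------------------------------------------------------
# MACS2 peaks.xls dialect (tab-separated text, 1-based inclusive)

_MACS2_REQUIRED = [
    "chr",
    "start",
    "end",
    "abs_summit",
    "fold_enrichment",
    "-log10(qvalue)",
]


def read_macs2_xls(path: str | Path, experiment_id: str = "") -> list[Peak]:
    """Read the MACS2 ``peaks.xls`` tab-separated dialect.

    1-based inclusive coordinates are converted to half-open
    (``start - 1``); the 1-based ``abs_summit`` column becomes an offset
    from the converted start (``abs_summit - start``, the same value MACS2
    writes to the narrowPeak point-source column).  Rows sharing
    coordinates are merged into one multi-summit Peak.
    """
    header: list[str] | None = None
    merged: "OrderedDict[tuple, dict]" = OrderedDict()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                missing = [c for c in _MACS2_REQUIRED if c not in header]
                if missing:
                    raise SchemaError(
                        f"{path}: missing required MACS2 columns {missing}; "
                        f"expected at least {_MACS2_REQUIRED}"
                    )
                continue
            row = dict(zip(header, fields))
            try:
                start1 = int(row["start"])
                end1 = int(row["end"])
                abs_summit = int(row["abs_summit"])
                fe = float(row["fold_enrichment"])
                neg_log_q = float(row["-log10(qvalue)"])
                neg_log_p = float(row.get("-log10(pvalue)", "-1"))
            except (KeyError, ValueError) as exc:
                raise ParseError(f"{path}:{lineno}: malformed row ({exc})") from exc
            start0 = start1 - 1
            key = (row["chr"], start0, end1)
            entry = merged.setdefault(
                key,
                {
                    "name": row.get("name", "."),
                    "summits": [],
                    "fe": fe,
                    "q": _neg_log10_to_prob(neg_log_q),
                    "p": _neg_log10_to_prob(neg_log_p),
                },
            )
            offset = abs_summit - start1
            if offset not in entry["summits"]:
                entry["summits"].append(offset)
    peaks = []
    for (contig, start, end), e in merged.items():
        peaks.append(
            Peak(
                contig_id=contig,
                start=start,
                end=end,
                summit_offsets=tuple(sorted(e["summits"])),
                fold_enrichment=e["fe"],
                q_value=e["q"],
                p_value=e["p"],
                name=e["name"],
                experiment_id=experiment_id,
            )
        )
    return peaks


def write_macs2_xls(peaks: Sequence[Peak], path: str | Path) -> None:
    """Write peaks in the MACS2 ``peaks.xls`` dialect (one row per summit)."""
    cols = [
        "chr",
        "start",
        "end",
        "length",
        "abs_summit",
        "-log10(pvalue)",
        "fold_enrichment",
        "-log10(qvalue)",
        "name",
    ]
    with open(path, "w") as fh:
        fh.write("# peaks written by aimchip\n")
        fh.write("\t".join(cols) + "\n")
        for pk in sorted(peaks, key=lambda p: (p.contig_id, p.start, p.end)):
            start1 = pk.start + 1
            offsets: Sequence[int] = pk.summit_offsets or (pk.midpoint - pk.start,)
            for off in offsets:
                fh.write(
                    f"{pk.contig_id}\t{start1}\t{pk.end}\t{pk.end - pk.start}\t"
                    f"{start1 + off}\t{_prob_to_neg_log10(pk.p_value):.6f}\t"
                    f"{pk.fold_enrichment:.6g}\t{_prob_to_neg_log10(pk.q_value):.6f}\t"
                    f"{pk.name}\n"
                )
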