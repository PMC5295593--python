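"""End-to-end orchestration: one reproducible run over a full input set.

Composes the stages in the order the downstream analysis of such a study
runs them: enrichment filter -> four-way consensus -> orientation
assignment -> promoter AIM scan and summit concordance -> (optional)
repeat/RIP census -> (optional) ddCt classification -> (optional)
category enrichment.  Emits a master locus table, a Venn-count summary,
a repeat table, a mutation-census JSON, an enrichment table and a run
manifest; all outputs are deterministic given config and inputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

import aimchip
from aimchip import io as aio
from aimchip.consensus import (
    build_consensus_loci,
    build_experiment_sets,
    venn_partition,
)
from aimchip.enrichment import CategoryMap, enrich
from aimchip.models import BindingLocus, OrientationClass
from aimchip.motifs import ConcordanceVerdict, scan_aim, summit_concordance
from aimchip.promoters import classify_locus, extract_promoter
from aimchip.qpcr import classify_regulation, fold_table
from aimchip.repeats import build_family, census_for_family

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    fasta: str = ""
    gff3: str = ""
    peak_files: dict[str, str] = field(default_factory=dict)
    control_files: dict[str, str] = field(default_factory=dict)
    ct_table: str | None = None
    category_map: str | None = None
    repeat_seed_fasta: str | None = None
    enrichment_threshold: float = 4.0
    enrichment_mode: str = "column"  # or "control": ratio vs overlapping control
    fold_threshold: float = 2.0
    concordance_window: int = 50
    repeat_min_identity: float = 75.0
    max_distance: int = 3000
    consensus_mode: str = "gene"
    reference_gene: str = "tub"
    baseline: tuple[str, str] = ("control", "minusCm")
    rng_seed: int = 1
    outdir: str = "results/pipeline"

    def __post_init__(self) -> None:
        for name in ("enrichment_threshold", "fold_threshold", "repeat_min_identity"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = json.load(fh)
        if "baseline" in data:
            data["baseline"] = tuple(data["baseline"])
        return cls(**data)

    def manifest(self) -> dict:
        cfg = dataclasses.asdict(self)
        blob = json.dumps(cfg, sort_keys=True).encode()
        return {
            "tool": "aimchip",
            "version": aimchip.__version__,
            "config": cfg,
            "config_sha256": hashlib.sha256(blob).hexdigest(),
        }


def _read_peaks(path: str, experiment_id: str):
    if path.endswith(".xls"):
        return aio.read_macs2_xls(path, experiment_id)
    return aio.read_narrowpeak(path, experiment_id)


def effective_enrichment(peaks, control_peaks):
    """Rescale each peak's enrichment by the best overlapping control peak.

    Where a treatment peak overlaps no control peak the control level is
    taken as 1 (background).  Returns new Peak objects.
    """
    out = []
    for p in peaks:
        ctrl = max(
            (
                c.fold_enrichment
                for c in control_peaks
                if c.contig_id == p.contig_id and c.start < p.end and p.start < c.end
            ),
            default=1.0,
        )
        out.append(
            dataclasses.replace(
                p, fold_enrichment=p.fold_enrichment / max(ctrl, 1e-9)
            )
        )
    return out


@dataclass
class LocusReport:
    locus: BindingLocus
    orientation: OrientationClass
    oriented_genes: list[str]
    aim_present: str  # Y / N / Na
    aim_summit: str  # Y / N / Na
    aim_hits: int = 0
    qpcr_classes: dict[str, str] = field(default_factory=dict)


@dataclass
class PipelineResult:
    config: PipelineConfig
    venn_counts: dict[str, int]
    loci: list[LocusReport]
    repeat_table: pd.DataFrame | None
    census: dict | None
    qpcr_table: pd.DataFrame | None
    enrichment_table: pd.DataFrame | None

    @property
    def consensus_count(self) -> int:
        return len(self.loci)

    def orientation_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for rep in self.loci:
            out[rep.orientation.value] = out.get(rep.orientation.value, 0) + 1
        return out


def analyse_loci(
    loci: list[BindingLocus],
    annotation,
    genome,
    window: int = 50,
) -> list[LocusReport]:
    """Orientation, promoter AIM scan and summit concordance per locus.

    Tail-to-tail loci get Na in both AIM columns (they are excluded from
    promoter-centric analysis); for the rest, the upstream intergenic
    regions of every gene in correct orientation are scanned and the
    verdict aggregates over all their hits.
    """
    reports = []
    for locus in loci:
        klass, oriented = classify_locus(locus, annotation)
        if klass == OrientationClass.TAIL_TO_TAIL:
            reports.append(
                LocusReport(locus, klass, [], "Na", "Na")
            )
            continue
        hits = []
        for gene in oriented:
            if klass == OrientationClass.INTRAGENIC:
                # scan the locus interval itself: the binding site sits
                # inside the gene body, there is no upstream promoter
                contig = next(c for c in genome if c.contig_id == locus.contig_id)
                seq = contig.sequence[locus.start : locus.end]
                hits.extend(scan_aim(seq, locus.contig_id, locus.start))
            else:
                region, _sense_seq = extract_promoter(gene, annotation, genome)
                if region.length == 0:
                    continue
                # scan the forward-strand genomic slice (both strands are
                # scanned) so hit coordinates are comparable to summits
                hits.extend(
                    scan_aim(contig_slice(genome, region), region.contig_id, region.start)
                )
        # divergent genes share one intergenic region; drop duplicate hits
        hits = sorted(set(hits), key=lambda h: (h.start, h.strand))
        verdict = summit_concordance(hits, locus, window)
        aim_present = "Y" if hits else "N"
        aim_summit = {
            ConcordanceVerdict.CONCORDANT: "Y",
            ConcordanceVerdict.MOTIF_WITHOUT_SUMMIT_MATCH: "N",
            ConcordanceVerdict.NO_MOTIF: "Na",
        }[verdict]
        reports.append(
            LocusReport(locus, klass, [g.gene_id for g in oriented], aim_present, aim_summit, len(hits))
        )
    return reports


def contig_slice(genome, region) -> str:
    contig = next(c for c in genome if c.contig_id == region.contig_id)
    return contig.sequence[region.start : region.end]


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    genome = aio.read_fasta(config.fasta)
    annotation = aio.read_gff3(config.gff3)
    contig_lengths = {c.contig_id: len(c) for c in genome}

    peak_lists = {
        exp: _read_peaks(path, exp) for exp, path in sorted(config.peak_files.items())
    }
    if config.enrichment_mode == "control":
        for exp in peak_lists:
            ctrl_path = config.control_files.get(exp)
            if ctrl_path:
                controls = _read_peaks(ctrl_path, f"{exp}_control")
                peak_lists[exp] = effective_enrichment(peak_lists[exp], controls)
    elif config.enrichment_mode != "column":
        raise ValueError(f"unknown enrichment_mode {config.enrichment_mode!r}")

    sets = build_experiment_sets(
        peak_lists,
        annotation,
        config.enrichment_threshold,
        config.max_distance,
        contig_lengths,
    )
    for s in sets:
        logger.info("experiment %s: %d peaks, %d genes", s.experiment_id, len(s.peaks), len(s.associated_genes))

    partition = venn_partition({s.experiment_id: set(s.associated_genes) for s in sets})
    venn_counts = {
        "+".join(sorted(names)): len(items) for names, items in partition.items()
    }
    loci = build_consensus_loci(sets, mode=config.consensus_mode)
    reports = analyse_loci(loci, annotation, genome, config.concordance_window)

    # optional repeat / RIP stage
    repeat_table = census = None
    if config.repeat_seed_fasta:
        seed = aio.read_fasta(config.repeat_seed_fasta)[0].sequence
        family = build_family(genome, seed, config.repeat_min_identity)
        _aln, census_obj = census_for_family(genome, family)
        repeat_table = pd.DataFrame(
            [
                {
                    "contig": c.contig_id,
                    "start": c.start,
                    "end": c.end,
                    "strand": c.strand,
                    "percent_identity": c.percent_identity,
                }
                for c in [family.reference, *family.members]
            ]
        )
        census = {
            "n_variant_columns": census_obj.n_variant_columns,
            "n_transitions": census_obj.n_transitions,
            "n_transversions": census_obj.n_transversions,
            "n_indel_events": census_obj.n_indel_events,
            "indel_lengths": list(census_obj.indel_lengths),
            "itr_length": family.itr_length,
            "itr_identity": family.itr_identity,
        }

    # optional qPCR stage
    qpcr_df = None
    if config.ct_table:
        ct = pd.read_csv(config.ct_table, sep="\t")
        qpcr_df = fold_table(ct, reference_gene=config.reference_gene, baseline=config.baseline)
        classes = {
            gene: classify_regulation(qpcr_df, gene, config.fold_threshold).regulatory_class.value
            for gene in sorted(set(qpcr_df["gene"]))
        }
        qpcr_df["regulatory_class"] = qpcr_df["gene"].map(classes)
        for rep in reports:
            for g in rep.oriented_genes:
                if g in classes:
                    rep.qpcr_classes[g] = classes[g]

    # optional enrichment stage
    enr_df = None
    if config.category_map:
        catmap = CategoryMap.from_tsv(config.category_map)
        query = {g for rep in reports for g in rep.oriented_genes}
        results, dropped = enrich(query, catmap)
        enr_df = pd.DataFrame(
            [
                {
                    "category": r.category,
                    "k": r.k,
                    "n": r.n,
                    "K": r.K,
                    "N": r.N,
                    "p_value": r.p_value,
                    "q_value": r.q_value,
                }
                for r in results
            ]
        )
        enr_df.attrs["dropped_unannotated"] = dropped

    result = PipelineResult(config, venn_counts, reports, repeat_table, census, qpcr_df, enr_df)
    _write_bundle(result, outdir)
    return result


def _write_bundle(result: PipelineResult, outdir: Path) -> None:
    rows = []
    for rep in result.loci:
        rows.append(
            {
                "locus_id": rep.locus.locus_id,
                "contig": rep.locus.contig_id,
                "start": rep.locus.start,
                "end": rep.locus.end,
                "orientation": rep.orientation.value,
                "oriented_genes": ",".join(rep.oriented_genes),
                "aim_sequence": rep.aim_present,
                "aim_summit": rep.aim_summit,
                "n_aim_hits": rep.aim_hits,
                "qpcr_class": ";".join(
                    f"{g}:{c}" for g, c in sorted(rep.qpcr_classes.items())
                ),
            }
        )
    master_columns = [
        "locus_id",
        "contig",
        "start",
        "end",
        "orientation",
        "oriented_genes",
        "aim_sequence",
        "aim_summit",
        "n_aim_hits",
        "qpcr_class",
    ]
    pd.DataFrame(rows, columns=master_columns).to_csv(
        outdir / "master_loci.tsv", sep="\t", index=False
    )

    venn = pd.DataFrame(
        sorted(result.venn_counts.items()), columns=["membership", "n_genes"]
    )
    venn.to_csv(outdir / "venn_counts.tsv", sep="\t", index=False)

    if result.repeat_table is not None:
        result.repeat_table.to_csv(outdir / "repeat_copies.tsv", sep="\t", index=False)
    if result.census is not None:
        with open(outdir / "mutation_census.json", "w") as fh:
            json.dump(result.census, fh, indent=1, sort_keys=True)
            fh.write("\n")
    if result.qpcr_table is not None:
        result.qpcr_table.to_csv(
            outdir / "qpcr_results.tsv", sep="\t", index=False, float_format="%.6g"
        )
    if result.enrichment_table is not None:
        result.enrichment_table.to_csv(
            outdir / "enrichment.tsv", sep="\t", index=False, float_format="%.6g"
        )
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(result.config.manifest(), fh, indent=1, sort_keys=True)
        fh.write("\n")
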