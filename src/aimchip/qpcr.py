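"""ddCt quantification, contrast testing, and regulatory classification.

Relative expression follows the classic ddCt scheme with a reference
(housekeeping) gene as internal control: technical replicates are averaged
per biological replicate, dCt = Ct_target - Ct_reference, ddCt is taken
against the mean dCt of the baseline cell (control strain, non-inducing
condition), and the per-replicate fold is 2^(-ddCt).  The reported fold
is the arithmetic mean over biological replicates with SEM on the fold
scale (a geometric-mean mode is available).  Genes are then classed by
the study's twofold rules: a gene positively regulated by both factors
drops more than twofold in both knockout strains under both growth
conditions; a negatively regulated gene rises twofold or more in a
knockout; a Cm-only gene responds to the inducer but not to the
knockouts.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from aimchip.models import ExpressionResult

REQUIRED_COLUMNS = ["gene", "strain", "condition", "bio_rep", "tech_rep", "ct"]
DEFAULT_BASELINE = ("control", "minusCm")
DEFAULT_FOLD_THRESHOLD = 2.0


def _check_table(table: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"Ct table missing columns {missing}")
    if (table["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")


def ddct_fold_change(
    table: pd.DataFrame,
    target_gene: str,
    reference_gene: str = "tub",
    baseline: tuple[str, str] = DEFAULT_BASELINE,
    aggregation: str = "arithmetic",
) -> list[ExpressionResult]:
    """ddCt fold changes for one target gene, per strain x condition.

    Biological replicates missing a matched reference measurement are
    dropped with a warning; a cell with no usable replicates raises.
    The baseline cell's mean fold is exactly 1 by construction.
    """
    _check_table(table)
    if aggregation not in ("arithmetic", "geometric"):
        raise ValueError(f"unknown aggregation {aggregation!r}")

    sub = table[table["gene"].isin([target_gene, reference_gene])]
    if target_gene not in set(sub["gene"]):
        raise ValueError(f"no measurements for target gene {target_gene!r}")
    # mean over technical replicates
    mean_ct = (
        sub.groupby(["gene", "strain", "condition", "bio_rep"])["ct"]
        .mean()
        .unstack("gene")
    )
    if reference_gene not in mean_ct.columns:
        raise ValueError(f"no measurements for reference gene {reference_gene!r}")
    dct = mean_ct[target_gene] - mean_ct[reference_gene]
    incomplete = dct.isna()
    if incomplete.any():
        warnings.warn(
            f"{target_gene}: dropped {int(incomplete.sum())} biological replicate(s) "
            "lacking target or reference Ct"
        )
        dct = dct.dropna()

    b_strain, b_cond = baseline
    try:
        baseline_dct = dct.xs((b_strain, b_cond), level=("strain", "condition"))
    except KeyError as exc:
        raise ValueError(f"baseline cell {baseline} absent from table") from exc
    if baseline_dct.empty:
        raise ValueError(f"baseline cell {baseline} has no usable replicates")
    baseline_mean = float(baseline_dct.mean())

    raw: list[tuple[str, str, np.ndarray]] = []
    for (strain, condition), cell in dct.groupby(level=["strain", "condition"]):
        ddct = cell.to_numpy() - baseline_mean
        raw.append((strain, condition, 2.0 ** (-ddct)))

    def _agg(folds: np.ndarray) -> float:
        if aggregation == "arithmetic":
            return float(np.mean(folds))
        return float(np.exp(np.mean(np.log(folds))))

    # renormalise so the baseline cell reads exactly 1 (the published
    # convention: the control grown without inducer is set to one)
    norm = next(_agg(f) for s, c, f in raw if (s, c) == baseline)
    results = []
    for strain, condition, folds in raw:
        fold = _agg(folds) / norm
        sem = (
            float(np.std(folds / norm, ddof=1) / np.sqrt(folds.size))
            if folds.size > 1
            else 0.0
        )
        results.append(
            ExpressionResult(
                gene_id=target_gene,
                strain=strain,
                condition=condition,
                fold_change=fold,
                sem=sem,
                n_bio_reps=int(folds.size),
                log2_folds=tuple(float(x) for x in np.log2(folds / norm)),
            )
        )
    return sorted(results, key=lambda r: (r.strain, r.condition))


def fold_table(
    table: pd.DataFrame,
    target_genes: list[str] | None = None,
    reference_gene: str = "tub",
    baseline: tuple[str, str] = DEFAULT_BASELINE,
) -> pd.DataFrame:
    """Long DataFrame of ExpressionResults for many genes."""
    if target_genes is None:
        target_genes = sorted(set(table["gene"]) - {reference_gene})
    rows = []
    for gene in target_genes:
        for r in ddct_fold_change(table, gene, reference_gene, baseline):
            rows.append(
                {
                    "gene": r.gene_id,
                    "strain": r.strain,
                    "condition": r.condition,
                    "fold_change": r.fold_change,
                    "sem": r.sem,
                    "n_bio_reps": r.n_bio_reps,
                }
            )
    return pd.DataFrame(rows)


def contrast_test(
    result_a: ExpressionResult,
    result_b: ExpressionResult,
    equal_var: bool = False,
) -> float:
    """Two-sample t-test on per-replicate log2 folds (Welch by default)."""
    a, b = np.asarray(result_a.log2_folds), np.asarray(result_b.log2_folds)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("contrast_test needs >= 2 biological replicates per side")
    if np.allclose(a, a[0]) and np.allclose(b, b[0]) and np.isclose(a[0], b[0]):
        return 1.0  # identical constant vectors: no evidence of difference
    return float(stats.ttest_ind(a, b, equal_var=equal_var).pvalue)


class RegulatoryClass(str, enum.Enum):
    POSITIVE_2_AND_5 = "positive_2_and_5"
    NEGATIVE = "negative"
    CM_ONLY = "cm_only"
    NO_EFFECT = "no_effect"
    MIXED = "mixed"


@dataclass(frozen=True)
class Classification:
    gene_id: str
    regulatory_class: RegulatoryClass
    triggering: tuple[str, ...] = ()
    incomplete: bool = False


def classify_regulation(
    folds: pd.DataFrame,
    gene: str,
    threshold: float = DEFAULT_FOLD_THRESHOLD,
    control_strain: str = "control",
    mutant_strains: tuple[str, ...] = ("aod2KO", "aod5KO"),
    conditions: tuple[str, ...] = ("minusCm", "plusCm"),
) -> Classification:
    """Apply the twofold rules to one gene's fold table.

    ``folds`` is the output of :func:`fold_table`.  Mutant effects are
    ratios against the matched-condition control; the Cm effect is the
    control's +inducer / -inducer ratio.  "Greater than twofold
    decreased" is strict; "twofold or greater increase" is inclusive.
    Missing cells are skipped and the result flagged incomplete.
    """
    sub = folds[folds["gene"] == gene]
    cell: dict[tuple[str, str], float] = {
        (r.strain, r.condition): r.fold_change for r in sub.itertuples()
    }

    decreases: list[str] = []
    increases: list[str] = []
    comparisons_possible = 0
    incomplete = False
    for strain in mutant_strains:
        for cond in conditions:
            if (strain, cond) not in cell or (control_strain, cond) not in cell:
                incomplete = True
                continue
            comparisons_possible += 1
            ratio = cell[(strain, cond)] / cell[(control_strain, cond)]
            if ratio < 1.0 / threshold:
                decreases.append(f"{strain}/{cond} down {1 / ratio:.2f}x")
            elif ratio >= threshold:
                increases.append(f"{strain}/{cond} up {ratio:.2f}x")

    cm_effect = None
    if (control_strain, conditions[1]) in cell and (control_strain, conditions[0]) in cell:
        cm_effect = cell[(control_strain, conditions[1])] / cell[(control_strain, conditions[0])]
    else:
        incomplete = True

    n_expected = len(mutant_strains) * len(conditions)
    incomplete = incomplete or comparisons_possible < n_expected
    if comparisons_possible and len(decreases) == comparisons_possible:
        return Classification(
            gene, RegulatoryClass.POSITIVE_2_AND_5, tuple(decreases), incomplete
        )
    if increases and not decreases:
        return Classification(
            gene, RegulatoryClass.NEGATIVE, tuple(increases), incomplete
        )
    if not increases and not decreases:
        if cm_effect is not None and cm_effect >= threshold:
            return Classification(
                gene,
                RegulatoryClass.CM_ONLY,
                (f"{control_strain} Cm effect {cm_effect:.2f}x",),
                incomplete,
            )
        return Classification(gene, RegulatoryClass.NO_EFFECT, (), incomplete)
    return Classification(
        gene, RegulatoryClass.MIXED, tuple(decreases + increases), incomplete
    )
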