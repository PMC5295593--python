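"""ddCt arithmetic, contrast testing and the twofold classification rules."""

import itertools

import numpy as np
import pandas as pd
import pytest

from aimchip.qpcr import (
    RegulatoryClass,
    classify_regulation,
    contrast_test,
    ddct_fold_change,
    fold_table,
)

STRAINS = ("control", "aod2KO", "aod5KO")
CONDITIONS = ("minusCm", "plusCm")


def _table(cells, reference_ct=20.0, bio_reps=4, tech_reps=3):
    """Build a Ct table from {(gene, strain, condition): target_ct}."""
    rows = []
    genes = sorted({g for g, _s, _c in cells})
    for (gene, strain, condition), ct in cells.items():
        for b in range(1, bio_reps + 1):
            for t in range(1, tech_reps + 1):
                rows.append((gene, strain, condition, b, t, ct))
    for strain, condition in itertools.product(STRAINS, CONDITIONS):
        for b in range(1, bio_reps + 1):
            for t in range(1, tech_reps + 1):
                rows.append(("tub", strain, condition, b, t, reference_ct))
    return pd.DataFrame(
        rows, columns=["gene", "strain", "condition", "bio_rep", "tech_rep", "ct"]
    )


def _full_cells(gene, fold_by_cell, baseline_ct=26.0):
    """Target Cts implementing planted folds relative to (control, minusCm)."""
    return {
        (gene, s, c): baseline_ct - float(np.log2(f))
        for (s, c), f in fold_by_cell.items()
    }


def _uniform(fold=1.0, overrides=None):
    cells = {(s, c): fold for s in STRAINS for c in CONDITIONS}
    cells.update(overrides or {})
    return cells


class TestDdct:
    def test_textbook_arithmetic(self):
        # sample: target 24, ref 20; baseline: target 26, ref 20
        # dCt sample = 4, dCt baseline = 6, ddCt = -2, fold = 4
        cells = _full_cells("g", _uniform(1.0, {("control", "plusCm"): 4.0}))
        table = _table(cells)
        assert table[(table.gene == "g") & (table.condition == "plusCm") & (table.strain == "control")]["ct"].iloc[0] == 24.0
        res = {(r.strain, r.condition): r for r in ddct_fold_change(table, "g")}
        assert res[("control", "plusCm")].fold_change == pytest.approx(4.0)

    def test_baseline_fold_is_exactly_one_with_zero_sem(self):
        table = _table(_full_cells("g", _uniform(1.0)))
        res = {(r.strain, r.condition): r for r in ddct_fold_change(table, "g")}
        assert res[("control", "minusCm")].fold_change == 1.0
        assert res[("control", "minusCm")].sem == pytest.approx(0.0)

    def test_equivariance_under_per_replicate_ct_shift(self):
        """Adding a constant to every Ct of one (strain, condition,
        bio_rep) across target and reference leaves all folds unchanged."""
        rng = np.random.default_rng(0)
        table = _table(_full_cells("g", _uniform(1.0, {("aod2KO", "plusCm"): 0.25})))
        table["ct"] += rng.normal(0, 0.1, len(table))  # make it non-degenerate
        shifted = table.copy()
        mask = (
            (shifted.strain == "aod2KO")
            & (shifted.condition == "plusCm")
            & (shifted.bio_rep == 2)
        )
        shifted.loc[mask, "ct"] += 3.7
        a = ddct_fold_change(table, "g")
        b = ddct_fold_change(shifted, "g")
        for x, y in zip(a, b):
            assert x.fold_change == pytest.approx(y.fold_change, rel=1e-9)

    def test_missing_reference_replicate_dropped_with_warning(self):
        table = _table(_full_cells("g", _uniform(1.0)))
        drop = (table.gene == "tub") & (table.strain == "aod2KO") & (
            table.condition == "plusCm"
        ) & (table.bio_rep == 1)
        table = table[~drop]
        with pytest.warns(UserWarning, match="dropped"):
            res = {(r.strain, r.condition): r for r in ddct_fold_change(table, "g")}
        assert res[("aod2KO", "plusCm")].n_bio_reps == 3

    def test_missing_baseline_errors(self):
        table = _table(_full_cells("g", _uniform(1.0)))
        table = table[~((table.strain == "control") & (table.condition == "minusCm"))]
        with pytest.raises(ValueError, match="baseline"):
            ddct_fold_change(table, "g")

    def test_geometric_mode_agrees_at_zero_noise(self):
        table = _table(_full_cells("g", _uniform(1.0, {("control", "plusCm"): 8.0})))
        ar = {(r.strain, r.condition): r.fold_change for r in ddct_fold_change(table, "g")}
        ge = {
            (r.strain, r.condition): r.fold_change
            for r in ddct_fold_change(table, "g", aggregation="geometric")
        }
        for k in ar:
            assert ar[k] == pytest.approx(ge[k])


class TestContrast:
    def _res(self, log2_folds):
        from aimchip.models import ExpressionResult

        return ExpressionResult(
            "g", "s", "c", 1.0, 0.0, len(log2_folds), tuple(log2_folds)
        )

    def test_identical_vectors_give_p_one(self):
        a = self._res([1.0, 1.0, 1.0, 1.0])
        assert contrast_test(a, a) == pytest.approx(1.0)

    def test_separated_vectors_give_small_p(self):
        rng = np.random.default_rng(1)
        a = self._res(list(0.0 + rng.normal(0, 1e-3, 4)))
        b = self._res(list(2.0 + rng.normal(0, 1e-3, 4)))
        assert contrast_test(a, b) < 1e-4

    def test_requires_two_replicates(self):
        with pytest.raises(ValueError):
            contrast_test(self._res([1.0]), self._res([1.0, 2.0]))

    def test_welch_p_matches_permutation_oracle(self):
        """Welch p agrees with a label-permutation test within Monte-Carlo
        error on small samples drawn from one distribution."""
        rng = np.random.default_rng(2)
        x = rng.normal(0.0, 1.0, 6)
        y = rng.normal(0.6, 1.0, 6)
        p_welch = contrast_test(self._res(list(x)), self._res(list(y)))
        pooled = np.concatenate([x, y])
        obs = abs(x.mean() - y.mean())
        n_perm = 20000
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            if abs(perm[:6].mean() - perm[6:].mean()) >= obs - 1e-12:
                count += 1
        p_perm = count / n_perm
        assert p_welch == pytest.approx(p_perm, abs=0.03)


class TestClassification:
    def _folds(self, fold_by_cell, gene="g"):
        table = _table(_full_cells(gene, fold_by_cell))
        return fold_table(table, [gene])

    def test_aox_like_pattern_is_positive(self):
        """Cm-induced control, both knockouts flat: positive regulation."""
        cells = _uniform(0.1)
        cells[("control", "minusCm")] = 1.0
        cells[("control", "plusCm")] = 18.0
        cls = classify_regulation(self._folds(cells), "g")
        assert cls.regulatory_class == RegulatoryClass.POSITIVE_2_AND_5

    def test_all_within_twofold_is_no_effect(self):
        cells = _uniform(1.0, {("aod2KO", "plusCm"): 1.8, ("aod5KO", "minusCm"): 0.6})
        cls = classify_regulation(self._folds(cells), "g")
        assert cls.regulatory_class == RegulatoryClass.NO_EFFECT

    def test_single_increase_is_negative(self):
        """A 2.5x rise in one knockout in one condition, all else flat:
        the factor represses there (the aod-3-like pattern)."""
        cells = _uniform(1.0, {("aod5KO", "minusCm"): 2.5})
        cls = classify_regulation(self._folds(cells), "g")
        assert cls.regulatory_class == RegulatoryClass.NEGATIVE
        assert any("aod5KO/minusCm" in t for t in cls.triggering)

    def test_cm_only_pattern(self):
        cells = _uniform(1.0)
        for s in STRAINS:
            cells[(s, "plusCm")] = 3.0
        cls = classify_regulation(self._folds(cells), "g")
        assert cls.regulatory_class == RegulatoryClass.CM_ONLY

    def test_conflicting_signals_are_mixed(self):
        cells = _uniform(1.0, {("aod2KO", "plusCm"): 0.2, ("aod5KO", "minusCm"): 3.0})
        cls = classify_regulation(self._folds(cells), "g")
        assert cls.regulatory_class == RegulatoryClass.MIXED

    def test_threshold_monotone(self):
        """Raising the threshold never moves a gene out of no_effect."""
        rng = np.random.default_rng(3)
        for _ in range(20):
            cells = {
                (s, c): float(2.0 ** rng.uniform(-2, 2))
                for s in STRAINS
                for c in CONDITIONS
            }
            cells[("control", "minusCm")] = 1.0
            folds = self._folds(cells)
            prev_no_effect = False
            for thr in (1.5, 2.0, 3.0, 4.0, 6.0):
                is_no_effect = (
                    classify_regulation(folds, "g", thr).regulatory_class
                    == RegulatoryClass.NO_EFFECT
                )
                if prev_no_effect:
                    assert is_no_effect
                prev_no_effect = is_no_effect

    def test_planted_study_classes_recovered(self, study):
        folds = fold_table(study.ct_table)
        got = {
            g: classify_regulation(folds, g).regulatory_class
            for g in sorted(set(folds["gene"]))
        }
        assert got["gene_pos_cm"] == RegulatoryClass.POSITIVE_2_AND_5
        assert got["gene_pos_nocm"] == RegulatoryClass.POSITIVE_2_AND_5
        assert got["gene_neg"] == RegulatoryClass.NEGATIVE
        assert got["gene_cm_only"] == RegulatoryClass.CM_ONLY
        assert got["gene_no_effect"] == RegulatoryClass.NO_EFFECT
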