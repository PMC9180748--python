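"""Differential-expression calling: normalization, FC, ANOVA, filters."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lysoquant import (
    DEPParams,
    DifferentialExpression,
    QuantMatrix,
    anova_p,
    call_deps,
    fold_change,
    gen_quant_dataset,
    normalize_intensities,
)
from lysoquant.diffexpr import evaluate_calls


class TestNormalize:
    def test_median_equal_matrix_is_fixed_point(self, tiny_quant):
        matrix, _ = tiny_quant
        normed = normalize_intensities(normalize_intensities(matrix))
        again = normalize_intensities(normed)
        pd.testing.assert_frame_equal(normed.intensities, again.intensities)

    def test_uniform_scaling_is_undone(self, tiny_quant):
        matrix, _ = tiny_quant
        scaled = matrix.intensities.copy()
        scaled["case_1"] *= 10.0
        distorted = QuantMatrix(scaled, matrix.group_of)
        normed = normalize_intensities(distorted)
        medians = normed.intensities.median(axis=0)
        assert np.allclose(medians, medians.iloc[0])

    def test_random_matrix_medians_equalized(self):
        rng = np.random.default_rng(3)
        vals = pd.DataFrame(
            rng.lognormal(5, 1, size=(200, 6)),
            index=[f"P{i}" for i in range(200)],
            columns=[f"s{i}" for i in range(6)],
        )
        matrix = QuantMatrix(vals, {f"s{i}": "g1" if i < 3 else "g2" for i in range(6)})
        normed = normalize_intensities(matrix)
        medians = normed.intensities.median(axis=0)
        assert np.allclose(medians, medians.iloc[0])

    def test_missing_cells_stay_missing(self, tiny_quant):
        matrix, _ = tiny_quant
        vals = matrix.intensities.copy()
        vals.iloc[0, 0] = np.nan
        normed = normalize_intensities(QuantMatrix(vals, matrix.group_of))
        assert np.isnan(normed.intensities.iloc[0, 0])

    def test_empty_sample_rejected(self, tiny_quant):
        matrix, _ = tiny_quant
        vals = matrix.intensities.copy()
        vals["case_1"] = np.nan
        with pytest.raises(ValueError, match="no observed"):
            normalize_intensities(QuantMatrix(vals, matrix.group_of))


class TestFoldChange:
    @pytest.mark.parametrize(
        "case,control,expected_signed,expected_mag",
        [
            ([10.0, 10.0], [10.0, 10.0], 1.0, 1.0),
            ([29.0, 31.0], [19.0, 21.0], 1.5, 1.5),
            ([19.0, 21.0], [29.0, 31.0], 2 / 3, 1.5),
        ],
    )
    def test_arithmetic(self, case, control, expected_signed, expected_mag):
        signed, mag = fold_change(case, control)
        assert signed == pytest.approx(expected_signed)
        assert mag == pytest.approx(expected_mag)

    def test_magnitude_symmetric_under_swap(self):
        rng = np.random.default_rng(1)
        a, b = rng.lognormal(3, 1, 4), rng.lognormal(3, 1, 4)
        s1, m1 = fold_change(a, b)
        s2, m2 = fold_change(b, a)
        assert s2 == pytest.approx(1 / s1)
        assert m2 == pytest.approx(m1)
        assert m1 >= 1

    def test_empty_side_rejected(self):
        with pytest.raises(ValueError, match="observed value"):
            fold_change([], [1.0])

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError, match="non-positive"):
            fold_change([0.0, 0.0], [1.0, 1.0])


class TestAnova:
    def test_identical_groups_give_p_one(self):
        assert anova_p([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]]) == pytest.approx(1.0)

    def test_constant_data_gives_p_one(self):
        assert anova_p([[5.0, 5.0], [5.0, 5.0]]) == 1.0

    def test_two_group_anova_equals_pooled_t_test(self):
        # F = t² for two groups: ANOVA p must equal the two-sided
        # pooled-variance t-test p
        rng = np.random.default_rng(42)
        for _ in range(50):
            a = rng.normal(0, 1, rng.integers(3, 8))
            b = rng.normal(0.5, 1.5, rng.integers(3, 8))
            p_anova = anova_p([a, b])
            p_t = stats.ttest_ind(a, b, equal_var=True).pvalue
            assert abs(p_anova - p_t) < 1e-10

    def test_undersized_group_rejected(self):
        with pytest.raises(ValueError, match="≥2 observed"):
            anova_p([[1.0], [2.0, 3.0]])


class TestCallDeps:
    def test_single_peptide_never_called(self, tiny_quant):
        matrix, meta = tiny_quant
        meta = meta.copy()
        meta["unique_peptides"] = [1, 5, 5]
        records = call_deps(matrix, meta, DEPParams(), "case", "control")
        assert not records[0].pass_peptides
        assert not records[0].is_dep

    def test_high_id_fdr_never_called(self, tiny_quant):
        matrix, meta = tiny_quant
        meta = meta.copy()
        meta["id_fdr"] = [0.02, 0.001, 0.001]
        records = call_deps(matrix, meta, DEPParams(), "case", "control")
        assert not records[0].pass_fdr
        assert not records[0].is_dep

    def test_fold_change_gate_is_inclusive(self, tiny_quant):
        # protein P00001 has means 30 vs 20, i.e. FC exactly 1.5
        matrix, meta = tiny_quant
        records = call_deps(
            matrix, meta, DEPParams(min_fc=1.5), "case", "control", normalize="none"
        )
        rec = records[0]
        assert rec.fc_magnitude == pytest.approx(1.5)
        assert rec.pass_fc

    def test_swapping_groups_inverts_sign_only(self, tiny_quant):
        matrix, meta = tiny_quant
        fwd = call_deps(matrix, meta, DEPParams(), "case", "control", normalize="none")
        rev = call_deps(matrix, meta, DEPParams(), "control", "case", normalize="none")
        for f, r in zip(fwd, rev):
            assert r.fc_signed == pytest.approx(1 / f.fc_signed)
            assert r.fc_magnitude == pytest.approx(f.fc_magnitude)
            assert r.p_value == pytest.approx(f.p_value)
            assert r.is_dep == f.is_dep

    def test_untestable_protein_reported_with_reason(self, tiny_quant):
        matrix, meta = tiny_quant
        vals = matrix.intensities.copy()
        vals.loc["P00002", ["case_1"]] = np.nan
        records = call_deps(
            QuantMatrix(vals, matrix.group_of), meta, DEPParams(), "case", "control",
            normalize="none",
        )
        rec = {r.accession: r for r in records}["P00002"]
        assert not rec.testable
        assert "replicate" in rec.reason
        assert not rec.is_dep

    def test_missing_group_rejected(self, tiny_quant):
        matrix, meta = tiny_quant
        with pytest.raises(ValueError, match="not present"):
            DifferentialExpression(matrix, meta, "treated", "control")

    def test_bh_correction_never_adds_calls(self):
        matrix, meta, _ = gen_quant_dataset(n_proteins=300, seed=8)
        raw = call_deps(matrix, meta, DEPParams(), "case", "control")
        adj = call_deps(matrix, meta, DEPParams(bh_correct=True), "case", "control")
        assert sum(r.is_dep for r in adj) <= sum(r.is_dep for r in raw)

    def test_planted_effects_are_recovered(self):
        matrix, meta, truth = gen_quant_dataset(
            n_proteins=1000, frac_dep=0.1, effect_log2=1.0, noise_sigma_log2=0.1,
            seed=21,
        )
        records = call_deps(matrix, meta, DEPParams(), "case", "control")
        perf = evaluate_calls(records, truth.dep_labels)
        assert perf["sensitivity"] >= 0.95
        assert perf["fdp"] <= 0.1

    def test_summary_reports_counts(self, tiny_quant):
        matrix, meta = tiny_quant
        results = DifferentialExpression(matrix, meta, "case", "control").fit()
        text = results.summary()
        assert "proteins" in text and "DEPs called" in text
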