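"""Signature scoring: collapse/standardize/score algebra against hand
computations, Welch comparison against the closed form, and the panel
driver's robustness contracts."""

import numpy as np
import pandas as pd
import pytest

from nrf2screen.signature import (ExpressionCohort, collapse_duplicate_genes,
                                  combined_score, compare_groups,
                                  run_signature_panel, standardize_genes)
from nrf2screen.synthetic import CohortSpec, generate_expression_cohort

from conftest import make_cohort


class TestCollapse:
    def test_median_of_duplicate_rows(self):
        values = pd.DataFrame([[2.0, 1.0], [4.0, 3.0], [9.0, 5.0]],
                              index=["NQO1", "NQO1", "NQO1"],
                              columns=["s1", "s2"])
        cohort = ExpressionCohort(values=values,
                                  labels=pd.Series({"s1": "tumour", "s2": "normal"}))
        out = collapse_duplicate_genes(cohort)
        assert out.values.loc["NQO1", "s1"] == 4.0  # median of [2, 4, 9]
        assert out.values.loc["NQO1", "s2"] == 3.0

    def test_even_count_median_is_midpoint(self):
        values = pd.DataFrame([[1.0], [3.0]], index=["G", "G"], columns=["s1"])
        labels = pd.Series({"s1": "tumour"})
        out = collapse_duplicate_genes(ExpressionCohort(values, labels))
        assert out.values.loc["G", "s1"] == 2.0

    def test_no_duplicates_is_identity(self):
        cohort = make_cohort({"A": [1, 2], "B": [3, 4]},
                             {"s1": "tumour", "s2": "normal"})
        out = collapse_duplicate_genes(cohort)
        pd.testing.assert_frame_equal(out.values, cohort.values)


class TestStandardize:
    def test_hand_computed_z(self):
        cohort = make_cohort({"A": [1.0, 2.0, 3.0]},
                             {"s1": "tumour", "s2": "tumour", "s3": "normal"})
        z = standardize_genes(cohort)
        np.testing.assert_allclose(z.loc["A"], [-1.0, 0.0, 1.0])  # sd ddof=1

    def test_rows_have_zero_mean_unit_sd(self, rng):
        vals = {f"G{i}": rng.lognormal(size=8) for i in range(10)}
        labels = {f"s{j}": "tumour" if j < 4 else "normal" for j in range(8)}
        z = standardize_genes(make_cohort(vals, labels))
        np.testing.assert_allclose(z.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(z.std(axis=1, ddof=1), 1.0, atol=1e-12)

    def test_constant_gene_raises_with_name(self):
        cohort = make_cohort({"FLAT": [5.0, 5.0, 5.0]},
                             {"s1": "tumour", "s2": "tumour", "s3": "normal"})
        with pytest.raises(ValueError, match="FLAT"):
            standardize_genes(cohort)


class TestCombinedScore:
    def test_singleton_set_equals_gene_z_score(self):
        cohort = make_cohort({"NQO1": [1.0, 4.0, 7.0], "X": [2.0, 2.0, 9.0]},
                             {"s1": "tumour", "s2": "tumour", "s3": "normal"})
        z = standardize_genes(cohort)
        score = combined_score(z, ["NQO1"])
        pd.testing.assert_series_equal(score.per_sample_score, z.loc["NQO1"],
                                       check_names=False)

    def test_two_gene_score_matches_hand_computation(self):
        cohort = make_cohort({"A": [1.0, 2.0, 3.0], "B": [2.0, 2.0, 5.0]},
                             {"s1": "tumour", "s2": "tumour", "s3": "normal"})
        score = combined_score(standardize_genes(cohort), ["A", "B"])
        # z(A) = [-1, 0, 1]; z(B) = [-1, -1, 2]/sqrt(3); mean of the two rows
        expected = (np.array([-1.0, 0.0, 1.0])
                    + np.array([-1.0, -1.0, 2.0]) / np.sqrt(3.0)) / 2.0
        np.testing.assert_allclose(score.per_sample_score, expected)

    def test_cohort_mean_is_zero(self, rng):
        vals = {f"G{i}": rng.lognormal(size=20) for i in range(15)}
        labels = {f"s{j}": "tumour" if j < 12 else "normal" for j in range(20)}
        z = standardize_genes(make_cohort(vals, labels))
        score = combined_score(z, [f"G{i}" for i in range(7)])
        assert abs(score.per_sample_score.mean()) < 1e-9

    def test_missing_genes_listed(self):
        cohort = make_cohort({"A": [1.0, 2.0, 3.0]},
                             {"s1": "tumour", "s2": "tumour", "s3": "normal"})
        with pytest.raises(KeyError, match="NOPE"):
            combined_score(standardize_genes(cohort), ["A", "NOPE"])

    def test_invariant_to_gene_wise_affine_rescaling(self, rng):
        vals = {f"G{i}": rng.lognormal(size=10) for i in range(6)}
        labels = {f"s{j}": "tumour" if j < 6 else "normal" for j in range(10)}
        cohort = make_cohort(vals, labels)
        scaled = ExpressionCohort(
            cohort.values.mul(rng.uniform(0.5, 4.0, 6), axis=0)
            .add(rng.uniform(0, 10, 6), axis=0),
            cohort.labels)
        genes = [f"G{i}" for i in range(4)]
        s1 = combined_score(standardize_genes(cohort), genes).per_sample_score
        s2 = combined_score(standardize_genes(scaled), genes).per_sample_score
        np.testing.assert_allclose(s1, s2, atol=1e-10)


class TestCompareGroups:
    def test_identical_groups_null(self):
        cohort = make_cohort({"A": [1.0, 2.0, 1.0, 2.0]},
                             {"s1": "tumour", "s2": "tumour",
                              "s3": "normal", "s4": "normal"})
        z = standardize_genes(cohort)
        cmp = compare_groups(combined_score(z, ["A"]), cohort.labels)
        assert cmp.t_statistic == pytest.approx(0.0, abs=1e-12)
        assert cmp.p_value == pytest.approx(1.0)

    def test_matches_closed_form_welch(self):
        score_vals = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
                               index=[f"s{i}" for i in range(6)])
        labels = pd.Series(["tumour"] * 3 + ["normal"] * 3,
                           index=score_vals.index)
        from nrf2screen.signature import SignatureScore
        cmp = compare_groups(SignatureScore(("A",), score_vals), labels)
        # hand computation: means 2 and 5, s^2 = 1, n = 3 each
        assert cmp.t_statistic == pytest.approx(-3.6742346141747673)
        assert cmp.df == pytest.approx(4.0)
        assert cmp.p_value == pytest.approx(0.0213116411287567, rel=1e-10)

    def test_small_group_rejected(self):
        cohort = make_cohort({"A": [1.0, 2.0, 3.0]},
                             {"s1": "tumour", "s2": "tumour", "s3": "normal"})
        z = standardize_genes(cohort)
        with pytest.raises(ValueError, match="2 samples per group"):
            compare_groups(combined_score(z, ["A"]), cohort.labels)


class TestPanel:
    def test_true_effect_detected_in_both_default_sets(self):
        cohort = generate_expression_cohort(
            CohortSpec(n_tumour=50, n_normal=50, n_genes=100, log2_effect=1.0,
                       noise_sd=0.5, seed=9))
        panel = run_signature_panel(cohort).set_index("gene_set")
        for name in ("NQO1", "NRF2_5gene"):
            row = panel.loc[name]
            assert row["status"] == "ok"
            assert row["p"] < 1e-6
            assert row["mean_tumour"] > row["mean_normal"]

    def test_missing_gene_set_flagged_but_run_continues(self):
        cohort = generate_expression_cohort(
            CohortSpec(n_tumour=10, n_normal=10, n_genes=50, seed=0))
        panel = run_signature_panel(
            cohort, {"good": ("NQO1",), "bad": ("NOT_A_GENE",)}
        ).set_index("gene_set")
        assert panel.loc["good", "status"] == "ok"
        assert panel.loc["bad", "status"].startswith("failed")

    def test_sign_of_score_difference_tracks_effect_sign(self):
        for effect in (0.7, -0.7):
            cohort = generate_expression_cohort(
                CohortSpec(n_tumour=60, n_normal=60, n_genes=80,
                           log2_effect=effect, noise_sd=0.5, seed=21))
            panel = run_signature_panel(cohort).set_index("gene_set")
            diff = (panel.loc["NRF2_5gene", "mean_tumour"]
                    - panel.loc["NRF2_5gene", "mean_normal"])
            assert np.sign(diff) == np.sign(effect)
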