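"""Imputation, standardization, T-scores, fold change, BH and PCA checks."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prosteo import preprocess as pp

from conftest import make_protein_frame


class TestHalfMinImputation:
    def test_missing_cell_gets_half_minimum(self):
        m = make_protein_frame([[2.0], [np.nan], [4.0]])
        out = pp.impute_half_min(m)
        assert list(out.iloc[:, 0]) == [2.0, 1.0, 4.0]

    def test_complete_column_unchanged(self):
        m = make_protein_frame([[1.0, 5.0], [2.0, 6.0]])
        pd.testing.assert_frame_equal(pp.impute_half_min(m), m)

    def test_fully_missing_column_errors_with_name(self):
        m = make_protein_frame([[np.nan, 1.0], [np.nan, 2.0]], columns=["bad", "ok"])
        with pytest.raises(ValueError, match="bad"):
            pp.impute_half_min(m)

    def test_fit_transform_split(self):
        """Minima learned on one set apply unchanged to another."""
        imp = pp.HalfMinImputer().fit(make_protein_frame([[4.0], [8.0]]))
        out = imp.transform(make_protein_frame([[np.nan], [10.0]]))
        assert out.iloc[0, 0] == 2.0


class TestStandardize:
    def test_basic_z_scores(self):
        m = make_protein_frame([[1.0], [2.0], [3.0]])
        z, params = pp.standardize(m)
        np.testing.assert_allclose(z.iloc[:, 0], [-1.0, 0.0, 1.0])
        assert params.loc["P0", "sd"] == 1.0  # ddof=1

    def test_idempotent_on_same_fit_set(self):
        m = make_protein_frame([[1.0], [2.0], [3.0]])
        z1, _ = pp.standardize(m)
        z2, _ = pp.standardize(z1)
        np.testing.assert_allclose(z1.to_numpy(), z2.to_numpy(), atol=1e-12)

    def test_constant_column_errors(self):
        with pytest.raises(ValueError, match="P0"):
            pp.standardize(make_protein_frame([[1.0], [1.0]]))

    def test_fit_subset_applied_to_all_rows(self):
        m = make_protein_frame([[0.0], [2.0], [100.0]])
        z, _ = pp.standardize(m, fit_on=[0, 1])
        # mean 1, sd sqrt(2) from the fitting rows
        np.testing.assert_allclose(z.iloc[:, 0], (m.iloc[:, 0] - 1.0) / np.sqrt(2.0))

    def test_impute_then_standardize_commutes_with_row_permutation(self, rng):
        m = make_protein_frame(rng.normal(size=(30, 4)))
        m.iloc[rng.integers(0, 30, 10), rng.integers(0, 4, 10)] = np.nan
        z = pp.standardize(pp.impute_half_min(m))[0]
        perm = rng.permutation(30)
        z_perm = pp.standardize(pp.impute_half_min(m.iloc[perm]))[0]
        np.testing.assert_allclose(z.iloc[perm].to_numpy(), z_perm.to_numpy(), atol=1e-12)


class TestTScore:
    @pytest.mark.parametrize(
        "bmd,expected_t,expected_status",
        [(0.64, -3.0, "osteoporosis"), (0.82, -1.5, "osteopenia"), (1.00, 0.0, "normal")],
    )
    def test_examples(self, bmd, expected_t, expected_status):
        t, status = pp.tscore_classify(bmd, 1.00, 0.12)
        assert t == pytest.approx(expected_t)
        assert status == expected_status

    def test_treated_override(self):
        _, status = pp.tscore_classify(1.00, 1.00, 0.12, treated=True)
        assert status == "osteoporosis"

    def test_invalid_ref_sd(self):
        with pytest.raises(ValueError):
            pp.tscore_classify(1.0, 1.0, 0.0)

    @given(st.floats(min_value=-10, max_value=10, allow_nan=False))
    @settings(deadline=None)
    def test_partition_is_total(self, t_value):
        """Every T-score maps to exactly one status; boundaries are half-open
        (osteoporosis T < -2.5, osteopenia -2.5 <= T < -1, normal T >= -1)."""
        _, status = pp.tscore_classify(t_value, 0.0, 1.0)
        if t_value < -2.5:
            assert status == "osteoporosis"
        elif t_value < -1.0:
            assert status == "osteopenia"
        else:
            assert status == "normal"


class TestFoldChange:
    def test_formula_and_welch_example(self):
        m = make_protein_frame([[3.0], [4.0], [5.0], [1.0], [2.0], [3.0]])
        out = pp.fold_change(m, case_rows=[0, 1, 2], control_rows=[3, 4, 5])
        assert out["fc"].iloc[0] == pytest.approx(1.0)
        # Welch t = 2/sqrt(2/3) = 2.449, df ~= 4
        assert out["p"].iloc[0] == pytest.approx(0.0705, abs=5e-3)

    def test_identical_groups(self):
        m = make_protein_frame([[1.0], [2.0], [1.0], [2.0]])
        out = pp.fold_change(m, [0, 1], [2, 3])
        assert out["fc"].iloc[0] == 0.0
        assert out["p"].iloc[0] >= 0.99

    def test_empty_group_rejected(self):
        m = make_protein_frame([[1.0], [2.0]])
        with pytest.raises(ValueError):
            pp.fold_change(m, [], [0, 1])

    def test_zero_control_mean_rejected(self):
        m = make_protein_frame([[1.0], [-1.0], [1.0], [2.0]])
        with pytest.raises(ValueError, match="control mean"):
            pp.fold_change(m, [2, 3], [0, 1])


class TestBhAdjust:
    def test_worked_example(self):
        np.testing.assert_allclose(
            pp.bh_adjust([0.002, 0.01, 0.03, 0.04]), [0.008, 0.02, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert pp.bh_adjust([0.3])[0] == 0.3

    def test_ties_collapse(self):
        np.testing.assert_allclose(pp.bh_adjust([0.05] * 10), [0.05] * 10)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            pp.bh_adjust([0.5, 1.2])

    def test_matches_brute_force_definition(self, rng):
        """q(i) = min over j >= i of min(1, m p(j)/j) on 1000 random vectors."""
        for _ in range(1000):
            m = int(rng.integers(1, 20))
            p = rng.random(m)
            q = pp.bh_adjust(p)
            order = np.argsort(p, kind="stable")
            expected = np.empty(m)
            for rank_pos, idx in enumerate(order):
                candidates = [
                    min(1.0, m * p[order[j]] / (j + 1)) for j in range(rank_pos, m)
                ]
                expected[idx] = min(candidates)
            np.testing.assert_allclose(q, expected, atol=1e-12)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.random(100)
        np.testing.assert_allclose(
            pp.bh_adjust(p), multipletests(p, method="fdr_bh")[1], atol=1e-12
        )


class TestPcaBatchCheck:
    def test_identical_batches_show_no_gap(self, rng):
        x = rng.normal(size=(40, 5))
        data = np.vstack([x, x])
        labels = ["a"] * 40 + ["b"] * 40
        out = pp.pca_batch_check(make_protein_frame(data), labels)
        assert out["pc1_batch_gap_sd"] == pytest.approx(0.0, abs=1e-10)

    def test_rank_one_matrix(self, rng):
        u = rng.normal(size=50)
        data = np.outer(u, [1.0, 2.0, 3.0])
        out = pp.pca_batch_check(make_protein_frame(data), ["a"] * 50)
        assert out["explained_variance_ratio"][0] == pytest.approx(1.0)
        assert np.isnan(out["pc1_batch_gap_sd"])

    def test_known_covariance_eigenvalue_share(self, rng):
        # diag(2, 1) covariance: PC1 share -> 2/3
        data = rng.normal(size=(20000, 2)) * np.sqrt([2.0, 1.0])
        out = pp.pca_batch_check(make_protein_frame(data), ["a"] * 20000)
        assert out["explained_variance_ratio"][0] == pytest.approx(2.0 / 3.0, abs=0.02)


class TestPairedT:
    def test_equal_samples(self):
        t, df, p = pp.paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (t, p) == (0.0, 1.0)

    def test_worked_example(self):
        # differences (1, 2, 3): mean 2, sd 1, t = 2/(1/sqrt(3)) = 3.464
        t, df, p = pp.paired_t([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(3.464, abs=1e-3)
        assert df == 2
        assert p == pytest.approx(0.0745, abs=2e-3)

    def test_degenerate_and_precondition(self):
        t, _, p = pp.paired_t([2.0, 3.0], [1.0, 2.0])  # constant nonzero diff
        assert np.isinf(t) and p == 0.0
        with pytest.raises(ValueError):
            pp.paired_t([1.0], [2.0])
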