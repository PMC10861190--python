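"""Two-sample Mendelian randomization estimators."""

import numpy as np
import pandas as pd
import pytest

from prosteo import mr, synth


def _inst(b_x, b_y, se_y, se_x=0.01):
    return pd.DataFrame({
        "b_x": b_x, "b_y": b_y,
        "se_x": np.full(len(b_x), se_x), "se_y": se_y,
    })


class TestFilterInstruments:
    @pytest.mark.parametrize("p,kept", [(4e-8, True), (5e-8, True), (6e-8, False)])
    def test_threshold_boundary(self, p, kept):
        rows = pd.DataFrame({"p_x": [p, 1e-10]})
        out = mr.filter_instruments(rows)
        assert (len(out) == 2) is kept

    def test_all_filtered_rejected(self):
        with pytest.raises(ValueError):
            mr.filter_instruments(pd.DataFrame({"p_x": [0.5, 0.1]}))


class TestHarmonize:
    def _frames(self, ea_o, oa_o, b_y=0.05, eaf=0.3):
        exposure = pd.DataFrame({
            "snp": ["rs1"], "effect_allele": ["A"], "other_allele": ["G"],
            "beta": [0.1], "se": [0.01], "pval": [1e-10], "eaf": [eaf],
        })
        outcome = pd.DataFrame({
            "snp": ["rs1"], "effect_allele": [ea_o], "other_allele": [oa_o],
            "beta": [b_y], "se": [0.02],
        })
        return exposure, outcome

    def test_swapped_alleles_flip_sign(self):
        out = mr.harmonize(*self._frames("G", "A"))
        assert out.loc[0, "b_y"] == pytest.approx(-0.05)

    def test_matching_alleles_unchanged(self):
        out = mr.harmonize(*self._frames("A", "G"))
        assert out.loc[0, "b_y"] == pytest.approx(0.05)

    def test_complementary_strand_flip(self):
        # exposure A/G; outcome on the other strand with swapped order C/T
        out = mr.harmonize(*self._frames("C", "T"))
        assert out.loc[0, "b_y"] == pytest.approx(-0.05)

    def test_palindromic_intermediate_eaf_dropped(self):
        exposure = pd.DataFrame({
            "snp": ["rs1"], "effect_allele": ["A"], "other_allele": ["T"],
            "beta": [0.1], "se": [0.01], "pval": [1e-10], "eaf": [0.5],
        })
        outcome = pd.DataFrame({
            "snp": ["rs1"], "effect_allele": ["A"], "other_allele": ["T"],
            "beta": [0.05], "se": [0.02],
        })
        with pytest.raises(ValueError):
            mr.harmonize(exposure, outcome)

    def test_incompatible_alleles_dropped(self):
        with pytest.raises(ValueError):
            mr.harmonize(*self._frames("A", "C"))

    def test_idempotent(self):
        exposure, outcome = self._frames("G", "A")
        once = mr.harmonize(exposure, outcome)
        out2 = once.rename(columns={"b_y": "beta", "se_y": "se"})[
            ["snp", "effect_allele", "other_allele", "beta", "se"]
        ]
        exp2 = once.rename(columns={"b_x": "beta", "se_x": "se", "p_x": "pval"})[
            ["snp", "effect_allele", "other_allele", "beta", "se", "pval", "eaf"]
        ]
        twice = mr.harmonize(exp2, out2)
        assert twice.loc[0, "b_y"] == pytest.approx(once.loc[0, "b_y"])


class TestWaldRatio:
    def test_formula(self):
        est = mr.wald_ratio(0.1, 0.01, 0.05, 0.02)
        assert est.beta == pytest.approx(0.5)
        assert est.se == pytest.approx(0.2)

    def test_zero_outcome_and_sign(self):
        assert mr.wald_ratio(0.1, 0.01, 0.0, 0.02).beta == 0.0
        assert mr.wald_ratio(-0.1, 0.01, 0.05, 0.02).beta == pytest.approx(-0.5)

    def test_zero_exposure_rejected(self):
        with pytest.raises(ValueError):
            mr.wald_ratio(0.0, 0.01, 0.05, 0.02)


class TestIvw:
    def test_hand_computed_two_snp_example(self):
        inst = _inst([0.1, 0.2], [0.02, 0.05], [0.01, 0.01])
        est = mr.ivw(inst)
        assert est.beta == pytest.approx(0.24)
        assert est.se == pytest.approx(np.sqrt(1 / (10000 * 0.05)), abs=5e-4)

    def test_identical_snps_equal_wald(self):
        inst = _inst([0.1, 0.1], [0.05, 0.05], [0.02, 0.02])
        est = mr.ivw(inst)
        wald = mr.wald_ratio(0.1, 0.01, 0.05, 0.02)
        assert est.beta == pytest.approx(wald.beta)

    def test_single_snp_rejected(self):
        with pytest.raises(ValueError):
            mr.ivw(_inst([0.1], [0.05], [0.02]))

    def test_generator_theta_recovered(self):
        table, _ = synth.generate_mr_summary(50, theta_true=0.5, pleiotropy_sd=0.0, seed=8)
        est = mr.ivw(table)
        assert est.beta == pytest.approx(0.5, abs=3 * est.se)


class TestEgger:
    def test_exact_line_recovers_slope_and_intercept(self):
        b_x = np.array([0.1, 0.2, 0.3, 0.4])
        b_y = 0.1 + 0.3 * b_x
        slope, intercept = mr.mr_egger(_inst(b_x, b_y, np.full(4, 0.01)))
        assert slope.beta == pytest.approx(0.3, abs=1e-10)
        assert intercept.beta == pytest.approx(0.1, abs=1e-10)

    def test_null_intercept_coverage(self):
        """With no pleiotropy the Egger intercept CI covers 0 in ~95% of reps."""
        from scipy import stats

        hits = 0
        n_reps = 200
        for rep in range(n_reps):
            table, _ = synth.generate_mr_summary(
                30, theta_true=0.4, pleiotropy_sd=0.0, seed=5000 + rep
            )
            _, intercept = mr.mr_egger(table)
            crit = stats.t.ppf(0.975, len(table) - 2)
            if abs(intercept.beta) < crit * intercept.se:
                hits += 1
        assert 0.90 <= hits / n_reps <= 0.99

    def test_constant_bx_rejected(self):
        with pytest.raises(ValueError):
            mr.mr_egger(_inst([0.1, 0.1, 0.1], [0.02, 0.03, 0.04], [0.01] * 3))


class TestWeightedMedian:
    def test_equal_weight_median(self):
        inst = _inst([0.1, 0.1, 0.1], [0.01, 0.02, 0.09], [0.01, 0.01, 0.01])
        est = mr.weighted_median(inst, n_boot=50, seed=0)
        assert est.beta == pytest.approx(0.2, abs=1e-9)

    def test_dominant_snp_wins(self):
        inst = _inst([0.1, 0.1, 0.1], [0.01, 0.05, 0.09],
                     [1e-4, 0.5, 0.5])  # first SNP holds nearly all weight
        est = mr.weighted_median(inst, n_boot=50, seed=0)
        assert est.beta == pytest.approx(0.1, abs=0.02)

    def test_robust_to_half_invalid_instruments(self):
        """50% directionally pleiotropic SNPs: the weighted median stays near
        theta while IVW is biased."""
        table, _ = synth.generate_mr_summary(
            100, theta_true=0.3, pleiotropy_sd=0.05, seed=99,
            frac_pleiotropic=0.5, pleiotropy_mean=0.15,
            se_y_range=(0.005, 0.015), pleiotropy_on_weakest=True,
        )
        wm = mr.weighted_median(table, seed=1)
        est_ivw = mr.ivw(table)
        assert abs(wm.beta - 0.3) < 0.1
        assert abs(est_ivw.beta - 0.3) > abs(wm.beta - 0.3)

    def test_too_few_snps(self):
        with pytest.raises(ValueError):
            mr.weighted_median(_inst([0.1, 0.2], [0.01, 0.02], [0.01, 0.01]))


class TestModeEstimators:
    def test_all_equal_ratios(self):
        inst = _inst([0.1, 0.2, 0.4], [0.03, 0.06, 0.12], [0.01] * 3)
        est = mr.mode_estimators(inst, "simple", seed=0, n_boot=50)
        assert est.beta == pytest.approx(0.3, abs=1e-3)

    def test_majority_cluster_beats_outliers(self):
        rng = np.random.default_rng(0)
        b_x = rng.uniform(0.1, 0.3, 12)
        b_y = 0.3 * b_x
        b_y[-2:] = 2.0 * b_x[-2:]  # two strong outliers
        inst = _inst(b_x, b_y, np.full(12, 0.005))
        est = mr.mode_estimators(inst, "simple", seed=0, n_boot=50)
        assert est.beta == pytest.approx(0.3, abs=0.1)

    def test_weighted_vs_simple_differ_with_precise_outlier(self):
        b_x = np.array([0.1, 0.12, 0.14, 0.2])
        b_y = np.array([0.03, 0.036, 0.042, 0.4])  # outlier ratio 2.0
        se_y = np.array([0.05, 0.05, 0.05, 1e-5])  # outlier extremely precise
        inst = _inst(b_x, b_y, se_y)
        simple = mr.mode_estimators(inst, "simple", seed=0, n_boot=20)
        weighted = mr.mode_estimators(inst, "weighted", seed=0, n_boot=20)
        assert simple.beta == pytest.approx(0.3, abs=0.1)
        assert weighted.beta == pytest.approx(2.0, abs=0.2)


def test_estimators_agree_without_pleiotropy():
    """With no pleiotropy, every pair of causal estimates is compatible at
    roughly the 2-sigma level of its own uncertainties across 20 seeds."""
    for seed in range(20):
        table, _ = synth.generate_mr_summary(100, theta_true=0.4, pleiotropy_sd=0.0,
                                             seed=7000 + seed)
        ests = [e for e in mr.run_all_estimators(table, seed=seed, n_boot=200)
                if e.method != "egger_intercept"]
        for i in range(len(ests)):
            for j in range(i + 1, len(ests)):
                assert abs(ests[i].beta - ests[j].beta) < 2 * (ests[i].se + ests[j].se), (
                    ests[i].method, ests[j].method)
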