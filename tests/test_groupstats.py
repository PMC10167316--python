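"""Group statistics: t-tests, chi-square, BH-FDR, channel-wise testing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.multitest import multipletests

from eegvuln.features import FeatureTable
from eegvuln.groupstats import (
    channelwise_group_test,
    chi2_2x2,
    export_topography,
    fdr_bh,
    ttest_from_summary,
    ttest_independent,
)


def _table(values: np.ndarray, groups) -> FeatureTable:
    idx = [f"s{i}" for i in range(len(values))]
    cols = [f"log_power|delta|ch{j}" for j in range(values.shape[1])]
    return FeatureTable(pd.DataFrame(values, index=idx, columns=cols),
                        pd.Series(groups, index=idx, name="group"))


class TestTTest:
    def test_identical_samples_give_t_zero_p_one(self):
        r = ttest_independent([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.t == pytest.approx(0.0)
        assert r.p == pytest.approx(1.0)

    def test_toy_samples_match_hand_computation(self):
        # {1,2,3} vs {4,5,6}: pooled sd = 1, se = sqrt(2/3), t = -3/se
        r = ttest_independent([1, 2, 3], [4, 5, 6], variant="pooled")
        assert r.t == pytest.approx(-3.674, abs=5e-4)
        assert r.df == 4

    def test_sign_follows_mean_difference(self):
        r = ttest_independent([5.0, 6.0, 7.0], [1.0, 2.0, 3.0])
        assert r.t > 0

    def test_welch_df_below_pooled_for_unequal_variances(self):
        a = [1.0, 2.0, 3.0, 4.0]
        b = [10.0, 30.0, 50.0, 70.0]
        pooled = ttest_independent(a, b, "pooled")
        welch = ttest_independent(a, b, "welch")
        assert welch.df < pooled.df

    def test_summary_matches_samples_constructed_to_summaries(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(20)
        x = (x - x.mean()) / x.std(ddof=1)  # exactly mean 0, sd 1
        a = 45.85 + 4.70 * x
        y = rng.standard_normal(20)
        y = (y - y.mean()) / y.std(ddof=1)
        b = 25.10 + 8.33 * y
        r_samples = ttest_independent(a, b)
        r_summary = ttest_from_summary(45.85, 4.70, 20, 25.10, 8.33, 20)
        assert r_samples.t == pytest.approx(r_summary.t, rel=1e-9)
        assert r_samples.p == pytest.approx(r_summary.p, rel=1e-9)

    def test_degenerate_equal_constant_samples_rejected(self):
        with pytest.raises(ValueError):
            ttest_independent([2.0, 2.0], [2.0, 2.0])

    def test_equal_means_summary_gives_t_zero(self):
        assert ttest_from_summary(5, 1, 10, 5, 2, 10).t == 0.0

    def test_invalid_summary_inputs_rejected(self):
        with pytest.raises(ValueError):
            ttest_from_summary(1, 0.0, 10, 2, 1, 10)
        with pytest.raises(ValueError):
            ttest_from_summary(1, 1, 1, 2, 1, 10)


class TestChi2:
    def test_gender_table_reproduces_printed_statistic(self):
        r = chi2_2x2([[16, 4], [9, 11]], correction="none")
        assert r.chi2 == pytest.approx(5.23, abs=0.005)
        assert r.df == 1

    def test_homogeneous_table_gives_zero(self):
        assert chi2_2x2([[10, 10], [10, 10]]).chi2 == 0.0

    def test_hand_computed_table(self):
        # [[20,10],[10,20]]: E=15 everywhere, chi2 = 4*25/15 = 6.667
        r = chi2_2x2([[20, 10], [10, 20]])
        assert r.chi2 == pytest.approx(6.667, abs=5e-4)

    def test_yates_correction_reduces_statistic(self):
        plain = chi2_2x2([[16, 4], [9, 11]], "none").chi2
        yates = chi2_2x2([[16, 4], [9, 11]], "yates").chi2
        assert yates < plain

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi2_2x2([[0, 0], [5, 5]])


class TestFDR:
    def test_all_small_pvalues_rejected(self):
        r = fdr_bh([0.01, 0.02, 0.03, 0.04, 0.05], q=0.05)
        assert r.reject.all()
        assert r.p_threshold == 0.05

    def test_all_ones_rejects_nothing(self):
        r = fdr_bh([1.0] * 10, q=0.05)
        assert not r.reject.any()
        assert r.p_threshold == 0.0

    def test_single_small_pvalue_rejected(self):
        assert fdr_bh([0.01], q=0.05).reject.all()

    def test_empty_family_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh([])

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=200),
           st.sampled_from([0.01, 0.05, 0.1]))
    def test_matches_brute_force_definition_and_statsmodels(self, pvals, q):
        p = np.array(pvals)
        r = fdr_bh(p, q)
        # brute force: largest i with p_(i) <= i q / m, reject p <= p_(i)
        m = len(p)
        sp = np.sort(p)
        thr, found = 0.0, False
        for i in range(m, 0, -1):
            if sp[i - 1] <= i * q / m:
                thr, found = sp[i - 1], True
                break
        assert r.p_threshold == pytest.approx(thr)
        assert np.array_equal(r.reject, p <= thr if found else np.zeros(m, bool))
        ref_reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
        assert np.array_equal(r.reject, ref_reject)

    def test_monotone_in_q(self, rng):
        p = rng.random(100) ** 2
        r1 = fdr_bh(p, 0.01)
        r5 = fdr_bh(p, 0.05)
        assert np.all(r5.reject[r1.reject])  # rejections at 0.01 subset of 0.05


class TestChannelwise:
    def test_planted_mean_shift_detected_and_masked_t_contract(self, rng):
        x = rng.standard_normal((40, 8))
        x[:20, 3] += 2.0  # strong effect in channel 3 for the high group
        ft = _table(x, ["high"] * 20 + ["low"] * 20)
        gsr = channelwise_group_test(ft, q=0.05)
        assert "log_power|delta|ch3" in gsr.significant
        assert np.all(gsr.masked_t[~gsr.fdr.reject] == 0.0)
        assert np.all(gsr.masked_t[gsr.fdr.reject] == gsr.t[gsr.fdr.reject])

    def test_label_permutation_keeps_empirical_fdr_below_q(self, rng):
        # under permuted (null) labels, families with any rejection are rare
        x = rng.standard_normal((40, 16))
        false_rates = []
        for _ in range(200):
            labels = np.array(["high"] * 20 + ["low"] * 20)
            rng.shuffle(labels)
            gsr = channelwise_group_test(_table(x, labels), q=0.05)
            false_rates.append(1.0 if gsr.fdr.n_rejected > 0 else 0.0)
        # BH under independence bounds E[V/max(R,1)] by q; with all-null
        # hypotheses this equals the family-wise rejection rate
        assert np.mean(false_rates) <= 0.05 + 2.5 * np.sqrt(0.05 * 0.95 / 200)

    def test_missing_group_rejected(self, rng):
        ft = _table(rng.standard_normal((10, 3)), ["high"] * 10)
        with pytest.raises(ValueError):
            channelwise_group_test(ft)


class TestTopography:
    def _null_result(self, montage, rng):
        cols = [f"log_power|delta|{c}" for c in montage.channel_names]
        x = rng.standard_normal((40, 32))
        ft = FeatureTable(pd.DataFrame(x, index=[f"s{i}" for i in range(40)], columns=cols),
                          pd.Series(["high"] * 20 + ["low"] * 20,
                                    index=[f"s{i}" for i in range(40)]))
        return channelwise_group_test(ft, q=0.05)

    def test_export_roundtrip_and_channel_order(self, tmp_path, montage, rng):
        gsr = self._null_result(montage, rng)
        path = export_topography(gsr, montage, tmp_path / "topo.tsv")
        df = pd.read_csv(path, sep="\t")
        assert df["channel"].tolist() == list(montage.channel_names)
        assert np.allclose(df["t"], gsr.t)
        assert np.allclose(df["masked_t"], gsr.masked_t)
        x0, y0 = montage.position("Cz")
        row = df[df["channel"] == "Cz"].iloc[0]
        assert (row["x"], row["y"]) == (x0, y0)

    def test_null_result_has_all_zero_masked_t(self, tmp_path, montage, rng):
        gsr = self._null_result(montage, rng)
        if gsr.fdr.n_rejected == 0:
            path = export_topography(gsr, montage, tmp_path / "topo.tsv")
            df = pd.read_csv(path, sep="\t")
            assert (df["masked_t"] == 0.0).all()

    def test_unknown_channel_rejected(self, tmp_path, montage, rng):
        gsr = channelwise_group_test(
            _table(rng.standard_normal((10, 2)), ["high"] * 5 + ["low"] * 5)
        )
        with pytest.raises(KeyError):
            export_topography(gsr, montage, tmp_path / "x.tsv")
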