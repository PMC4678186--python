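import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from phenodrought.stats import (
    agreement,
    area_series,
    cmh_test,
    gof_chi2,
    percent_reduction,
    survival_summary,
    welch_t_test,
)

from .oracles import cmh_statistic, gof_p_closed_form


class TestAgreement:
    def test_perfect_agreement(self):
        labels = {f"s{i}": "healthy" for i in range(47)}
        rec = agreement(labels, labels, das=13)
        assert rec.percent == 100 and rec.matches == 47

    def test_39_of_47_rounds_to_83(self):
        pred = {f"s{i}": "stressed" for i in range(47)}
        actual = dict(pred)
        for i in range(8):
            actual[f"s{i}"] = "healthy"
        rec = agreement(pred, actual, das=13)
        assert rec.matches == 39
        assert rec.percent == 83  # 82.98 rounds up

    def test_mismatched_sample_sets_rejected(self):
        with pytest.raises(ValueError):
            agreement({"a": "healthy"}, {"b": "healthy"}, das=1)
        with pytest.raises(ValueError):
            agreement({}, {}, das=1)


class TestGofChi2:
    def test_observed_equals_expected(self):
        res = gof_chi2(25, 50)
        assert res.statistic == 0.0 and res.pvalue == 1.0

    @pytest.mark.parametrize(
        "m,n,printed",
        [
            (50, 50, "1.5e-12"),
            (49, 50, "1.1e-11"),
            (47, 50, "4.9e-10"),
            (47, 47, "7.1e-12"),
            (32, 50, "4.8e-02"),
            (38, 50, "2.4e-04"),
            (39, 47, "6.1e-06"),
        ],
    )
    def test_reproduces_published_pvalues(self, m, n, printed):
        assert f"{gof_chi2(m, n).pvalue:.1e}" == printed

    @settings(max_examples=100, derandomize=True)
    @given(st.integers(1, 200))
    def test_p_matches_df1_closed_form(self, n):
        m = (n * 3) // 4
        res = gof_chi2(m, n)
        assert res.pvalue == pytest.approx(gof_p_closed_form(res.statistic), rel=1e-12)

    def test_bad_counts_rejected(self):
        with pytest.raises(ValueError):
            gof_chi2(1, 0)
        with pytest.raises(ValueError):
            gof_chi2(5, 4)


class TestWelch:
    def test_identical_groups_p_one(self):
        res = welch_t_test([3.0, 4.0, 5.0], [3.0, 4.0, 5.0])
        assert res.statistic == pytest.approx(0.0)
        assert res.pvalue == pytest.approx(1.0)

    def test_closed_form_example(self):
        # t = 3/sqrt(2/3), Welch df = 4
        res = welch_t_test([1, 2, 3], [4, 5, 6])
        assert res.statistic == pytest.approx(-3 / np.sqrt(2 / 3))
        assert res.df == pytest.approx(4.0)
        assert res.pvalue == pytest.approx(0.021, abs=5e-4)

    def test_symmetric_in_groups(self, rng):
        x, y = rng.normal(0, 1, 10), rng.normal(1, 2, 12)
        assert welch_t_test(x, y).pvalue == pytest.approx(welch_t_test(y, x).pvalue)

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            welch_t_test([1.0], [2.0, 3.0])


class TestCMH:
    def test_single_stratum_relates_to_pearson(self):
        table = np.array([[[12, 5], [6, 14]]], dtype=float)
        res = cmh_test(table, correction=False)
        chi2 = sps.chi2_contingency(table[0], correction=False).statistic
        n = table.sum()
        # classical identity: CMH = (N - 1)/N * Pearson for one stratum
        assert res.statistic == pytest.approx((n - 1) / n * chi2, rel=1e-9)

    @pytest.mark.parametrize("correction", [True, False])
    def test_matches_formula_oracle(self, correction, rng):
        tables = rng.integers(3, 25, size=(4, 2, 2)).astype(float)
        res = cmh_test(tables, correction=correction)
        expected = cmh_statistic(tables, correction=correction)
        assert res.statistic == pytest.approx(expected, rel=1e-9)
        assert res.pvalue == pytest.approx(float(sps.chi2.sf(expected, 1)), rel=1e-9)

    def test_two_identical_strata_pool(self):
        t = np.array([[10, 4], [3, 9]], dtype=float)
        res = cmh_test(np.stack([t, t]), correction=False)
        assert res.statistic == pytest.approx(cmh_statistic(np.stack([t, t]), False))

    def test_empty_stratum_rejected(self):
        with pytest.raises(ValueError):
            cmh_test(np.array([[[5, 5], [5, 5]], [[0, 0], [0, 0]]], dtype=float))


class TestSummaries:
    def test_percent_reduction_signature_values(self):
        assert percent_reduction(100.0, 42.0) == pytest.approx(58.0)

    def test_area_series_groups_and_se(self):
        df = pd.DataFrame(
            {
                "sample_id": ["a", "b", "c", "d"],
                "line": ["WT", "WT", "WT", "drs1"],
                "treatment": ["well-watered"] * 4,
                "das": [20, 20, 20, 20],
                "area": [10.0, 12.0, 14.0, 9.0],
            }
        )
        out = area_series(df)
        wt = out[out["line"] == "WT"].iloc[0]
        assert wt["mean"] == pytest.approx(12.0)
        assert wt["se"] == pytest.approx(2.0 / np.sqrt(3))
        drs = out[out["line"] == "drs1"].iloc[0]
        assert np.isnan(drs["se"])  # single observation

    def test_area_series_constant_group_zero_se(self):
        df = pd.DataFrame(
            {
                "sample_id": list("abc"),
                "line": ["WT"] * 3,
                "treatment": ["well-watered"] * 3,
                "das": [20] * 3,
                "area": [5.0, 5.0, 5.0],
            }
        )
        assert area_series(df)["se"].iloc[0] == 0.0

    def test_survival_percentages(self):
        df = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(10)],
                "line": ["WT"] * 8 + ["drs1"] * 2,
                "treatment": ["water-limited"] * 10,
                "final_status": ["alive"] * 2 + ["dead"] * 6 + ["alive"] * 2,
            }
        )
        out = survival_summary(df).set_index("line")
        assert out.loc["WT", "pct_alive"] == pytest.approx(25.0)
        assert out.loc["drs1", "pct_alive"] == pytest.approx(100.0)
        assert np.allclose(out["pct_alive"] + out["pct_dead"], 100.0)

    def test_unknown_final_status_rejected(self):
        df = pd.DataFrame(
            {
                "sample_id": ["a"],
                "line": ["WT"],
                "treatment": ["water-limited"],
                "final_status": ["unknown"],
            }
        )
        with pytest.raises(ValueError):
            survival_summary(df)
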