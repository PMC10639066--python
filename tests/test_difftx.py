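import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pausekit.difftx import (
    bh_adjust,
    classify_deg,
    classify_dtg,
    classify_results,
    length_summary,
    ma_table,
    nb_wald_test,
    size_factors,
)


def bh_oracle(p):
    """Brute-force BH: independent of the vectorised implementation."""
    p = list(p)
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    adj = [None] * n
    prev = 1.0
    for rank_from_end, idx in enumerate(reversed(order)):
        rank = n - rank_from_end
        val = min(p[idx] * n / rank, prev)
        adj[idx] = min(val, 1.0)
        prev = adj[idx]
    return adj


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self, rng):
        counts = rng.integers(1, 1000, size=(100, 1))
        df = pd.DataFrame(np.hstack([counts, counts]), columns=["a", "b"])
        np.testing.assert_allclose(size_factors(df).to_numpy(), [1.0, 1.0])

    def test_doubled_sample_splits_geometric_mean(self, rng):
        a = rng.integers(1, 1000, size=(200,))
        df = pd.DataFrame({"a": a, "b": 2 * a})
        np.testing.assert_allclose(
            size_factors(df).to_numpy(), [1 / np.sqrt(2), np.sqrt(2)], rtol=1e-12
        )

    def test_permuting_samples_permutes_factors(self, rng):
        df = pd.DataFrame(rng.integers(1, 500, size=(150, 3)), columns=["a", "b", "c"])
        f1 = size_factors(df)
        f2 = size_factors(df[["c", "a", "b"]])
        for s in "abc":
            assert f1[s] == pytest.approx(f2[s], rel=1e-12)

    def test_scaling_one_sample_scales_its_factor(self, rng):
        df = pd.DataFrame(rng.integers(1, 500, size=(300, 2)), columns=["a", "b"])
        f1 = size_factors(df)
        df2 = df.copy()
        df2["b"] = df2["b"] * 4
        f2 = size_factors(df2)
        # up to the change of the geometric-mean reference (factor 4**(1/2))
        assert f2["b"] / f1["b"] == pytest.approx(4 / np.sqrt(4), rel=1e-9)

    def test_no_common_nonzero_gene_raises(self):
        df = pd.DataFrame({"a": [0, 5], "b": [3, 0]})
        with pytest.raises(ValueError, match="pseudocount"):
            size_factors(df)


class TestBH:
    def test_analytic_example(self):
        np.testing.assert_allclose(
            bh_adjust(np.array([0.01, 0.02, 0.03, 0.04])), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert bh_adjust(np.array([0.3]))[0] == 0.3

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.5, 1.5]))

    def test_matches_bruteforce_oracle_on_random_vectors(self, rng):
        for _ in range(200):
            p = rng.random(rng.integers(1, 60))
            np.testing.assert_allclose(bh_adjust(p), bh_oracle(p), rtol=1e-12)

    def test_matches_statsmodels_reference(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.random(500)
        _, ref, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(bh_adjust(p), ref, rtol=1e-12)


class TestNBWald:
    def _design(self):
        return {"t1": "T", "t2": "T", "c1": "C", "c2": "C"}

    def test_identical_groups_are_null(self, rng):
        a = rng.integers(10, 2000, size=(200,))
        df = pd.DataFrame({"t1": a, "t2": a, "c1": a, "c2": a})
        res = nb_wald_test(df, self._design(), "T", "C")
        np.testing.assert_allclose(res["log2FC"], 0.0, atol=1e-12)
        assert (res["p"] >= 0.999).all()

    def test_all_zero_gene_flagged(self):
        df = pd.DataFrame(
            {"t1": [0, 100], "t2": [0, 120], "c1": [0, 90], "c2": [0, 105]}
        )
        res = nb_wald_test(df, self._design(), "T", "C")
        assert res.loc[0, "allZero"]
        assert res.loc[0, "p"] == 1.0 and res.loc[0, "log2FC"] == 0.0

    def test_null_type_one_error_calibrated(self, rng):
        """2-vs-2 NB null (alpha=0.05): rejections at p<0.05 stay near nominal."""
        n = 5000
        mu = rng.lognormal(5.5, 1.0, n)
        size = 1 / 0.05
        counts = rng.negative_binomial(size, size / (size + mu[:, None]), (n, 4))
        df = pd.DataFrame(counts, columns=["t1", "t2", "c1", "c2"])
        res = nb_wald_test(df, self._design(), "T", "C")
        frac = (res["p"] < 0.05).mean()
        assert 0.03 <= frac <= 0.07

    def test_power_at_generator_dispersion(self, rng):
        """FC 1.5 at alpha=0.01 and ~500-read genes is comfortably detectable."""
        n = 2000
        mu = rng.lognormal(np.log(500), 0.5, n)
        eff = rng.random(n) < 0.3
        size = 1 / 0.01
        mut = np.where(eff, mu * 1.5, mu)
        t = rng.negative_binomial(size, size / (size + mut[:, None]), (n, 2))
        c = rng.negative_binomial(size, size / (size + mu[:, None]), (n, 2))
        df = pd.DataFrame(np.hstack([t, c]), columns=["t1", "t2", "c1", "c2"])
        # depth is uniform by construction: unit factors isolate test power
        # from median-of-ratios composition bias (covered by pipeline tests)
        unit = pd.Series(1.0, index=df.columns)
        res = nb_wald_test(df, self._design(), "T", "C", factors=unit)
        assert (res["padj"][eff] <= 0.05).mean() >= 0.70

    def test_single_replicate_falls_back_to_trend(self, rng):
        df = pd.DataFrame({"t1": rng.integers(1, 500, 50), "c1": rng.integers(1, 500, 50)})
        res = nb_wald_test(df, {"t1": "T", "c1": "C"}, "T", "C")
        assert res["p"].between(0, 1).all()


class TestClassification:
    @pytest.mark.parametrize(
        "fc,padj,expected",
        [
            (1.30, 0.01, "UP"),
            (1.25, 0.05, "UP"),     # boundaries inclusive
            (0.79, 0.04, "DOWN"),
            (0.80, 0.05, "DOWN"),
            (2.00, 0.20, "NS"),
            (1.10, 0.001, "NS"),
        ],
    )
    def test_dtg_rule(self, fc, padj, expected):
        assert classify_dtg(fc, padj) == expected

    @pytest.mark.parametrize(
        "log2fc,padj,expected",
        [
            (1.2, 1e-4, "UP"),
            (-1.0, 1e-4, "DOWN"),   # boundary included
            (0.9, 1e-9, "NS"),
            (1.5, 0.01, "NS"),
        ],
    )
    def test_deg_rule(self, log2fc, padj, expected):
        assert classify_deg(log2fc, padj) == expected

    @given(fc=st.floats(0.01, 10), padj=st.floats(0, 1))
    @settings(max_examples=100, deadline=None)
    def test_dtg_is_pure_threshold_function(self, fc, padj):
        cls = classify_dtg(fc, padj)
        if cls == "UP":
            assert padj <= 0.05 and fc >= 1.25
        elif cls == "DOWN":
            assert padj <= 0.05 and fc <= 0.8
        else:
            assert padj > 0.05 or 0.8 < fc < 1.25


class TestMATable:
    def test_log2_of_base_mean(self):
        res = pd.DataFrame({"baseMean": [256.0], "log2FC": [1.5]}, index=["g"])
        ma = ma_table(res)
        assert ma.loc["g", "A"] == pytest.approx(8.0)
        assert ma.loc["g", "M"] == 1.5

    def test_empty_input(self):
        ma = ma_table(pd.DataFrame(columns=["baseMean", "log2FC"]))
        assert len(ma) == 0

    def test_class_tallies_consistent(self, rng):
        res = pd.DataFrame(
            {
                "baseMean": rng.lognormal(5, 1, 100),
                "log2FC": rng.normal(0, 1, 100),
                "padj": rng.random(100),
            }
        )
        res["class"] = classify_results(res, rule="dtg")
        ma = ma_table(res)
        assert ma["class"].value_counts().to_dict() == res["class"].value_counts().to_dict()


class TestLengthSummary:
    def test_five_point_example(self):
        (s,) = length_summary({"UP": [1, 2, 3, 4, 5]}).values()
        assert (s.q1, s.median, s.q3) == (2, 3, 4)
        assert (s.whisker_low, s.whisker_high) == (1, 5)
        assert s.outliers == ()

    def test_constant_vector_zero_width_box(self):
        (s,) = length_summary({"UP": [7, 7, 7, 7]}).values()
        assert s.q1 == s.median == s.q3 == 7
        assert s.outliers == ()

    def test_outlier_flagged_beyond_fence(self):
        (s,) = length_summary({"DOWN": [1, 2, 3, 4, 100]}).values()
        # type-7 quartiles of [1,2,3,4,100]: Q1=2, Q3=4, fence=4+1.5*2=7
        assert s.q3 == 4
        assert s.whisker_high == 4
        assert s.outliers == (100,)

    def test_empty_class_omitted(self):
        out = length_summary({"UP": [1, 2, 3], "DOWN": []})
        assert set(out) == {"UP"}

    def test_induced_shorter_than_repressed_detectable(self, rng):
        up = rng.lognormal(np.log(5_000), 0.4, 300)
        down = rng.lognormal(np.log(60_000), 0.4, 300)
        s = length_summary({"UP": up, "DOWN": down})
        assert s["UP"].median < s["DOWN"].median
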